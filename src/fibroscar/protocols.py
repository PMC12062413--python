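"""The study's experiments as runnable protocols.

* the deterministic line-scar conduction test (does a plane wave cross a
  diffusively uncoupled band bridged only by fibroblast units?);
* rapid edge pacing of the circular-scar geometry (T = 300 ms, 6 s)
  followed by NR/BR/PR classification;
* the full parameter sweep (lambda x np x realisation x Gs).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tissue_sim
from .analysis import ClassifierSettings, RegimeLabel, classify_regime
from .link_topology import (LinkSet, REALISATION_SEEDS, TissueGeometry,
                            generate_links)
from .tissue_sim import Recording, SimulationConfig, TissueState

__all__ = ["PacingProtocol", "SweepSpec", "ConductionResult",
           "line_scar_conduction_test", "build_line_scar_bridge",
           "paced_scar_run", "run_sweep", "marginal_fractions",
           "RAPID_PACING_PERIOD_MS", "RAPID_PACING_BEATS"]

RAPID_PACING_PERIOD_MS = 300.0
RAPID_PACING_BEATS = 20           # 6 s of pacing at T = 300 ms
LMAX_MM_DEFAULT = 2.5


@dataclass(frozen=True)
class PacingProtocol:
    """Stimulus schedule: edge / point pacing, an S1S2 train, or none."""

    mode: str = "edge"                      # edge | point | s1s2 | none
    period_ms: float = RAPID_PACING_PERIOD_MS
    n_beats: int = RAPID_PACING_BEATS
    s2_intervals: tuple = ()
    point: tuple | None = None              # (i, j) centre for point pacing
    stim_depth_pts: int = 3                 # edge-strip depth in grid points

    def __post_init__(self):
        if self.mode not in ("edge", "point", "s1s2", "none"):
            raise ValueError(f"unknown pacing mode {self.mode!r}")
        if self.mode != "none":
            if self.period_ms <= 0:
                raise ValueError("pacing period must be > 0")
            if self.n_beats < 1:
                raise ValueError("need at least one beat")

    def stim_times(self) -> list[float]:
        if self.mode == "none":
            return []
        times = [i * self.period_ms for i in range(self.n_beats)]
        if self.mode == "s1s2":
            last = times[-1]
            times += [last + ci for ci in self.s2_intervals]
        return times

    def stim_geometry_mode(self) -> str:
        if self.mode in ("edge", "s1s2"):
            return "edge"
        return self.mode

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def rapid_edge_pacing(cls) -> "PacingProtocol":
        return cls(mode="edge")


# ---------------------------------------------------------------------------
# line-scar conduction test

def build_line_scar_bridge(geom: TissueGeometry, gs_nS: float) -> LinkSet:
    """Deterministic bridging links for a line-scar geometry.

    One fibroblast unit per scar grid point; each unit attaches distally
    to the nearest non-scar point to its left and right in the same row,
    so every scar column is symmetrically linked to both flanks.
    """
    scar = geom.scar_mask
    prox = np.argwhere(scar)
    cols = np.nonzero(scar.any(axis=0))[0]
    jl, jr = cols.min() - 1, cols.max() + 1
    if jl < 0 or jr >= geom.n_cols:
        raise ValueError("line scar must not touch the domain edge")
    ptr = np.zeros(prox.shape[0] + 1, dtype=np.int64)
    distal = []
    for u, (i, _) in enumerate(prox):
        distal.append((i, jl))
        distal.append((i, jr))
        ptr[u + 1] = len(distal)
    return LinkSet(prox_ij=prox, distal_ptr=ptr,
                   distal_ij=np.array(distal, dtype=np.int64),
                   gs_nS=gs_nS, meta={"kind": "deterministic_bridge"})


@dataclass
class ConductionResult:
    conducted: bool
    delay_ms: float              # NaN when blocked
    arrival_pre_ms: float        # wavefront arrival at the proximal flank
    arrival_post_ms: float       # first activation on the distal flank


def line_scar_conduction_test(gs_nS: float, nf: int,
                              geom: TissueGeometry | None = None,
                              vfr_variant: str = "depolarized",
                              duration_ms: float = 600.0,
                              dt_ms: float = 0.01,
                              scar_mode: str = "active") -> ConductionResult:
    """Pace one plane wave from the left edge against a bridged line scar.

    Conducted means the tissue distal (right) of the scar activates;
    the delay is the activation-time difference between the flanking
    columns immediately left and right of the scar (median over rows).
    """
    geom = geom or TissueGeometry.line_scar()
    links = build_line_scar_bridge(geom, gs_nS)
    cfg = SimulationConfig(duration_ms=duration_ms, dt_ms=dt_ms,
                           gs_nS=gs_nS, nf=nf, vfr_variant=vfr_variant,
                           scar_mode=scar_mode,
                           snapshot_cadence_ms=duration_ms)
    protocol = PacingProtocol(mode="edge", period_ms=duration_ms, n_beats=1)
    rec = tissue_sim.run(cfg, geom, links, protocol, record_line=False)

    cols = np.nonzero(geom.scar_mask.any(axis=0))[0]
    jl, jr = cols.min() - 1, cols.max() + 1
    first = np.where(rec.act_n > 0, rec.act_t[0], np.nan)
    pre = float(np.nanmedian(first[:, jl]))
    post_col = first[:, jr]
    distal_active = np.isfinite(first[:, jr:]).any()
    if not distal_active or not np.isfinite(post_col).any():
        return ConductionResult(False, float("nan"), pre, float("nan"))
    post = float(np.nanmedian(post_col))
    return ConductionResult(True, post - pre, pre, post)


# ---------------------------------------------------------------------------
# circular-scar pacing and the parameter sweep

def paced_scar_run(cfg: SimulationConfig, geom: TissueGeometry,
                   links: LinkSet,
                   protocol: PacingProtocol | None = None,
                   settings: ClassifierSettings = ClassifierSettings(),
                   progress: bool = False) -> tuple[Recording, RegimeLabel]:
    """Run the rapid-pacing train on a circular-scar tissue and classify."""
    protocol = protocol or PacingProtocol.rapid_edge_pacing()
    rec = tissue_sim.run(cfg, geom, links, protocol, progress=progress)
    label = classify_regime(
        rec.act_t, rec.act_n, geom, rec.manifest["stim_times"],
        protocol.period_ms,
        lmax_mm=links.meta.get("lmax_mm", LMAX_MM_DEFAULT),
        settings=settings)
    return rec, label


@dataclass(frozen=True)
class SweepSpec:
    """The study's sweep: lambda x np x realisation x Gs (180 runs)."""

    lam_values: tuple = (40.0, 50.0, 60.0)
    np_values: tuple = (10_000, 20_000, 30_000)
    realisations: tuple = (1, 2, 3, 4, 5)
    gs_values: tuple = (1.0, 2.0, 3.0, 4.0)
    lmax_mm: float = LMAX_MM_DEFAULT
    scar_mode: str = "active"
    vfr_variant: str = "depolarized"
    nf: int = 8

    @property
    def n_runs(self) -> int:
        return (len(self.lam_values) * len(self.np_values)
                * len(self.realisations) * len(self.gs_values))

    def rows(self) -> list[dict]:
        """The Cartesian-product enumeration, one dict per run."""
        out = []
        for lam, n_units, real, gs in itertools.product(
                self.lam_values, self.np_values, self.realisations,
                self.gs_values):
            out.append({"lam": lam, "np": n_units, "realisation": real,
                        "gs_nS": gs, "lmax_mm": self.lmax_mm,
                        "scar_mode": self.scar_mode,
                        "vfr_variant": self.vfr_variant, "nf": self.nf,
                        "seed": REALISATION_SEEDS.get(real, 7100 + real)})
        return out


def run_sweep(spec: SweepSpec, geom: TissueGeometry | None = None,
              out_csv: str | Path | None = None,
              duration_ms: float = RAPID_PACING_BEATS
              * RAPID_PACING_PERIOD_MS,
              n_beats: int = RAPID_PACING_BEATS,
              period_ms: float = RAPID_PACING_PERIOD_MS,
              progress: bool = False) -> pd.DataFrame:
    """Run (or resume) the full sweep; one row per parameter combination.

    Individual run failures are recorded in the ``error`` column and the
    sweep continues.  With ``out_csv`` given, completed rows found in an
    existing file are skipped.
    """
    geom = geom or TissueGeometry.circular_scar(200, r_cm=2.0)
    rows = spec.rows()
    done = pd.DataFrame()
    key_cols = ["lam", "np", "realisation", "gs_nS"]
    if out_csv is not None and Path(out_csv).exists():
        done = pd.read_csv(out_csv)
    results = [] if done.empty else done.to_dict("records")
    done_keys = {tuple(r[k] for k in key_cols) for r in results}

    for row in rows:
        key = tuple(row[k] for k in key_cols)
        if key in done_keys:
            continue
        rec_row = dict(row)
        try:
            links = generate_links(geom, int(row["np"]), row["lam"],
                                   row["lmax_mm"], seed=row["seed"],
                                   gs_nS=row["gs_nS"])
            cfg = SimulationConfig(
                duration_ms=duration_ms, gs_nS=row["gs_nS"],
                scar_mode=row["scar_mode"], vfr_variant=row["vfr_variant"],
                nf=row["nf"], seed=row["seed"])
            protocol = PacingProtocol(mode="edge", period_ms=period_ms,
                                      n_beats=n_beats)
            _, label = paced_scar_run(cfg, geom, links, protocol,
                                      progress=progress)
            rec_row.update({"regime": label.label,
                            "retro_components": label.retro_components,
                            "max_retro_distance_mm":
                                label.max_retro_distance_mm,
                            "error": ""})
        except Exception as exc:  # recorded per-row, sweep continues
            rec_row.update({"regime": "", "retro_components": -1,
                            "max_retro_distance_mm": float("nan"),
                            "error": str(exc)})
        results.append(rec_row)
        if out_csv is not None:
            pd.DataFrame(results).to_csv(out_csv, index=False)
        if progress:
            print(f"sweep: {rec_row}", flush=True)
    return pd.DataFrame(results)


def marginal_fractions(table: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Fraction of NR/BR/PR per value of one sweep axis (sums to 1)."""
    ok = table[table["regime"].isin(["NR", "BR", "PR"])]
    frac = (ok.groupby(axis)["regime"]
              .value_counts(normalize=True)
              .unstack(fill_value=0.0))
    for lbl in ("NR", "BR", "PR"):
        if lbl not in frac.columns:
            frac[lbl] = 0.0
    return frac[["NR", "BR", "PR"]]
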