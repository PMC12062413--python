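"""Deterministic fixtures, config handling and file-format round-trips.

Every artefact written carries a schema version and, where applicable,
the generating seed, so any run is regenerable from its manifest alone.
Formats: YAML for configs/manifests, CSV for link tables, plain integer
rasters for masks, HDF5 for recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .link_topology import LinkSet, TissueGeometry, generate_links
from .protocols import build_line_scar_bridge
from .tissue_sim import Recording, SCHEMA_VERSION, SimulationConfig

__all__ = ["FixtureSpec", "make_fixture", "save_config", "load_config",
           "save_links", "load_links", "save_geometry", "load_geometry",
           "save_recording", "load_recording", "roundtrip",
           "write_manifest", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("tiny_strip", "small_circle", "line_scar", "paper_circle")
LINK_FIXTURES = ("none", "deterministic_bridge", "seeded_random")


@dataclass(frozen=True)
class FixtureSpec:
    """A named deterministic test geometry + optional link set."""

    name: str = "tiny_strip"
    link_fixture: str = "none"
    seed: int = 0
    gs_nS: float = 1.0

    def __post_init__(self):
        if self.name not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.name!r}; "
                             f"choose from {FIXTURE_NAMES}")
        if self.link_fixture not in LINK_FIXTURES:
            raise ValueError(f"unknown link fixture {self.link_fixture!r}")


def make_fixture(spec: FixtureSpec):
    """Build (geometry, links-or-None, config) for a named fixture."""
    if spec.name == "tiny_strip":
        geom = TissueGeometry.uniform(12, 60)
        duration = 100.0
    elif spec.name == "small_circle":
        geom = TissueGeometry.circular_scar(100, r_cm=0.5)
        duration = 600.0
    elif spec.name == "line_scar":
        geom = TissueGeometry.line_scar(60, 200)
        duration = 600.0
    else:  # paper_circle: the full study geometry
        geom = TissueGeometry.circular_scar(200, r_cm=2.0)
        duration = 6000.0

    links = None
    if spec.link_fixture == "deterministic_bridge":
        links = build_line_scar_bridge(geom, spec.gs_nS)
    elif spec.link_fixture == "seeded_random":
        n_units = max(50, int(0.75 * geom.scar_mask.sum()))
        links = generate_links(geom, n_units, lam=50.0, lmax_mm=2.5,
                               seed=spec.seed, gs_nS=spec.gs_nS)
    cfg = SimulationConfig(duration_ms=duration, gs_nS=spec.gs_nS,
                           seed=spec.seed)
    return geom, links, cfg


# ---------------------------------------------------------------------------
# round-trippable serialization

def _check_schema(found, path):
    if int(found) != SCHEMA_VERSION:
        raise ValueError(f"{path}: schema version {found} does not match "
                         f"supported version {SCHEMA_VERSION}")


def save_config(cfg: SimulationConfig, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, "kind": "simulation_config",
           "config": cfg.to_dict()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text())
    _check_schema(doc.get("schema_version", -1), path)
    return SimulationConfig(**doc["config"])


def save_links(links: LinkSet, path) -> None:
    rows = []
    for u in range(links.n_units):
        pi, pj = links.prox_ij[u]
        rows.append((u, "proximal", int(pi), int(pj), links.gs_nS))
        for (i, j) in links.distal_of(u):
            rows.append((u, "distal", int(i), int(j), links.gs_nS))
    df = pd.DataFrame(rows, columns=["unit_id", "role", "grid_i", "grid_j",
                                     "gs_nS"])
    with open(path, "w") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        for k, v in sorted(links.meta.items()):
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def load_links(path) -> LinkSet:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = yaml.safe_load(v.strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    _check_schema(meta.pop("schema_version", -1), path)
    n_units = int(df["unit_id"].max()) + 1 if len(df) else 0
    prox = np.zeros((n_units, 2), dtype=np.int64)
    ptr = np.zeros(n_units + 1, dtype=np.int64)
    distal = []
    gs = float(df["gs_nS"].iloc[0]) if len(df) else 1.0
    for u in range(n_units):
        sub = df[df["unit_id"] == u]
        prow = sub[sub["role"] == "proximal"].iloc[0]
        prox[u] = (prow["grid_i"], prow["grid_j"])
        for _, r in sub[sub["role"] == "distal"].iterrows():
            distal.append((int(r["grid_i"]), int(r["grid_j"])))
        ptr[u + 1] = len(distal)
    return LinkSet(prox_ij=prox, distal_ptr=ptr,
                   distal_ij=np.array(distal, dtype=np.int64).reshape(-1, 2),
                   gs_nS=gs, meta=meta)


def save_geometry(geom: TissueGeometry, path) -> None:
    """Scar mask as a plain 0/1 integer raster with a YAML header."""
    hdr = dict(geom.to_dict())
    hdr["schema_version"] = SCHEMA_VERSION
    header = yaml.safe_dump(hdr, sort_keys=True).strip()
    np.savetxt(path, geom.scar_mask.astype(np.int8), fmt="%d",
               header=header)


def load_geometry(path) -> TissueGeometry:
    header_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
            else:
                break
    hdr = yaml.safe_load("\n".join(header_lines))
    _check_schema(hdr.pop("schema_version", -1), path)
    mask = np.loadtxt(path, dtype=np.int8).astype(bool)
    mask = np.atleast_2d(mask)
    return TissueGeometry(n_rows=hdr["n_rows"], n_cols=hdr["n_cols"],
                          scar_mask=mask, dx_mm=hdr["dx_mm"],
                          d_reg=hdr["d_reg"], shape_spec=hdr["shape_spec"])


_REC_ARRAYS = ("t_snap", "v_snap", "line_points", "t_line", "line_v",
               "t_fib", "fib_v", "act_t", "act_n")


def save_recording(rec: Recording, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["manifest"] = yaml.safe_dump(rec.manifest, sort_keys=True)
        for name in _REC_ARRAYS:
            h5.create_dataset(name, data=getattr(rec, name))


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as h5:
        _check_schema(h5.attrs.get("schema_version", -1), path)
        arrays = {name: h5[name][...] for name in _REC_ARRAYS}
        manifest = yaml.safe_load(h5.attrs["manifest"])
    return Recording(manifest=manifest, **arrays)


def roundtrip(obj, path):
    """Write-then-read; returns the reloaded object (identity check is on
    the caller)."""
    if isinstance(obj, SimulationConfig):
        save_config(obj, path)
        return load_config(path)
    if isinstance(obj, LinkSet):
        save_links(obj, path)
        return load_links(path)
    if isinstance(obj, TissueGeometry):
        save_geometry(obj, path)
        return load_geometry(path)
    if isinstance(obj, Recording):
        save_recording(obj, path)
        return load_recording(path)
    raise TypeError(f"cannot round-trip {type(obj).__name__}")


def write_manifest(run_dir, cfg: SimulationConfig, extra: dict | None = None):
    """One manifest per run directory: every parameter and seed."""
    from . import __version__
    doc = {"schema_version": SCHEMA_VERSION, "code_version": __version__,
           "config": cfg.to_dict()}
    if extra:
        doc.update(extra)
    p = Path(run_dir) / "manifest.yaml"
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(yaml.safe_dump(doc, sort_keys=True))
    return p
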