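"""2D monodomain solver: myocyte field + fibroblast units + M-F links.

Forward-Euler integration of the reaction-diffusion myocyte field

    dV/dt = -I_ion/Cm + sum_links Gs (Vf - V)/Cm + div(D grad V)

together with the fibroblast-unit equations

    dVf/dt = -I_f,ion + sum_attachments Gs (V - Vf)/(Nf Cf)

on a square lattice with no-flux boundaries at the domain edges and at
the scar rim (face diffusivity zero whenever either neighbour is scar).
In inactive-scar mode, scar points carry no ionic current and evolve
only through their gap junctions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, maccannell as mac, tp06
from .cell_models import (FibroblastParams, MyocyteParams,
                          STIM_AMPLITUDE_PApF, STIM_DURATION_MS,
                          equilibrate_myocyte)
from .link_topology import LinkSet, TissueGeometry

__all__ = ["SimulationConfig", "TissueState", "Recording",
           "diffusion_term", "face_diffusivities", "step", "run"]

SCHEMA_VERSION = 1


@dataclass
class SimulationConfig:
    """Run parameters for one tissue simulation."""

    duration_ms: float
    dt_ms: float = 0.01
    gs_nS: float = 1.0
    scar_mode: str = "active"            # "active" | "inactive"
    vfr_variant: str = "depolarized"     # fibroblast resting-potential variant
    nf: int = 8
    snapshot_cadence_ms: float = 20.0
    seed: int = 0
    gate_mode: str = "rush_larsen"       # "rush_larsen" | "euler"
    stim_amplitude_pApF: float = STIM_AMPLITUDE_PApF
    stim_duration_ms: float = STIM_DURATION_MS
    equilibrate_ms: float = 2000.0       # 0D pre-pacing quiescent equilibration
    settle_ms: float = 200.0             # coupled tissue relaxation before t=0
    myo_ion_on: bool = True              # debug: freeze all myocyte ionics
    fib_ion_on: bool = True              # debug: freeze fibroblast ionics

    def __post_init__(self):
        if self.dt_ms <= 0 or self.duration_ms < 0:
            raise ValueError("dt must be > 0 and duration >= 0")
        if self.scar_mode not in ("active", "inactive"):
            raise ValueError(f"unknown scar mode {self.scar_mode!r}")
        if self.gate_mode not in ("rush_larsen", "euler"):
            raise ValueError(f"unknown gate mode {self.gate_mode!r}")
        n = self.duration_ms / self.dt_ms
        if abs(n - round(n)) > 1e-6:
            raise ValueError("duration must be a multiple of dt")

    def validate_stability(self, geom: TissueGeometry) -> None:
        # explicit five-point stencil stability bound
        dx_cm = geom.dx_mm / 10.0
        if self.dt_ms * 4.0 * geom.d_reg / dx_cm ** 2 >= 1.0:
            raise ValueError(
                f"unstable configuration: dt*4*D/dx^2 = "
                f"{self.dt_ms * 4 * geom.d_reg / dx_cm ** 2:.3f} >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TissueState:
    """Myocyte field (n_rows, n_cols, 19) plus fibroblast units (K, 3)."""

    U: np.ndarray
    F: np.ndarray
    t_ms: float = 0.0

    @classmethod
    def resting(cls, geom: TissueGeometry, links: LinkSet | None,
                cfg: SimulationConfig,
                myo_params: MyocyteParams | None = None) -> "TissueState":
        """Equilibrated myocyte resting state tiled over the lattice, with
        every fibroblast unit at its variant's uncoupled resting state."""
        myo_params = myo_params or MyocyteParams.shallow()
        if cfg.myo_ion_on:
            u0 = equilibrate_myocyte(myo_params, cfg.equilibrate_ms,
                                     cfg.dt_ms).u
        else:
            u0 = tp06.initial_state()
        U = np.tile(u0, (geom.n_rows, geom.n_cols, 1))
        nfib = links.n_units if links is not None else 0
        if nfib:
            # units start at the myocyte resting voltage and relax into
            # the coupled equilibrium during the settle period, avoiding
            # a spurious coupling-onset transient
            f0 = mac.initial_state(float(u0[tp06.IV]))
            F = np.tile(f0, (nfib, 1))
        else:
            F = np.empty((0, mac.NVARF))
        return cls(U=np.ascontiguousarray(U), F=np.ascontiguousarray(F))

    @property
    def v_field(self) -> np.ndarray:
        return self.U[:, :, tp06.IV]

    @property
    def vf(self) -> np.ndarray:
        return self.F[:, mac.FV]

    def copy(self) -> "TissueState":
        return TissueState(self.U.copy(), self.F.copy(), self.t_ms)


def face_diffusivities(geom: TissueGeometry):
    """Face diffusivity arrays divided by dx^2 (1/ms); zero on any face
    touching a scar point and on the domain border."""
    d = geom.diffusion_field()  # cm^2/ms
    dx_cm = geom.dx_mm / 10.0
    inv = 1.0 / dx_cm ** 2
    n, m = d.shape
    xf = np.zeros((n, m + 1))
    yf = np.zeros((n + 1, m))
    both = np.minimum(d[:, :-1], d[:, 1:])   # 0 if either neighbour is scar
    xf[:, 1:m] = both * inv
    both = np.minimum(d[:-1, :], d[1:, :])
    yf[1:n, :] = both * inv
    return xf, yf


def diffusion_term(v_field: np.ndarray, geom: TissueGeometry) -> np.ndarray:
    """div(D grad V) (mV/ms) with no-flux edges and scar rim; vectorized
    reference implementation of the kernel's stencil."""
    v = np.asarray(v_field, dtype=float)
    if v.shape != (geom.n_rows, geom.n_cols):
        raise ValueError("field shape does not match geometry")
    xf, yf = face_diffusivities(geom)
    out = np.zeros_like(v)
    out[:, :-1] += xf[:, 1:-1] * (v[:, 1:] - v[:, :-1])
    out[:, 1:] -= xf[:, 1:-1] * (v[:, 1:] - v[:, :-1])
    out[:-1, :] += yf[1:-1, :] * (v[1:, :] - v[:-1, :])
    out[1:, :] -= yf[1:-1, :] * (v[1:, :] - v[:-1, :])
    return out


@dataclass
class Recording:
    """Everything a paced run leaves behind.

    Datasets: down-sampled voltage snapshots, full-rate line traces
    along the sampling line, fibroblast voltages at snapshot cadence,
    and the per-grid-point activation log.
    """

    t_snap: np.ndarray            # (nsnap,)
    v_snap: np.ndarray            # (nsnap, n_rows, n_cols) float32
    line_points: np.ndarray       # (ns, 2)
    t_line: np.ndarray            # (nt_line,)
    line_v: np.ndarray            # (nt_line, ns) float32
    t_fib: np.ndarray             # (nsnap,)
    fib_v: np.ndarray             # (nsnap, K) float32
    act_t: np.ndarray             # (Amax, n_rows, n_cols), NaN-padded
    act_n: np.ndarray             # (n_rows, n_cols) int32
    manifest: dict = field(default_factory=dict)

    def final_v(self) -> np.ndarray:
        return self.v_snap[-1]


def _stim_mask(geom: TissueGeometry, mode: str, depth: int = 3,
               point=None, block: int = 5) -> np.ndarray:
    mask = np.zeros((geom.n_rows, geom.n_cols), dtype=bool)
    if mode == "edge":
        mask[:, :depth] = True
    elif mode == "point":
        ci, cj = point if point is not None else (geom.n_rows // 2, block)
        h = block // 2
        mask[max(0, ci - h):ci + h + 1, max(0, cj - h):cj + h + 1] = True
    elif mode == "none":
        pass
    else:
        raise ValueError(f"unknown stimulus mode {mode!r}")
    mask &= ~geom.scar_mask
    return mask


def step(state: TissueState, cfg: SimulationConfig, geom: TissueGeometry,
         links: LinkSet | None, stim_field: np.ndarray | None = None,
         n_steps: int = 1) -> TissueState:
    """Advance ``n_steps`` forward-Euler steps in place.

    ``stim_field`` is an optional boolean mask receiving the configured
    stimulus current for the whole call.  Pacing runs go through
    :func:`run`; this is the single-step surface for tests and custom
    drivers.
    """
    if stim_field is not None:
        starts = np.array([state.t_ms])
        dur = n_steps * cfg.dt_ms
        cfg = dataclasses.replace(cfg, stim_duration_ms=max(
            cfg.stim_duration_ms, dur))
    else:
        starts = np.empty(0)
    _advance(state, cfg, geom, links, stim_starts=starts, nsteps=n_steps,
             line_points=np.empty((0, 2), dtype=np.int64), act_cap=4,
             stim_mask=stim_field)
    return state


def _advance(state, cfg, geom, links, stim_starts, nsteps, line_points,
             act_cap, stim_mask=None, myo_params=None, line_buf=None,
             line_pos=0, act_t=None, act_n=None, last_act=None):
    myo_params = myo_params or MyocyteParams.shallow()
    p = myo_params.as_array()
    fp = FibroblastParams.for_variant(cfg.vfr_variant, nf=cfg.nf).as_array()
    xf, yf = face_diffusivities(geom)
    if links is not None:
        if state.F.shape[0] < links.n_units:
            raise ValueError(
                f"state has {state.F.shape[0]} fibroblast units but the "
                f"link set references {links.n_units}")
        li, lj, lu, lg = links.flat_links(geom.n_cols)
        # Nf parallel fibroblasts each form their own Gs junction, so a
        # unit's effective link conductance is Nf*Gs; the unit equation
        # (divided by Nf*Cf in the kernel) then reduces to the
        # per-fibroblast form dVf/dt = -I_ion + Gs(V - Vf)/Cf.
        lg = np.full(li.shape[0], cfg.gs_nS * cfg.nf)
    else:
        li = lj = lu = np.empty(0, dtype=np.int64)
        lg = np.empty(0)
    if stim_mask is None:
        stim_mask = np.zeros((geom.n_rows, geom.n_cols), dtype=bool)
    if line_buf is None:
        line_buf = np.empty((nsteps, line_points.shape[0]), dtype=np.float32)
    if act_t is None:
        act_t = np.full((act_cap, geom.n_rows, geom.n_cols), np.nan)
        act_n = np.zeros((geom.n_rows, geom.n_cols), dtype=np.int32)
        last_act = np.full((geom.n_rows, geom.n_cols), -1e18)
    gm = 0 if cfg.gate_mode == "rush_larsen" else 1
    tab = tp06.build_tables(cfg.dt_ms, gm, myo_params.tau_f_scale,
                            myo_params.tau_f2_scale)
    code, bi, bj = _kernels.advance(
        state.U, state.F, p, fp, xf, yf, cfg.dt_ms, state.t_ms, nsteps,
        geom.scar_mask, cfg.scar_mode == "inactive",
        cfg.myo_ion_on, cfg.fib_ion_on,
        li, lj, lu, lg,
        stim_mask, np.asarray(stim_starts, dtype=float),
        cfg.stim_duration_ms, cfg.stim_amplitude_pApF,
        line_points[:, 0].astype(np.int64).copy()
        if line_points.size else np.empty(0, dtype=np.int64),
        line_points[:, 1].astype(np.int64).copy()
        if line_points.size else np.empty(0, dtype=np.int64),
        line_buf, line_pos,
        act_t, act_n, -40.0, 50.0, last_act, gm, tab)
    state.t_ms += nsteps * cfg.dt_ms
    if code != 0:
        raise FloatingPointError(
            f"solver blow-up at t = {state.t_ms:.2f} ms, "
            f"grid point ({bi}, {bj})")
    v = state.U[:, :, tp06.IV]
    bad = ~np.isfinite(v) | (np.abs(v) > 1.0e3)
    if bad.any():
        bi, bj = np.argwhere(bad)[0]
        raise FloatingPointError(
            f"solver blow-up by t = {state.t_ms:.2f} ms, "
            f"grid point ({bi}, {bj})")
    if state.F.size and not np.isfinite(state.F[:, mac.FV]).all():
        k = int(np.argwhere(~np.isfinite(state.F[:, mac.FV]))[0])
        raise FloatingPointError(
            f"solver blow-up by t = {state.t_ms:.2f} ms, "
            f"fibroblast unit {k}")
    return act_t, act_n, last_act, line_buf


def run(cfg: SimulationConfig, geom: TissueGeometry,
        links: LinkSet | None = None, protocol=None,
        state: TissueState | None = None,
        myo_params: MyocyteParams | None = None,
        record_line: bool = True, progress: bool = False) -> Recording:
    """Run a full pacing protocol and return the Recording.

    Identical (cfg, geometry, links, protocol) give identical results;
    all randomness lives in the link generation, not in the solver.
    """
    from .protocols import PacingProtocol

    protocol = protocol or PacingProtocol(mode="none")
    cfg.validate_stability(geom)
    myo_params = myo_params or MyocyteParams.shallow()
    if state is None:
        state = TissueState.resting(geom, links, cfg, myo_params)
        if cfg.settle_ms > 0:
            # coupled relaxation on negative time; the recording and the
            # activation log start at t = 0
            state.t_ms = -cfg.settle_ms
            _advance(state, cfg, geom, links, np.empty(0),
                     int(round(cfg.settle_ms / cfg.dt_ms)),
                     np.empty((0, 2), dtype=np.int64), act_cap=8,
                     myo_params=myo_params)
            state.t_ms = 0.0

    stim_mask = _stim_mask(geom, protocol.stim_geometry_mode(),
                           depth=getattr(protocol, "stim_depth_pts", 3),
                           point=protocol.point)
    stim_starts = np.asarray(protocol.stim_times(), dtype=float) + state.t_ms

    nsteps_total = int(round(cfg.duration_ms / cfg.dt_ms))
    snap_stride = max(1, int(round(cfg.snapshot_cadence_ms / cfg.dt_ms)))

    if record_line and geom.scar_mask.any():
        line_points = geom.sampling_line()
    else:
        line_points = np.empty((0, 2), dtype=np.int64)
    line_buf = np.empty((nsteps_total, line_points.shape[0]),
                        dtype=np.float32)

    act_cap = int(cfg.duration_ms / 250.0) + 4
    act_t = np.full((act_cap, geom.n_rows, geom.n_cols), np.nan)
    act_n = np.zeros((geom.n_rows, geom.n_cols), dtype=np.int32)
    last_act = np.full((geom.n_rows, geom.n_cols), -1e18)

    t_snap, v_snap, fib_v = [], [], []
    t0 = state.t_ms
    pos = 0
    while pos < nsteps_total:
        t_snap.append(state.t_ms)
        v_snap.append(state.v_field.astype(np.float32).copy())
        fib_v.append(state.vf.astype(np.float32).copy())
        chunk = min(snap_stride, nsteps_total - pos)
        _advance(state, cfg, geom, links, stim_starts, chunk, line_points,
                 act_cap, stim_mask=stim_mask, myo_params=myo_params,
                 line_buf=line_buf, line_pos=pos, act_t=act_t, act_n=act_n,
                 last_act=last_act)
        pos += chunk
        if progress:
            print(f"  t = {state.t_ms:.0f} / {t0 + cfg.duration_ms:.0f} ms",
                  flush=True)
    t_snap.append(state.t_ms)
    v_snap.append(state.v_field.astype(np.float32).copy())
    fib_v.append(state.vf.astype(np.float32).copy())

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": cfg.to_dict(),
        "geometry": geom.to_dict(),
        "protocol": protocol.to_dict(),
        "links_meta": dict(links.meta) if links is not None else None,
        "myocyte_params": myo_params.to_dict(),
        "stim_times": [float(s) for s in stim_starts],
    }
    return Recording(
        t_snap=np.asarray(t_snap),
        v_snap=np.stack(v_snap),
        line_points=line_points,
        t_line=t0 + np.arange(nsteps_total) * cfg.dt_ms,
        line_v=line_buf,
        t_fib=np.asarray(t_snap),
        fib_v=np.stack(fib_v) if fib_v else np.empty((0, 0)),
        act_t=act_t, act_n=act_n,
        manifest=manifest,
    )
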