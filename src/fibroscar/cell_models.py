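"""Public single-cell surface: myocyte and fibroblast models and their coupling.

The myocyte is the TP06 human ventricular cell (epicardial, Shallow
restitution parameter set, see :mod:`fibroscar.tp06`); the fibroblast is
the MacCannell active model (:mod:`fibroscar.maccannell`).  A gap
junction of conductance ``Gs`` (nS) between a myocyte (capacitance Cm)
and a fibroblast unit of ``Nf`` parallel fibroblasts (capacitance Nf*Cf)
injects ``Gs*(Vf - V)`` pA into the myocyte and the exact negative into
the fibroblast unit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import brentq

from . import maccannell as mac
from . import tp06

__all__ = [
    "MyocyteParams", "MyocyteState", "FibroblastParams", "FibroblastState",
    "myocyte_currents", "fibroblast_currents", "coupling_current",
    "calibrate_vfr_shift", "equilibrate_myocyte", "run_single_cell",
    "s1s2_restitution", "RestitutionPoint", "RestitutionResult",
    "DEPOLARIZED_KV_SHIFT", "HYPERPOLARIZED_KV_SHIFT",
    "STIM_AMPLITUDE_PApF", "STIM_DURATION_MS",
]

MYOCYTE_CURRENT_NAMES = (
    "i_na", "i_to", "i_k1", "i_kr", "i_ks", "i_cal",
    "i_naca", "i_nak", "i_pca", "i_pk", "i_bca", "i_bna",
)
FIBROBLAST_CURRENT_NAMES = ("i_fk1", "i_fkv", "i_fnak", "i_fbna")

#: Kv gating-voltage shifts (mV) calibrated once with
#: :func:`calibrate_vfr_shift` so that the uncoupled unit rests at the
#: two study resting potentials; stored as constants so tissue runs are
#: deterministic and do not re-run the calibration.
DEPOLARIZED_KV_SHIFT = 34.716794    # -> Vf_rest = -24.5 mV
HYPERPOLARIZED_KV_SHIFT = -0.098522  # -> Vf_rest = -49.0 mV

#: default stimulus: ~2x diastolic threshold, applied as an inward
#: (depolarizing) current density for 1 ms
STIM_AMPLITUDE_PApF = -52.0
STIM_DURATION_MS = 1.0


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class MyocyteParams:
    """TP06 conductances/rates (nS/pF unless noted) and capacitance (pF)."""

    g_na: float = tp06.EPI_BASELINE["g_na"]
    g_to: float = tp06.EPI_BASELINE["g_to"]
    g_k1: float = tp06.EPI_BASELINE["g_k1"]
    g_kr: float = tp06.SHALLOW_OVERRIDES["g_kr"]
    g_ks: float = tp06.SHALLOW_OVERRIDES["g_ks"]
    g_cal: float = tp06.EPI_BASELINE["g_cal"]
    k_naca: float = tp06.EPI_BASELINE["k_naca"]
    k_nak: float = tp06.EPI_BASELINE["k_nak"]
    g_pca: float = tp06.SHALLOW_OVERRIDES["g_pca"]
    g_pk: float = tp06.SHALLOW_OVERRIDES["g_pk"]
    g_bca: float = tp06.EPI_BASELINE["g_bca"]
    g_bna: float = tp06.EPI_BASELINE["g_bna"]
    cm_pF: float = tp06.EPI_BASELINE["cm_pF"]
    tau_f_scale: float = tp06.SHALLOW_OVERRIDES.get("tau_f_scale", 1.0)
    tau_f2_scale: float = tp06.SHALLOW_OVERRIDES.get("tau_f2_scale", 1.0)
    variant: str = "Shallow"

    def __post_init__(self):
        for f_ in dataclasses.fields(self):
            if f_.name == "variant":
                continue
            v = getattr(self, f_.name)
            if not (v >= 0.0 and math.isfinite(v)):
                raise ValueError(f"{f_.name} must be finite and >= 0, got {v}")
        if self.cm_pF <= 0:
            raise ValueError("cm_pF must be > 0")

    @classmethod
    def shallow(cls) -> "MyocyteParams":
        return cls()

    def as_array(self) -> np.ndarray:
        return tp06.param_array_from_dict(self.to_dict())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MyocyteParams":
        return cls(**d)


@dataclass
class MyocyteState:
    """TP06 state: V (mV), 12 gates in [0,1], concentrations (mM)."""

    u: np.ndarray = field(default_factory=tp06.initial_state)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (tp06.NVAR,):
            raise ValueError(f"state must have shape ({tp06.NVAR},)")

    @property
    def v(self) -> float:
        return float(self.u[tp06.IV])

    def __getattr__(self, name):
        try:
            idx = tp06.STATE_NAMES.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return float(self.u[idx])

    def copy(self) -> "MyocyteState":
        return MyocyteState(self.u.copy())

    def validate(self) -> None:
        for idx, name in enumerate(tp06.STATE_NAMES):
            x = self.u[idx]
            if not np.isfinite(x):
                raise ValueError(f"non-finite state variable {name!r}: {x}")
        for idx in tp06.GATE_IDX:
            if not (0.0 <= self.u[idx] <= 1.0):
                raise ValueError(
                    f"gate {tp06.STATE_NAMES[idx]!r} out of [0,1]: {self.u[idx]}")
        for idx in (tp06.ICAI, tp06.ICASR, tp06.ICASS, tp06.INAI, tp06.IKI):
            if self.u[idx] <= 0.0:
                raise ValueError(
                    f"concentration {tp06.STATE_NAMES[idx]!r} must be > 0")


@dataclass(frozen=True)
class FibroblastParams:
    """MacCannell conductances, per-fibroblast capacitance and Nf lumping."""

    g_fk1: float = mac.BASELINE["g_fk1"]
    g_fkv: float = mac.BASELINE["g_fkv"]
    i_fnak_max: float = mac.BASELINE["i_fnak_max"]
    g_fbna: float = mac.BASELINE["g_fbna"]
    cf_pF: float = 50.0
    nf: int = 8
    kv_shift_mV: float = DEPOLARIZED_KV_SHIFT
    variant: str = "depolarized"

    def __post_init__(self):
        if self.cf_pF <= 0:
            raise ValueError("cf_pF must be > 0")
        if self.nf < 1:
            raise ValueError("nf must be >= 1")
        for name in ("g_fk1", "g_fkv", "i_fnak_max", "g_fbna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.variant not in ("depolarized", "hyperpolarized", "custom"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @classmethod
    def depolarized(cls, nf: int = 8) -> "FibroblastParams":
        """Study variant with uncoupled resting potential -24.5 mV."""
        return cls(nf=nf, kv_shift_mV=DEPOLARIZED_KV_SHIFT,
                   variant="depolarized")

    @classmethod
    def hyperpolarized(cls, nf: int = 8) -> "FibroblastParams":
        """Study variant with uncoupled resting potential -49.0 mV."""
        return cls(nf=nf, kv_shift_mV=HYPERPOLARIZED_KV_SHIFT,
                   variant="hyperpolarized")

    @classmethod
    def for_variant(cls, variant: str, nf: int = 8) -> "FibroblastParams":
        if variant == "depolarized":
            return cls.depolarized(nf=nf)
        if variant == "hyperpolarized":
            return cls.hyperpolarized(nf=nf)
        raise ValueError(f"unknown VFR variant {variant!r}")

    @property
    def unit_capacitance_pF(self) -> float:
        return self.nf * self.cf_pF

    def as_array(self) -> np.ndarray:
        return mac.param_array_from_dict({
            "g_fk1": self.g_fk1, "g_fkv": self.g_fkv,
            "i_fnak_max": self.i_fnak_max, "g_fbna": self.g_fbna,
            "cf_pF": self.cf_pF, "nf": float(self.nf),
            "kv_shift_mV": self.kv_shift_mV,
        })

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FibroblastParams":
        return cls(**d)


@dataclass
class FibroblastState:
    """Fibroblast unit state: Vf (mV) and the two Kv gates r, s."""

    f: np.ndarray = field(default_factory=lambda: mac.initial_state())

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (mac.NVARF,):
            raise ValueError(f"state must have shape ({mac.NVARF},)")

    @property
    def vf(self) -> float:
        return float(self.f[mac.FV])

    @property
    def r(self) -> float:
        return float(self.f[mac.FR])

    @property
    def s(self) -> float:
        return float(self.f[mac.FS])

    def copy(self) -> "FibroblastState":
        return FibroblastState(self.f.copy())

    def validate(self) -> None:
        if not np.all(np.isfinite(self.f)):
            name = ("Vf", "r", "s")[int(np.argmax(~np.isfinite(self.f)))]
            raise ValueError(f"non-finite state variable {name!r}")
        for i, name in ((mac.FR, "r"), (mac.FS, "s")):
            if not (0.0 <= self.f[i] <= 1.0):
                raise ValueError(f"gate {name!r} out of [0,1]: {self.f[i]}")


# ---------------------------------------------------------------------------
# bundled parameter files (human-readable key-value configs, one per variant)

def _load_param_file(name: str) -> dict:
    import importlib.resources as res

    import yaml

    text = (res.files("fibroscar") / "params" / f"{name}.yaml").read_text()
    doc = yaml.safe_load(text)
    if doc.get("schema_version") != 1:
        raise ValueError(f"unsupported schema in bundled params {name!r}")
    return doc


def load_myocyte_params(name: str = "shallow_myocyte") -> MyocyteParams:
    doc = _load_param_file(name)
    if doc["kind"] != "myocyte_params":
        raise ValueError(f"{name!r} is not a myocyte parameter file")
    return MyocyteParams.from_dict(doc["params"])


def load_fibroblast_params(name: str) -> FibroblastParams:
    doc = _load_param_file(name)
    if doc["kind"] != "fibroblast_params":
        raise ValueError(f"{name!r} is not a fibroblast parameter file")
    return FibroblastParams.from_dict(doc["params"])


# ---------------------------------------------------------------------------
def myocyte_currents(state: MyocyteState, params: MyocyteParams) -> dict:
    """Per-current breakdown (pA/pF) plus the total under key ``i_ion``."""
    state.validate()
    vals = tp06.tp06_currents(state.u, params.as_array())
    out = dict(zip(MYOCYTE_CURRENT_NAMES, (float(x) for x in vals)))
    out["i_ion"] = float(sum(vals))
    return out


def fibroblast_currents(state: FibroblastState,
                        params: FibroblastParams) -> dict:
    """Per-current breakdown (pA/pF) plus the total under key ``i_ion``."""
    state.validate()
    vals = mac.fib_currents(state.vf, state.r, state.s, params.as_array())
    out = dict(zip(FIBROBLAST_CURRENT_NAMES, (float(x) for x in vals)))
    out["i_ion"] = float(sum(vals))
    return out


def coupling_current(v_mV: float, vf_mV: float, gs_nS: float) -> float:
    """Gap-junction current into the myocyte, pA; fibroblast gets the negative."""
    if gs_nS < 0:
        raise ValueError(f"Gs must be >= 0, got {gs_nS}")
    return gs_nS * (vf_mV - v_mV)


def fibroblast_resting_potential(params: FibroblastParams,
                                 shift: float | None = None) -> float:
    """Uncoupled steady-state Vf (mV) with Kv gates at their steady values."""
    p = params.as_array()
    s = params.kv_shift_mV if shift is None else shift
    return float(brentq(lambda v: mac.steady_current(v, s, p), -95.0, 40.0,
                        xtol=1e-10))


_SHIFT_BRACKET = (-5.0, 60.0)


def calibrate_vfr_shift(params: FibroblastParams, target_vfr_mV: float,
                        tol_mV: float = 0.1) -> float:
    """Kv gating shift (mV) giving an uncoupled resting potential of target.

    Searched on the depolarizing branch (shift in [-5, 60] mV), where the
    resting potential increases monotonically with the shift; raises with
    the achievable range if the target lies outside it.
    """
    if not (-60.0 <= target_vfr_mV <= -10.0):
        raise ValueError("target resting potential must lie in [-60, -10] mV")
    lo, hi = _SHIFT_BRACKET
    vlo = fibroblast_resting_potential(params, shift=lo)
    vhi = fibroblast_resting_potential(params, shift=hi)
    if not (vlo - tol_mV <= target_vfr_mV <= vhi + tol_mV):
        raise ValueError(
            f"target {target_vfr_mV} mV unreachable by Kv shift; achievable "
            f"range is [{vlo:.2f}, {vhi:.2f}] mV")
    p = params.as_array()
    shift = brentq(lambda s: mac.steady_current(target_vfr_mV, s, p), lo, hi,
                   xtol=1e-9)
    achieved = fibroblast_resting_potential(params, shift=shift)
    if abs(achieved - target_vfr_mV) > tol_mV:
        raise RuntimeError(
            f"calibration failed: achieved {achieved:.3f} mV for target "
            f"{target_vfr_mV} mV")
    return float(shift)


# ---------------------------------------------------------------------------
# 0D integration drivers (njit inner loops)

@njit(cache=True)
def _run0d(u, p, fstates, fp, gs, dt, nsteps, t0, stim_starts, stim_dur,
           stim_amp, rec_stride, v_out, vf_out, gate_mode):
    cm = p[tp06.PCM]
    nf_cf = fp[mac.FNF] * fp[mac.FCF]
    # Nf parallel fibroblasts per unit, each with its own Gs junction:
    # the unit injects Nf*Gs*(Vf - V) into the myocyte and obeys
    # dVf/dt = -I_ion + Gs(V - Vf)/Cf.
    gs_unit = gs * fp[mac.FNF]
    nfib = fstates.shape[0]
    irec = 0
    for istep in range(nsteps):
        t = t0 + istep * dt
        istim = 0.0
        for k in range(stim_starts.shape[0]):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                istim = stim_amp
                break
        v = u[tp06.IV]
        dv_extra = 0.0
        for k in range(nfib):
            imyo = gs_unit * (fstates[k, mac.FV] - v)  # pA into myocyte
            dv_extra += imyo / cm
            mac.fib_step(fstates[k], fp, dt, -imyo / nf_cf, gate_mode)
        tp06.tp06_step(u, p, dt, istim, dv_extra, gate_mode, True)
        if rec_stride > 0 and istep % rec_stride == 0:
            v_out[irec] = u[tp06.IV]
            if nfib > 0:
                vf_out[irec] = fstates[0, mac.FV]
            irec += 1
    return irec


def run_single_cell(state: MyocyteState, params: MyocyteParams,
                    duration_ms: float, dt: float = 0.01,
                    stim_times=(), stim_amplitude: float = STIM_AMPLITUDE_PApF,
                    stim_duration: float = STIM_DURATION_MS,
                    fibroblasts: list[FibroblastState] | None = None,
                    fib_params: FibroblastParams | None = None,
                    gs_nS: float = 0.0, t0: float = 0.0,
                    record_dt: float | None = 0.1,
                    gate_mode: str = "rush_larsen"):
    """Integrate one myocyte (optionally coupled to fibroblast units) in place.

    Returns ``(t, V, Vf)`` arrays sampled every ``record_dt`` ms (Vf is
    None when no fibroblasts are attached; with several units the first
    one is recorded).  ``record_dt=None`` disables recording.
    """
    if gs_nS < 0:
        raise ValueError("Gs must be >= 0")
    nsteps = int(round(duration_ms / dt))
    gm = 0 if gate_mode == "rush_larsen" else 1
    if fibroblasts:
        fst = np.stack([f.f for f in fibroblasts])
        fp = (fib_params or FibroblastParams.depolarized()).as_array()
    else:
        fst = np.empty((0, mac.NVARF))
        fp = FibroblastParams.depolarized().as_array()
    rec_stride = 0 if record_dt is None else max(1, int(round(record_dt / dt)))
    nrec = 0 if rec_stride == 0 else (nsteps + rec_stride - 1) // rec_stride
    v_out = np.empty(nrec)
    vf_out = np.empty(nrec)
    starts = np.asarray(list(stim_times), dtype=float)
    n = _run0d(state.u, params.as_array(), fst, fp, gs_nS, dt, nsteps, t0,
               starts, stim_duration, stim_amplitude, rec_stride, v_out,
               vf_out, gm)
    if fibroblasts:
        for k, f in enumerate(fibroblasts):
            f.f[:] = fst[k]
    if rec_stride == 0:
        return None, None, None
    t = t0 + np.arange(n) * rec_stride * dt
    return t, v_out[:n], (vf_out[:n] if fibroblasts else None)


def equilibrate_myocyte(params: MyocyteParams | None = None,
                        duration_ms: float = 2000.0,
                        dt: float = 0.01) -> MyocyteState:
    """Published initial conditions followed by quiescent equilibration."""
    params = params or MyocyteParams.shallow()
    st = MyocyteState()
    run_single_cell(st, params, duration_ms, dt=dt, record_dt=None)
    return st


# ---------------------------------------------------------------------------
# S1S2 restitution

@dataclass(frozen=True)
class RestitutionPoint:
    s2_interval_ms: float
    di_ms: float
    apd_ms: float
    captured: bool


@dataclass
class RestitutionResult:
    points: list[RestitutionPoint]
    max_slope: float
    s1_apd_ms: float

    def curve(self) -> np.ndarray:
        """(DI, APD) pairs for captured beats, sorted by DI."""
        pts = [(p.di_ms, p.apd_ms) for p in self.points if p.captured]
        return np.array(sorted(pts))


DEFAULT_DI_GRID = (
    2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0,
    60.0, 80.0, 100.0, 150.0, 200.0, 300.0, 500.0, 800.0,
)


def max_restitution_slope(di: np.ndarray, apd: np.ndarray) -> float:
    """Maximum finite-difference slope of an APD(DI) table."""
    order = np.argsort(di)
    di = np.asarray(di, dtype=float)[order]
    apd = np.asarray(apd, dtype=float)[order]
    if di.size < 2:
        return float("nan")
    slopes = np.diff(apd) / np.diff(di)
    return float(np.max(slopes))


def s1s2_restitution(params: MyocyteParams | None = None,
                     s1_period_ms: float = 1000.0, n_s1: int = 10,
                     s2_intervals=None, di_grid=DEFAULT_DI_GRID,
                     dt: float = 0.01,
                     fib_params: FibroblastParams | None = None,
                     n_fib_units: int = 0, gs_nS: float = 0.0,
                     ) -> RestitutionResult:
    """Standard S1S2 APD-restitution protocol on a single (optionally
    fibroblast-coupled) myocyte.

    An S1 train of ``n_s1`` beats establishes periodic steady state, a
    single premature S2 follows at a range of coupling intervals, and
    APD90 of the S2 beat is tabulated against the diastolic interval.
    S2 beats that fail to capture are flagged, not dropped.
    """
    from .analysis import apd90_of_beat, detect_activations

    if n_s1 < 10:
        raise ValueError("S1 train must have at least 10 beats")
    params = params or MyocyteParams.shallow()
    st = equilibrate_myocyte(params, dt=dt)
    fibs = [FibroblastState(mac.initial_state(-24.5))
            for _ in range(n_fib_units)]

    # S1 train up to (and including) the last S1 beat
    stim_times = [i * s1_period_ms for i in range(n_s1)]
    run_single_cell(st, params, stim_times[-1], dt=dt,
                    stim_times=stim_times[:-1], record_dt=None,
                    fibroblasts=fibs, fib_params=fib_params, gs_nS=gs_nS)
    base = st  # state at onset of the last S1 stimulus
    base_fibs = [f.copy() for f in fibs]

    # last S1 beat alone, long horizon, to measure steady APD
    st1 = base.copy()
    t, v, _ = run_single_cell(st1, params, s1_period_ms + 400.0, dt=dt,
                              stim_times=(0.0,), record_dt=0.1,
                              fibroblasts=[f.copy() for f in base_fibs],
                              fib_params=fib_params, gs_nS=gs_nS)
    acts = detect_activations(t, v)
    if len(acts) == 0:
        raise RuntimeError("S1 beat did not capture")
    s1_apd = apd90_of_beat(t, v, acts[0])

    if s2_intervals is None:
        s2_intervals = [s1_apd + di for di in di_grid]

    points = []
    for ci in sorted(s2_intervals):
        stc = base.copy()
        fc = [f.copy() for f in base_fibs]
        t, v, _ = run_single_cell(stc, params, ci + 600.0, dt=dt,
                                  stim_times=(0.0, ci), record_dt=0.1,
                                  fibroblasts=fc, fib_params=fib_params,
                                  gs_nS=gs_nS)
        acts = detect_activations(t, v)
        di = ci - s1_apd
        s2_acts = [a for a in acts if a >= ci - 2.0]
        if len(s2_acts) == 0:
            points.append(RestitutionPoint(ci, di, float("nan"), False))
            continue
        apd = apd90_of_beat(t, v, s2_acts[0])
        # graded (non-overshooting) responses count as failure to capture
        i0 = int(np.searchsorted(t, s2_acts[0]))
        captured = bool(np.max(v[i0:]) > 0.0) and np.isfinite(apd)
        points.append(RestitutionPoint(ci, di, apd, captured))

    cap = [(p.di_ms, p.apd_ms) for p in points if p.captured]
    if len(cap) >= 2:
        arr = np.array(cap)
        slope = max_restitution_slope(arr[:, 0], arr[:, 1])
    else:
        slope = float("nan")
    return RestitutionResult(points=points, max_slope=slope, s1_apd_ms=s1_apd)


DEFAULT_DYNAMIC_CLS = (
    1000.0, 800.0, 600.0, 500.0, 450.0, 400.0, 370.0, 340.0, 320.0, 300.0,
    285.0, 270.0, 260.0, 250.0, 240.0, 230.0, 220.0, 210.0, 200.0,
)


def dynamic_restitution(params: MyocyteParams | None = None,
                        cls_ms=DEFAULT_DYNAMIC_CLS, n_beats: int = 30,
                        alternans_thresh_ms: float = 5.0,
                        dt: float = 0.01) -> RestitutionResult:
    """Steady-pacing (beat-to-beat) restitution: APD vs DI at decreasing CL.

    This is the restitution measure that labels the myocyte variants:
    the cell is paced to an approximately periodic state at each cycle
    length in descending order (state carried over, as in the standard
    dynamic protocol) and the last beats' APD90 is plotted against the
    preceding diastolic interval.  The protocol stops at the onset of
    alternans or loss of 1:1 capture, where a single steady APD no
    longer exists; the maximum finite-difference slope is taken over the
    retained 1:1 branch.
    """
    from .analysis import apd90_of_beat, detect_activations

    params = params or MyocyteParams.shallow()
    st = equilibrate_myocyte(params, dt=dt)
    points = []
    for cl in sorted(cls_ms, reverse=True):
        stim = [i * cl for i in range(n_beats)]
        t, v, _ = run_single_cell(st, params, n_beats * cl, dt=dt,
                                  stim_times=stim, record_dt=0.25)
        acts = detect_activations(t, v)
        if len(acts) < n_beats - 1:       # loss of 1:1 capture
            break
        tail = acts[-7:]
        apds = np.array([apd90_of_beat(t, v, a, b)
                         for a, b in zip(tail[:-1], tail[1:])])
        apds = apds[np.isfinite(apds)]
        if apds.size < 4:
            break
        if abs(np.mean(apds[-4::2]) - np.mean(apds[-3::2])) \
                > alternans_thresh_ms:    # alternans onset
            break
        apd = float(np.mean(apds[-2:]))
        points.append(RestitutionPoint(cl, cl - apd, apd, True))
    if len(points) < 2:
        return RestitutionResult(points=points, max_slope=float("nan"),
                                 s1_apd_ms=float("nan"))
    arr = np.array([(p.di_ms, p.apd_ms) for p in points])
    slope = max_restitution_slope(arr[:, 0], arr[:, 1])
    return RestitutionResult(points=points, max_slope=slope,
                             s1_apd_ms=points[0].apd_ms)
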