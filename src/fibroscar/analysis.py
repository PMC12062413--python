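"""Post-processing: activations, APD90, restitution, dispersion, regimes.

All analyses operate on recorded voltage traces or on the per-grid-point
activation log; none of them touch the solver.  APD is measured as APD90
(repolarization to 90% of the per-beat amplitude) with an activation
threshold of -40 mV and a 50 ms lockout, the community convention for
the TP06 model.

Regime classification formalizes what is usually judged from movies:

``NR``
    pacing waves pass (possibly detouring around the scar) and no
    retrograde activity appears;
``BR``
    retrograde (re-entrant) activity appears but stays confined to the
    border-zone annulus around the scar and dies out;
``PR``
    retrograde activity escapes the annulus (or outlives pacing),
    invading the surrounding tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "detect_activations", "apd90_of_beat", "compute_apd", "APDSeries",
    "restitution_curves", "apd_dispersion", "classify_regime",
    "RegimeLabel", "ClassifierSettings", "space_time_section",
]

ACT_THRESHOLD_MV = -40.0
ACT_LOCKOUT_MS = 50.0


def detect_activations(t, v, upstroke_threshold: float = ACT_THRESHOLD_MV,
                       lockout_ms: float = ACT_LOCKOUT_MS) -> np.ndarray:
    """Times of upward threshold crossings in a uniformly sampled trace.

    Crossing times are linearly interpolated between samples; crossings
    within ``lockout_ms`` of the previous accepted one are suppressed.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape:
        raise ValueError("t and v must have the same shape")
    if v.size < 2:
        return np.empty(0)
    up = np.flatnonzero((v[:-1] < upstroke_threshold)
                        & (v[1:] >= upstroke_threshold))
    out = []
    last = -np.inf
    for i in up:
        frac = (upstroke_threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= lockout_ms:
            out.append(tc)
            last = tc
    return np.asarray(out)


def apd90_of_beat(t, v, act_time, next_act=None,
                  threshold: float = ACT_THRESHOLD_MV) -> float:
    """APD90 (ms) of the beat starting at ``act_time``.

    The per-beat amplitude runs from the pre-upstroke resting voltage to
    the in-beat peak; APD90 is the time from activation to the downward
    crossing of rest + 10% of amplitude.  Returns NaN when the membrane
    has not repolarized to 90% before ``next_act`` (flagged beat).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    i0 = int(np.searchsorted(t, act_time))
    i1 = v.size if next_act is None else int(np.searchsorted(t, next_act))
    if i1 - i0 < 3:
        return float("nan")
    # resting level: minimum over the 20 ms preceding the upstroke
    jpre0 = int(np.searchsorted(t, act_time - 20.0))
    vrest = float(np.min(v[jpre0:i0 + 1])) if i0 > jpre0 else float(v[i0])
    seg = v[i0:i1]
    ipk = int(np.argmax(seg))
    vpeak = float(seg[ipk])
    if vpeak < threshold:
        return float("nan")
    v90 = vrest + 0.1 * (vpeak - vrest)
    below = np.flatnonzero(seg[ipk:] <= v90)
    if below.size == 0:
        return float("nan")
    k = ipk + below[0]
    if k == 0:
        return float("nan")
    # interpolate the crossing
    va, vb = seg[k - 1], seg[k]
    ta, tb = t[i0 + k - 1], t[i0 + k]
    frac = (va - v90) / (va - vb) if va != vb else 1.0
    return float(ta + frac * (tb - ta) - act_time)


@dataclass
class APDSeries:
    """Per-cell beat series: activation times, APD_n, CL_n and DI_n.

    ``cl[n] = act[n+1] - act[n]`` (length len(act)-1) and
    ``di[n] = cl[n] - apd[n]``, the diastolic interval preceding beat
    n+1.  Beats that never reached 90% repolarization before the next
    activation carry ``apd = NaN`` and ``flagged = True``.
    """

    activation_times: np.ndarray
    apd: np.ndarray
    flagged: np.ndarray = field(default=None)

    def __post_init__(self):
        a = np.asarray(self.activation_times, dtype=float)
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise ValueError("activation times must be strictly increasing")
        self.activation_times = a
        self.apd = np.asarray(self.apd, dtype=float)
        if self.flagged is None:
            self.flagged = ~np.isfinite(self.apd)

    @property
    def cl(self) -> np.ndarray:
        return np.diff(self.activation_times)

    @property
    def di(self) -> np.ndarray:
        return self.cl - self.apd[:-1]

    def __len__(self) -> int:
        return self.activation_times.size


def compute_apd(t, v, activations=None) -> APDSeries:
    """APD90 series for one trace; blocked (undetected) beats do not appear."""
    if activations is None:
        activations = detect_activations(t, v)
    activations = np.asarray(activations, dtype=float)
    apds = np.empty(activations.size)
    for n, a in enumerate(activations):
        nxt = activations[n + 1] if n + 1 < activations.size else None
        apds[n] = apd90_of_beat(t, v, a, nxt)
    return APDSeries(activation_times=activations, apd=apds)


def restitution_curves(t, line_traces, border_mask=None) -> pd.DataFrame:
    """Local (CL_n, APD_{n+1}) point sets for each cell on a sampling line.

    Parameters
    ----------
    t : (nt,) times of the line recording.
    line_traces : (nt, ns) voltage of each cell along the line.
    border_mask : optional (ns,) bool, True for border-zone cells.

    Returns a DataFrame with columns cell, in_border_zone, beat, cl_n,
    apd_next; flagged (non-repolarized) beats are excluded.
    """
    line_traces = np.asarray(line_traces)
    ns = line_traces.shape[1]
    if border_mask is None:
        border_mask = np.zeros(ns, dtype=bool)
    rows = []
    for s in range(ns):
        series = compute_apd(t, line_traces[:, s])
        cl = series.cl
        for n in range(cl.size):
            apd_next = series.apd[n + 1]
            if not np.isfinite(apd_next):
                continue
            rows.append((s, bool(border_mask[s]), n, cl[n], apd_next))
    return pd.DataFrame(
        rows, columns=["cell", "in_border_zone", "beat", "cl_n", "apd_next"])


def restitution_from_recording(rec, geom, lmax_mm: float = 2.5
                               ) -> pd.DataFrame:
    """Local restitution curves for the cells on a recording's sampling
    line, grouped into border-zone vs normal-zone by geometry."""
    bz = geom.border_zone(lmax_mm=lmax_mm)
    border_mask = np.array([bz[i, j] for (i, j) in rec.line_points])
    return restitution_curves(rec.t_line, rec.line_v, border_mask)


def apd_dispersion(curves: pd.DataFrame, at_cl_ms: float,
                   tol_ms: float = 5.0) -> float:
    """Dispersion (max - min, ms) of APD_{n+1} at a given CL_n.

    Each cell on the sampling line contributes the median of its
    APD_{n+1} values whose CL_n falls within ``at_cl_ms +- tol_ms``;
    at least two qualifying cells are required.
    """
    sel = curves[np.abs(curves["cl_n"] - at_cl_ms) <= tol_ms]
    per_cell = sel.groupby("cell")["apd_next"].median()
    if len(per_cell) < 2:
        raise ValueError(
            f"fewer than 2 cells have a beat with CL within +-{tol_ms} ms "
            f"of {at_cl_ms} ms")
    return float(per_cell.max() - per_cell.min())


def space_time_section(t, line_traces) -> np.ndarray:
    """Voltage matrix (time x position) along a sampling line, no resampling."""
    m = np.asarray(line_traces)
    if m.ndim == 1:
        m = m[:, None]
    return m


# ---------------------------------------------------------------------------
# regime classification

@dataclass(frozen=True)
class ClassifierSettings:
    """Codified thresholds for the NR/BR/PR decision.

    late_fraction : an activation is attributed to retrograde (not the
        incident pacing wave) when it lags the reference wavefront by
        more than this fraction of the pacing period.
    annulus_margin_mm : the border-zone annulus extends to
        Lmax + margin from the scar rim.
    dieout_periods : retrograde activity occurring later than this many
        periods after the last stimulus counts as self-sustaining (PR).
    min_component : connected late-activation sets smaller than this are
        ignored as noise.
    """

    late_fraction: float = 0.5
    annulus_margin_mm: float = 0.5   # 2 * dx at the default dx
    dieout_periods: float = 2.0
    min_component: int = 3


@dataclass
class RegimeLabel:
    """Categorical outcome of a pacing run with supporting evidence."""

    label: str                       # "NR" | "BR" | "PR"
    retro_components: int = 0
    max_retro_distance_mm: float = 0.0
    beyond_annulus: bool = False
    persists_after_pacing: bool = False

    def __post_init__(self):
        if self.label not in ("NR", "BR", "PR"):
            raise ValueError(f"invalid regime label {self.label!r}")


def _reference_front(act_t, act_n, ref_rows, stim_times, period):
    """Median incident-wave arrival per (beat, column) over scar-free rows."""
    nbeats = len(stim_times)
    ncols = act_t.shape[2]
    ref = np.full((nbeats, ncols), np.nan)
    for b, ts in enumerate(stim_times):
        t_lo, t_hi = ts, ts + period
        for j in range(ncols):
            vals = []
            for i in ref_rows:
                for k in range(act_n[i, j]):
                    a = act_t[k, i, j]
                    if t_lo <= a < t_hi:
                        vals.append(a)
                        break
            if vals:
                ref[b, j] = np.median(vals)
    return ref


def classify_regime(act_t, act_n, geom, stim_times, period_ms,
                    lmax_mm: float,
                    settings: ClassifierSettings = ClassifierSettings(),
                    ) -> RegimeLabel:
    """Label a paced run NR / BR / PR from its activation log.

    Parameters
    ----------
    act_t : (Amax, N, M) activation times, NaN-padded per grid point.
    act_n : (N, M) int, number of logged activations per point.
    geom : TissueGeometry (scar mask, distances, pacing along +columns).
    stim_times, period_ms : the pacing train.
    lmax_mm : link cutoff; sets the border-zone annulus extent.
    """
    act_t = np.asarray(act_t)
    act_n = np.asarray(act_n)
    scar = geom.scar_mask
    if act_t.shape[1:] != scar.shape or act_n.shape != scar.shape:
        raise ValueError("activation log does not cover the geometry")
    n_rows, n_cols = scar.shape
    stim_times = np.asarray(list(stim_times), dtype=float)
    if stim_times.size == 0:
        return RegimeLabel(label="NR")

    dist = geom.distance_to_scar_mm()
    annulus_lim = lmax_mm + settings.annulus_margin_mm

    # reference rows: scar-free rows nearest the domain edges
    free = np.flatnonzero(~scar.any(axis=1))
    if free.size == 0:
        raise ValueError("no scar-free rows available for the reference front")
    ref_rows = np.unique(np.concatenate([free[:3], free[-3:]]))
    ref = _reference_front(act_t, act_n, ref_rows, stim_times, period_ms)

    late_cut = settings.late_fraction * period_ms
    horizon = stim_times[-1] + settings.dieout_periods * period_ms

    retro_components = 0
    max_retro_dist = 0.0
    beyond = False
    persists = False

    for b in range(stim_times.size):
        late = np.zeros((n_rows, n_cols), dtype=bool)
        late_t = np.full((n_rows, n_cols), np.nan)
        for i in range(n_rows):
            for j in range(n_cols):
                if scar[i, j]:
                    continue
                r = ref[b, j]
                if not np.isfinite(r):
                    continue
                t_lo = stim_times[b]
                t_hi = stim_times[b] + period_ms if b + 1 < stim_times.size \
                    else np.inf
                for k in range(act_n[i, j]):
                    a = act_t[k, i, j]
                    if t_lo <= a < t_hi and a - r > late_cut:
                        late[i, j] = True
                        late_t[i, j] = a
                        break
        if not late.any():
            continue
        labels, ncomp = ndimage.label(late, structure=np.ones((3, 3)))
        for c in range(1, ncomp + 1):
            ii, jj = np.nonzero(labels == c)
            if ii.size < settings.min_component:
                continue
            # retrograde = activation-time gradient opposing the incident
            # (+column) direction within the component
            tt = late_t[ii, jj]
            if np.ptp(jj) == 0:
                continue
            slope = np.polyfit(jj.astype(float), tt, 1)[0]
            if slope >= 0:
                continue
            retro_components += 1
            d = float(dist[ii, jj].max())
            max_retro_dist = max(max_retro_dist, d)
            if d > annulus_lim:
                beyond = True
            if np.nanmax(tt) > horizon:
                persists = True

    if retro_components == 0:
        return RegimeLabel(label="NR")
    if beyond or persists:
        return RegimeLabel(label="PR", retro_components=retro_components,
                           max_retro_distance_mm=max_retro_dist,
                           beyond_annulus=beyond,
                           persists_after_pacing=persists)
    return RegimeLabel(label="BR", retro_components=retro_components,
                       max_retro_distance_mm=max_retro_dist)
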