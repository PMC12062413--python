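"""Activation detection, APD90, restitution curves, dispersion, regimes."""

import numpy as np
import pandas as pd
import pytest

from fibroscar.analysis import (APDSeries, ClassifierSettings, apd90_of_beat,
                                apd_dispersion, classify_regime, compute_apd,
                                detect_activations, restitution_curves,
                                space_time_section)
from fibroscar.link_topology import TissueGeometry

from conftest import synthetic_square_pulse


class TestDetectActivations:
    def test_constant_trace_has_none(self):
        t = np.arange(0, 1000, 0.5)
        assert detect_activations(t, np.full_like(t, -86.0)).size == 0

    def test_two_pulse_square_wave(self):
        t = np.arange(0, 600, 0.5)
        v = np.full_like(t, -86.0)
        v[(t >= 100) & (t < 150)] = 20.0
        v[(t >= 400) & (t < 450)] = 20.0
        acts = detect_activations(t, v)
        assert acts == pytest.approx([100.0, 400.0], abs=0.5)

    def test_threshold_above_trace_max(self):
        t, v = synthetic_square_pulse(50.0)
        assert detect_activations(t, v, upstroke_threshold=30.0).size == 0

    def test_lockout_suppresses_rebounce(self):
        t = np.arange(0, 200, 0.5)
        v = np.full_like(t, -86.0)
        for t0 in (50, 60, 70):   # re-crossings inside the 50 ms lockout
            v[(t >= t0) & (t < t0 + 5)] = 0.0
        assert detect_activations(t, v).size == 1


class TestApd90:
    @pytest.mark.parametrize("width", [40.0, 120.0, 250.0])
    def test_square_pulse_width(self, width):
        t, v = synthetic_square_pulse(width, dt=0.1)
        acts = detect_activations(t, v)
        apd = apd90_of_beat(t, v, acts[0])
        assert apd == pytest.approx(width, abs=0.2)

    def test_symmetric_triangle_closed_form(self):
        # time-reversed-symmetric triangle, rest -80, peak +20, edges
        # rising/falling at 20 mV/ms: upstroke crosses -40 at 102 ms,
        # V90 = -70 is crossed on the way down at 109.5 ms -> APD = 7.5
        dt = 0.01
        t = np.arange(0, 300, dt)
        v = np.full_like(t, -80.0)
        rise = (t >= 100) & (t < 105)
        fall = (t >= 105) & (t < 110)
        v[rise] = -80 + 20 * (t[rise] - 100)
        v[fall] = 20 - 20 * (t[fall] - 105)
        acts = detect_activations(t, v)
        apd = apd90_of_beat(t, v, acts[0])
        assert apd == pytest.approx(7.5, abs=0.05)

    def test_non_repolarizing_beat_flagged(self):
        t = np.arange(0, 300, 0.5)
        v = np.where(t > 100, 10.0, -86.0)  # never comes back down
        apd = apd90_of_beat(t, v, 100.0)
        assert np.isnan(apd)

    def test_blocked_beat_absent_from_series(self):
        t = np.arange(0, 800, 0.5)
        v = np.full_like(t, -86.0)
        v[(t >= 100) & (t < 250)] = 15.0   # one real beat
        v[(t >= 500) & (t < 520)] = -60.0  # subthreshold bump
        series = compute_apd(t, v)
        assert len(series) == 1
        assert series.apd[0] == pytest.approx(150.0, abs=0.5)


class TestAPDSeries:
    def test_cl_and_di_identities(self):
        s = APDSeries(activation_times=np.array([0.0, 300.0, 620.0]),
                      apd=np.array([250.0, 260.0, 255.0]))
        assert s.cl == pytest.approx([300.0, 320.0])
        assert s.di == pytest.approx([50.0, 60.0])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            APDSeries(activation_times=np.array([0.0, 300.0, 200.0]),
                      apd=np.zeros(3))


def _pulse_train(apds, cl=300.0, dt=0.5, v_rest=-86.0):
    n = len(apds)
    t = np.arange(0, n * cl + 400, dt)
    v = np.full_like(t, v_rest)
    for k, w in enumerate(apds):
        v[(t >= k * cl) & (t < k * cl + w)] = 20.0
    return t, v


class TestRestitutionCurvesAndDispersion:
    def test_identical_cells_coincide(self):
        t, v = _pulse_train([200, 200, 200, 200])
        traces = np.stack([v, v, v], axis=1)
        curves = restitution_curves(t, traces)
        spread = curves.groupby("beat")["apd_next"].agg(np.ptp)
        assert (spread <= 2.0).all()

    def test_constant_cl_single_point_curves(self):
        t, v = _pulse_train([200, 200, 200, 200])
        curves = restitution_curves(t, v[:, None])
        assert curves["cl_n"].nunique() == 1

    def test_dispersion_zero_for_identical_cells(self):
        t, v = _pulse_train([200, 200, 200])
        curves = restitution_curves(t, np.stack([v, v], axis=1))
        assert apd_dispersion(curves, 300.0) == pytest.approx(0.0, abs=1e-9)

    def test_dispersion_direct_max_minus_min(self):
        rows = [(0, True, 0, 300.0, 200.0), (1, True, 0, 300.0, 340.0),
                (2, False, 0, 300.0, 260.0)]
        curves = pd.DataFrame(rows, columns=["cell", "in_border_zone",
                                             "beat", "cl_n", "apd_next"])
        assert apd_dispersion(curves, 300.0) == pytest.approx(140.0)

    def test_dispersion_matches_series_route(self):
        t, va = _pulse_train([200, 210, 205])
        _, vb = _pulse_train([240, 250, 245])
        curves = restitution_curves(t, np.stack([va, vb], axis=1))
        d = apd_dispersion(curves, 300.0)
        sa = compute_apd(t, va)
        sb = compute_apd(t, vb)
        direct = abs(np.median(sb.apd[1:]) - np.median(sa.apd[1:]))
        assert d == pytest.approx(direct, abs=1.0)

    def test_dispersion_too_few_cells_errors(self):
        t, v = _pulse_train([200, 200])
        curves = restitution_curves(t, v[:, None])
        with pytest.raises(ValueError, match="CL"):
            apd_dispersion(curves, 800.0)


class TestSpaceTime:
    def test_uniform_field_constant_matrix(self):
        m = space_time_section(None, np.full((50, 7), -86.0))
        assert np.all(m == -86.0)

    def test_single_cell_line_equals_trace(self):
        tr = np.linspace(-86, 20, 40)
        m = space_time_section(None, tr)
        assert np.array_equal(m[:, 0], tr)

    def test_reversing_line_order_reverses_columns(self):
        m = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(space_time_section(None, m[:, ::-1]),
                              m[:, ::-1])


# ---------------------------------------------------------------------------
# regime classification on constructed activation maps

N = 40
T = 200.0
STIMS = [0.0, 200.0, 400.0]
LMAX = 1.0   # mm; annulus limit = 1.5 mm = 6 grid points


@pytest.fixture(scope="module")
def cgeom():
    return TissueGeometry.circular_scar(N, r_cm=0.125)  # scar radius 5 pts


def _plane_map(geom, cv_pts_per_ms=0.5):
    """Activation log of clean pacing waves along +columns."""
    amax = len(STIMS) + 2
    act_t = np.full((amax, N, N), np.nan)
    act_n = np.zeros((N, N), dtype=np.int32)
    for b, ts in enumerate(STIMS):
        for i in range(N):
            for j in range(N):
                if geom.scar_mask[i, j]:
                    continue
                act_t[act_n[i, j], i, j] = ts + j / cv_pts_per_ms
        act_n[~geom.scar_mask] += 1
    return act_t, act_n


def _add_late_ring(act_t, act_n, geom, cells, t_base):
    """Retrograde component: activation later at smaller column index."""
    for (i, j) in cells:
        act_t[act_n[i, j], i, j] = t_base + (25 - j) * 3.0
        act_n[i, j] += 1


def classify(act_t, act_n, geom):
    return classify_regime(act_t, act_n, geom, STIMS, T, lmax_mm=LMAX)


class TestClassifyRegime:
    def test_plane_wave_is_nr(self, cgeom):
        act_t, act_n = _plane_map(cgeom)
        assert classify(act_t, act_n, cgeom).label == "NR"

    def test_obstacle_detour_is_nr(self, cgeom):
        act_t, act_n = _plane_map(cgeom)
        # wrap-around delay behind the scar, well under T/2
        for i in range(17, 24):
            for j in range(26, 31):
                for k in range(act_n[i, j]):
                    act_t[k, i, j] += 30.0
        assert classify(act_t, act_n, cgeom).label == "NR"

    def test_confined_ring_is_br(self, cgeom):
        act_t, act_n = _plane_map(cgeom)
        dist = cgeom.distance_to_scar_mm()
        cells = [(i, j) for i in range(14, 27) for j in range(26, 30)
                 if not cgeom.scar_mask[i, j] and dist[i, j] <= 1.0]
        assert len(cells) >= 3
        # ref arrival at j=26..30 is ~252-260 for beat 1; +140 is "late"
        _add_late_ring(act_t, act_n, cgeom, cells, t_base=400.0)
        label = classify(act_t, act_n, cgeom)
        assert label.label == "BR"
        assert label.retro_components >= 1

    def test_escaping_spiral_is_pr(self, cgeom):
        act_t, act_n = _plane_map(cgeom)
        dist = cgeom.distance_to_scar_mm()
        cells = [(20, j) for j in range(26, 38)]
        cells += [(21, j) for j in range(26, 38)]
        cells = [(i, j) for (i, j) in cells if not cgeom.scar_mask[i, j]]
        assert any(dist[i, j] > LMAX + 0.5 for (i, j) in cells)
        _add_late_ring(act_t, act_n, cgeom, cells, t_base=400.0)
        label = classify(act_t, act_n, cgeom)
        assert label.label == "PR"
        assert label.beyond_annulus

    def test_persistent_activity_after_pacing_is_pr(self, cgeom):
        act_t, act_n = _plane_map(cgeom)
        dist = cgeom.distance_to_scar_mm()
        cells = [(i, j) for i in range(16, 25) for j in range(26, 30)
                 if not cgeom.scar_mask[i, j] and dist[i, j] <= 1.0]
        # dies-out horizon is last stim + 2T = 800 ms
        _add_late_ring(act_t, act_n, cgeom, cells, t_base=950.0)
        label = classify(act_t, act_n, cgeom)
        assert label.label == "PR"
        assert label.persists_after_pacing

    def test_quiescent_map_is_nr(self, cgeom):
        amax = 4
        act_t = np.full((amax, N, N), np.nan)
        act_n = np.zeros((N, N), dtype=np.int32)
        assert classify(act_t, act_n, cgeom).label == "NR"

    def test_determinism(self, cgeom):
        act_t, act_n = _plane_map(cgeom)
        a = classify(act_t, act_n, cgeom)
        b = classify(act_t, act_n, cgeom)
        assert a == b

    def test_coverage_mismatch_errors(self, cgeom):
        act_t = np.full((3, 10, 10), np.nan)
        act_n = np.zeros((10, 10), dtype=np.int32)
        with pytest.raises(ValueError, match="cover"):
            classify_regime(act_t, act_n, cgeom, STIMS, T, lmax_mm=LMAX)

    def test_settings_are_exposed(self, cgeom):
        act_t, act_n = _plane_map(cgeom)
        strict = ClassifierSettings(late_fraction=0.05)
        # even the detour delay of 0 is not late; plane map stays NR
        lbl = classify_regime(act_t, act_n, cgeom, STIMS, T, lmax_mm=LMAX,
                              settings=strict)
        assert lbl.label == "NR"
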