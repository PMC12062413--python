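"""Monodomain solver: stencil, conservation, coupling, determinism."""

import dataclasses

import numpy as np
import pytest

from fibroscar import maccannell as mac
from fibroscar import tissue_sim, tp06
from fibroscar.link_topology import LinkSet, TissueGeometry
from fibroscar.protocols import PacingProtocol, build_line_scar_bridge
from fibroscar.tissue_sim import (Recording, SimulationConfig, TissueState,
                                  diffusion_term, face_diffusivities, run,
                                  step)


class TestDiffusionOperator:
    def test_uniform_field_zero(self, small_circle_geom):
        v = np.full((48, 48), -77.0)
        out = diffusion_term(v, small_circle_geom)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_conservation_for_any_field(self, small_circle_geom):
        rng = np.random.default_rng(0)
        v = rng.normal(-60, 30, size=(48, 48))
        out = diffusion_term(v, small_circle_geom)
        # telescoping fluxes: no-flux edges and scar rim conserve sum(V)
        assert abs(out.sum()) < 1e-9 * np.abs(out).sum()

    def test_scar_points_isolated(self, small_circle_geom):
        rng = np.random.default_rng(1)
        v = rng.normal(-60, 30, size=(48, 48))
        out = diffusion_term(v, small_circle_geom)
        assert np.all(out[small_circle_geom.scar_mask] == 0.0)

    def test_face_diffusivity_zero_on_scar_faces(self, small_circle_geom):
        xf, yf = face_diffusivities(small_circle_geom)
        scar = small_circle_geom.scar_mask
        for i, j in np.argwhere(scar):
            assert xf[i, j] == 0.0 and xf[i, j + 1] == 0.0
            assert yf[i, j] == 0.0 and yf[i + 1, j] == 0.0

    def test_heat_kernel_widening(self):
        # 1D Gaussian on a uniform strip against the closed-form heat
        # kernel: sigma^2 grows by 2*D*t
        geom = TissueGeometry.uniform(4, 240)
        dxmm = geom.dx_mm
        x = (np.arange(240) - 120) * dxmm
        sig0 = 1.5   # mm
        amp = 40.0
        v0 = -80.0 + amp * np.exp(-x**2 / (2 * sig0**2))
        cfg = SimulationConfig(duration_ms=10.0, myo_ion_on=False,
                               settle_ms=0.0, snapshot_cadence_ms=10.0)
        state = TissueState.resting(geom, None, cfg)
        state.U[:, :, tp06.IV] = v0[None, :]
        step(state, cfg, geom, None, n_steps=1000)
        d_mm2 = geom.d_reg * 100.0   # cm^2/ms -> mm^2/ms
        sig2 = sig0**2 + 2 * d_mm2 * 10.0
        expected = -80.0 + amp * sig0 / np.sqrt(sig2) \
            * np.exp(-x**2 / (2 * sig2))
        err = np.abs(state.U[2, :, tp06.IV] - expected).max() / amp
        assert err < 0.01


def _bare_cfg(**kw):
    kw.setdefault("duration_ms", 1.0)
    kw.setdefault("settle_ms", 0.0)
    kw.setdefault("equilibrate_ms", 500.0)
    return SimulationConfig(**kw)


class TestStep:
    def test_resting_field_unchanged_over_100_steps(self, strip_geom):
        cfg = _bare_cfg(equilibrate_ms=2000.0)
        state = TissueState.resting(strip_geom, None, cfg)
        v0 = state.v_field.copy()
        step(state, cfg, strip_geom, None, n_steps=100)
        assert np.abs(state.v_field - v0).max() < 1e-3
        # and stays exactly uniform
        assert np.ptp(state.v_field) < 1e-12

    def test_two_variable_linear_relaxation(self):
        # single link, D = 0 (all-scar), all ionic currents frozen: the
        # pair obeys a linear two-variable ODE whose solution is known
        geom = TissueGeometry(2, 2, np.ones((2, 2), dtype=bool))
        links = LinkSet(prox_ij=np.array([[0, 0]]),
                        distal_ptr=np.array([0, 0]),
                        distal_ij=np.empty((0, 2), dtype=int))
        gs, nf, cf, cm = 4.0, 8, 50.0, 150.0
        cfg = _bare_cfg(gs_nS=gs, nf=nf, scar_mode="inactive",
                        myo_ion_on=True, fib_ion_on=False)
        state = TissueState.resting(geom, links, cfg)
        v0, vf0 = -80.0, -20.0
        state.U[:, :, tp06.IV] = v0
        state.F[0, mac.FV] = vf0
        q0 = cm * v0 + nf * cf * vf0
        n_steps, dt = 3000, cfg.dt_ms
        step(state, cfg, geom, links, n_steps=n_steps)
        v, vf = state.U[0, 0, tp06.IV], state.F[0, mac.FV]
        # conservation of total charge
        assert cm * v + nf * cf * vf == pytest.approx(q0, rel=1e-9)
        # exponential relaxation: rate = Nf*Gs/Cm + Gs/Cf
        lam = nf * gs / cm + gs / cf
        t = n_steps * dt
        veq = q0 / (cm + nf * cf)
        v_expect = veq + (v0 - veq) * np.exp(-lam * t)
        assert v == pytest.approx(v_expect, abs=0.05)
        # monotone approach from both sides
        assert v0 < v < vf < vf0 or vf0 < vf < v < v0

    def test_coupling_charge_antisymmetry_fieldwide(self, small_circle_geom):
        # frozen ionics, D on: total charge Cm*sum(V) + Nf*Cf*sum(Vf)
        # changes only through diffusion (which conserves sum V)
        geom = small_circle_geom
        from fibroscar.link_topology import generate_links
        links = generate_links(geom, 100, lam=10.0, lmax_mm=2.0, seed=2)
        cfg = _bare_cfg(gs_nS=3.0, nf=8, myo_ion_on=False, fib_ion_on=False)
        state = TissueState.resting(geom, links, cfg)
        rng = np.random.default_rng(3)
        state.U[:, :, tp06.IV] = rng.normal(-70, 20, size=(48, 48))
        state.F[:, mac.FV] = rng.normal(-40, 10, size=100)
        q0 = 150.0 * state.v_field.sum() + 8 * 50.0 * state.vf.sum()
        step(state, cfg, geom, links, n_steps=500)
        q1 = 150.0 * state.v_field.sum() + 8 * 50.0 * state.vf.sum()
        assert q1 == pytest.approx(q0, rel=1e-12)

    def test_blowup_aborts_with_location(self, strip_geom):
        cfg = _bare_cfg()
        state = TissueState.resting(strip_geom, None, cfg)
        state.U[3, 40, tp06.IV] = 5.0e3   # numerically exploded voltage
        with pytest.raises(FloatingPointError, match=r"\(3, 40\)"):
            step(state, cfg, strip_geom, None, n_steps=1)


class TestRun:
    def test_zero_duration_echoes_initial_state(self, strip_geom):
        cfg = _bare_cfg(duration_ms=0.0)
        rec = run(cfg, strip_geom, None, PacingProtocol(mode="none"))
        assert rec.v_snap.shape[0] == 1
        assert np.ptp(rec.v_snap[0]) < 1e-6

    def test_unstable_config_rejected(self):
        geom = TissueGeometry.uniform(8, 8, d_reg=0.05)
        cfg = _bare_cfg(duration_ms=1.0)
        with pytest.raises(ValueError, match="unstable"):
            run(cfg, geom, None, PacingProtocol(mode="none"))

    def test_duration_not_multiple_of_dt_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            SimulationConfig(duration_ms=10.005, dt_ms=0.01)

    def test_determinism_bit_identical(self, strip_geom):
        def one():
            cfg = SimulationConfig(duration_ms=30.0, settle_ms=0.0,
                                   equilibrate_ms=500.0,
                                   snapshot_cadence_ms=10.0)
            prot = PacingProtocol(mode="edge", period_ms=30.0, n_beats=1)
            return run(cfg, strip_geom, None, prot)

        a, b = one(), one()
        assert np.array_equal(a.v_snap, b.v_snap)
        assert np.array_equal(a.act_t, b.act_t, equal_nan=True)

    def test_mirror_symmetry(self):
        # geometry, bridge links and edge stimulus are all symmetric
        # under row reflection, so the whole run must be too
        geom = TissueGeometry.line_scar(n_rows=15, n_cols=60)
        links = build_line_scar_bridge(geom, 4.0)
        cfg = SimulationConfig(duration_ms=60.0, gs_nS=4.0, settle_ms=50.0,
                               equilibrate_ms=500.0, snapshot_cadence_ms=20.0)
        prot = PacingProtocol(mode="edge", period_ms=60.0, n_beats=1)
        rec = run(cfg, geom, links, prot, record_line=False)
        for snap in rec.v_snap:
            assert np.allclose(snap, snap[::-1, :], atol=1e-8)

    def test_gate_bounds_through_paced_run(self, strip_geom):
        cfg = SimulationConfig(duration_ms=40.0, settle_ms=0.0,
                               equilibrate_ms=500.0)
        state = TissueState.resting(strip_geom, None, cfg)
        prot = PacingProtocol(mode="edge", period_ms=40.0, n_beats=1)
        run(cfg, strip_geom, None, prot, state=state)
        gates = state.U[:, :, list(tp06.GATE_IDX)]
        assert gates.min() >= 0.0 and gates.max() <= 1.0

    def test_point_pacing_mode(self, strip_geom):
        cfg = SimulationConfig(duration_ms=30.0, settle_ms=0.0,
                               equilibrate_ms=500.0)
        prot = PacingProtocol(mode="point", period_ms=30.0, n_beats=1,
                              point=(4, 10))
        rec = run(cfg, strip_geom, None, prot)
        first = np.where(rec.act_n > 0, rec.act_t[0], np.nan)
        assert np.isfinite(first[4, 10])
        # radial spread: nearer points activate earlier
        assert first[4, 20] < first[4, 40]


class TestConductionVelocity:
    def test_cv_scales_as_sqrt_d(self):
        # quartering D must halve the conduction velocity (within 5%);
        # measured on a refined lattice so the slow wavefront stays
        # well resolved
        dx = 0.0625
        ncol = 480

        def cv(d_reg):
            geom = TissueGeometry(6, ncol,
                                  np.zeros((6, ncol), dtype=bool),
                                  dx_mm=dx, d_reg=d_reg)
            cfg = SimulationConfig(duration_ms=160.0, dt_ms=0.005,
                                   settle_ms=0.0, equilibrate_ms=1000.0,
                                   snapshot_cadence_ms=160.0)
            # stimulus depth keeps the same physical extent (0.75 mm)
            prot = PacingProtocol(mode="edge", period_ms=160.0, n_beats=1,
                                  stim_depth_pts=12)
            rec = run(cfg, geom, None, prot, record_line=False)
            first = np.where(rec.act_n > 0, rec.act_t[0], np.nan)
            j = np.arange(ncol)
            sel = (j > 120) & (j < 400)
            tt = first[3, sel]
            assert np.all(np.isfinite(tt))
            slope = np.polyfit(j[sel] * dx, tt, 1)[0]  # ms/mm
            return 1.0 / slope

        ratio = cv(0.001) / cv(0.00025)
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestInactiveScar:
    def test_scar_points_keep_resting_voltage_without_links(
            self, small_circle_geom):
        cfg = SimulationConfig(duration_ms=30.0, scar_mode="inactive",
                               settle_ms=0.0, equilibrate_ms=500.0)
        state = TissueState.resting(small_circle_geom, None, cfg)
        v0 = state.v_field.copy()
        prot = PacingProtocol(mode="edge", period_ms=30.0, n_beats=1)
        run(cfg, small_circle_geom, None, prot, state=state)
        scar = small_circle_geom.scar_mask
        # no ionic current, no diffusion, no links: frozen exactly
        assert np.array_equal(state.v_field[scar], v0[scar])
        # outside tissue still activated
        assert state.v_field[~scar].max() > 0.0
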