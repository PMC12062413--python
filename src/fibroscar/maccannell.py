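"""MacCannell "active" cardiac fibroblast model.

Four membrane currents: an inward-rectifier potassium current I_fK1, a
time- and voltage-dependent potassium current I_fKv (gates r, s), a
Na+/K+ pump current I_fNaK and a background sodium current I_fbNa.
Intracellular Na+ and K+ are held fixed, so the only state variables are
the membrane potential Vf and the two Kv gates.

The Kv gating voltage dependence can be shifted by a constant (mV) to
retune the uncoupled resting potential; the two study variants used in
tissue runs ("depolarized" -> -24.5 mV, "hyperpolarized" -> -49.0 mV)
are obtained this way.  A unit of Nf identical fibroblasts in parallel
has unchanged current densities, and total capacitance Nf*Cf, which is
how gap-junction currents are normalized on the fibroblast side.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NVARF = 3
FV, FR, FS = 0, 1, 2

RGAS = 8314.472
FARADAY = 96485.3415
TEMP = 310.0
RTONF = RGAS * TEMP / FARADAY

# fixed ionic milieu (mM)
KO_F = 5.3581
KI_F = 129.4349
NAO_F = 130.0110
NAI_F = 8.5547

EK_F = RTONF * math.log(KO_F / KI_F)
ENA_F = RTONF * math.log(NAO_F / NAI_F)

# parameter-vector layout (FibroblastParams.as_array())
NPARF = 7
FGK1, FGKV, FINAK, FGBNA, FCF, FNF, FSHIFT = range(NPARF)

BASELINE = {
    "g_fk1": 0.4822,     # nS/pF
    "g_fkv": 0.25,       # nS/pF
    "i_fnak_max": 2.002,  # pA/pF
    "g_fbna": 0.0095,    # nS/pF
    "cf_pF": 50.0,       # per-fibroblast capacitance (myofibroblast)
    "nf": 8.0,
    "kv_shift_mV": 0.0,
}

KMK_F = 1.0
KMNA_F = 11.0
VREV_NAK = -150.0
BNAK = -200.0


def param_array_from_dict(d) -> np.ndarray:
    p = np.empty(NPARF)
    p[FGK1] = d["g_fk1"]
    p[FGKV] = d["g_fkv"]
    p[FINAK] = d["i_fnak_max"]
    p[FGBNA] = d["g_fbna"]
    p[FCF] = d["cf_pF"]
    p[FNF] = d["nf"]
    p[FSHIFT] = d["kv_shift_mV"]
    return p


def baseline_param_array(**overrides) -> np.ndarray:
    d = dict(BASELINE)
    d.update(overrides)
    return param_array_from_dict(d)


def initial_state(vf: float = -49.6) -> np.ndarray:
    """Resting state; gates start at their steady-state values at vf."""
    f = np.empty(NVARF)
    f[FV] = vf
    f[FR] = 0.0
    f[FS] = 1.0
    return f


@njit(cache=True, fastmath=True)
def fib_currents(vf, r, s, p):
    """Current densities (pA/pF): (i_fk1, i_fkv, i_fnak, i_fbna)."""
    dvk = vf - EK_F
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (dvk - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (dvk + 100.0))
           + math.exp(0.1 * (dvk - 10.0))) / (1.0 + math.exp(-0.5 * dvk))
    ifk1 = p[FGK1] * ak1 / (ak1 + bk1) * dvk

    ifkv = p[FGKV] * r * s * dvk

    nai15 = NAI_F ** 1.5
    ifnak = (p[FINAK] * KO_F / (KO_F + KMK_F)
             * nai15 / (nai15 + KMNA_F ** 1.5)
             * (vf - VREV_NAK) / (vf - BNAK))

    ifbna = p[FGBNA] * (vf - ENA_F)
    return ifk1, ifkv, ifnak, ifbna


@njit(cache=True, fastmath=True)
def fib_gate_rates(vf, shift):
    """Kv gate steady states and time constants at shifted voltage."""
    v = vf - shift
    rinf = 1.0 / (1.0 + math.exp(-(v + 20.0) / 11.0))
    taur = 20.3 + 138.0 * math.exp(-((v + 20.0) / 25.9) ** 2)
    sinf = 1.0 / (1.0 + math.exp((v + 23.0) / 7.0))
    taus = 1574.0 + 5268.0 * math.exp(-((v + 23.0) / 22.7) ** 2)
    return rinf, taur, sinf, taus


@njit(cache=True, fastmath=True)
def fib_step(f, p, dt, dvf_extra, gate_mode):
    """Advance one fibroblast unit one step in place.

    dvf_extra is the gap-junction term in mV/ms (already divided by the
    unit capacitance Nf*Cf upstream).  Returns the total ionic current
    density (pA/pF).
    """
    vf = f[FV]
    ifk1, ifkv, ifnak, ifbna = fib_currents(vf, f[FR], f[FS], p)
    iion = ifk1 + ifkv + ifnak + ifbna

    rinf, taur, sinf, taus = fib_gate_rates(vf, p[FSHIFT])
    if gate_mode == 0:
        f[FR] = rinf - (rinf - f[FR]) * math.exp(-dt / taur)
        f[FS] = sinf - (sinf - f[FS]) * math.exp(-dt / taus)
    else:
        rn = f[FR] + dt * (rinf - f[FR]) / taur
        sn = f[FS] + dt * (sinf - f[FS]) / taus
        f[FR] = min(max(rn, 0.0), 1.0)
        f[FS] = min(max(sn, 0.0), 1.0)

    f[FV] = vf + dt * (-iion + dvf_extra)
    return iion


@njit(cache=True)
def integrate_uncoupled(f, p, duration_ms, dt, gate_mode=0):
    """Quiescent integration of an uncoupled unit, in place."""
    n = int(round(duration_ms / dt))
    for _ in range(n):
        fib_step(f, p, dt, 0.0, gate_mode)
    return f


def steady_current(vf: float, shift: float, p=None) -> float:
    """Net ionic current at voltage vf with gates at steady state.

    Zero of this function in vf is the uncoupled resting potential; used
    by the resting-potential calibration.
    """
    if p is None:
        p = baseline_param_array()
    p = np.asarray(p, dtype=float).copy()
    p[FSHIFT] = shift
    rinf, _, sinf, _ = fib_gate_rates(vf, shift)
    return float(sum(fib_currents(vf, rinf, sinf, p)))
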