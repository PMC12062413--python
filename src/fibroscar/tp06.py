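"""ten Tusscher-Panfilov 2006 (TP06) human ventricular myocyte model.

Epicardial formulation with the *Shallow* restitution parameter set
(maximum S1S2 restitution slope ~0.7), which is deliberately
non-alternans-prone: any reentry seen in tissue runs is then attributable
to the myocyte-fibroblast coupling and not to an intrinsic restitution
instability.

Units contract (package-wide): V in mV, t in ms, current densities in
pA/pF, conductances of membrane currents in nS/pF, concentrations in mM.

State vector layout (19 variables, see the ``I*`` index constants):
V, gates (m, h, j, xr1, xr2, xs, r, s, d, f, f2, fCass), the ryanodine
release adaptation variable Rbar, and the concentrations Cai, CaSR,
CaSS, Nai, Ki.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# state-vector indices
NVAR = 19
IV, IM, IH, IJ, IXR1, IXR2, IXS, IR, IS, ID, IF, IF2, IFCASS, IRBAR, \
    ICAI, ICASR, ICASS, INAI, IKI = range(NVAR)

GATE_IDX = (IM, IH, IJ, IXR1, IXR2, IXS, IR, IS, ID, IF, IF2, IFCASS)

STATE_NAMES = (
    "V", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fcass", "rbar", "cai", "casr", "cass", "nai", "ki",
)

# ---------------------------------------------------------------------------
# physical constants and fixed model parameters (epicardial TP06)
RGAS = 8314.472        # mJ/(mol K)
FARADAY = 96485.3415   # C/mol
TEMP = 310.0           # K
RTONF = RGAS * TEMP / FARADAY

KO = 5.4               # mM
CAO = 2.0
NAO = 140.0

VC = 0.016404          # cytoplasmic volume (units of the source model)
VSR = 0.001094
VSS = 0.00005468
CAPACITANCE = 0.185

BUFC = 0.2
KBUFC = 0.001
BUFSR = 10.0
KBUFSR = 0.3
BUFSS = 0.4
KBUFSS = 0.00025

VMAXUP = 0.006375
KUP = 0.00025
VREL = 0.102
K1P = 0.15
K2P = 0.045
K3 = 0.060
K4 = 0.005
EC = 1.5
MAXSR = 2.5
MINSR = 1.0
VLEAK = 0.00036
VXFER = 0.0038

PKNA = 0.03
KMK = 1.0
KMNA = 40.0
KMNAI = 87.5
KMCA = 1.38
KSAT = 0.1
NGAMMA = 0.35
KPCA = 0.0005

# ---------------------------------------------------------------------------
# tunable-parameter vector layout (MyocyteParams.as_array())
NPAR = 15
PGNA, PGTO, PGK1, PGKR, PGKS, PGCAL, PKNACA, PKNAK, PGPCA, PGPK, \
    PGBCA, PGBNA, PCM, PTAUF, PTAUF2 = range(NPAR)

#: Epicardial baseline conductances (nS/pF except as noted in the source
#: formulation) and the Shallow-restitution overrides of I_Kr, I_Ks,
#: I_pCa and I_pK.
EPI_BASELINE = {
    "g_na": 14.838,
    "g_to": 0.294,
    "g_k1": 5.405,
    "g_kr": 0.153,
    "g_ks": 0.392,
    "g_cal": 3.980e-5,
    "k_naca": 1000.0,
    "k_nak": 2.724,
    "g_pca": 0.1238,
    "g_pk": 0.0146,
    "g_bca": 0.000592,
    "g_bna": 0.00029,
    "cm_pF": 150.0,
}

SHALLOW_OVERRIDES = {
    "g_kr": 0.172,
    "g_ks": 0.441,
    "g_pca": 0.8666,
    "g_pk": 0.00219,
}


def shallow_param_array() -> np.ndarray:
    d = dict(EPI_BASELINE)
    d.update(SHALLOW_OVERRIDES)
    return param_array_from_dict(d)


def param_array_from_dict(d) -> np.ndarray:
    p = np.empty(NPAR)
    p[PGNA] = d["g_na"]
    p[PGTO] = d["g_to"]
    p[PGK1] = d["g_k1"]
    p[PGKR] = d["g_kr"]
    p[PGKS] = d["g_ks"]
    p[PGCAL] = d["g_cal"]
    p[PKNACA] = d["k_naca"]
    p[PKNAK] = d["k_nak"]
    p[PGPCA] = d["g_pca"]
    p[PGPK] = d["g_pk"]
    p[PGBCA] = d["g_bca"]
    p[PGBNA] = d["g_bna"]
    p[PCM] = d["cm_pF"]
    p[PTAUF] = d.get("tau_f_scale", 1.0)
    p[PTAUF2] = d.get("tau_f2_scale", 1.0)
    return p


#: published resting initial conditions (epicardial)
def initial_state() -> np.ndarray:
    u = np.empty(NVAR)
    u[IV] = -86.2
    u[IM] = 0.0
    u[IH] = 0.75
    u[IJ] = 0.75
    u[IXR1] = 0.0
    u[IXR2] = 1.0
    u[IXS] = 0.0
    u[IR] = 0.0
    u[IS] = 1.0
    u[ID] = 0.0
    u[IF] = 1.0
    u[IF2] = 1.0
    u[IFCASS] = 1.0
    u[IRBAR] = 1.0
    u[ICAI] = 0.00007
    u[ICASR] = 1.3
    u[ICASS] = 0.00007
    u[INAI] = 7.67
    u[IKI] = 138.3
    return u


@njit(cache=True, fastmath=True)
def tp06_currents(u, p):
    """All 12 membrane current densities (pA/pF) at the given state.

    Returns (ina, ito, ik1, ikr, iks, ical, inaca, inak, ipca, ipk,
    ibca, ibna).
    """
    v = u[IV]
    cai = u[ICAI]
    cass = u[ICASS]
    nai = u[INAI]
    ki = u[IKI]

    ek = RTONF * math.log(KO / ki)
    ena = RTONF * math.log(NAO / nai)
    eks = RTONF * math.log((KO + PKNA * NAO) / (ki + PKNA * nai))
    eca = 0.5 * RTONF * math.log(CAO / cai)

    ina = p[PGNA] * u[IM] ** 3 * u[IH] * u[IJ] * (v - ena)
    ito = p[PGTO] * u[IR] * u[IS] * (v - ek)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (v - ek + 100.0))
           + math.exp(0.1 * (v - ek - 10.0))) / (1.0 + math.exp(-0.5 * (v - ek)))
    ik1 = p[PGK1] * ak1 / (ak1 + bk1) * (v - ek)

    ikr = p[PGKR] * math.sqrt(KO / 5.4) * u[IXR1] * u[IXR2] * (v - ek)
    iks = p[PGKS] * u[IXS] * u[IXS] * (v - eks)

    # L-type Ca current (GHK-like driving force about +15 mV)
    vshift = v - 15.0
    if abs(vshift) < 1e-6:
        vshift = 1e-6
    expv = math.exp(2.0 * vshift / RTONF)
    ical = (p[PGCAL] * u[ID] * u[IF] * u[IF2] * u[IFCASS] * 4.0 * vshift
            * (FARADAY / RTONF)
            * (0.25 * cass * expv - CAO) / (expv - 1.0))

    expg = math.exp(NGAMMA * v / RTONF)
    expg1 = math.exp((NGAMMA - 1.0) * v / RTONF)
    inaca = (p[PKNACA]
             * (expg * nai ** 3 * CAO - expg1 * NAO ** 3 * cai * 2.5)
             / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO)
                * (1.0 + KSAT * expg1)))

    inak = (p[PKNAK] * KO / (KO + KMK) * nai / (nai + KMNA)
            / (1.0 + 0.1245 * math.exp(-0.1 * v / RTONF)
               + 0.0353 * math.exp(-v / RTONF)))

    ipca = p[PGPCA] * cai / (KPCA + cai)
    ipk = p[PGPK] * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    ibca = p[PGBCA] * (v - eca)
    ibna = p[PGBNA] * (v - ena)

    return ina, ito, ik1, ikr, iks, ical, inaca, inak, ipca, ipk, ibca, ibna


@njit(cache=True, fastmath=True)
def tp06_total_current(u, p):
    c = tp06_currents(u, p)
    return (c[0] + c[1] + c[2] + c[3] + c[4] + c[5] + c[6] + c[7] + c[8]
            + c[9] + c[10] + c[11])


@njit(cache=True, fastmath=True)
def _gate_update(x, xinf, tau, dt, gate_mode):
    if gate_mode == 0:  # Rush-Larsen exponential integration
        return xinf - (xinf - x) * math.exp(-dt / tau)
    xn = x + dt * (xinf - x) / tau  # clamped forward Euler
    if xn < 0.0:
        xn = 0.0
    elif xn > 1.0:
        xn = 1.0
    return xn


@njit(cache=True, fastmath=True)
def tp06_step(u, p, dt, i_stim, dv_extra, gate_mode, ion_active):
    """Advance one myocyte one forward-Euler step of length dt (ms), in place.

    i_stim : stimulus current density, pA/pF (negative = depolarizing,
        entering dV/dt as -(I_ion + I_stim)).
    dv_extra : additional dV/dt already in mV/ms (diffusion + gap-junction
        coupling to fibroblasts, both normalized by Cm upstream).
    ion_active : False models inactive scar tissue (I_ion = 0, gates and
        concentrations frozen); the membrane then evolves only through
        dv_extra and stimulus.

    Returns the total ionic current density used for the V update.
    """
    v = u[IV]

    if not ion_active:
        u[IV] = v + dt * (-i_stim + dv_extra)
        return 0.0

    c = tp06_currents(u, p)
    ina, ito, ik1, ikr, iks, ical, inaca, inak, ipca, ipk, ibca, ibna = c
    iion = (ina + ito + ik1 + ikr + iks + ical + inaca + inak + ipca + ipk
            + ibca + ibna)

    # --- gates -------------------------------------------------------------
    minf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) \
        + 0.10 / (1.0 + math.exp((v - 50.0) / 200.0))
    taum = am * bm

    hinf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    tauh = 1.0 / (ah + bh)

    jinf = hinf
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * v)
               - 6.948e-6 * math.exp(-0.04391 * v)) * (v + 37.78)
              / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * v) \
            / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    tauj = 1.0 / (aj + bj)

    xr1inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    tauxr1 = axr1 * bxr1

    xr2inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    tauxr2 = axr2 * bxr2

    xsinf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    tauxs = axs * bxs + 80.0

    # epicardial transient-outward gates
    rinf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    taur = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    sinf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
    taus = 85.0 * math.exp(-(v + 45.0) ** 2 / 320.0) \
        + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0

    dinf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    taud = ad * bd + gd

    finf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tauf = (1102.5 * math.exp(-(v + 27.0) ** 2 / 225.0)
            + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
            + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0) * p[PTAUF]

    f2inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    tauf2 = (562.0 * math.exp(-(v + 27.0) ** 2 / 240.0)
             + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
             + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0))) * p[PTAUF2]

    cass = u[ICASS]
    fcassinf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    u[IM] = _gate_update(u[IM], minf, taum, dt, gate_mode)
    u[IH] = _gate_update(u[IH], hinf, tauh, dt, gate_mode)
    u[IJ] = _gate_update(u[IJ], jinf, tauj, dt, gate_mode)
    u[IXR1] = _gate_update(u[IXR1], xr1inf, tauxr1, dt, gate_mode)
    u[IXR2] = _gate_update(u[IXR2], xr2inf, tauxr2, dt, gate_mode)
    u[IXS] = _gate_update(u[IXS], xsinf, tauxs, dt, gate_mode)
    u[IR] = _gate_update(u[IR], rinf, taur, dt, gate_mode)
    u[IS] = _gate_update(u[IS], sinf, taus, dt, gate_mode)
    u[ID] = _gate_update(u[ID], dinf, taud, dt, gate_mode)
    u[IF] = _gate_update(u[IF], finf, tauf, dt, gate_mode)
    u[IF2] = _gate_update(u[IF2], f2inf, tauf2, dt, gate_mode)
    u[IFCASS] = _gate_update(u[IFCASS], fcassinf, taufcass, dt, gate_mode)

    # --- calcium subsystem (instantaneous-buffer formulation) --------------
    casr = u[ICASR]
    cai = u[ICAI]

    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    rbar = u[IRBAR]
    u[IRBAR] = rbar + dt * (-k2 * cass * rbar + K4 * (1.0 - rbar))
    oo = k1 * cass * cass * rbar / (K3 + k1 * cass * cass)
    irel = VREL * oo * (casr - cass)
    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)

    inv_vc_f2 = 1.0 / (2.0 * VC * FARADAY)
    inv_vc_f = 1.0 / (VC * FARADAY)
    inv_vss_f2 = 1.0 / (2.0 * VSS * FARADAY)

    casrbuf = BUFSR * casr / (casr + KBUFSR)
    dcasr = dt * (iup - irel - ileak)
    bjsr = BUFSR - casrbuf - dcasr - casr + KBUFSR
    cjsr = KBUFSR * (casrbuf + dcasr + casr)
    u[ICASR] = (math.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    cassbuf = BUFSS * cass / (cass + KBUFSS)
    dcass = dt * (-ixfer * (VC / VSS) + irel * (VSR / VSS)
                  + (-ical * inv_vss_f2 * CAPACITANCE))
    bcss = BUFSS - cassbuf - dcass - cass + KBUFSS
    ccss = KBUFSS * (cassbuf + dcass + cass)
    u[ICASS] = (math.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0

    caibuf = BUFC * cai / (cai + KBUFC)
    dcai = dt * ((-(ibca + ipca - 2.0 * inaca) * inv_vc_f2 * CAPACITANCE)
                 - (iup - ileak) * (VSR / VC) + ixfer)
    bc = BUFC - caibuf - dcai - cai + KBUFC
    cc = KBUFC * (caibuf + dcai + cai)
    u[ICAI] = (math.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    u[INAI] += dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca)
                     * inv_vc_f * CAPACITANCE)
    u[IKI] += dt * (-(i_stim + ik1 + ito + ikr + iks - 2.0 * inak + ipk)
                    * inv_vc_f * CAPACITANCE)

    u[IV] = v + dt * (-iion - i_stim + dv_extra)
    return iion


# ---------------------------------------------------------------------------
# tabulated fast path for tissue runs
#
# All purely voltage-dependent factors (gate steady states, the per-step
# gate update factor for a fixed dt, and the exponential coefficients of
# I_CaL, I_NaCa, I_NaK, I_pK and the I_K1 rectification) are tabulated
# on a 0.02 mV grid and linearly interpolated.  The calcium subsystem
# and ion bookkeeping are identical to tp06_step.

TAB_VMIN = -150.0
TAB_VMAX = 100.0
TAB_DV = 0.02
TAB_N = int(round((TAB_VMAX - TAB_VMIN) / TAB_DV)) + 2

# column ids: 11 voltage gates x (inf, update factor), then currents
(CM_INF, CM_F, CH_INF, CH_F, CJ_INF, CJ_F, CXR1_INF, CXR1_F, CXR2_INF,
 CXR2_F, CXS_INF, CXS_F, CR_INF, CR_F, CS_INF, CS_F, CD_INF, CD_F,
 CF_INF, CF_F, CF2_INF, CF2_F, CCAL_A, CCAL_B, CNACA_1, CNACA_2,
 CNAK_F, CPK_F, CK1_INF) = range(29)
TAB_NCOL = 29

_TABLE_CACHE: dict = {}


def build_tables(dt: float, gate_mode: int = 0, tau_f_scale: float = 1.0,
                 tau_f2_scale: float = 1.0) -> np.ndarray:
    """(TAB_N, TAB_NCOL) lookup table for a fixed time step.

    Gate update-factor columns hold exp(-dt/tau) in Rush-Larsen mode and
    dt/tau in clamped forward-Euler mode.  Column CK1_INF is indexed by
    V - E_K rather than V.
    """
    key = (round(dt, 9), gate_mode, round(tau_f_scale, 9),
           round(tau_f2_scale, 9))
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key]
    v = TAB_VMIN + TAB_DV * np.arange(TAB_N)
    tab = np.empty((TAB_N, TAB_NCOL))

    def fac(tau):
        return np.exp(-dt / tau) if gate_mode == 0 else dt / tau

    tab[:, CM_INF] = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) \
        + 0.10 / (1.0 + np.exp((v - 50.0) / 200.0))
    tab[:, CM_F] = fac(am * bm)

    hinf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    tab[:, CH_INF] = hinf
    ah = np.where(v >= -40.0, 0.0, 0.057 * np.exp(-(v + 80.0) / 6.8))
    bh = np.where(v >= -40.0,
                  0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
                  2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v))
    tab[:, CH_F] = fac(1.0 / (ah + bh))

    tab[:, CJ_INF] = hinf
    aj = np.where(
        v >= -40.0, 0.0,
        (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
    bj = np.where(
        v >= -40.0,
        0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
        0.02424 * np.exp(-0.01052 * v)
        / (1.0 + np.exp(-0.1378 * (v + 40.14))))
    tab[:, CJ_F] = fac(1.0 / (aj + bj))

    tab[:, CXR1_INF] = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    tab[:, CXR1_F] = fac(450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
                         * 6.0 / (1.0 + np.exp((v + 30.0) / 11.5)))
    tab[:, CXR2_INF] = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    tab[:, CXR2_F] = fac(3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
                         * 1.12 / (1.0 + np.exp((v - 60.0) / 20.0)))
    tab[:, CXS_INF] = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    tab[:, CXS_F] = fac(1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
                        / (1.0 + np.exp((v - 35.0) / 15.0)) + 80.0)
    tab[:, CR_INF] = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tab[:, CR_F] = fac(9.5 * np.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8)
    tab[:, CS_INF] = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    tab[:, CS_F] = fac(85.0 * np.exp(-(v + 45.0) ** 2 / 320.0)
                       + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0)
    tab[:, CD_INF] = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tab[:, CD_F] = fac(ad * bd + gd)
    tab[:, CF_INF] = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tab[:, CF_F] = fac((1102.5 * np.exp(-(v + 27.0) ** 2 / 225.0)
                        + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
                        + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)
                       * tau_f_scale)
    tab[:, CF2_INF] = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tab[:, CF2_F] = fac((562.0 * np.exp(-(v + 27.0) ** 2 / 240.0)
                         + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
                         + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0)))
                        * tau_f2_scale)

    vs = np.where(np.abs(v - 15.0) < 1e-6, 1e-6, v - 15.0)
    expv = np.exp(2.0 * vs / RTONF)
    coef = 4.0 * vs * (FARADAY / RTONF) / (expv - 1.0)
    tab[:, CCAL_A] = coef * 0.25 * expv     # multiplies CaSS (per G*d*f*f2*fcass)
    tab[:, CCAL_B] = coef * CAO             # subtracted constant part

    expg = np.exp(NGAMMA * v / RTONF)
    expg1 = np.exp((NGAMMA - 1.0) * v / RTONF)
    den = ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO) * (1.0 + KSAT * expg1))
    tab[:, CNACA_1] = expg * CAO / den      # multiplies Nai^3
    tab[:, CNACA_2] = expg1 * NAO ** 3 * 2.5 / den  # multiplies Cai

    tab[:, CNAK_F] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTONF)
                            + 0.0353 * np.exp(-v / RTONF))
    tab[:, CPK_F] = 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))

    dvk = v  # column indexed by V - E_K
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (dvk - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (dvk + 100.0)) + np.exp(0.1 * (dvk - 10.0))) \
        / (1.0 + np.exp(-0.5 * dvk))
    tab[:, CK1_INF] = ak1 / (ak1 + bk1)

    _TABLE_CACHE[key] = tab
    return tab


@njit(cache=True, fastmath=True, inline="always")
def _tab_idx(v):
    x = (v - TAB_VMIN) / TAB_DV
    if x < 0.0:
        x = 0.0
    elif x > TAB_N - 2:
        x = TAB_N - 2.0
    i = int(x)
    return i, x - i


@njit(cache=True, fastmath=True)
def tp06_step_tab(u, p, dt, i_stim, dv_extra, gate_mode, ion_active, tab):
    """Table-driven variant of tp06_step (same state layout and units)."""
    v = u[IV]

    if not ion_active:
        u[IV] = v + dt * (-i_stim + dv_extra)
        return 0.0

    cai = u[ICAI]
    cass = u[ICASS]
    nai = u[INAI]
    ki = u[IKI]

    ek = RTONF * math.log(KO / ki)
    ena = RTONF * math.log(NAO / nai)
    eks = RTONF * math.log((KO + PKNA * NAO) / (ki + PKNA * nai))
    eca = 0.5 * RTONF * math.log(CAO / cai)

    i0, w = _tab_idx(v)
    r0 = tab[i0]
    r1 = tab[i0 + 1]

    ina = p[PGNA] * u[IM] ** 3 * u[IH] * u[IJ] * (v - ena)
    ito = p[PGTO] * u[IR] * u[IS] * (v - ek)

    k0, wk = _tab_idx(v - ek)
    xk1 = tab[k0, CK1_INF] + wk * (tab[k0 + 1, CK1_INF] - tab[k0, CK1_INF])
    ik1 = p[PGK1] * xk1 * (v - ek)

    ikr = p[PGKR] * u[IXR1] * u[IXR2] * (v - ek)  # sqrt(Ko/5.4) = 1
    iks = p[PGKS] * u[IXS] * u[IXS] * (v - eks)

    cal_a = r0[CCAL_A] + w * (r1[CCAL_A] - r0[CCAL_A])
    cal_b = r0[CCAL_B] + w * (r1[CCAL_B] - r0[CCAL_B])
    ical = p[PGCAL] * u[ID] * u[IF] * u[IF2] * u[IFCASS] \
        * (cal_a * cass - cal_b)

    n1 = r0[CNACA_1] + w * (r1[CNACA_1] - r0[CNACA_1])
    n2 = r0[CNACA_2] + w * (r1[CNACA_2] - r0[CNACA_2])
    inaca = p[PKNACA] * (n1 * nai ** 3 - n2 * cai)

    nakf = r0[CNAK_F] + w * (r1[CNAK_F] - r0[CNAK_F])
    inak = p[PKNAK] * KO / (KO + KMK) * nai / (nai + KMNA) * nakf

    ipca = p[PGPCA] * cai / (KPCA + cai)
    pkf = r0[CPK_F] + w * (r1[CPK_F] - r0[CPK_F])
    ipk = p[PGPK] * (v - ek) * pkf
    ibca = p[PGBCA] * (v - eca)
    ibna = p[PGBNA] * (v - ena)

    iion = (ina + ito + ik1 + ikr + iks + ical + inaca + inak + ipca + ipk
            + ibca + ibna)

    # --- gates via tables --------------------------------------------------
    for g in range(11):
        cinf = 2 * g
        cfac = 2 * g + 1
        xinf = r0[cinf] + w * (r1[cinf] - r0[cinf])
        f = r0[cfac] + w * (r1[cfac] - r0[cfac])
        idx = IM + g
        x = u[idx]
        if gate_mode == 0:
            u[idx] = xinf + (x - xinf) * f
        else:
            xn = x + f * (xinf - x)
            if xn < 0.0:
                xn = 0.0
            elif xn > 1.0:
                xn = 1.0
            u[idx] = xn

    fcassinf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    u[IFCASS] = _gate_update(u[IFCASS], fcassinf, taufcass, dt, gate_mode)

    # --- calcium subsystem and bookkeeping (identical to tp06_step) --------
    casr = u[ICASR]

    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    rbar = u[IRBAR]
    u[IRBAR] = rbar + dt * (-k2 * cass * rbar + K4 * (1.0 - rbar))
    oo = k1 * cass * cass * rbar / (K3 + k1 * cass * cass)
    irel = VREL * oo * (casr - cass)
    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)

    inv_vc_f2 = 1.0 / (2.0 * VC * FARADAY)
    inv_vc_f = 1.0 / (VC * FARADAY)
    inv_vss_f2 = 1.0 / (2.0 * VSS * FARADAY)

    casrbuf = BUFSR * casr / (casr + KBUFSR)
    dcasr = dt * (iup - irel - ileak)
    bjsr = BUFSR - casrbuf - dcasr - casr + KBUFSR
    cjsr = KBUFSR * (casrbuf + dcasr + casr)
    u[ICASR] = (math.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

    cassbuf = BUFSS * cass / (cass + KBUFSS)
    dcass = dt * (-ixfer * (VC / VSS) + irel * (VSR / VSS)
                  + (-ical * inv_vss_f2 * CAPACITANCE))
    bcss = BUFSS - cassbuf - dcass - cass + KBUFSS
    ccss = KBUFSS * (cassbuf + dcass + cass)
    u[ICASS] = (math.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0

    caibuf = BUFC * cai / (cai + KBUFC)
    dcai = dt * ((-(ibca + ipca - 2.0 * inaca) * inv_vc_f2 * CAPACITANCE)
                 - (iup - ileak) * (VSR / VC) + ixfer)
    bc = BUFC - caibuf - dcai - cai + KBUFC
    cc = KBUFC * (caibuf + dcai + cai)
    u[ICAI] = (math.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    u[INAI] += dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca)
                     * inv_vc_f * CAPACITANCE)
    u[IKI] += dt * (-(i_stim + ik1 + ito + ikr + iks - 2.0 * inak + ipk)
                    * inv_vc_f * CAPACITANCE)

    u[IV] = v + dt * (-iion - i_stim + dv_extra)
    return iion
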