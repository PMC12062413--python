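"""Numba inner loops for the 2D monodomain solver.

The myocyte field is stored C-contiguously as (n_rows, n_cols, 19) so a
grid point's state is one contiguous slice; fibroblast units as (K, 3).
Face diffusivities (already divided by dx^2, units 1/ms) implement the
flux-conservative five-point stencil; a zero face is both the domain
no-flux boundary and the scar-rim no-flux boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import maccannell as mac
from . import tp06


@njit(cache=True, fastmath=True)
def laplacian_into(v, xf, yf, out):
    """Flux-form discrete div(D grad V) (mV/ms) into ``out``.

    xf : (n_rows, n_cols + 1), xf[i, j] = D/dx^2 on the face between
         columns j-1 and j (0 at domain borders and scar faces);
    yf : (n_rows + 1, n_cols) analogous between rows.
    """
    n_rows, n_cols = v.shape
    for i in range(n_rows):
        for j in range(n_cols):
            acc = 0.0
            f = xf[i, j + 1]
            if f > 0.0:
                acc += f * (v[i, j + 1] - v[i, j])
            f = xf[i, j]
            if f > 0.0:
                acc -= f * (v[i, j] - v[i, j - 1])
            f = yf[i + 1, j]
            if f > 0.0:
                acc += f * (v[i + 1, j] - v[i, j])
            f = yf[i, j]
            if f > 0.0:
                acc -= f * (v[i, j] - v[i - 1, j])
            out[i, j] = acc


@njit(cache=True, fastmath=True)
def advance(U, F, p, fp, xf, yf, dt, t0, nsteps,
            scar, inactive_scar, myo_ion_on, fib_ion_on,
            link_i, link_j, link_unit, link_gs,
            stim_mask, stim_starts, stim_dur, stim_amp,
            line_i, line_j, line_buf, line_pos,
            act_t, act_n, act_thresh, act_lockout, last_act,
            gate_mode, tab):
    """Advance the coupled myocyte field + fibroblast units by nsteps.

    Both sides of every gap junction are evaluated at the same time
    level (the pre-step voltages).  Returns the index of the first
    non-finite grid point as (code, i, j) where code 0 = ok, 1 = blow-up.
    """
    n_rows, n_cols, _ = U.shape
    nfib = F.shape[0]
    nlink = link_i.shape[0]
    nline = line_i.shape[0]
    cm = p[tp06.PCM]
    nf_cf = fp[mac.FNF] * fp[mac.FCF]

    vold = np.empty((n_rows, n_cols))
    lap = np.empty((n_rows, n_cols))
    cplm = np.zeros((n_rows, n_cols))
    cplf = np.zeros(nfib)

    for istep in range(nsteps):
        t = t0 + istep * dt

        stim_now = 0.0
        for k in range(stim_starts.shape[0]):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                stim_now = stim_amp
                break

        for i in range(n_rows):
            for j in range(n_cols):
                vold[i, j] = U[i, j, tp06.IV]
                cplm[i, j] = 0.0
        for k in range(nfib):
            cplf[k] = 0.0

        laplacian_into(vold, xf, yf, lap)

        # gap junctions, both directions from the same time level
        for l in range(nlink):
            i = link_i[l]
            j = link_j[l]
            k = link_unit[l]
            imyo = link_gs[l] * (F[k, mac.FV] - vold[i, j])  # pA into myocyte
            cplm[i, j] += imyo
            cplf[k] -= imyo

        for k in range(nfib):
            if fib_ion_on:
                mac.fib_step(F[k], fp, dt, cplf[k] / nf_cf, gate_mode)
            else:
                F[k, mac.FV] += dt * cplf[k] / nf_cf

        for i in range(n_rows):
            for j in range(n_cols):
                istim = stim_now if stim_mask[i, j] else 0.0
                active = myo_ion_on and not (inactive_scar and scar[i, j])
                extra = lap[i, j] + cplm[i, j] / cm
                tp06.tp06_step_tab(U[i, j], p, dt, istim, extra, gate_mode,
                                   active, tab)
                vnew = U[i, j, tp06.IV]
                # magnitude guard (robust under fastmath, where NaN
                # checks are unreliable)
                if not (-1.0e3 < vnew < 1.0e3):
                    return 1, i, j
                # activation logging: upward crossing with lockout
                if vold[i, j] < act_thresh <= vnew:
                    if t - last_act[i, j] >= act_lockout:
                        n = act_n[i, j]
                        if n < act_t.shape[0]:
                            act_t[n, i, j] = t
                            act_n[i, j] = n + 1
                        last_act[i, j] = t

        for s in range(nline):
            line_buf[line_pos + istep, s] = U[line_i[s], line_j[s], tp06.IV]

    return 0, -1, -1
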