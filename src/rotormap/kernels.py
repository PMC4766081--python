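"""Fixed-step monodomain integration kernel.

Operator-split scheme: explicit 5-point finite-difference diffusion plus a
Rush-Larsen exponential update for the voltage-gated channels, forward
Euler for membrane potential, Ca-handling gates with slow/state-dependent
time constants, and the intracellular concentrations.  All voltage-dependent
rate expressions are pre-tabulated on a fine V grid (0.05 mV spacing,
nearest-entry lookup), which removes every transcendental from the gate
updates; only the two Ca-release sigmoids are evaluated per node per step.

The kernel is numba-compiled and operates on flat state arrays:

``V``    (ny, nx) float64 membrane potential, mV
``G``    (N, 20) float64 remaining state (gates then concentrations), in
         the order of ``ionic.STATE_NAMES[1:]``
``EN``   (N, 4) cached slowly-varying per-node terms: ENa, EK, ECa and the
         Nai-dependent INaK saturation factor, refreshed every
         ``nernst_every`` sub-steps (default 10, i.e. 0.5 ms at dt=0.05).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import ionic
from .ionic import (CAO, CA_UP_MAX, CM, CSQN_MAX, CMDN_MAX, FARADAY, GAMMA,
                    G_B_CA, G_B_NA, G_KR, G_KS, I_NAK_MAX, I_PCA_MAX, KM_CA,
                    KM_CMDN, KM_CSQN, KM_KO, KM_NA, KM_NAI, KM_TRPN, KO, K_REL,
                    K_SAT, K_UP, NAO, RTF, SIGMA_NAK, TAU_TR, TRPN_MAX, V_I,
                    V_REL, V_UP, IonicParams)

V_TAB_MIN = -110.0
V_TAB_MAX = 80.0
V_TAB_STEP = 0.05

# Ca-release activation (Fn) table: the two release-gate sigmoids are steep
# functions of Fn alone; tabulating them removes the last per-node exps
FN_MAX = 6e-13
FN_STEP = 2.5e-16

_GATE_ORDER = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")

# table row layout: 2 rows (inf, rl) per tabulated gate, then current helpers
ROW_IK1 = 24
ROW_IKR = 25
ROW_FNAK = 26
ROW_E1 = 27
ROW_E2 = 28
ROW_GKUR = 29
N_ROWS = 30

# prm vector layout
(P_GNA, P_GTO, P_GCAL, P_GK1, P_GKR, P_GKS, P_GBNA, P_GBCA, P_IPCA,
 P_INAK, P_INACA, P_IUP, P_RL_FCA, P_RL_U, P_C_NAI, P_C_CAI, P_VUP_VI,
 P_VREL_VI, P_VREL_VUP, P_C_FN, P_CAUPMAX_INV) = range(21)


def build_tables(params: IonicParams, dt: float):
    """Rate/current lookup tables plus the packed parameter vector."""
    vv = np.arange(V_TAB_MIN, V_TAB_MAX + V_TAB_STEP / 2, V_TAB_STEP)
    tab = np.empty((N_ROWS, vv.size))
    rates = ionic.gate_rates(vv)
    for k, name in enumerate(_GATE_ORDER):
        inf, tau = rates[name]
        tab[2 * k] = inf
        tab[2 * k + 1] = np.exp(-dt / tau)
    tab[ROW_IK1] = 1.0 / (1.0 + np.exp(0.07 * (vv + 80.0)))
    tab[ROW_IKR] = 1.0 / (1.0 + np.exp((vv + 15.0) / 22.4))
    tab[ROW_FNAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * vv / RTF)
                           + 0.0365 * SIGMA_NAK * np.exp(-vv / RTF))
    e1 = np.exp(GAMMA * vv / RTF)
    e2 = np.exp((GAMMA - 1.0) * vv / RTF)
    tab[ROW_E1] = e1 / (1.0 + K_SAT * e2)   # saturation folded in
    tab[ROW_E2] = e2 / (1.0 + K_SAT * e2)
    tab[ROW_GKUR] = params.gKur_scale * ionic.gkur(vv)
    # V-major float32 layout: one node's 30 lookups share a cache line pair
    # and the whole table stays L2-resident during fibrillation
    tab = np.ascontiguousarray(tab.T, dtype=np.float32)

    prm = np.zeros(21)
    prm[P_GNA] = params.gNa
    prm[P_GTO] = params.gto
    prm[P_GCAL] = params.gCaL
    prm[P_GK1] = params.gK1
    prm[P_GKR] = G_KR
    prm[P_GKS] = G_KS
    prm[P_GBNA] = G_B_NA
    prm[P_GBCA] = G_B_CA
    prm[P_IPCA] = I_PCA_MAX
    prm[P_INAK] = I_NAK_MAX * KO / (KO + KM_KO)
    prm[P_INACA] = params.INaCaMax / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO))
    prm[P_IUP] = params.IupMax
    prm[P_RL_FCA] = math.exp(-dt / 2.0)
    prm[P_RL_U] = math.exp(-dt / 8.0)
    prm[P_C_NAI] = CM / (FARADAY * V_I)
    prm[P_C_CAI] = CM / (2.0 * FARADAY * V_I)
    prm[P_VUP_VI] = V_UP / V_I
    prm[P_VREL_VI] = V_REL / V_I
    prm[P_VREL_VUP] = V_REL / V_UP
    prm[P_C_FN] = 5e-13 / FARADAY * CM
    prm[P_CAUPMAX_INV] = 1.0 / CA_UP_MAX

    fn = np.arange(0.0, FN_MAX + FN_STEP / 2, FN_STEP)
    fntab = np.empty((fn.size, 3), dtype=np.float32)
    sig = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    fntab[:, 0] = sig                                                   # u_inf
    fntab[:, 1] = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 13.67e-16))  # v_inf
    fntab[:, 2] = 1.0 / (1.91 + 2.09 * sig)                             # 1/tau_v
    return tab, prm, np.ascontiguousarray(fntab)


def initial_grid_state(ny: int, nx: int,
                       y0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Uniform tissue state (V 2D array, G flat array) from a cell vector."""
    y = np.array(ionic.RESTING_STATE if y0 is None else y0, dtype=float)
    V = np.full((ny, nx), y[0])
    G = np.tile(y[1:], (ny * nx, 1))
    return V, np.ascontiguousarray(G)


@njit(cache=True, fastmath=True, nogil=True)
def _refresh_slow(G, EN):
    n = G.shape[0]
    for i in range(n):
        nai = G[i, 15]
        ki = G[i, 16]
        cai = G[i, 17]
        EN[i, 0] = RTF * math.log(NAO / nai)
        EN[i, 1] = RTF * math.log(KO / ki)
        EN[i, 2] = 0.5 * RTF * math.log(CAO / cai)
        EN[i, 3] = 1.0 / (1.0 + (KM_NAI / nai) ** 1.5)


@njit(cache=True, nogil=True)
def diffusion_only(V, dt, nsteps, cdiff, Lap):
    """Pure-diffusion stepping (ionic and stimulus zeroed); test mode."""
    ny, nx = V.shape
    for s in range(nsteps):
        for r in range(ny):
            rm = 0 if r == 0 else r - 1
            rp = ny - 1 if r == ny - 1 else r + 1
            for c in range(nx):
                cm_ = 0 if c == 0 else c - 1
                cp = nx - 1 if c == nx - 1 else c + 1
                Lap[r, c] = (V[rm, c] + V[rp, c] + V[r, cm_] + V[r, cp]
                             - 4.0 * V[r, c])
        for r in range(ny):
            for c in range(nx):
                V[r, c] += dt * cdiff * Lap[r, c]


@njit(cache=True, fastmath=True, nogil=True, error_model="numpy")
def advance(V, G, EN, lesion, Tab, FnTab, prm, dt, nsteps, cdiff,
            stim_idx, stim_amp, vrest, nernst_every, Lap):
    """Advance the tissue by ``nsteps`` sub-steps of ``dt`` ms.

    ``cdiff`` = Deff/dx^2 (1/ms); ``stim_idx`` flat node indices receiving
    ``stim_amp`` pA/pF for the whole call; lesioned nodes are clamped to
    ``vrest`` but still enter the Laplacian (resting-tissue diffusion).
    Returns the sub-step index at which a non-finite potential was first
    seen, or -1 on success.
    """
    ny, nx = V.shape
    n = ny * nx
    inv_dv = 1.0 / V_TAB_STEP
    nv = Tab.shape[0]
    inv_dfn = 1.0 / FN_STEP
    nfn1 = float(FnTab.shape[0] - 1)
    Vf = V.reshape(n)
    Lf = Lap.reshape(n)

    for s in range(nsteps):
        if s % nernst_every == 0:
            _refresh_slow(G, EN)

        # 5-point Laplacian; zero-flux boundaries (ghost = boundary node),
        # the conservative finite-volume form
        for r in range(ny):
            rm = 0 if r == 0 else r - 1
            rp = ny - 1 if r == ny - 1 else r + 1
            base = r * nx
            for c in range(nx):
                cm_ = 0 if c == 0 else c - 1
                cp = nx - 1 if c == nx - 1 else c + 1
                Lf[base + c] = (V[rm, c] + V[rp, c] + V[r, cm_] + V[r, cp]
                                - 4.0 * V[r, c])

        for i in range(n):
            if lesion[i]:
                continue
            v = Vf[i]
            if not math.isfinite(v):
                return s
            x = (v - V_TAB_MIN) * inv_dv + 0.5
            if x < 0.0:
                x = 0.0
            elif x > nv - 1:
                x = float(nv - 1)
            i0 = int(x)

            m = G[i, 0]
            h = G[i, 1]
            j = G[i, 2]
            oa = G[i, 3]
            oi = G[i, 4]
            ua = G[i, 5]
            ui = G[i, 6]
            xr = G[i, 7]
            xs = G[i, 8]
            d = G[i, 9]
            f = G[i, 10]
            fca = G[i, 11]
            u = G[i, 12]
            vg = G[i, 13]
            w = G[i, 14]
            nai = G[i, 15]
            ki = G[i, 16]
            cai = G[i, 17]
            caup = G[i, 18]
            carel = G[i, 19]

            ena = EN[i, 0]
            ek = EN[i, 1]
            eca = EN[i, 2]
            fnak_nai = EN[i, 3]

            t_ik1 = Tab[i0, ROW_IK1]
            t_ikr = Tab[i0, ROW_IKR]
            t_fnak = Tab[i0, ROW_FNAK]
            t_e1 = Tab[i0, ROW_E1]
            t_e2 = Tab[i0, ROW_E2]
            t_gkur = Tab[i0, ROW_GKUR]

            ina = prm[P_GNA] * m * m * m * h * j * (v - ena)
            ik1 = prm[P_GK1] * (v - ek) * t_ik1
            ito = prm[P_GTO] * oa * oa * oa * oi * (v - ek)
            ikur = t_gkur * ua * ua * ua * ui * (v - ek)
            ikr = prm[P_GKR] * xr * (v - ek) * t_ikr
            iks = prm[P_GKS] * xs * xs * (v - ek)
            ical = prm[P_GCAL] * d * f * fca * (v - 65.0)
            inak = prm[P_INAK] * t_fnak * fnak_nai
            inaca = (prm[P_INACA]
                     * (t_e1 * nai * nai * nai * CAO
                        - t_e2 * NAO * NAO * NAO * cai))
            ibna = prm[P_GBNA] * (v - ena)
            ibca = prm[P_GBCA] * (v - eca)
            ipca = prm[P_IPCA] * cai / (0.0005 + cai)

            irel = K_REL * u * u * vg * w * (carel - cai)
            itr = (caup - carel) / TAU_TR
            iup = prm[P_IUP] * cai / (cai + K_UP)
            iupleak = prm[P_IUP] * caup * prm[P_CAUPMAX_INV]

            i_ion = (ina + ik1 + ito + ikur + ikr + iks + ical + inak
                     + inaca + ibna + ibca + ipca)

            # Rush-Larsen exponential update for the tabulated gates
            for g in range(12):
                inf = Tab[i0, 2 * g]
                rl = Tab[i0, 2 * g + 1]
                if g < 11:  # m..f occupy slots 0..10; w sits at slot 14
                    G[i, g] = inf + (G[i, g] - inf) * rl
                else:
                    G[i, 14] = inf + (w - inf) * rl

            fca_inf = 1.0 / (1.0 + cai / 0.00035)
            G[i, 11] = fca_inf + (fca - fca_inf) * prm[P_RL_FCA]

            fn = 1e-12 * V_REL * irel - prm[P_C_FN] * (0.5 * ical - 0.2 * inaca)
            fx = fn * inv_dfn
            if fx < 0.0:
                fx = 0.0
            elif fx > nfn1:
                fx = nfn1
            fi = int(fx + 0.5)
            sig_u = FnTab[fi, 0]
            v_inf = FnTab[fi, 1]
            inv_tau_v = FnTab[fi, 2]
            G[i, 12] = sig_u + (u - sig_u) * prm[P_RL_U]
            G[i, 13] = vg + dt * (v_inf - vg) * inv_tau_v

            G[i, 15] = nai + dt * ((-3.0 * inak - 3.0 * inaca - ibna - ina)
                                   * prm[P_C_NAI])
            G[i, 16] = ki + dt * ((2.0 * inak - ik1 - ito - ikur - ikr - iks)
                                  * prm[P_C_NAI])
            b1 = ((2.0 * inaca - ipca - ical - ibca) * prm[P_C_CAI]
                  + prm[P_VUP_VI] * (iupleak - iup) + irel * prm[P_VREL_VI])
            kc1 = cai + KM_TRPN
            kc2 = cai + KM_CMDN
            a1 = kc1 * kc1
            a2 = kc2 * kc2
            # Cai buffering factor written with a single division
            denom = a1 * a2 + TRPN_MAX * KM_TRPN * a2 + CMDN_MAX * KM_CMDN * a1
            G[i, 17] = cai + dt * b1 * a1 * a2 / denom
            G[i, 18] = caup + dt * (iup - iupleak - itr * prm[P_VREL_VUP])
            kc3 = carel + KM_CSQN
            a3 = kc3 * kc3
            G[i, 19] = carel + dt * (itr - irel) * a3 / (a3 + CSQN_MAX * KM_CSQN)

            Vf[i] = v + dt * (cdiff * Lf[i] - i_ion)

        for k in range(stim_idx.size):
            Vf[stim_idx[k]] += dt * (-stim_amp)

        for i in range(n):
            if lesion[i]:
                Vf[i] = vrest
    return -1
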