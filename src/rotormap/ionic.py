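"""Courtemanche human atrial action-potential kinetics.

Implements the 21-variable human atrial ionic model (membrane potential,
15 gating variables, 5 intracellular/SR concentrations) together with the
two parameter presets used throughout the package:

``control``
    the published maximal conductances (gNa 7.8, gto 0.1652, gCaL 0.1238,
    gK1 0.09 nS/pF; INaCa_max 1600 pA/pF; Iup_max 0.005 mM/ms),

``peaf``
    persistent-AF electrical remodeling expressed as multiplicative
    scalers on those maxima: INa x0.9, Ito x0.3, ICaL x0.5, IK1 x2.0,
    IKur x0.5, INaCa x1.4, Iup x1.25.  The remodeled cell has a much
    shorter action potential and supports sustained reentry.

Units follow the cell model: mV, ms, pA/pF, mM, nS/pF (conductances are
normalised by the 100 pF membrane capacitance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# Physical constants and cell geometry
# ---------------------------------------------------------------------------

R_GAS = 8.3143          # J / (mol K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C / mmol
RTF = R_GAS * TEMP / FARADAY  # mV

CM = 100.0              # pF, whole-cell membrane capacitance

V_CELL = 20100.0        # um^3
V_I = 13668.0           # um^3, intracellular volume
V_UP = 1109.52          # um^3, SR uptake compartment
V_REL = 96.48           # um^3, SR release compartment

KO = 5.4                # mM extracellular K+
NAO = 140.0             # mM extracellular Na+
CAO = 1.8               # mM extracellular Ca2+

K_Q10 = 3.0             # temperature scaling for Ito / IKur gates
GAMMA = 0.35            # INaCa voltage partition

KM_NAI = 10.0           # mM, INaK half-saturation for Nai
KM_KO = 1.5             # mM, INaK half-saturation for Ko
KM_NA = 87.5            # mM, INaCa
KM_CA = 1.38            # mM, INaCa
K_SAT = 0.1             # INaCa saturation factor
SIGMA_NAK = (math.exp(NAO / 67.3) - 1.0) / 7.0

K_REL = 30.0            # 1/ms, SR release rate
K_UP = 0.00092          # mM, SERCA half-saturation
CA_UP_MAX = 15.0        # mM
TAU_TR = 180.0          # ms, SR transfer time constant

CMDN_MAX = 0.05         # mM calmodulin
TRPN_MAX = 0.07         # mM troponin
CSQN_MAX = 10.0         # mM calsequestrin
KM_CMDN = 0.00238       # mM
KM_TRPN = 0.0005        # mM
KM_CSQN = 0.8           # mM

G_KR = 0.029411765      # nS/pF
G_KS = 0.12941176       # nS/pF
G_B_CA = 0.001131       # nS/pF
G_B_NA = 0.0006744375   # nS/pF
I_NAK_MAX = 0.59933874  # pA/pF
I_PCA_MAX = 0.275       # pA/pF

#: state-vector layout used everywhere a flat vector is needed
STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "vg", "w", "Nai", "Ki", "Cai", "CaUp", "CaRel",
)
N_STATE = len(STATE_NAMES)

#: published resting steady state (1 Hz-adapted initial conditions)
RESTING_STATE = np.array([
    -81.18,        # V
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # fca
    2.35e-112,     # u
    1.0,           # vg
    9.992e-1,      # w
    1.117e1,       # Nai
    1.390e2,       # Ki
    1.013e-4,      # Cai
    1.488,         # CaUp
    1.488,         # CaRel
])


@dataclass
class CellState:
    """Named view of one node's 21 state variables."""

    V: float = -81.18
    m: float = 2.908e-3
    h: float = 9.649e-1
    j: float = 9.775e-1
    oa: float = 3.043e-2
    oi: float = 9.992e-1
    ua: float = 4.966e-3
    ui: float = 9.986e-1
    xr: float = 3.296e-5
    xs: float = 1.869e-2
    d: float = 1.367e-4
    f: float = 9.996e-1
    fca: float = 7.755e-1
    u: float = 2.35e-112
    vg: float = 1.0
    w: float = 9.992e-1
    Nai: float = 1.117e1
    Ki: float = 1.390e2
    Cai: float = 1.013e-4
    CaUp: float = 1.488
    CaRel: float = 1.488

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(**{n: float(v) for n, v in zip(STATE_NAMES, y)})

    def validate(self) -> None:
        y = self.to_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite state variable")
        gates = y[1:16]
        if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
            raise ValueError("gate variable outside [0, 1]")
        if np.any(y[16:] <= 0):
            raise ValueError("non-positive concentration")


@dataclass(frozen=True)
class RemodelingScalers:
    """Multiplicative remodeling factors on the channel maxima."""

    sNa: float = 1.0
    sTo: float = 1.0
    sCaL: float = 1.0
    sK1: float = 1.0
    sKur: float = 1.0
    sNaCa: float = 1.0
    sUp: float = 1.0

    def validate(self) -> None:
        for name in ("sNa", "sTo", "sCaL", "sK1", "sKur", "sNaCa", "sUp"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative remodeling scaler {name}")


#: persistent-AF remodeling set
PEAF_SCALERS = RemodelingScalers(
    sNa=0.9, sTo=0.3, sCaL=0.5, sK1=2.0, sKur=0.5, sNaCa=1.4, sUp=1.25,
)


@dataclass(frozen=True)
class IonicParams:
    """Maximal conductances / currents that differ between presets.

    All remaining model constants are module-level and shared.
    ``gKur_scale`` multiplies the voltage-dependent gKur(V) sigmoid.
    """

    gNa: float = 7.8          # nS/pF
    gto: float = 0.1652       # nS/pF
    gCaL: float = 0.1238      # nS/pF
    gK1: float = 0.09         # nS/pF
    gKur_scale: float = 1.0   # multiplies gkur(V)
    INaCaMax: float = 1600.0  # pA/pF
    IupMax: float = 0.005     # mM/ms
    name: str = "control"

    def validate(self) -> None:
        for k in ("gNa", "gto", "gCaL", "gK1", "gKur_scale", "INaCaMax", "IupMax"):
            if getattr(self, k) < 0:
                raise ValueError(f"negative maximum {k}")


CONTROL_PARAMS = IonicParams()


def apply_remodeling(params: IonicParams, s: RemodelingScalers,
                     name: str | None = None) -> IonicParams:
    """Scale channel maxima by the remodeling factors; other constants untouched."""
    s.validate()
    params.validate()
    return replace(
        params,
        gNa=params.gNa * s.sNa,
        gto=params.gto * s.sTo,
        gCaL=params.gCaL * s.sCaL,
        gK1=params.gK1 * s.sK1,
        gKur_scale=params.gKur_scale * s.sKur,
        INaCaMax=params.INaCaMax * s.sNaCa,
        IupMax=params.IupMax * s.sUp,
        name=name or params.name,
    )


PEAF_PARAMS = apply_remodeling(CONTROL_PARAMS, PEAF_SCALERS, name="peaf")

PRESETS = {"control": CONTROL_PARAMS, "peaf": PEAF_PARAMS}


def get_preset(name: str) -> IonicParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


def gkur(V: float | np.ndarray) -> float | np.ndarray:
    """Voltage-dependent ultrarapid-K+ maximal conductance (nS/pF)."""
    return 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))


# ---------------------------------------------------------------------------
# Gate kinetics (rates in 1/ms, V in mV)
# ---------------------------------------------------------------------------

def _safe_ratio(num, den, limit):
    """num/den with the removable singularity at den == 0 replaced by limit."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-9
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def gate_rates(V):
    """Steady states and time constants for the 12 V-dependent gates.

    Returns dict name -> (inf, tau).  fca/u/vg depend on Cai/Fn and are
    handled in the right-hand side itself.
    """
    V = np.asarray(V, dtype=float)
    out = {}

    a = _safe_ratio(0.32 * (V + 47.13), 1.0 - np.exp(-0.1 * (V + 47.13)), 3.2)
    b = 0.08 * np.exp(-V / 11.0)
    out["m"] = (a / (a + b), 1.0 / (a + b))

    low = V < -40.0
    ah = np.where(low, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    bh = np.where(low,
                  3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
                  1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))))
    out["h"] = (ah / (ah + bh), 1.0 / (ah + bh))

    aj = np.where(
        low,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0)
    bj = np.where(
        low,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))))
    out["j"] = (aj / (aj + bj), 1.0 / (aj + bj))

    ao = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    bo = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    out["oa"] = (1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54)),
                 1.0 / ((ao + bo) * K_Q10))

    aoi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    boi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    out["oi"] = (1.0 / (1.0 + np.exp((V + 43.1) / 5.3)),
                 1.0 / ((aoi + boi) * K_Q10))

    out["ua"] = (1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6)),
                 1.0 / ((ao + bo) * K_Q10))  # shares Ito activation rates

    aui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    bui = np.exp((V - 158.0) / 16.0)
    out["ui"] = (1.0 / (1.0 + np.exp((V - 99.45) / 27.48)),
                 1.0 / ((aui + bui) * K_Q10))

    axr = _safe_ratio(0.0003 * (V + 14.1),
                      1.0 - np.exp(-(V + 14.1) / 5.0), 0.0015)
    bxr = _safe_ratio(7.3898e-5 * (V - 3.3328),
                      np.exp((V - 3.3328) / 5.1237) - 1.0, 3.7862e-4)
    out["xr"] = (1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5)), 1.0 / (axr + bxr))

    axs = _safe_ratio(4e-5 * (V - 19.9),
                      1.0 - np.exp(-(V - 19.9) / 17.0), 6.8e-4)
    bxs = _safe_ratio(3.5e-5 * (V - 19.9),
                      np.exp((V - 19.9) / 9.0) - 1.0, 3.15e-4)
    out["xs"] = (1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7)),
                 0.5 / (axs + bxs))

    e_d = np.exp(-(V + 10.0) / 6.24)
    tau_d = _safe_ratio(1.0 - e_d, 0.035 * (V + 10.0) * (1.0 + e_d),
                        1.0 / (6.24 * 0.035 * 2.0))
    out["d"] = (1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0)), tau_d)

    out["f"] = (1.0 / (1.0 + np.exp((V + 28.0) / 6.9)),
                9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02))

    e_w = np.exp(-(V - 7.9) / 5.0)
    tau_w = _safe_ratio(6.0 * (1.0 - e_w),
                        (1.0 + 0.3 * e_w) * (V - 7.9), 6.0 / (1.3 * 5.0))
    out["w"] = (1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0)), tau_w)

    return out


def membrane_currents(y: np.ndarray, p: IonicParams) -> dict:
    """All twelve membrane currents (pA/pF) plus SR fluxes for a state vector."""
    (V, m, h, j, oa, oi, ua, ui, xr, xs,
     d, f, fca, u, vg, w, Nai, Ki, Cai, CaUp, CaRel) = y

    ENa = RTF * math.log(NAO / Nai)
    EK = RTF * math.log(KO / Ki)
    ECa = 0.5 * RTF * math.log(CAO / Cai)

    cur = {}
    cur["INa"] = p.gNa * m ** 3 * h * j * (V - ENa)
    cur["IK1"] = p.gK1 * (V - EK) / (1.0 + math.exp(0.07 * (V + 80.0)))
    cur["Ito"] = p.gto * oa ** 3 * oi * (V - EK)
    cur["IKur"] = p.gKur_scale * float(gkur(V)) * ua ** 3 * ui * (V - EK)
    cur["IKr"] = G_KR * xr * (V - EK) / (1.0 + math.exp((V + 15.0) / 22.4))
    cur["IKs"] = G_KS * xs ** 2 * (V - EK)
    cur["ICaL"] = p.gCaL * d * f * fca * (V - 65.0)

    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / RTF)
                  + 0.0365 * SIGMA_NAK * math.exp(-V / RTF))
    cur["INaK"] = (I_NAK_MAX * fnak / (1.0 + (KM_NAI / Nai) ** 1.5)
                   * KO / (KO + KM_KO))

    e1 = math.exp(GAMMA * V / RTF)
    e2 = math.exp((GAMMA - 1.0) * V / RTF)
    cur["INaCa"] = (p.INaCaMax * (e1 * Nai ** 3 * CAO - e2 * NAO ** 3 * Cai)
                    / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO)
                       * (1.0 + K_SAT * e2)))

    cur["IbNa"] = G_B_NA * (V - ENa)
    cur["IbCa"] = G_B_CA * (V - ECa)
    cur["IpCa"] = I_PCA_MAX * Cai / (0.0005 + Cai)

    cur["Irel"] = K_REL * u ** 2 * vg * w * (CaRel - Cai)
    cur["Itr"] = (CaUp - CaRel) / TAU_TR
    cur["Iup"] = p.IupMax / (1.0 + K_UP / Cai)
    cur["IupLeak"] = p.IupMax * CaUp / CA_UP_MAX
    return cur


def ionic_rhs(y: np.ndarray, p: IonicParams, stim: float = 0.0) -> np.ndarray:
    """Time derivative of the 21-vector state; ``stim`` in pA/pF.

    Raises ``FloatingPointError`` on a non-finite state so integration
    failures surface instead of propagating NaNs.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to ionic_rhs")

    (V, m, h, j, oa, oi, ua, ui, xr, xs,
     d, f, fca, u, vg, w, Nai, Ki, Cai, CaUp, CaRel) = y
    cur = membrane_currents(y, p)

    i_ion = (cur["INa"] + cur["IK1"] + cur["Ito"] + cur["IKur"] + cur["IKr"]
             + cur["IKs"] + cur["ICaL"] + cur["INaK"] + cur["INaCa"]
             + cur["IbNa"] + cur["IbCa"] + cur["IpCa"])

    dy = np.empty(N_STATE)
    dy[0] = -(i_ion + stim)

    rates = gate_rates(V)
    for k, name in enumerate(("m", "h", "j", "oa", "oi", "ua", "ui",
                              "xr", "xs", "d", "f")):
        inf, tau = rates[name]
        dy[1 + k] = (float(inf) - y[1 + k]) / float(tau)

    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    dy[12] = (fca_inf - fca) / 2.0

    fn = (1e-12 * V_REL * cur["Irel"]
          - (5e-13 / FARADAY) * (0.5 * cur["ICaL"] - 0.2 * cur["INaCa"]) * CM)
    sig_u = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    u_inf = sig_u
    dy[13] = (u_inf - u) / 8.0
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 * sig_u
    dy[14] = (v_inf - vg) / tau_v
    w_inf, tau_w = rates["w"]
    dy[15] = (float(w_inf) - w) / float(tau_w)

    dy[16] = (-3.0 * cur["INaK"] - 3.0 * cur["INaCa"] - cur["IbNa"]
              - cur["INa"]) * CM / (FARADAY * V_I)
    dy[17] = (2.0 * cur["INaK"] - cur["IK1"] - cur["Ito"] - cur["IKur"]
              - cur["IKr"] - cur["IKs"]) * CM / (FARADAY * V_I)

    b1 = ((2.0 * cur["INaCa"] - cur["IpCa"] - cur["ICaL"] - cur["IbCa"])
          * CM / (2.0 * FARADAY * V_I)
          + (V_UP * (cur["IupLeak"] - cur["Iup"]) + cur["Irel"] * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (Cai + KM_CMDN) ** 2)
    dy[18] = b1 / b2

    dy[19] = cur["Iup"] - cur["IupLeak"] - cur["Itr"] * V_REL / V_UP
    dy[20] = ((cur["Itr"] - cur["Irel"])
              / (1.0 + CSQN_MAX * KM_CSQN / (CaRel + KM_CSQN) ** 2))
    return dy


def reference_ap(params: IonicParams, cl_ms: float = 1000.0, n_beats: int = 2,
                 stim_pa_pf: float = -20.0, stim_ms: float = 2.0,
                 dt_out: float = 0.5, y0: np.ndarray | None = None):
    """Brute-force adaptive reference integration of a paced single cell.

    Uses LSODA on :func:`ionic_rhs`; this is the slow, independent check
    against which the fixed-step tissue kernel is validated.  Returns
    (t, V, y_end) for the final beat.
    """
    from scipy.integrate import solve_ivp

    y = np.array(RESTING_STATE if y0 is None else y0, dtype=float)
    t_out = v_out = None
    for beat in range(n_beats):
        sol1 = solve_ivp(lambda t, yy: ionic_rhs(yy, params, stim_pa_pf),
                         (0.0, stim_ms), y, method="LSODA",
                         max_step=0.05, rtol=1e-6, atol=1e-8)
        y = sol1.y[:, -1]
        tseg = np.arange(stim_ms, cl_ms + 1e-9, dt_out)
        sol2 = solve_ivp(lambda t, yy: ionic_rhs(yy, params, 0.0),
                         (stim_ms, cl_ms), y, method="LSODA",
                         t_eval=tseg, max_step=1.0, rtol=1e-6, atol=1e-8)
        y = sol2.y[:, -1]
        if beat == n_beats - 1:
            t_out = np.concatenate([sol1.t, sol2.t])
            v_out = np.concatenate([sol1.y[0], sol2.y[0]])
            t_out, keep = np.unique(t_out, return_index=True)
            v_out = v_out[keep]
    return t_out, v_out, y


def apd(t: np.ndarray, V: np.ndarray, repol_fraction: float = 0.9) -> float:
    """Action-potential duration at the given repolarisation level (ms).

    Measured from the maximum-dV/dt upstroke time to the downward crossing
    of Vrest + (1 - fraction) * amplitude.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    dv = np.gradient(V, t)
    i_up = int(np.argmax(dv))
    v_rest = float(V[: max(i_up, 1)].min()) if i_up > 0 else float(V.min())
    v_peak = float(V.max())
    v_level = v_peak - repol_fraction * (v_peak - v_rest)
    below = np.nonzero((V[i_up:] < v_level))[0]
    # first sustained downward crossing after the peak
    i_peak = int(np.argmax(V))
    below = below[below + i_up > i_peak]
    if below.size == 0:
        raise ValueError("no repolarisation crossing found")
    k = below[0] + i_up
    # linear interpolation between samples
    t0, t1 = t[k - 1], t[k]
    v0, v1 = V[k - 1], V[k]
    t_cross = t0 + (v0 - v_level) / (v0 - v1) * (t1 - t0)
    return float(t_cross - t[i_up])
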