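"""ten Tusscher-Panfilov 2006 epicardial human ventricular myocyte model.

Full equation set of the published epicardial parameterisation (constants
and initial state from the authors' source code / CellML encoding,
including the erratum values k4 = 0.005 ms^-1 and V_rel = 0.102 mM/ms),
with the three slow-delayed-rectifier parameters exposed for injection:

* ``g_ks``  - maximal IKs conductance, mS/uF (published epicardial 0.392);
* ``v50``   - midpoint of the xs activation curve, mV (published -5);
* ``slope`` - slope factor of the xs activation curve, mV (published 14);

so that xs_inf(V) = 1/(1 + exp((v50 - V)/slope)) and
IKs = g_ks * xs^2 * (V - E_Ks).  The xs time constant keeps its
published voltage dependence (an optional multiplicative ``tau_scale``
is provided, 1 by default).

Units: time ms, voltage mV, currents A/F, concentrations mM.
The right-hand side is jit-compiled with numba when available and falls
back to the identical pure-Python function otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "IKsParams",
    "PacingConfig",
    "APBiomarkers",
    "BeatTrace",
    "PacingResult",
    "STATE_NAMES",
    "initial_state",
    "xs_steady_state",
    "e_ks",
    "iks_current",
    "derivatives",
    "compute_currents",
    "pace_to_steady_state",
    "measure_biomarkers",
    "compare_variants",
]

# --- physical constants ----------------------------------------------------
R_GAS = 8314.472        # J / (kmol K)
T_BODY = 310.0          # K
FARADAY = 96485.3415    # C / mol
RTONF = R_GAS * T_BODY / FARADAY  # mV

# --- cell geometry / capacitance -------------------------------------------
CM = 0.185              # uF
V_C = 0.016404          # cytosolic volume (um^3 scaled)
V_SR = 0.001094
V_SS = 0.00005468

# --- external concentrations (mM) ------------------------------------------
K_O = 5.4
NA_O = 140.0
CA_O = 2.0

# --- maximal conductances / fluxes (epicardial) -----------------------------
G_NA = 14.838
G_K1 = 5.405
G_TO = 0.294
G_KR = 0.153
G_KS_DEFAULT = 0.392
P_KNA = 0.03
G_CAL = 3.98e-5
K_NACA = 1000.0
GAMMA = 0.35
KM_CA = 1.38
KM_NAI = 87.5
K_SAT = 0.1
ALPHA_NACA = 2.5
P_NAK = 2.724
KM_K = 1.0
KM_NA = 40.0
G_PK = 0.0146
G_PCA = 0.1238
K_PCA = 0.0005
G_BNA = 0.00029
G_BCA = 0.000592

# --- SR calcium handling ----------------------------------------------------
VMAX_UP = 0.006375
K_UP = 0.00025
V_REL = 0.102           # erratum value
V_XFER = 0.0038
V_LEAK = 0.00036
K1_PRIME = 0.15
K2_PRIME = 0.045
K3_RYR = 0.060
K4_RYR = 0.005          # erratum value
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0
BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

STATE_NAMES = (
    "v", "m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
    "xr1", "xr2", "xs", "rbar", "ca_i", "ca_sr", "ca_ss", "na_i", "k_i",
)

# published epicardial initial state (1 Hz paced quasi-steady state)
_Y0 = np.array(
    [
        -85.23,       # v
        0.00172,      # m
        0.7444,       # h
        0.7045,       # j
        3.373e-5,     # d
        0.7888,       # f
        0.9755,       # f2
        0.9953,       # fcass
        2.42e-8,      # r
        0.999998,     # s
        0.00621,      # xr1
        0.4712,       # xr2
        0.0095,       # xs
        0.9073,       # rbar
        0.000126,     # ca_i
        3.64,         # ca_sr
        0.00036,      # ca_ss
        8.604,        # na_i
        136.89,       # k_i
    ]
)


def initial_state() -> np.ndarray:
    """Published epicardial initial conditions (copy)."""
    return _Y0.copy()


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IKsParams:
    """Injectable IKs parameters (conductance, activation midpoint, slope)."""

    g_ks: float = G_KS_DEFAULT   # mS/uF
    v50: float = -5.0            # mV
    slope: float = 14.0          # mV
    tau_scale: float = 1.0       # multiplies the published tau_xs(V); 1 = off

    def __post_init__(self) -> None:
        if self.g_ks < 0:
            raise ValueError("g_ks must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.tau_scale <= 0:
            raise ValueError("tau_scale must be > 0")

    def to_dict(self) -> dict:
        return {"g_ks": self.g_ks, "v50": self.v50, "slope": self.slope,
                "tau_scale": self.tau_scale}


@dataclass(frozen=True)
class PacingConfig:
    """Stimulation and solver settings for steady-state pacing."""

    frequency_hz: float = 1.0
    n_beats: int = 100
    stim_amplitude: float = -52.0  # A/F, conventional for this model
    stim_duration_ms: float = 1.0
    rtol: float = 1e-7
    atol: float = 1e-9
    sample_ms: float = 1.0
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.stim_duration_ms <= 0 or self.sample_ms <= 0:
            raise ValueError("durations must be positive")

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    def to_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency_hz,
            "n_beats": self.n_beats,
            "stim_amplitude": self.stim_amplitude,
            "stim_duration_ms": self.stim_duration_ms,
            "rtol": self.rtol,
            "atol": self.atol,
            "sample_ms": self.sample_ms,
            "method": self.method,
        }


@dataclass
class APBiomarkers:
    """Action-potential biomarkers of one stimulated beat."""

    apd50_ms: float
    apd90_ms: float
    apa_mv: float
    rmp_mv: float

    def to_dict(self) -> dict:
        return {"apd50_ms": self.apd50_ms, "apd90_ms": self.apd90_ms,
                "apa_mv": self.apa_mv, "rmp_mv": self.rmp_mv}


@dataclass
class BeatTrace:
    """Sampled final beat: time, voltage and membrane currents."""

    t_ms: np.ndarray
    v_mv: np.ndarray
    currents: Dict[str, np.ndarray]   # A/F, keys i_ks, i_kr, i_k1, i_to, i_na, i_cal, ...

    @property
    def iks(self) -> np.ndarray:
        return self.currents["i_ks"]


@dataclass
class PacingResult:
    """Outcome of pace_to_steady_state."""

    trace: BeatTrace
    apd90_series: List[float]
    biomarkers: APBiomarkers
    final_state: np.ndarray
    iks: IKsParams
    pacing: PacingConfig


# ---------------------------------------------------------------------------
# model right-hand side
# ---------------------------------------------------------------------------

def xs_steady_state(v: float, params: IKsParams) -> float:
    """Boltzmann xs_inf(V) with injectable midpoint and slope."""
    return 1.0 / (1.0 + math.exp((params.v50 - v) / params.slope))


def e_ks(k_in: float, k_out: float, na_in: float, na_out: float) -> float:
    """Na-permeable IKs reversal potential (P_Na/P_K = 0.03)."""
    return RTONF * math.log((k_out + P_KNA * na_out) / (k_in + P_KNA * na_in))


def iks_current(
    v: float,
    xs: float,
    params: IKsParams,
    k_in: float = 136.89,
    k_out: float = K_O,
    na_in: float = 8.604,
    na_out: float = NA_O,
) -> float:
    """IKs = g_ks * xs^2 * (V - E_Ks), A/F."""
    return params.g_ks * xs * xs * (v - e_ks(k_in, k_out, na_in, na_out))


def _rhs_py(t, y, i_stim, g_ks, v50, slope, tau_scale):
    v = y[0]
    m = y[1]; h = y[2]; j = y[3]
    d = y[4]; f = y[5]; f2 = y[6]; fcass = y[7]
    r = y[8]; s = y[9]
    xr1 = y[10]; xr2 = y[11]; xs = y[12]
    rbar = y[13]
    ca_i = y[14]; ca_sr = y[15]; ca_ss = y[16]
    na_i = y[17]; k_i = y[18]

    # reversal potentials
    e_k = RTONF * math.log(K_O / k_i)
    e_na = RTONF * math.log(NA_O / na_i)
    e_ks_v = RTONF * math.log((K_O + P_KNA * NA_O) / (k_i + P_KNA * na_i))
    e_ca = 0.5 * RTONF * math.log(CA_O / ca_i)

    # fast Na+ current
    i_na = G_NA * m * m * m * h * j * (v - e_na)
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    b_m = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (
        1.0 + math.exp((v - 50.0) / 200.0))
    tau_m = a_m * b_m
    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        a_h = 0.057 * math.exp(-(v + 80.0) / 6.8)
        b_h = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    tau_h = 1.0 / (a_h + b_h)
    j_inf = h_inf
    if v >= -40.0:
        a_j = 0.0
        b_j = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        a_j = ((-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
               * (v + 37.78)) / (1.0 + math.exp(0.311 * (v + 79.23)))
        b_j = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    tau_j = 1.0 / (a_j + b_j)

    # L-type Ca2+ current
    z = 2.0 * (v - 15.0) * FARADAY / (R_GAS * T_BODY)
    if abs(z) < 1e-7:
        gal = G_CAL * d * f * f2 * fcass * 2.0 * FARADAY * (0.25 * ca_ss - CA_O)
    else:
        gal = (G_CAL * d * f * f2 * fcass * 2.0 * FARADAY * z
               * (0.25 * ca_ss * math.exp(z) - CA_O) / (math.exp(z) - 1.0))
    i_cal = gal
    d_inf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tau_f = (1102.5 * math.exp(-(v + 27.0) ** 2 / 225.0)
             + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
             + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * math.exp(-(v + 27.0) ** 2 / 240.0)
              + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
              + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0)))
    fcass_inf = 0.6 / (1.0 + (ca_ss / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (ca_ss / 0.05) ** 2) + 2.0

    # transient outward (epicardial r/s)
    i_to = G_TO * r * s * (v - e_k)
    r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
    tau_s = (85.0 * math.exp(-(v + 45.0) ** 2 / 320.0)
             + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0)

    # rapid delayed rectifier
    i_kr = G_KR * math.sqrt(K_O / 5.4) * xr1 * xr2 * (v - e_k)
    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    a_xr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1
    xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2

    # slow delayed rectifier with injectable activation parameters
    i_ks = g_ks * xs * xs * (v - e_ks_v)
    xs_inf = 1.0 / (1.0 + math.exp((v50 - v) / slope))
    a_xs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    tau_xs = (a_xs * b_xs + 80.0) * tau_scale

    # inward rectifier
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
    b_k1 = ((3.0 * math.exp(0.0002 * (v - e_k + 100.0)) + math.exp(0.1 * (v - e_k - 10.0)))
            / (1.0 + math.exp(-0.5 * (v - e_k))))
    xk1_inf = a_k1 / (a_k1 + b_k1)
    i_k1 = G_K1 * math.sqrt(K_O / 5.4) * xk1_inf * (v - e_k)

    # exchangers / pumps / background
    vfrt = v * FARADAY / (R_GAS * T_BODY)
    i_naca = (K_NACA
              * (math.exp(GAMMA * vfrt) * na_i ** 3 * CA_O
                 - math.exp((GAMMA - 1.0) * vfrt) * NA_O ** 3 * ca_i * ALPHA_NACA)
              / ((KM_NAI ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                 * (1.0 + K_SAT * math.exp((GAMMA - 1.0) * vfrt))))
    i_nak = (P_NAK * K_O * na_i
             / ((K_O + KM_K) * (na_i + KM_NA)
                * (1.0 + 0.1245 * math.exp(-0.1 * vfrt) + 0.0353 * math.exp(-vfrt))))
    i_pca = G_PCA * ca_i / (K_PCA + ca_i)
    i_pk = G_PK * (v - e_k) / (1.0 + math.exp((25.0 - v) / 5.98))
    i_bna = G_BNA * (v - e_na)
    i_bca = G_BCA * (v - e_ca)

    # SR calcium fluxes and RyR
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / ca_sr) ** 2)
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    o_ryr = k1 * ca_ss * ca_ss * rbar / (K3_RYR + k1 * ca_ss * ca_ss)
    i_rel = V_REL * o_ryr * (ca_sr - ca_ss)
    i_up = VMAX_UP / (1.0 + (K_UP / ca_i) ** 2)
    i_leak = V_LEAK * (ca_sr - ca_i)
    i_xfer = V_XFER * (ca_ss - ca_i)

    dy = np.empty(19)
    i_ion = (i_k1 + i_to + i_kr + i_ks + i_cal + i_nak + i_na + i_bna
             + i_naca + i_bca + i_pk + i_pca)
    dy[0] = -(i_ion + i_stim)
    dy[1] = (m_inf - m) / tau_m
    dy[2] = (h_inf - h) / tau_h
    dy[3] = (j_inf - j) / tau_j
    dy[4] = (d_inf - d) / tau_d
    dy[5] = (f_inf - f) / tau_f
    dy[6] = (f2_inf - f2) / tau_f2
    dy[7] = (fcass_inf - fcass) / tau_fcass
    dy[8] = (r_inf - r) / tau_r
    dy[9] = (s_inf - s) / tau_s
    dy[10] = (xr1_inf - xr1) / tau_xr1
    dy[11] = (xr2_inf - xr2) / tau_xr2
    dy[12] = (xs_inf - xs) / tau_xs
    dy[13] = -k2 * ca_ss * rbar + K4_RYR * (1.0 - rbar)

    ca_i_buf = 1.0 / (1.0 + BUF_C * K_BUF_C / (ca_i + K_BUF_C) ** 2)
    ca_sr_buf = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (ca_sr + K_BUF_SR) ** 2)
    ca_ss_buf = 1.0 / (1.0 + BUF_SS * K_BUF_SS / (ca_ss + K_BUF_SS) ** 2)
    dy[14] = ca_i_buf * (
        (i_leak - i_up) * V_SR / V_C + i_xfer
        - (i_bca + i_pca - 2.0 * i_naca) * CM / (2.0 * V_C * FARADAY)
    )
    dy[15] = ca_sr_buf * (i_up - i_rel - i_leak)
    dy[16] = ca_ss_buf * (
        -i_cal * CM / (2.0 * V_SS * FARADAY)
        + i_rel * V_SR / V_SS - i_xfer * V_C / V_SS
    )
    dy[17] = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * CM / (V_C * FARADAY)
    dy[18] = -(i_k1 + i_to + i_kr + i_ks + i_pk + i_stim - 2.0 * i_nak) * CM / (
        V_C * FARADAY)
    return dy


try:  # jit-compile the RHS when numba is importable; same function otherwise
    from numba import njit

    _rhs = njit(cache=True)(_rhs_py)
    _rhs(0.0, _Y0.copy(), 0.0, G_KS_DEFAULT, -5.0, 14.0, 1.0)  # warm compile
except Exception:  # pragma: no cover - exercised only without numba
    _rhs = _rhs_py


def derivatives(
    state: Sequence[float],
    t: float = 0.0,
    iks: IKsParams = IKsParams(),
    i_stim: float = 0.0,
) -> np.ndarray:
    """Full right-hand side dy/dt of the epicardial model (validated entry point)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (19,):
        raise ValueError("state must have 19 components")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    return _rhs(float(t), y, float(i_stim), iks.g_ks, iks.v50, iks.slope,
                iks.tau_scale)


def compute_currents(
    state: Sequence[float], iks: IKsParams = IKsParams()
) -> Dict[str, float]:
    """All membrane currents (A/F) at one state, recomputed independently
    of the RHS (used for traces and for the bookkeeping cross-check)."""
    (v, m, h, j, d, f, f2, fcass, r, s, xr1, xr2, xs, _rbar,
     ca_i, _ca_sr, ca_ss, na_i, k_i) = [float(x) for x in state]
    e_k = RTONF * math.log(K_O / k_i)
    e_na = RTONF * math.log(NA_O / na_i)
    e_ca = 0.5 * RTONF * math.log(CA_O / ca_i)
    out: Dict[str, float] = {}
    out["i_na"] = G_NA * m ** 3 * h * j * (v - e_na)
    z = 2.0 * (v - 15.0) * FARADAY / (R_GAS * T_BODY)
    if abs(z) < 1e-7:
        out["i_cal"] = G_CAL * d * f * f2 * fcass * 2.0 * FARADAY * (
            0.25 * ca_ss - CA_O)
    else:
        out["i_cal"] = (G_CAL * d * f * f2 * fcass * 2.0 * FARADAY * z
                        * (0.25 * ca_ss * math.exp(z) - CA_O)
                        / (math.exp(z) - 1.0))
    out["i_to"] = G_TO * r * s * (v - e_k)
    out["i_kr"] = G_KR * math.sqrt(K_O / 5.4) * xr1 * xr2 * (v - e_k)
    out["i_ks"] = iks_current(v, xs, iks, k_in=k_i, na_in=na_i)
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
    b_k1 = ((3.0 * math.exp(0.0002 * (v - e_k + 100.0))
             + math.exp(0.1 * (v - e_k - 10.0)))
            / (1.0 + math.exp(-0.5 * (v - e_k))))
    out["i_k1"] = G_K1 * math.sqrt(K_O / 5.4) * (a_k1 / (a_k1 + b_k1)) * (v - e_k)
    vfrt = v * FARADAY / (R_GAS * T_BODY)
    out["i_naca"] = (K_NACA
                     * (math.exp(GAMMA * vfrt) * na_i ** 3 * CA_O
                        - math.exp((GAMMA - 1.0) * vfrt) * NA_O ** 3 * ca_i
                        * ALPHA_NACA)
                     / ((KM_NAI ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                        * (1.0 + K_SAT * math.exp((GAMMA - 1.0) * vfrt))))
    out["i_nak"] = (P_NAK * K_O * na_i
                    / ((K_O + KM_K) * (na_i + KM_NA)
                       * (1.0 + 0.1245 * math.exp(-0.1 * vfrt)
                          + 0.0353 * math.exp(-vfrt))))
    out["i_pca"] = G_PCA * ca_i / (K_PCA + ca_i)
    out["i_pk"] = G_PK * (v - e_k) / (1.0 + math.exp((25.0 - v) / 5.98))
    out["i_bna"] = G_BNA * (v - e_na)
    out["i_bca"] = G_BCA * (v - e_ca)
    return out


# ---------------------------------------------------------------------------
# pacing and biomarkers
# ---------------------------------------------------------------------------

def _integrate_beat(
    y0: np.ndarray,
    iks: IKsParams,
    pacing: PacingConfig,
    t_eval: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """One stimulated cycle; returns (samples at t_eval, end state)."""
    cl = pacing.cycle_length_ms
    sd = pacing.stim_duration_ms
    args_stim = (pacing.stim_amplitude, iks.g_ks, iks.v50, iks.slope, iks.tau_scale)
    args_rest = (0.0, iks.g_ks, iks.v50, iks.slope, iks.tau_scale)
    samples = np.empty((19, t_eval.size))

    mask1 = t_eval <= sd
    sol1 = solve_ivp(_rhs, (0.0, sd), y0, method=pacing.method,
                     rtol=pacing.rtol, atol=pacing.atol, args=args_stim,
                     dense_output=True)
    if not sol1.success:
        raise RuntimeError(f"solver failed during stimulus: {sol1.message}")
    if mask1.any():
        samples[:, mask1] = sol1.sol(t_eval[mask1])
    y_mid = sol1.y[:, -1]

    sol2 = solve_ivp(_rhs, (sd, cl), y_mid, method=pacing.method,
                     rtol=pacing.rtol, atol=pacing.atol, args=args_rest,
                     dense_output=True)
    if not sol2.success:
        raise RuntimeError(f"solver failed after stimulus: {sol2.message}")
    mask2 = ~mask1
    if mask2.any():
        samples[:, mask2] = sol2.sol(t_eval[mask2])
    return samples, sol2.y[:, -1]


def pace_to_steady_state(
    iks: IKsParams = IKsParams(),
    pacing: PacingConfig = PacingConfig(),
    y0: Optional[np.ndarray] = None,
) -> PacingResult:
    """Pace the model for ``n_beats`` cycles and return the final beat.

    The final beat is sampled at ``sample_ms`` resolution with all
    membrane currents; APD90 is measured on every beat so convergence to
    the pacing steady state can be checked beat to beat.
    """
    y = initial_state() if y0 is None else np.asarray(y0, dtype=float).copy()
    cl = pacing.cycle_length_ms
    t_eval = np.arange(0.0, cl + 0.5 * pacing.sample_ms, pacing.sample_ms)
    t_eval = t_eval[t_eval <= cl]
    apd90_series: List[float] = []
    samples = None
    for beat in range(pacing.n_beats):
        try:
            samples, y = _integrate_beat(y, iks, pacing, t_eval)
        except RuntimeError as exc:
            raise RuntimeError(f"beat {beat + 1}: {exc}") from exc
        bio = measure_biomarkers(t_eval, samples[0])
        apd90_series.append(bio.apd90_ms)
    assert samples is not None
    currents: Dict[str, np.ndarray] = {}
    per_sample = [compute_currents(samples[:, k], iks) for k in range(t_eval.size)]
    for key in per_sample[0]:
        currents[key] = np.array([c[key] for c in per_sample])
    trace = BeatTrace(t_ms=t_eval.copy(), v_mv=samples[0].copy(), currents=currents)
    return PacingResult(
        trace=trace,
        apd90_series=apd90_series,
        biomarkers=measure_biomarkers(t_eval, samples[0]),
        final_state=y.copy(),
        iks=iks,
        pacing=pacing,
    )


def _cross_down(t: np.ndarray, v: np.ndarray, level: float, start_idx: int) -> float:
    """First downward crossing of ``level`` after ``start_idx`` (linear interp)."""
    for k in range(start_idx, v.size - 1):
        if v[k] >= level > v[k + 1]:
            frac = (v[k] - level) / (v[k] - v[k + 1])
            return float(t[k] + frac * (t[k + 1] - t[k]))
    raise ValueError("repolarisation level never crossed")


def measure_biomarkers(t_ms: Sequence[float], v_mv: Sequence[float]) -> APBiomarkers:
    """APD50/APD90, amplitude and resting potential of one stimulated beat.

    RMP is the pre-stimulus voltage (first sample); APA = Vpeak - RMP;
    APDx runs from the time of maximum upstroke velocity to the downward
    crossing of RMP + (1 - x/100) * APA, linearly interpolated.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mv, dtype=float)
    if t.size < 3:
        raise ValueError("trace too short")
    rmp = float(v[0])
    v_peak = float(v.max())
    apa = v_peak - rmp
    dvdt = np.diff(v) / np.diff(t)
    up_idx = int(np.argmax(dvdt))
    if apa < 10.0 or dvdt[up_idx] < 1.0:
        raise ValueError("no action-potential upstroke detected")
    t_up = float(t[up_idx])
    peak_idx = int(np.argmax(v))
    apd = {}
    for frac, name in ((0.5, 50), (0.9, 90)):
        level = rmp + (1.0 - frac) * apa
        t_cross = _cross_down(t, v, level, peak_idx)
        apd[name] = t_cross - t_up
    return APBiomarkers(apd50_ms=apd[50], apd90_ms=apd[90], apa_mv=apa, rmp_mv=rmp)


# ---------------------------------------------------------------------------
# variant comparison
# ---------------------------------------------------------------------------

@dataclass
class VariantComparison:
    wt: PacingResult
    variant: PacingResult
    delta_apd50_ms: float
    delta_apd90_ms: float
    delta_apa_mv: float
    delta_rmp_mv: float

    def to_dict(self) -> dict:
        return {
            "wt": self.wt.biomarkers.to_dict(),
            "variant": self.variant.biomarkers.to_dict(),
            "delta_apd50_ms": self.delta_apd50_ms,
            "delta_apd90_ms": self.delta_apd90_ms,
            "delta_apa_mv": self.delta_apa_mv,
            "delta_rmp_mv": self.delta_rmp_mv,
            "wt_iks_peak_apf": float(np.max(self.wt.trace.iks)),
            "variant_iks_peak_apf": float(np.max(self.variant.trace.iks)),
        }


def compare_variants(
    iks_wt: IKsParams,
    iks_variant: IKsParams,
    pacing: PacingConfig = PacingConfig(),
) -> VariantComparison:
    """Steady-state biomarkers and final-beat IKs traces for two parameterisations."""
    wt = pace_to_steady_state(iks_wt, pacing)
    var = pace_to_steady_state(iks_variant, pacing)
    return VariantComparison(
        wt=wt,
        variant=var,
        delta_apd50_ms=var.biomarkers.apd50_ms - wt.biomarkers.apd50_ms,
        delta_apd90_ms=var.biomarkers.apd90_ms - wt.biomarkers.apd90_ms,
        delta_apa_mv=var.biomarkers.apa_mv - wt.biomarkers.apa_mv,
        delta_rmp_mv=var.biomarkers.rmp_mv - wt.biomarkers.rmp_mv,
    )
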