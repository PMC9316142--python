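"""Synthetic whole-cell IKs recordings and auxiliary fixtures.

Emulates CHO-cell recordings of the slow delayed rectifier carried by
Kv7.1/KCNE1 under the two-step activation protocol (holding -80 mV, 6 s
depolarising steps -60..+80 mV in 20 mV increments, tail at -40 mV), for
three expression groups:

* ``WT``  - wild-type channels;
* ``HOM`` - homozygous loss-of-function mutant: right-shifted activation,
  shallower voltage dependence, reduced conductance density;
* ``HET`` - 1:1 co-expression. Tetramers assemble binomially from the
  subunit pool; under the strict dominant-negative rule only all-WT
  tetramers (fraction ``(1-f_mut)^4``) gate like WT, while every
  mutant-containing tetramer behaves like the mutant homotetramer.

The gate is a single Hodgkin-Huxley activation variable x with
dx/dt = (x_inf(V) - x)/tau(V), a Boltzmann x_inf and a bell-shaped
tau(V); macroscopic current is g * x^p * (V - E_rev) plus Gaussian
recording noise. The generator also produces 1-D fluorescence intensity
profiles (membrane-localisation fixture) and toy amino-acid alignments
(conservation-logo fixture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .aux_quant import AMINO_ACIDS, Alignment, IntensityProfile
from .ephys_analysis import SweepSet, VoltageProtocol

__all__ = [
    "GateModel",
    "SyntheticCellConfig",
    "DNMixture",
    "WT_GATE",
    "MUT_GATE",
    "GROUPS",
    "nernst_potential",
    "dn_functional_fraction",
    "simulate_iks_sweeps",
    "simulate_mixture_sweeps",
    "generate_cell_population",
    "generate_intensity_profile",
    "generate_alignment",
    "conserved_column",
    "uniform_column",
]

# gas constant (J / kmol / K) and Faraday constant (C / mol)
GAS_CONSTANT = 8314.472
FARADAY = 96485.3415

#: recording temperature, K (room temperature, 24 C)
ROOM_TEMPERATURE_K = 297.15

#: bath / pipette K+ (mM): 5.4 external, 140 internal
K_OUT_MM = 5.4
K_IN_MM = 140.0

DEFAULT_SEED = 2022
SAMPLE_RATE_KHZ = 1.0  # 1 kHz sampling


def nernst_potential(
    conc_in_mm: float,
    conc_out_mm: float,
    valence: int = 1,
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> float:
    """Nernst equilibrium potential (mV), (RT/zF) ln(out/in)."""
    if conc_in_mm <= 0 or conc_out_mm <= 0:
        raise ValueError("concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    rt_zf = GAS_CONSTANT * temperature_k / (valence * FARADAY)
    return rt_zf * math.log(conc_out_mm / conc_in_mm)


#: K+ reversal under the recording solutions, ~ -83.4 mV
EK_RECORDING_MV = nernst_potential(K_IN_MM, K_OUT_MM)


# ---------------------------------------------------------------------------
# gating model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateModel:
    """Single activation gate: Boltzmann x_inf, bell-shaped tau(V).

    tau(V) = tau_base + tau_amp / cosh((V - tau_vpeak)/tau_width), all ms.
    """

    v_half: float
    slope_k: float
    tau_params: Tuple[float, float, float, float] = (100.0, 900.0, -10.0, 30.0)
    gate_power: int = 1

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in (self.v_half, self.slope_k, *self.tau_params)):
            raise ValueError("gate parameters must be finite")
        if self.slope_k <= 0:
            raise ValueError("slope_k must be positive")
        if self.gate_power < 1:
            raise ValueError("gate_power must be >= 1")
        base, amp, _, width = self.tau_params
        if base <= 0 or amp < 0 or width <= 0:
            raise ValueError("tau parameters give non-positive tau")

    def x_inf(self, v_mv: float) -> float:
        return 1.0 / (1.0 + math.exp((self.v_half - v_mv) / self.slope_k))

    def tau_ms(self, v_mv: float) -> float:
        base, amp, vpeak, width = self.tau_params
        return base + amp / math.cosh((v_mv - vpeak) / width)


#: baseline wild-type gate for CHO recordings
WT_GATE = GateModel(v_half=25.0, slope_k=17.0)
#: homozygous mutant: right-shifted, shallower, see module docstring
MUT_GATE = GateModel(v_half=40.0, slope_k=23.0)

#: per-group conductance densities, nS/pF
WT_G_DENSITY = 0.8
MUT_G_DENSITY = 0.25

GROUPS = ("WT", "HOM", "HET")


@dataclass(frozen=True)
class SyntheticCellConfig:
    """Per-cell recording parameters."""

    capacitance_pf: float = 10.0
    g_density_ns_pf: float = WT_G_DENSITY
    e_rev_mv: float = EK_RECORDING_MV
    noise_sd_pa: float = 5.0
    seed: int = DEFAULT_SEED
    sample_khz: float = SAMPLE_RATE_KHZ

    def __post_init__(self) -> None:
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")
        if self.g_density_ns_pf < 0 or self.noise_sd_pa < 0:
            raise ValueError("g_density and noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# dominant-negative mixing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DNMixture:
    """Binomial tetramer assembly from a WT/mutant subunit pool.

    ``rule`` is ``"all-WT-required"`` (strict dominant negative: a single
    mutant subunit silences the tetramer) or
    ``"any-mutant-tolerated-with-scaling"`` (conductance proportional to
    the WT subunit fraction of the tetramer).
    """

    f_mut: float = 0.5
    rule: str = "all-WT-required"

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_mut <= 1.0:
            raise ValueError("f_mut must be in [0, 1]")
        if self.rule not in ("all-WT-required", "any-mutant-tolerated-with-scaling"):
            raise ValueError(f"unknown rule {self.rule!r}")


def dn_functional_fraction(mixture: DNMixture) -> float:
    """Expected WT-like functional fraction over binomially assembled tetramers."""
    f = mixture.f_mut
    if mixture.rule == "all-WT-required":
        return (1.0 - f) ** 4
    # conductance scales with the WT subunit fraction; expectation is 1 - f
    return 1.0 - f


def dn_fraction_by_enumeration(mixture: DNMixture) -> float:
    """Brute-force oracle: enumerate all 2^4 subunit compositions."""
    f = mixture.f_mut
    total = 0.0
    for combo in product((0, 1), repeat=4):  # 1 = mutant subunit
        m = sum(combo)
        weight = f ** m * (1.0 - f) ** (4 - m)
        if mixture.rule == "all-WT-required":
            w = 1.0 if m == 0 else 0.0
        else:
            w = (4 - m) / 4.0
        total += weight * w
    return total


# ---------------------------------------------------------------------------
# sweep simulation
# ---------------------------------------------------------------------------

def gate_closed_form(
    gate: GateModel,
    protocol: VoltageProtocol,
    step_mv: float,
    t_ms: np.ndarray,
) -> np.ndarray:
    """Analytic piecewise solution of the one-gate ODE along the protocol.

    The gate starts equilibrated at the holding potential; within each
    constant-voltage segment x relaxes exponentially towards x_inf(V)
    with time constant tau(V).
    """
    x_hold = gate.x_inf(protocol.holding_mv)
    x_inf_step, tau_step = gate.x_inf(step_mv), gate.tau_ms(step_mv)
    x_inf_tail, tau_tail = gate.x_inf(protocol.tail_mv), gate.tau_ms(protocol.tail_mv)
    t_step0 = protocol.step_start_ms
    t_tail0 = protocol.tail_start_ms

    x = np.empty_like(np.asarray(t_ms, dtype=float))
    t = np.asarray(t_ms, dtype=float)
    pre = t < t_step0
    step = (t >= t_step0) & (t < t_tail0)
    tail = t >= t_tail0
    x[pre] = x_hold
    x[step] = x_inf_step + (x_hold - x_inf_step) * np.exp(-(t[step] - t_step0) / tau_step)
    x_end = x_inf_step + (x_hold - x_inf_step) * math.exp(-protocol.step_ms / tau_step)
    x[tail] = x_inf_tail + (x_end - x_inf_tail) * np.exp(-(t[tail] - t_tail0) / tau_tail)
    return x


def _voltage_at(protocol: VoltageProtocol, step_mv: float, t: float) -> float:
    if t < protocol.step_start_ms:
        return protocol.holding_mv
    if t < protocol.tail_start_ms:
        return step_mv
    return protocol.tail_mv


def _integrate_gate(
    gate: GateModel,
    protocol: VoltageProtocol,
    step_mv: float,
    t_eval: np.ndarray,
) -> np.ndarray:
    """Numerically integrate dx/dt=(x_inf-x)/tau segment by segment."""
    def rhs(t, x, v):
        return (gate.x_inf(v) - x[0]) / gate.tau_ms(v)

    bounds = [0.0, protocol.step_start_ms, protocol.tail_start_ms, protocol.total_ms]
    volts = [protocol.holding_mv, step_mv, protocol.tail_mv]
    x0 = gate.x_inf(protocol.holding_mv)
    out = np.empty_like(t_eval)
    for lo, hi, v in zip(bounds[:-1], bounds[1:], volts):
        if hi <= lo:
            continue
        last = hi >= bounds[-1]
        mask = (t_eval >= lo) & ((t_eval <= hi) if last else (t_eval < hi))
        sol = solve_ivp(
            rhs, (lo, hi), [x0], args=(v,),
            rtol=1e-10, atol=1e-12, method="RK45", dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"gate integration failed on segment at {v} mV")
        seg_t = t_eval[mask]
        if seg_t.size:
            out[mask] = sol.sol(np.clip(seg_t, lo, hi))[0]
        x0 = float(sol.y[0, -1])
    return out


def simulate_mixture_sweeps(
    components: Sequence[Tuple[GateModel, float]],
    protocol: VoltageProtocol,
    cell: SyntheticCellConfig,
    cell_id: str = "cell",
    group: str = "",
    exact: bool = False,
) -> SweepSet:
    """Simulate sweeps for a sum of gating components.

    ``components`` is a list of (gate, conductance density nS/pF); the
    currents of the components add, and one Gaussian noise realisation is
    applied to the summed trace.  With ``exact=True`` the analytic
    piecewise gate solution replaces numerical integration (used by
    oracle tests; default is the ODE integrator).
    """
    dt = 1.0 / cell.sample_khz
    t = np.arange(0.0, protocol.total_ms + 0.5 * dt, dt)
    v_of_t = {s: np.array([_voltage_at(protocol, s, tt) for tt in t]) for s in
              protocol.step_potentials_mv}
    rng = np.random.default_rng(cell.seed)
    sweeps: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}
    for step_mv in protocol.step_potentials_mv:
        i_total = np.zeros_like(t)
        for gate, g_density in components:
            if g_density < 0:
                raise ValueError("conductance density must be non-negative")
            if exact:
                x = gate_closed_form(gate, protocol, step_mv, t)
            else:
                x = _integrate_gate(gate, protocol, step_mv, t)
            g_ns = g_density * cell.capacitance_pf
            i_total = i_total + g_ns * x ** gate.gate_power * (
                v_of_t[step_mv] - cell.e_rev_mv
            )
        if cell.noise_sd_pa > 0:
            i_total = i_total + rng.normal(0.0, cell.noise_sd_pa, size=t.size)
        sweeps[float(step_mv)] = (t.copy(), i_total)
    meta = {
        "components": [
            {
                "v_half": g.v_half,
                "slope_k": g.slope_k,
                "tau_params": list(g.tau_params),
                "gate_power": g.gate_power,
                "g_density_ns_pf": gd,
            }
            for g, gd in components
        ],
        "e_rev_mv": cell.e_rev_mv,
        "noise_sd_pa": cell.noise_sd_pa,
        "seed": cell.seed,
        "sample_khz": cell.sample_khz,
        "protocol": protocol.to_dict(),
    }
    return SweepSet(cell_id=cell_id, capacitance_pf=cell.capacitance_pf,
                    sweeps=sweeps, group=group, meta=meta)


def simulate_iks_sweeps(
    gate: GateModel,
    protocol: VoltageProtocol,
    cell: SyntheticCellConfig,
    cell_id: str = "cell",
    group: str = "",
    exact: bool = False,
) -> SweepSet:
    """Simulate a single-component cell (see :func:`simulate_mixture_sweeps`)."""
    return simulate_mixture_sweeps(
        [(gate, cell.g_density_ns_pf)], protocol, cell, cell_id, group, exact=exact
    )


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

#: group sizes mirroring the study (WT 15, HOM 17, HET 16 cells)
DEFAULT_N_CELLS = {"WT": 15, "HOM": 17, "HET": 16}

# log-normal capacitance: median 10 pF, sigma 0.3 (typical CHO whole-cell)
CAPACITANCE_MEDIAN_PF = 10.0
CAPACITANCE_SIGMA = 0.3


def group_components(
    group: str,
    mixture: DNMixture = DNMixture(),
    wt_gate: GateModel = WT_GATE,
    mut_gate: GateModel = MUT_GATE,
    wt_g: float = WT_G_DENSITY,
    mut_g: float = MUT_G_DENSITY,
) -> List[Tuple[GateModel, float]]:
    """Gating components and conductance densities for an expression group."""
    if group == "WT":
        return [(wt_gate, wt_g)]
    if group == "HOM":
        return [(mut_gate, mut_g)]
    if group == "HET":
        f_func = dn_functional_fraction(mixture)
        comps = []
        if f_func > 0:
            comps.append((wt_gate, f_func * wt_g))
        if f_func < 1:
            comps.append((mut_gate, (1.0 - f_func) * mut_g))
        return comps
    raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


def generate_cell_population(
    group: str,
    n_cells: int,
    seed: int = DEFAULT_SEED,
    protocol: VoltageProtocol = VoltageProtocol(),
    mixture: DNMixture = DNMixture(),
    noise_sd_pa: float = 5.0,
    exact: bool = False,
) -> List[SweepSet]:
    """Reproducible population of synthetic cells for one expression group."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    comps = group_components(group, mixture)
    # per-cell streams depend on seed and cell index only, not on the group
    # label, so populations are paired across groups (and a HET group with
    # f_mut=0 reproduces the WT group exactly)
    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(n_cells)
    rng_cap = np.random.default_rng(ss)
    cells = []
    for idx in range(n_cells):
        cap = CAPACITANCE_MEDIAN_PF * math.exp(rng_cap.normal(0.0, CAPACITANCE_SIGMA))
        cell_seed = int(children[idx].generate_state(1)[0] % (2 ** 31))
        cfg = SyntheticCellConfig(
            capacitance_pf=cap,
            noise_sd_pa=noise_sd_pa,
            seed=cell_seed,
        )
        cells.append(
            simulate_mixture_sweeps(
                comps, protocol, cfg,
                cell_id=f"{group}_{idx:03d}", group=group, exact=exact,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# intensity profiles and alignments
# ---------------------------------------------------------------------------

def generate_intensity_profile(
    length: int = 100,
    membrane_peak: float = 3.0,
    cytosol_level: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> IntensityProfile:
    """1-D fluorescence line profile: cytosolic plateau + two membrane peaks.

    Gaussian peaks are centred inside the two 15% end segments (at 7.5%
    and 92.5% of the profile), emulating the green-channel intensity
    measured across a cell.  ``membrane_peak`` is the target mean
    intensity of the 15% membrane segments (the generator's ratio
    parameter membrane_peak/cytosol_level is what the segment quantifier
    recovers); the Gaussian amplitude is calibrated accordingly.
    """
    if length < 10:
        raise ValueError("profile length must be >= 10")
    x = np.arange(length, dtype=float)
    c1, c2 = 0.075 * (length - 1), 0.925 * (length - 1)
    width = max(0.03 * length, 1.0)
    shape = (
        np.exp(-0.5 * ((x - c1) / width) ** 2) + np.exp(-0.5 * ((x - c2) / width) ** 2)
    )
    n_end = int(math.floor(0.15 * length + 0.5))
    ends = np.zeros(length, dtype=bool)
    ends[:n_end] = True
    ends[length - n_end:] = True
    # amplitude such that the mean over the membrane segments hits membrane_peak
    amp = (membrane_peak - cytosol_level) * ends.sum() / shape[ends].sum()
    intensities = cytosol_level + amp * shape
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, noise_sd, size=length)
    intensities = np.clip(intensities, 0.0, None)
    return IntensityProfile(positions=x, intensities=intensities)


def conserved_column(letter: str) -> Dict[str, float]:
    """Distribution spec: a fully conserved column."""
    if letter not in AMINO_ACIDS:
        raise ValueError(f"{letter!r} is not a standard amino acid")
    return {letter: 1.0}


def uniform_column() -> Dict[str, float]:
    """Distribution spec: uniform over the 20 amino acids."""
    return {aa: 1.0 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}


def generate_alignment(
    n_seqs: int,
    conservation: Sequence[Mapping[str, float]],
    seed: int = DEFAULT_SEED,
) -> Alignment:
    """Toy protein alignment with independently drawn columns.

    ``conservation`` gives one letter-probability mapping per column
    (see :func:`conserved_column` / :func:`uniform_column`); each must
    sum to 1 within 1e-6.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    if not conservation:
        raise ValueError("need at least one column distribution")
    rng = np.random.default_rng(seed)
    cols = []
    for j, dist in enumerate(conservation):
        letters = list(dist)
        probs = np.array([dist[l] for l in letters], dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"column {j}: probabilities must be >= 0 and sum to 1")
        bad = [l for l in letters if l not in AMINO_ACIDS and l != "-"]
        if bad:
            raise ValueError(f"column {j}: letters {bad} outside the amino-acid alphabet")
        cols.append(rng.choice(letters, size=n_seqs, p=probs / probs.sum()))
    seqs = ["".join(cols[j][i] for j in range(len(cols))) for i in range(n_seqs)]
    return Alignment(sequences=seqs, ids=[f"seq{i:03d}" for i in range(n_seqs)])
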