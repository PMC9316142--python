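"""Whole-cell IKs voltage-clamp analysis.

Implements the standard activation-protocol workflow for slow delayed
rectifier recordings: peak tail currents at a fixed repolarisation
potential, capacitance-normalised current densities, tail I–V curves with
group mean ± SEM, Boltzmann fits of the voltage dependence of activation,
and single-exponential fits of activation/deactivation time courses.

Voltages are in mV, times in ms, currents in pA, capacitance in pF and
current densities in pA/pF throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "VoltageProtocol",
    "SweepSet",
    "TailIV",
    "ActivationFit",
    "KineticsFit",
    "extract_tail_peak",
    "tail_density",
    "build_tail_iv",
    "fit_boltzmann",
    "fit_exponential",
    "fit_activation_kinetics",
    "fit_deactivation_kinetics",
    "summarize_group",
    "boltzmann",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoltageProtocol:
    """Two-step square-pulse activation protocol.

    A short pre-segment at the holding potential is recorded before the
    depolarising step so the baseline is visible in every sweep; the tail
    segment at ``tail_mv`` follows the step.
    """

    holding_mv: float = -80.0
    step_potentials_mv: Tuple[float, ...] = (-60, -40, -20, 0, 20, 40, 60, 80)
    step_ms: float = 6000.0
    tail_mv: float = -40.0
    tail_ms: float = 3000.0
    pre_ms: float = 100.0

    def __post_init__(self) -> None:
        steps = tuple(float(v) for v in self.step_potentials_mv)
        if len(steps) < 1:
            raise ValueError("protocol needs at least one step potential")
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("step potentials must be strictly increasing")
        if self.step_ms <= 0 or self.tail_ms <= 0 or self.pre_ms < 0:
            raise ValueError("segment durations must be positive")
        object.__setattr__(self, "step_potentials_mv", steps)

    @property
    def step_start_ms(self) -> float:
        return self.pre_ms

    @property
    def tail_start_ms(self) -> float:
        return self.pre_ms + self.step_ms

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.step_ms + self.tail_ms

    def to_dict(self) -> dict:
        return {
            "holding_mv": self.holding_mv,
            "steps_mv": list(self.step_potentials_mv),
            "step_ms": self.step_ms,
            "tail_mv": self.tail_mv,
            "tail_ms": self.tail_ms,
            "pre_ms": self.pre_ms,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VoltageProtocol":
        return cls(
            holding_mv=float(d.get("holding_mv", -80.0)),
            step_potentials_mv=tuple(d.get("steps_mv", (-60, -40, -20, 0, 20, 40, 60, 80))),
            step_ms=float(d.get("step_ms", 6000.0)),
            tail_mv=float(d.get("tail_mv", -40.0)),
            tail_ms=float(d.get("tail_ms", 3000.0)),
            pre_ms=float(d.get("pre_ms", 100.0)),
        )


@dataclass
class SweepSet:
    """One cell's recordings: a (time, current) trace per step potential."""

    cell_id: str
    capacitance_pf: float
    sweeps: Dict[float, Tuple[np.ndarray, np.ndarray]]
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capacitance_pf <= 0:
            raise ValueError(f"cell {self.cell_id}: capacitance must be positive")

    def potentials(self) -> List[float]:
        return sorted(self.sweeps)


@dataclass
class TailIV:
    """Peak tail current densities as a function of pre-pulse potential."""

    potentials_mv: np.ndarray
    densities: pd.DataFrame        # rows: cell_id, columns: potentials, values pA/pF
    groups: Dict[str, str]         # cell_id -> group label
    summary: pd.DataFrame          # per (group, potential): mean, sem, n

    def group_mean(self, group: str) -> np.ndarray:
        sub = self.summary.loc[self.summary["group"] == group]
        sub = sub.set_index("potential_mv").loc[self.potentials_mv]
        return sub["mean"].to_numpy()


@dataclass
class ActivationFit:
    """Boltzmann parameters y = Imax / (1 + exp((V50 - V)/k))."""

    i_max: float
    v50_mv: float
    k_mv: float
    residual_norm: float
    success: bool = True
    message: str = ""


@dataclass
class KineticsFit:
    """Single-exponential fit y(t) = offset + amplitude * exp(-t/tau)."""

    tau_ms: float
    amplitude: float
    offset: float
    residual_norm: float
    success: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# tail currents and densities
# ---------------------------------------------------------------------------

def _boxcar(y: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation (constant stays constant)."""
    if width <= 1:
        return y
    kernel = np.ones(width)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def extract_tail_peak(
    t_ms: np.ndarray,
    i_pa: np.ndarray,
    tail_start_ms: float,
    blank_ms: float = 5.0,
    window_ms: float = 100.0,
    smooth_ms: float = 25.0,
) -> float:
    """Peak (signed extremum) tail current after the repolarising step.

    The first ``blank_ms`` after the step are skipped to avoid the
    capacitive transient; the extremum is searched over the following
    ``window_ms``.  The segment is low-pass filtered with a centered
    ``smooth_ms`` boxcar before taking the extremum (0 disables), as the
    slow IKs tail is essentially flat on that time scale while the peak
    of the raw noisy trace would be biased upward.  Outward tails are
    positive.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    t_ms = np.asarray(t_ms, dtype=float)
    i_pa = np.asarray(i_pa, dtype=float)
    lo = tail_start_ms + blank_ms
    hi = lo + window_ms
    if lo < t_ms[0] - 1e-9 or hi > t_ms[-1] + 1e-9:
        raise ValueError(
            f"tail window [{lo}, {hi}] ms outside sweep [{t_ms[0]}, {t_ms[-1]}] ms"
        )
    mask = (t_ms >= lo - 1e-9) & (t_ms <= hi + 1e-9)
    seg = i_pa[mask]
    if seg.size == 0:
        raise ValueError("no samples in tail window")
    if smooth_ms > 0 and seg.size > 2:
        dt = float(np.median(np.diff(t_ms[mask]))) if seg.size > 1 else 1.0
        width = max(int(round(smooth_ms / dt)), 1)
        seg = _boxcar(seg, min(width, seg.size))
    return float(seg[np.argmax(np.abs(seg))])


def tail_density(peak_pa: float, capacitance_pf: float) -> float:
    """Capacitance-normalised current (pA/pF)."""
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    return peak_pa / capacitance_pf


def build_tail_iv(
    cells: Iterable[SweepSet],
    protocol: VoltageProtocol,
    blank_ms: float = 5.0,
    window_ms: float = 100.0,
    smooth_ms: float = 25.0,
) -> TailIV:
    """Per-cell tail densities at every protocol potential, plus group mean ± SEM."""
    cells = list(cells)
    if not cells:
        raise ValueError("no cells supplied")
    pots = np.array(protocol.step_potentials_mv, dtype=float)
    rows = {}
    groups = {}
    for cell in cells:
        dens = []
        for v in pots:
            if v not in cell.sweeps:
                raise ValueError(f"cell {cell.cell_id}: missing sweep at {v} mV")
            t, i = cell.sweeps[v]
            peak = extract_tail_peak(
                t, i, protocol.tail_start_ms, blank_ms, window_ms, smooth_ms
            )
            dens.append(tail_density(peak, cell.capacitance_pf))
        rows[cell.cell_id] = dens
        groups[cell.cell_id] = cell.group
    densities = pd.DataFrame.from_dict(rows, orient="index", columns=pots)
    densities.index.name = "cell_id"

    records = []
    for grp in sorted(set(groups.values())):
        ids = [c for c, g in groups.items() if g == grp]
        sub = densities.loc[ids]
        for v in pots:
            mean, sem, n = summarize_group(sub[v].to_numpy())
            records.append(
                {"group": grp, "potential_mv": v, "mean": mean, "sem": sem, "n": n}
            )
    summary = pd.DataFrame.from_records(records)
    return TailIV(potentials_mv=pots, densities=densities, groups=groups, summary=summary)


def summarize_group(values: Sequence[float]) -> Tuple[float, float, int]:
    """Descriptive mean, SEM (= sd/sqrt(n), ddof=1) and n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, sem, int(arr.size)


# ---------------------------------------------------------------------------
# curve fits
# ---------------------------------------------------------------------------

def boltzmann(v: np.ndarray, i_max: float, v50: float, k: float) -> np.ndarray:
    return i_max / (1.0 + np.exp((v50 - np.asarray(v, dtype=float)) / k))


def fit_boltzmann(
    potentials_mv: Sequence[float],
    amplitudes: Sequence[float],
    n_restarts: int = 5,
    seed: int = 0,
) -> ActivationFit:
    """Least-squares Boltzmann fit of an activation curve.

    Initialisation: V50 at the half-range crossing, k = 15 mV,
    Imax = 1.1 x observed maximum; on failure up to ``n_restarts``
    jittered restarts before a flagged (never silent) failure result.
    """
    v = np.asarray(potentials_mv, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if v.size < 4 or np.unique(v).size < 4:
        raise ValueError("need at least 4 distinct potentials")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite amplitudes")

    y_max = float(y.max())
    half = 0.5 * (float(y.min()) + y_max)
    crossing = v[np.argmin(np.abs(y - half))]
    init = (1.1 * y_max if y_max > 0 else 1.0, float(crossing), 15.0)

    rng = np.random.default_rng(seed)
    model = lmfit.Model(boltzmann, independent_vars=["v"])
    best = None
    for attempt in range(n_restarts + 1):
        i0, v0, k0 = init
        if attempt > 0:
            v0 += rng.normal(0.0, 10.0)
            k0 = abs(k0 + rng.normal(0.0, 5.0)) or 15.0
            i0 *= math.exp(rng.normal(0.0, 0.2))
        params = model.make_params(i_max=i0, v50=v0, k=k0)
        params["k"].set(min=1e-3)
        try:
            res = model.fit(y, params, v=v)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
        if res.success and np.isfinite(res.chisqr):
            best = res if res.chisqr <= best.chisqr else best
            break
    if best is None:
        return ActivationFit(math.nan, math.nan, math.nan, math.inf,
                             success=False, message="optimizer failed on all restarts")
    p = best.params
    return ActivationFit(
        i_max=float(p["i_max"].value),
        v50_mv=float(p["v50"].value),
        k_mv=float(p["k"].value),
        residual_norm=float(math.sqrt(best.chisqr)),
        success=bool(best.success),
        message="" if best.success else str(best.message),
    )


def _exponential(t, offset, amplitude, tau):
    return offset + amplitude * np.exp(-np.asarray(t, dtype=float) / tau)


def fit_exponential(
    t_ms: Sequence[float],
    y: Sequence[float],
    direction: str = "deactivation",
) -> KineticsFit:
    """Single-exponential fit y(t) = offset + amplitude * exp(-t/tau).

    ``direction`` selects the initial guess: a decaying tail
    ("deactivation", amplitude > 0) or a rising activation time course
    ("activation", amplitude < 0).  A near-constant series has no
    identifiable tau and returns a flagged failure.
    """
    if direction not in ("activation", "deactivation"):
        raise ValueError("direction must be 'activation' or 'deactivation'")
    t = np.asarray(t_ms, dtype=float)
    yv = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")

    t0 = t - t[0]
    span = float(yv.max() - yv.min())
    scale = max(abs(yv.max()), abs(yv.min()), 1.0)
    if span < 1e-12 * scale:
        return KineticsFit(math.nan, 0.0, float(yv.mean()), 0.0,
                           success=False, message="constant series: tau unidentifiable")

    tau0 = max((t0[-1] - t0[0]) / 3.0, 1e-3)
    if direction == "deactivation":
        off0, amp0 = float(yv[-1]), float(yv[0] - yv[-1])
    else:
        off0, amp0 = float(yv[-1]), float(yv[0] - yv[-1])
    model = lmfit.Model(_exponential, independent_vars=["t"])
    params = model.make_params(offset=off0, amplitude=amp0, tau=tau0)
    params["tau"].set(min=1e-6)
    try:
        res = model.fit(yv, params, t=t0)
    except Exception as exc:  # pragma: no cover - lmfit rarely raises here
        return KineticsFit(math.nan, math.nan, math.nan, math.inf,
                           success=False, message=str(exc))
    p = res.params
    fit = KineticsFit(
        tau_ms=float(p["tau"].value),
        amplitude=float(p["amplitude"].value),
        offset=float(p["offset"].value),
        residual_norm=float(math.sqrt(res.chisqr)),
        success=bool(res.success),
        message="" if res.success else str(res.message),
    )
    # an amplitude indistinguishable from zero also leaves tau unidentified
    if abs(fit.amplitude) < 1e-9 * scale:
        fit.success = False
        fit.message = "amplitude ~ 0: tau unidentifiable"
    return fit


def fit_activation_kinetics(
    cell: SweepSet,
    protocol: VoltageProtocol,
    step_mv: float,
    blank_ms: float = 20.0,
) -> KineticsFit:
    """tau_A from the rising current during the depolarising step."""
    t, i = cell.sweeps[step_mv]
    lo = protocol.step_start_ms + blank_ms
    hi = protocol.tail_start_ms
    mask = (t >= lo) & (t < hi)
    return fit_exponential(t[mask], i[mask], direction="activation")


def fit_deactivation_kinetics(
    cell: SweepSet,
    protocol: VoltageProtocol,
    step_mv: float,
    blank_ms: float = 5.0,
) -> KineticsFit:
    """tau_D from the decaying tail current after the step to ``step_mv``."""
    t, i = cell.sweeps[step_mv]
    lo = protocol.tail_start_ms + blank_ms
    mask = t >= lo
    return fit_exponential(t[mask], i[mask], direction="deactivation")
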