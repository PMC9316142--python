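"""Membrane-localisation profiles and conservation logos.

Two small quantifiers used alongside the electrophysiology:

* a 1-D fluorescence line profile across a cell is split 15% / 70% / 15%
  into two membrane segments (M1, M2) and the cytosolic middle; segment
  means are normalised to the whole-profile mean and summarised by a
  membrane index mean(M1, M2)/cytosol;
* per-column Shannon entropy and information content of a protein
  alignment, in the standard sequence-logo convention: stack height
  R = log2(20) - H, letter heights frequency-proportional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "IntensityProfile",
    "ProfileSegments",
    "Alignment",
    "LogoColumn",
    "segment_profile",
    "column_entropy",
    "logo_columns",
    "conserved_positions",
    "logo_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


# ---------------------------------------------------------------------------
# intensity profiles
# ---------------------------------------------------------------------------

@dataclass
class IntensityProfile:
    """Ordered 1-D intensity samples (arbitrary units, non-negative)."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have the same length")
        if self.intensities.size < 10:
            raise ValueError("profile must have at least 10 samples")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.intensities.size)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"position": self.positions, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IntensityProfile":
        df = pd.read_csv(path)
        return cls(df["position"].to_numpy(), df["intensity"].to_numpy())


@dataclass
class ProfileSegments:
    """Segment means of a line profile, raw and mean-normalised."""

    m1_mean: float
    cytosol_mean: float
    m2_mean: float
    m1_norm: float
    cytosol_norm: float
    m2_norm: float
    membrane_index: float
    membrane_fraction: float
    n_end: int

    @property
    def membrane_norm(self) -> float:
        """Normalised mean of the two membrane segments."""
        return 0.5 * (self.m1_norm + self.m2_norm)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def segment_profile(
    profile: IntensityProfile, membrane_fraction: float = 0.15
) -> ProfileSegments:
    """15/70/15 segmentation of a cell line profile.

    Each end segment holds round-half-up(membrane_fraction * n) samples
    (the membrane, M1 and M2); the middle is cytosol.  Means are also
    normalised to the whole-profile mean intensity.
    """
    if not 0.0 < membrane_fraction < 0.5:
        raise ValueError("membrane_fraction must be in (0, 0.5)")
    y = profile.intensities
    n = y.size
    n_end = _round_half_up(membrane_fraction * n)
    if n_end < 1 or 2 * n_end >= n:
        raise ValueError("profile too short for this membrane fraction")
    m1 = float(y[:n_end].mean())
    m2 = float(y[n - n_end:].mean())
    cyt = float(y[n_end: n - n_end].mean())
    whole = float(y.mean())
    if whole <= 0 or cyt <= 0:
        raise ValueError("profile mean and cytosol mean must be positive")
    return ProfileSegments(
        m1_mean=m1,
        cytosol_mean=cyt,
        m2_mean=m2,
        m1_norm=m1 / whole,
        cytosol_norm=cyt / whole,
        m2_norm=m2 / whole,
        membrane_index=0.5 * (m1 + m2) / cyt,
        membrane_fraction=membrane_fraction,
        n_end=n_end,
    )


# ---------------------------------------------------------------------------
# alignments and logos
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Equal-length protein sequences over the 20-letter alphabet (+ gaps)."""

    sequences: List[str]
    ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise ValueError("alignment needs at least one sequence")
        ncol = len(self.sequences[0])
        if any(len(s) != ncol for s in self.sequences):
            raise ValueError("all sequences must have equal length")
        allowed = set(AMINO_ACIDS) | {GAP}
        for i, s in enumerate(self.sequences):
            bad = set(s.upper()) - allowed
            if bad:
                raise ValueError(f"sequence {i}: letters {sorted(bad)} outside alphabet")
        self.sequences = [s.upper() for s in self.sequences]
        if not self.ids:
            self.ids = [f"seq{i:03d}" for i in range(len(self.sequences))]

    @property
    def n_cols(self) -> int:
        return len(self.sequences[0])

    @property
    def n_seqs(self) -> int:
        return len(self.sequences)

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.sequences)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=i, description="")
            for s, i in zip(self.sequences, self.ids)
        ]
        write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "fasta")
        return cls(sequences=[str(r.seq) for r in aln], ids=[r.id for r in aln])


@dataclass
class LogoColumn:
    """Per-column logo numbers: frequencies, entropy, stack and letter heights."""

    position: int
    frequencies: Dict[str, float]
    entropy_bits: float
    stack_bits: float
    letter_heights: Dict[str, float]
    all_gap: bool = False


def column_entropy(frequencies: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy H = -sum p log2 p (bits), with 0*log 0 = 0."""
    if isinstance(frequencies, Mapping):
        probs = np.array(list(frequencies.values()), dtype=float)
    else:
        probs = np.asarray(list(frequencies), dtype=float)
    if np.any(probs < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    nz = probs[probs > 0]
    return float(-(nz * np.log2(nz)).sum())


def logo_columns(alignment: Alignment, alphabet_size: int = 20) -> List[LogoColumn]:
    """Sequence-logo numbers for every alignment column.

    Gaps are excluded and residue frequencies renormalised; an all-gap
    column is flagged and carries a zero stack.  Letter heights are
    frequency * stack and are reported in descending-frequency order.
    """
    r_max = math.log2(alphabet_size)
    out: List[LogoColumn] = []
    for j in range(alignment.n_cols):
        col = alignment.column(j)
        residues = [c for c in col if c != GAP]
        if not residues:
            out.append(LogoColumn(j, {}, 0.0, 0.0, {}, all_gap=True))
            continue
        counts: Dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        total = len(residues)
        freqs = {c: counts[c] / total for c in
                 sorted(counts, key=lambda c: (-counts[c], c))}
        h = column_entropy(freqs)
        stack = r_max - h
        heights = {c: f * stack for c, f in freqs.items()}
        out.append(LogoColumn(j, freqs, h, stack, heights))
    return out


def conserved_positions(columns: Sequence[LogoColumn], threshold_bits: float = 0.0) -> List[int]:
    """Column indices with entropy <= threshold (default: fully conserved)."""
    if threshold_bits < 0:
        raise ValueError("threshold must be >= 0")
    return [
        c.position
        for c in columns
        if not c.all_gap and c.entropy_bits <= threshold_bits + 1e-12
    ]


def logo_table(columns: Sequence[LogoColumn]) -> pd.DataFrame:
    """Flat per-column table (position, entropy, stack, letter:height pairs)."""
    rows = []
    for c in columns:
        rows.append(
            {
                "position": c.position,
                "entropy_bits": c.entropy_bits,
                "stack_bits": c.stack_bits,
                "all_gap": c.all_gap,
                "letters": ";".join(
                    f"{l}:{h:.6g}" for l, h in c.letter_heights.items()
                ),
            }
        )
    return pd.DataFrame.from_records(rows)
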