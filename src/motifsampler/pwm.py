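"""Position weight matrices and motif scoring.

The model chain is counts -> site frequencies -> weight matrix -> scores:

* site-specific counts ``c_ij``: how many aligned motif windows carry
  nucleotide ``i`` at motif position ``j`` (one window per sequence);
* site-specific frequencies with a background pseudocount,
  ``p_ij = (c_ij + p_i) / (n + 1)`` where ``p_i`` is the pooled background
  frequency — one total pseudo-observation distributed as the background;
* weight matrix ``PWM_ij = log(p_ij / p'_i)``, natural log by default, where
  ``p'_i`` is by default the background recomputed after excluding the
  nucleotides inside the motif windows;
* PWMS of a motif: the sum of its per-position weights (log form) or the
  exponential of that sum (odds form);
* global alignment score ``F``: the sum of log-PWMS over all sequences.

All matrices use the fixed row order A, C, G, U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, BackgroundError, EmptyInputError
from .io import RNA_ALPHABET, BackgroundComposition, SequenceSet, encode


@dataclass(frozen=True)
class MotifAlignment:
    """One fixed-width motif window per sequence (OOPS model).

    ``starts`` are 1-based, one per sequence, in sequence-set order.
    """

    width: int
    starts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.width < 1:
            raise AlignmentError(f"motif width must be >= 1, got {self.width}")

    def validate(self, seqs: SequenceSet) -> None:
        """Raise :class:`AlignmentError` unless valid for ``seqs``."""
        if len(self.starts) != seqs.n:
            raise AlignmentError(
                f"alignment has {len(self.starts)} starts for {seqs.n} sequences"
            )
        for rec, start in zip(seqs, self.starts):
            hi = rec.length - self.width + 1
            if not 1 <= start <= hi:
                raise AlignmentError(
                    f"sequence {rec.id!r}: start {start} outside [1, {hi}]"
                )

    def window(self, seqs: SequenceSet, k: int) -> str:
        """Motif window of sequence ``k`` as a residue string."""
        s = self.starts[k]
        return seqs[k].residues[s - 1 : s - 1 + self.width]

    def windows(self, seqs: SequenceSet) -> list[str]:
        return [self.window(seqs, k) for k in range(seqs.n)]


@dataclass(frozen=True)
class PositionCountMatrix:
    """Site-specific nucleotide counts ``c_ij`` (4 x width), column sums n."""

    counts: np.ndarray  # shape (4, width), int
    n: int

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def residue_totals(self) -> np.ndarray:
        """Total count of each nucleotide inside motif windows, M_i."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class SiteFrequencyMatrix:
    """Pseudocount-smoothed site frequencies ``p_ij`` (4 x width)."""

    freqs: np.ndarray

    @property
    def width(self) -> int:
        return self.freqs.shape[1]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-ratio weights ``PWM_ij`` (4 x width) in base ``log_base``."""

    weights: np.ndarray
    log_base: float = math.e

    @property
    def width(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class MotifScore:
    """PWMS of one motif: log form (sum of weights) and odds form."""

    log_pwms: float
    log_base: float = math.e

    @property
    def odds_pwms(self) -> float:
        return float(self.log_base**self.log_pwms)


@dataclass(frozen=True)
class AlignmentScore:
    """Global alignment score F: sum of per-sequence log-PWMS values."""

    F: float
    per_sequence: tuple[float, ...]


def count_matrix(seqs: SequenceSet, aln: MotifAlignment) -> PositionCountMatrix:
    """Tally residues in each aligned window column."""
    aln.validate(seqs)
    counts = np.zeros((4, aln.width), dtype=np.int64)
    for k, idx in enumerate(seqs.encoded()):
        s = aln.starts[k] - 1
        window = idx[s : s + aln.width]
        counts[window, np.arange(aln.width)] += 1
    return PositionCountMatrix(counts, seqs.n)


def site_frequencies(
    cm: PositionCountMatrix,
    bg: BackgroundComposition,
    *,
    pseudocount_mass: float = 1.0,
) -> SiteFrequencyMatrix:
    """Smooth counts with background pseudocounts.

    ``p_ij = (c_ij + m * p_i) / (n + m)`` with total pseudocount mass ``m``
    (default one pseudo-observation).  Every column sums to exactly 1 and no
    entry can be 0 or 1, so downstream logs are always finite.
    """
    if cm.n == 0:
        raise EmptyInputError("count matrix built from zero sequences")
    if pseudocount_mass <= 0:
        raise ValueError("pseudocount_mass must be > 0")
    p = bg.freqs[:, None]
    freqs = (cm.counts + pseudocount_mass * p) / (cm.n + pseudocount_mass)
    return SiteFrequencyMatrix(freqs)


def excluded_background(
    bg: BackgroundComposition, cm: PositionCountMatrix
) -> BackgroundComposition:
    """Background recomputed after removing the motif-window nucleotides.

    Subtracts the per-nucleotide window totals ``M_i`` from the pooled counts
    (total drops by ``n * width``).  Raises :class:`BackgroundError` when a
    count would go negative or nothing remains outside the windows.
    """
    adjusted = np.asarray(bg.counts, dtype=float) - cm.residue_totals
    if (adjusted < 0).any():
        raise BackgroundError(
            "motif windows contain more nucleotides than the background"
        )
    return BackgroundComposition(tuple(float(c) for c in adjusted))


def weight_matrix(
    sf: SiteFrequencyMatrix,
    bg_denominator: BackgroundComposition,
    *,
    log_base: float = math.e,
) -> PositionWeightMatrix:
    """Log-ratio of site frequencies to a denominator background.

    The denominator is typically the motif-excluded background; passing the
    full background gives the textbook log-odds matrix.  Any base may be
    used; natural log is the default reporting convention.
    """
    denom = bg_denominator.freqs[:, None]
    if (denom <= 0).any() or (sf.freqs <= 0).any():
        raise BackgroundError("weight matrix requires strictly positive frequencies")
    weights = np.log(sf.freqs / denom) / math.log(log_base)
    return PositionWeightMatrix(weights, float(log_base))


def build_pwm(
    seqs: SequenceSet,
    aln: MotifAlignment,
    bg: BackgroundComposition | None = None,
    *,
    exclude_motif_background: bool = True,
    log_base: float = math.e,
    pseudocount_mass: float = 1.0,
) -> PositionWeightMatrix:
    """Convenience chain: counts -> frequencies -> weights for one alignment."""
    from .io import background_composition

    if bg is None:
        bg = background_composition(seqs)
    cm = count_matrix(seqs, aln)
    sf = site_frequencies(cm, bg, pseudocount_mass=pseudocount_mass)
    denom = excluded_background(bg, cm) if exclude_motif_background else bg
    return weight_matrix(sf, denom, log_base=log_base)


def motif_score(pwm: PositionWeightMatrix, motif: str) -> MotifScore:
    """PWMS of a motif string: sum of weights along its residues."""
    if len(motif) != pwm.width:
        raise AlignmentError(
            f"motif {motif!r} has length {len(motif)}, PWM width is {pwm.width}"
        )
    idx = encode(motif)
    if (idx == 255).any():
        bad = motif[int(np.argmax(idx == 255))]
        raise AlignmentError(
            f"motif residue {bad!r} outside alphabet {RNA_ALPHABET}"
        )
    total = float(pwm.weights[idx, np.arange(pwm.width)].sum())
    return MotifScore(total, pwm.log_base)


def alignment_score(
    pwm: PositionWeightMatrix, seqs: SequenceSet, aln: MotifAlignment
) -> AlignmentScore:
    """Global score F: sum of log-PWMS of every sequence's aligned window."""
    aln.validate(seqs)
    if pwm.width != aln.width:
        raise AlignmentError(
            f"PWM width {pwm.width} != alignment width {aln.width}"
        )
    per_seq = tuple(
        motif_score(pwm, aln.window(seqs, k)).log_pwms for k in range(seqs.n)
    )
    return AlignmentScore(float(sum(per_seq)), per_seq)


# ---------------------------------------------------------------------------
# tabular views (TSV-ready DataFrames mirroring the report layout)

def count_table(cm: PositionCountMatrix) -> pd.DataFrame:
    df = pd.DataFrame(cm.counts.T, columns=list(RNA_ALPHABET))
    df.insert(0, "Position", np.arange(1, cm.width + 1))
    return df


def frequency_table(sf: SiteFrequencyMatrix) -> pd.DataFrame:
    df = pd.DataFrame(sf.freqs.T, columns=list(RNA_ALPHABET))
    df.insert(0, "Position", np.arange(1, sf.width + 1))
    return df


def pwm_table(pwm: PositionWeightMatrix) -> pd.DataFrame:
    df = pd.DataFrame(pwm.weights.T, columns=list(RNA_ALPHABET))
    df.insert(0, "Position", np.arange(1, pwm.width + 1))
    return df


def motif_report(
    seqs: SequenceSet, aln: MotifAlignment, pwm: PositionWeightMatrix
) -> pd.DataFrame:
    """Per-sequence motif, start and PWMS (log and odds forms)."""
    rows = []
    for k, rec in enumerate(seqs):
        motif = aln.window(seqs, k)
        score = motif_score(pwm, motif)
        rows.append(
            {
                "SeqName": rec.id,
                "Motif": motif,
                "Start": aln.starts[k],
                "PWMS_log": score.log_pwms,
                "PWMS": score.odds_pwms,
            }
        )
    return pd.DataFrame(rows)
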