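"""Positional analysis of motif placement: upstream/downstream distances.

For each sequence the motif window splits it into an upstream segment (from
the 5' end to the site) and a downstream segment (from the site to the 3'
end).  Their lengths are the S1 and S2 distances:

    S1D = start - 1
    S2D = length - start - width + 1

so that S1D + width + S2D equals the sequence length exactly.  Summary
statistics use the sample (n-1) standard deviation, and the dispersion is
reported as the standard error of the mean, sem = sd / sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .io import SequenceSet
from .pwm import MotifAlignment


@dataclass(frozen=True)
class DistanceSummary:
    """Mean, sample SD and SEM of one distance over all sequences."""

    mean: float
    sd: float
    sem: float


@dataclass(frozen=True)
class PositionalSummary:
    """Per-sequence S1D/S2D values and their summary statistics."""

    ids: tuple[str, ...]
    width: int
    s1d: tuple[int, ...]
    s2d: tuple[int, ...]
    s1d_summary: DistanceSummary
    s2d_summary: DistanceSummary

    @property
    def n(self) -> int:
        return len(self.s1d)


def _summarize(values: np.ndarray) -> DistanceSummary:
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return DistanceSummary(mean, sd, sd / math.sqrt(n) if n > 1 else 0.0)


def distances_from_starts(
    starts, lengths, width: int, ids=None
) -> PositionalSummary:
    """Positional summary from raw 1-based starts and sequence lengths.

    Useful when only the motif coordinates are known (e.g. a published
    start table) without the underlying sequences.
    """
    starts = np.asarray(starts, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    if starts.size == 0:
        raise EmptyInputError("no starts given")
    if starts.shape != lengths.shape:
        raise ValueError("starts and lengths must have equal length")
    s1d = starts - 1
    s2d = lengths - starts - width + 1
    if (s1d < 0).any() or (s2d < 0).any():
        k = int(np.argmax((s1d < 0) | (s2d < 0)))
        raise ValueError(
            f"entry {k}: start {starts[k]} incompatible with length "
            f"{lengths[k]} and width {width}"
        )
    if ids is None:
        ids = tuple(f"seq_{k + 1}" for k in range(starts.size))
    return PositionalSummary(
        ids=tuple(ids),
        width=width,
        s1d=tuple(int(v) for v in s1d),
        s2d=tuple(int(v) for v in s2d),
        s1d_summary=_summarize(s1d),
        s2d_summary=_summarize(s2d),
    )


def positional_distances(
    seqs: SequenceSet, aln: MotifAlignment
) -> PositionalSummary:
    """S1D/S2D of every sequence under an alignment, with summaries."""
    aln.validate(seqs)
    return distances_from_starts(
        aln.starts, seqs.lengths, aln.width, ids=seqs.ids
    )


def scatter_table(ps: PositionalSummary) -> pd.DataFrame:
    """Per-sequence (SeqName, S1D, S2D) table in input order, plot-ready."""
    return pd.DataFrame(
        {"SeqName": list(ps.ids), "S1D": list(ps.s1d), "S2D": list(ps.s2d)}
    )


def summary_dict(ps: PositionalSummary) -> dict:
    """Summary block as a JSON-serializable mapping."""
    return {
        "n": ps.n,
        "width": ps.width,
        "S1D": {
            "mean": ps.s1d_summary.mean,
            "sd": ps.s1d_summary.sd,
            "sem": ps.s1d_summary.sem,
        },
        "S2D": {
            "mean": ps.s2d_summary.mean,
            "sd": ps.s2d_summary.sd,
            "sem": ps.s2d_summary.sem,
        },
    }
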