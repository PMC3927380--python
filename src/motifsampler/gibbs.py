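"""Gibbs site sampler for one-occurrence-per-sequence motif discovery.

The sampler searches for the motif alignment (one fixed-width window per
sequence) maximizing the global log-odds score F.  Each step leaves one
sequence out, builds a weight matrix from the remaining windows, scores every
candidate window of the left-out sequence and resamples its start from the
categorical distribution proportional to exp(window score).  Periodic phase
shifts move the whole alignment left or right to escape misregistered local
optima.

Conventions shared with :mod:`motifsampler.pwm`: background-frequency
pseudocounts (one pseudo-observation) in the numerator frequencies, and a
motif-excluded background in the denominator.  Inside the sampler both the
pseudocount vector and the excluded-background denominator are smoothed with
a light uniform prior so the objective stays finite even when the motif
windows consume every copy of a nucleotide, or the input lacks one entirely
— both happen routinely on the tiny instances used for exhaustive
verification.  On realistic inputs the smoothing is numerically negligible
(relative effect ~1/total_length).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import AlignmentError, SearchSpaceError
from .io import BackgroundComposition, SequenceSet, background_composition
from .pwm import MotifAlignment

_EPS_IMPROVE = 1e-12


@dataclass(frozen=True)
class SamplerConfig:
    """Run parameters for :func:`run_sampler`.

    Attributes
    ----------
    width:
        Motif length in nucleotides.
    iterations:
        Maximum number of full sweeps per restart (one sweep resamples every
        sequence once).
    restarts:
        Independent chains; restart ``r`` is seeded with ``seed + r``.
    seed:
        Base RNG seed.
    plateau:
        Stop a restart after this many sweeps without best-F improvement.
    phase_shift_period:
        Propose a coordinated column shift every this many sweeps (0 = off).
    max_shift:
        Largest column offset tried by a phase-shift proposal.
    shuffle_order:
        Visit sequences in random order each sweep instead of input order.
    """

    width: int = 6
    iterations: int = 500
    restarts: int = 20
    seed: int = 0
    plateau: int = 40
    phase_shift_period: int = 5
    max_shift: int = 3
    shuffle_order: bool = False

    def __post_init__(self) -> None:
        if self.width < 1 or self.iterations < 1 or self.restarts < 1:
            raise ValueError("width, iterations and restarts must be >= 1")
        if self.plateau < 1:
            raise ValueError("plateau must be >= 1")


@dataclass(frozen=True)
class SamplerResult:
    """Outcome of a sampler run."""

    best_alignment: MotifAlignment
    best_F: float
    trajectory: tuple[float, ...]
    chain_id: int
    restart_best: tuple[float, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# internal numeric core (operates on uint8-encoded sequences)


def _window_counts(enc: list[np.ndarray], starts: np.ndarray, width: int) -> np.ndarray:
    counts = np.zeros((4, width), dtype=np.int64)
    cols = np.arange(width)
    for idx, s in zip(enc, starts):
        counts[idx[s : s + width], cols] += 1
    return counts


def _weights_from_counts(
    counts: np.ndarray, n_windows: int, bg_counts: np.ndarray
) -> np.ndarray:
    """Natural-log weight matrix under the sampler's smoothed conventions.

    The pseudocount vector is the background frequency under a light uniform
    prior (half a count per nucleotide), so the weights stay finite even when
    the input lacks a nucleotide entirely or the motif windows consume every
    copy of one.  The same vector smooths the excluded-background denominator.
    """
    p = (bg_counts + 0.5) / (bg_counts.sum() + 2.0)
    site = (counts + p[:, None]) / (n_windows + 1)
    denom_counts = bg_counts - counts.sum(axis=1) + p
    denom = denom_counts / denom_counts.sum()
    return np.log(site) - np.log(denom)[:, None]


def _objective_from_counts(
    counts: np.ndarray, n_windows: int, bg_counts: np.ndarray
) -> float:
    w = _weights_from_counts(counts, n_windows, bg_counts)
    return float((w * counts).sum())


def alignment_objective(
    seqs: SequenceSet,
    aln: MotifAlignment,
    bg: BackgroundComposition | None = None,
) -> float:
    """Global score F of an alignment under the sampler's objective.

    Builds the weight matrix from the alignment itself (smoothed excluded
    background) and sums the per-window log scores.  This is the quantity
    :func:`run_sampler` maximizes and :func:`exhaustive_oracle` enumerates.
    """
    aln.validate(seqs)
    if bg is None:
        bg = background_composition(seqs)
    enc = seqs.encoded()
    starts = np.asarray(aln.starts, dtype=np.int64) - 1
    counts = _window_counts(enc, starts, aln.width)
    bg_counts = np.asarray(bg.counts, dtype=float)
    return _objective_from_counts(counts, seqs.n, bg_counts)


def _candidate_log_weights(
    enc_k: np.ndarray,
    counts_minus: np.ndarray,
    n_other: int,
    bg_counts: np.ndarray,
    width: int,
) -> np.ndarray:
    """Log sampling weight of every candidate start in the left-out sequence."""
    w = _weights_from_counts(counts_minus, n_other, bg_counts)
    windows = sliding_window_view(enc_k, width)
    return w[windows, np.arange(width)].sum(axis=1)


def initialize_alignment(
    seqs: SequenceSet, width: int, rng: np.random.Generator
) -> MotifAlignment:
    """Draw each start uniformly from its valid range."""
    starts = []
    for rec in seqs:
        hi = rec.length - width + 1
        if hi < 1:
            raise AlignmentError(
                f"sequence {rec.id!r} (length {rec.length}) is shorter than "
                f"the motif width {width}"
            )
        starts.append(int(rng.integers(1, hi + 1)))
    return MotifAlignment(width, tuple(starts))


def candidate_distribution(
    seqs: SequenceSet,
    aln: MotifAlignment,
    leftout: int,
    bg: BackgroundComposition | None = None,
) -> np.ndarray:
    """Sampling probabilities over candidate starts for the left-out sequence.

    Position ``x`` of the returned array is the probability of 1-based start
    ``x + 1``.  Exposed so tests can verify the categorical weights directly.
    """
    aln.validate(seqs)
    if not 0 <= leftout < seqs.n:
        raise AlignmentError(f"left-out index {leftout} outside [0, {seqs.n})")
    if bg is None:
        bg = background_composition(seqs)
    enc = seqs.encoded()
    starts = np.asarray(aln.starts, dtype=np.int64) - 1
    bg_counts = np.asarray(bg.counts, dtype=float)
    counts = _window_counts(enc, starts, aln.width)
    cols = np.arange(aln.width)
    counts_minus = counts.copy()
    s = starts[leftout]
    counts_minus[enc[leftout][s : s + aln.width], cols] -= 1
    logw = _candidate_log_weights(
        enc[leftout], counts_minus, seqs.n - 1, bg_counts, aln.width
    )
    w = np.exp(logw - logw.max())
    return w / w.sum()


def sampling_step(
    seqs: SequenceSet,
    aln: MotifAlignment,
    leftout: int,
    bg: BackgroundComposition | None = None,
    rng: np.random.Generator | None = None,
) -> MotifAlignment:
    """Resample the left-out sequence's start; all other starts unchanged."""
    if rng is None:
        rng = np.random.default_rng()
    probs = candidate_distribution(seqs, aln, leftout, bg)
    new_start = int(rng.choice(len(probs), p=probs)) + 1
    starts = list(aln.starts)
    starts[leftout] = new_start
    return MotifAlignment(aln.width, tuple(starts))


def phase_shift(
    seqs: SequenceSet,
    aln: MotifAlignment,
    max_shift: int,
    rng: np.random.Generator | None = None,
    bg: BackgroundComposition | None = None,
) -> MotifAlignment:
    """Shift all starts by the offset maximizing F; ties keep the alignment.

    Candidate offsets delta in [-max_shift, max_shift] are applied to every
    start (clipped to each sequence's valid range); the shifted alignment is
    accepted only when its objective strictly exceeds the current one, so a
    tie always resolves to delta = 0.  Deterministic; ``rng`` is accepted for
    interface symmetry but unused.
    """
    aln.validate(seqs)
    if max_shift <= 0:
        return aln
    if bg is None:
        bg = background_composition(seqs)
    lengths = np.asarray(seqs.lengths)
    base = np.asarray(aln.starts, dtype=np.int64)
    best_aln = aln
    best_F = alignment_objective(seqs, aln, bg)
    for delta in sorted(range(-max_shift, max_shift + 1), key=lambda d: (abs(d), d)):
        if delta == 0:
            continue
        shifted = np.clip(base + delta, 1, lengths - aln.width + 1)
        cand = MotifAlignment(aln.width, tuple(int(s) for s in shifted))
        F = alignment_objective(seqs, cand, bg)
        if F > best_F + _EPS_IMPROVE:
            best_F, best_aln = F, cand
    return best_aln


def run_sampler(seqs: SequenceSet, cfg: SamplerConfig) -> SamplerResult:
    """Multi-restart Gibbs site sampling; returns the best alignment found.

    Each restart initializes uniformly at random, then sweeps: one
    :func:`sampling_step` per sequence (input order unless
    ``cfg.shuffle_order``), with a phase-shift proposal every
    ``cfg.phase_shift_period`` sweeps.  A restart stops after
    ``cfg.iterations`` sweeps or ``cfg.plateau`` sweeps without improvement
    of its best F.  Fully reproducible under a fixed seed.
    """
    for rec in seqs:
        if rec.length < cfg.width:
            raise AlignmentError(
                f"sequence {rec.id!r} (length {rec.length}) is shorter than "
                f"the motif width {cfg.width}"
            )
    bg = background_composition(seqs)
    bg_counts = np.asarray(bg.counts, dtype=float)
    enc = seqs.encoded()
    n = seqs.n
    width = cfg.width
    cols = np.arange(width)

    global_best_F = -math.inf
    global_best_starts: np.ndarray | None = None
    global_chain = -1
    trajectory: list[float] = []
    restart_best: list[float] = []

    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + r)
        aln0 = initialize_alignment(seqs, width, rng)
        starts = np.asarray(aln0.starts, dtype=np.int64) - 1
        counts = _window_counts(enc, starts, width)
        best_F = _objective_from_counts(counts, n, bg_counts)
        best_starts = starts.copy()
        stale = 0
        for sweep in range(cfg.iterations):
            order = rng.permutation(n) if cfg.shuffle_order else range(n)
            for k in order:
                s = starts[k]
                counts[enc[k][s : s + width], cols] -= 1
                logw = _candidate_log_weights(enc[k], counts, n - 1, bg_counts, width)
                w = np.exp(logw - logw.max())
                new_s = int(rng.choice(len(w), p=w / w.sum()))
                starts[k] = new_s
                counts[enc[k][new_s : new_s + width], cols] += 1
            if cfg.phase_shift_period and (sweep + 1) % cfg.phase_shift_period == 0:
                cand = phase_shift(
                    seqs,
                    MotifAlignment(width, tuple(int(s) + 1 for s in starts)),
                    cfg.max_shift,
                    bg=bg,
                )
                starts = np.asarray(cand.starts, dtype=np.int64) - 1
                counts = _window_counts(enc, starts, width)
            F = _objective_from_counts(counts, n, bg_counts)
            if F > best_F + _EPS_IMPROVE:
                best_F = F
                best_starts = starts.copy()
                stale = 0
            else:
                stale += 1
            trajectory.append(max(best_F, global_best_F))
            if stale >= cfg.plateau:
                break
        restart_best.append(best_F)
        if best_F > global_best_F + _EPS_IMPROVE:
            global_best_F = best_F
            global_best_starts = best_starts
            global_chain = r

    assert global_best_starts is not None
    best_aln = MotifAlignment(width, tuple(int(s) + 1 for s in global_best_starts))
    return SamplerResult(
        best_alignment=best_aln,
        best_F=float(global_best_F),
        trajectory=tuple(trajectory),
        chain_id=global_chain,
        restart_best=tuple(restart_best),
    )


def exhaustive_oracle(
    seqs: SequenceSet, width: int, *, max_combinations: int = 10**6
) -> MotifAlignment:
    """Brute-force optimum of the sampler objective on a tiny instance.

    Enumerates every combination of starts in lexicographic order and keeps
    the first alignment attaining the maximal F, i.e. ties break to the
    lexicographically smallest start vector.  Intended for tests; refuses
    search spaces above ``max_combinations``.
    """
    ranges = []
    for rec in seqs:
        hi = rec.length - width + 1
        if hi < 1:
            raise AlignmentError(
                f"sequence {rec.id!r} (length {rec.length}) is shorter than "
                f"the motif width {width}"
            )
        ranges.append(range(hi))
    space = math.prod(len(r) for r in ranges)
    if space > max_combinations:
        raise SearchSpaceError(
            f"{space} start combinations exceed the cap {max_combinations}"
        )
    bg = background_composition(seqs)
    bg_counts = np.asarray(bg.counts, dtype=float)
    enc = seqs.encoded()
    best_F = -math.inf
    best: tuple[int, ...] | None = None
    for combo in itertools.product(*ranges):
        counts = _window_counts(enc, np.asarray(combo, dtype=np.int64), width)
        F = _objective_from_counts(counts, seqs.n, bg_counts)
        if F > best_F + _EPS_IMPROVE:
            best_F, best = F, combo
    assert best is not None
    return MotifAlignment(width, tuple(s + 1 for s in best))
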