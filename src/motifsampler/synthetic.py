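"""Planted-motif synthetic sequence sets with known ground truth.

The generator emulates the study conditions of the reference dataset: 34
sequences totalling roughly 31.5 kb, background composition near
(A 0.2419, C 0.2532, G 0.2818, U 0.2231), and a planted 6-mer consensus
(CUGGAA by default) with independent per-position substitution noise.  The
true planted start of every sequence is returned alongside the sequences, so
sampler recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError
from .io import RNA_ALPHABET, SequenceRecord, SequenceSet, decode, encode
from .pwm import MotifAlignment

#: Background frequencies of the reference dataset (A, C, G, U order).
DEFAULT_COMPOSITION = (0.2419, 0.2532, 0.2818, 0.2231)

#: Per-position substitution rate matching the divergence of the reference
#: motif assignments (16 mismatches to the consensus over 34 x 6 positions).
DEFAULT_MUTATION_RATE = 0.08


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-motif dataset.

    Defaults reproduce the reference study conditions: n = 34 sequences of
    mean length 927 nt (total ~31.5 kb), reference background composition,
    consensus CUGGAA planted once per sequence.
    """

    n_seqs: int = 34
    mean_length: int = 927
    length_spread: int = 400
    composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION
    consensus: str = "CUGGAA"
    per_position_mutation_rate: float = DEFAULT_MUTATION_RATE
    plant_probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if any(p < 0 for p in self.composition):
            raise ValueError("composition frequencies must be non-negative")
        if not 0.0 <= self.per_position_mutation_rate <= 1.0:
            raise ValueError("per_position_mutation_rate must be in [0, 1]")
        if not 0.0 <= self.plant_probability <= 1.0:
            raise ValueError("plant_probability must be in [0, 1]")
        if self.length_spread < 0:
            raise ValueError("length_spread must be >= 0")
        if self.mean_length < len(self.consensus):
            raise ValueError("mean_length must be >= consensus length")
        bad = encode(self.consensus)
        if len(self.consensus) == 0 or (bad == 255).any():
            raise AlphabetError(
                f"consensus {self.consensus!r} must be a non-empty string "
                f"over {RNA_ALPHABET}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted-motif ground truth for one generated dataset."""

    alignment: MotifAlignment
    planted: tuple[bool, ...]
    motifs: tuple[str, ...]  # planted window after substitution noise

    @property
    def n_planted(self) -> int:
        return sum(self.planted)


def _remove_chance_consensus(
    seq_idx: np.ndarray,
    consensus_idx: np.ndarray,
    planted_start0: int | None,
    comp: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Redraw background residues until the exact consensus occurs only at
    the planted site.

    Keeps the benchmark identifiable: without this, a ~31.5 kb background
    contains several chance copies of any specific 6-mer, and a sampler that
    lands on one of them is indistinguishable (equal score) from one that
    found the plant.  Only exact copies of the consensus are removed; the
    composition is otherwise untouched.
    """
    width = len(consensus_idx)
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, width)
    while True:
        hits = np.flatnonzero((windows == consensus_idx).all(axis=1))
        if planted_start0 is not None:
            hits = hits[hits != planted_start0]
        if hits.size == 0:
            return
        for h in hits:
            protected = (
                range(planted_start0, planted_start0 + width)
                if planted_start0 is not None
                else range(0)
            )
            free = [j for j in range(h, h + width) if j not in protected]
            seq_idx[free] = rng.choice(4, size=len(free), p=comp).astype(np.uint8)


def generate(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[SequenceSet, GroundTruth]:
    """Draw a sequence set with planted motifs; reproducible under the seed.

    Background residues are i.i.d. from ``spec.composition``; lengths are
    uniform integers on ``mean_length +/- length_spread`` (floored at the
    consensus length).  Each selected sequence receives exactly one planted
    window at a uniform-random position, each residue independently replaced
    with probability ``per_position_mutation_rate`` by a uniform draw from
    the other three nucleotides.  Chance background copies of the exact
    consensus are redrawn so the planted site is the unique exact occurrence
    (see :func:`_remove_chance_consensus`).  The returned ground-truth
    alignment is
    always valid for the returned set; for sequences left unplanted the
    recorded start is the position that would have been used, flagged False
    in ``planted``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    width = len(spec.consensus)
    consensus_idx = encode(spec.consensus)
    comp = np.asarray(spec.composition, dtype=float)
    comp = comp / comp.sum()

    lo = max(width, spec.mean_length - spec.length_spread)
    hi = max(width, spec.mean_length + spec.length_spread)

    records: list[SequenceRecord] = []
    starts: list[int] = []
    planted: list[bool] = []
    motifs: list[str] = []
    for k in range(spec.n_seqs):
        length = int(rng.integers(lo, hi + 1))
        seq_idx = rng.choice(4, size=length, p=comp).astype(np.uint8)
        start0 = int(rng.integers(0, length - width + 1))
        plant = bool(rng.random() < spec.plant_probability)
        motif_idx = consensus_idx.copy()
        mutate = rng.random(width) < spec.per_position_mutation_rate
        for j in np.flatnonzero(mutate):
            # uniform over the three alternatives to the consensus residue
            motif_idx[j] = (motif_idx[j] + 1 + rng.integers(0, 3)) % 4
        if plant:
            seq_idx[start0 : start0 + width] = motif_idx
        _remove_chance_consensus(
            seq_idx, consensus_idx, start0 if plant else None, comp, rng
        )
        records.append(SequenceRecord(f"synth_{k + 1}", decode(seq_idx)))
        starts.append(start0 + 1)
        planted.append(plant)
        motifs.append(decode(motif_idx) if plant else "")
    truth = GroundTruth(
        alignment=MotifAlignment(width, tuple(starts)),
        planted=tuple(planted),
        motifs=tuple(motifs),
    )
    return SequenceSet(tuple(records)), truth


def ground_truth_table(seqs: SequenceSet, truth: GroundTruth):
    """Ground truth as a (SeqName, Start, Planted, PlantedMotif) DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "SeqName": list(seqs.ids),
            "Start": list(truth.alignment.starts),
            "Planted": list(truth.planted),
            "PlantedMotif": list(truth.motifs),
        }
    )
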