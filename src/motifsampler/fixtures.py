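"""The worked-example reference tables, shipped as machine-readable data.

The package bundles the published E. coli NC101 contig-1 worked example —
background composition, site-specific counts and frequencies, final PWM and
the per-gene motif assignments — as TSV files so that tests and the
acceptance script can verify the scoring chain without any external data.

Two entries of the published site-frequency table were printed without their
decimal separators ("095091", "020691"); the bundled table restores them as
0.95091 and 0.20691.  Negative PWM entries are written with a leading minus
(the original typography used a trailing minus).  All other values are
verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import RNA_ALPHABET, BackgroundComposition
from .pwm import PositionCountMatrix, PositionWeightMatrix, SiteFrequencyMatrix

#: Published global alignment score of the 34-sequence motif alignment.
REFERENCE_F = 230.9101

#: Number of sequences and motif width of the reference run.
REFERENCE_N = 34
REFERENCE_WIDTH = 6

#: Total nucleotides over the 34 sequences.
REFERENCE_TOTAL_LENGTH = 31509

#: Reported consensus motif.
REFERENCE_CONSENSUS = "CUGGAA"

#: Reported positional summaries (mean, sem) of S1D and S2D.
REFERENCE_S1D = (270.61, 37.17)
REFERENCE_S2D = (650.11, 157.24)


def _read(name: str) -> pd.DataFrame:
    with resources.files("motifsampler.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _matrix(df: pd.DataFrame) -> np.ndarray:
    """Position-by-nucleotide table -> 4 x width array in A,C,G,U order."""
    return df[list(RNA_ALPHABET)].to_numpy().T


@dataclass(frozen=True)
class FixtureTables:
    """All reference tables, typed for direct use with the model chain."""

    background: BackgroundComposition
    site_counts: PositionCountMatrix
    site_frequencies: SiteFrequencyMatrix
    pwm: PositionWeightMatrix
    assignments: pd.DataFrame  # SeqName, Motif, Start, PWMS
    F: float = REFERENCE_F


def background_fixture() -> BackgroundComposition:
    df = _read("background.tsv")
    counts = dict(zip(df["Code"], df["Count"]))
    return BackgroundComposition(tuple(float(counts[c]) for c in RNA_ALPHABET))


def site_count_fixture() -> PositionCountMatrix:
    return PositionCountMatrix(_matrix(_read("site_counts.tsv")), REFERENCE_N)


def site_frequency_fixture() -> SiteFrequencyMatrix:
    return SiteFrequencyMatrix(_matrix(_read("site_frequencies.tsv")))


def pwm_fixture() -> PositionWeightMatrix:
    return PositionWeightMatrix(_matrix(_read("pwm.tsv")), math.e)


def assignment_fixture() -> pd.DataFrame:
    return _read("motif_assignments.tsv")


def fixture_tables() -> FixtureTables:
    """Load every reference table at once."""
    return FixtureTables(
        background=background_fixture(),
        site_counts=site_count_fixture(),
        site_frequencies=site_frequency_fixture(),
        pwm=pwm_fixture(),
        assignments=assignment_fixture(),
    )
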