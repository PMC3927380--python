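"""Matrix chain (counts -> frequencies -> weights) and PWMS/F scoring.

The published worked example doubles as an oracle: the bundled tables were
produced by an independent implementation, so reproducing them end to end
checks every convention (pseudocount rule, excluded background, natural
log, odds-form PWMS) at once.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifsampler.errors import AlignmentError, BackgroundError
from motifsampler.io import BackgroundComposition, background_composition
from motifsampler.pwm import (
    MotifAlignment,
    PositionWeightMatrix,
    alignment_score,
    build_pwm,
    count_matrix,
    excluded_background,
    motif_score,
    site_frequencies,
    weight_matrix,
)

from conftest import seqset


class TestCountMatrix:
    def test_homogeneous_input(self):
        cm = count_matrix(seqset("AA", "AA"), MotifAlignment(2, (1, 1)))
        assert cm.n == 2
        assert (cm.counts == [[2, 2], [0, 0], [0, 0], [0, 0]]).all()

    def test_forced_column(self):
        cm = count_matrix(seqset("AC", "GC", "UC"), MotifAlignment(1, (2, 2, 2)))
        assert cm.counts[:, 0].tolist() == [0, 3, 0, 0]

    def test_reference_column_sums(self, reference):
        cm = reference.site_counts
        assert (cm.counts.sum(axis=0) == cm.n).all()
        assert cm.counts[:, 0].tolist() == [0, 34, 0, 0]
        assert cm.counts.sum() == cm.n * cm.width

    def test_start_out_of_range_names_sequence(self):
        with pytest.raises(AlignmentError, match="s2"):
            count_matrix(seqset("ACGU", "ACG"), MotifAlignment(3, (1, 2)))


class TestSiteFrequencies:
    def test_reference_entries_to_five_decimals(self, reference):
        sf = site_frequencies(reference.site_counts, reference.background)
        assert np.round(sf.freqs, 5).tolist() == reference.site_frequencies.freqs.tolist()

    def test_worked_entries(self, reference):
        sf = site_frequencies(reference.site_counts, reference.background)
        p = reference.background.freqs
        # direct arithmetic oracle: (c + p_i) / (n + 1)
        assert sf.freqs[1, 0] == pytest.approx((34 + p[1]) / 35, abs=1e-12)
        assert sf.freqs[0, 0] == pytest.approx(p[0] / 35, abs=1e-12)
        assert sf.freqs[0, 3] == pytest.approx((7 + p[0]) / 35, abs=1e-12)

    def test_columns_sum_to_one(self, reference):
        sf = site_frequencies(reference.site_counts, reference.background)
        assert np.allclose(sf.freqs.sum(axis=0), 1.0, atol=1e-12)
        assert ((sf.freqs > 0) & (sf.freqs < 1)).all()


class TestExcludedBackground:
    def test_reference_arithmetic(self, reference):
        ex = excluded_background(reference.background, reference.site_counts)
        assert ex.counts == (7554.0, 7943.0, 8818.0, 6990.0)
        assert ex.total == 31509 - 204
        assert ex.freqs[0] == pytest.approx(7554 / 31305, abs=1e-12)

    def test_zero_windows_identity(self):
        seqs = seqset("ACGU", "UGCA")
        bg = background_composition(seqs)
        cm = count_matrix(seqs, MotifAlignment(1, (1, 1)))
        zero = type(cm)(np.zeros_like(cm.counts), 0)
        assert excluded_background(bg, zero) == bg

    def test_entirely_motif_degenerate(self):
        seqs = seqset("ACGU")
        bg = background_composition(seqs)
        cm = count_matrix(seqs, MotifAlignment(4, (1,)))
        with pytest.raises(BackgroundError):
            excluded_background(bg, cm)


class TestWeightMatrix:
    def test_reference_pwm_reproduced(self, reference):
        sf = site_frequencies(reference.site_counts, reference.background)
        ex = excluded_background(reference.background, reference.site_counts)
        pwm = weight_matrix(sf, ex)
        assert np.abs(pwm.weights - reference.pwm.weights).max() < 2e-3

    def test_log_of_one_is_zero(self):
        bg = BackgroundComposition((1.0, 1.0, 1.0, 1.0))
        sf = site_frequencies(
            count_matrix(seqset("ACGU"), MotifAlignment(1, (2,))), bg
        )
        # column equal to its denominator background gives weight 0
        uniformish = BackgroundComposition(tuple(sf.freqs[:, 0] * 4))
        pwm = weight_matrix(sf, uniformish)
        assert np.allclose(pwm.weights[:, 0], 0.0, atol=1e-12)

    def test_base_two_matches_scaled_natural_log(self, reference):
        sf = site_frequencies(reference.site_counts, reference.background)
        ex = excluded_background(reference.background, reference.site_counts)
        nat = weight_matrix(sf, ex)
        two = weight_matrix(sf, ex, log_base=2)
        assert np.allclose(two.weights, nat.weights / math.log(2), atol=1e-9)

    def test_sign_tracks_enrichment(self, reference):
        sf = site_frequencies(reference.site_counts, reference.background)
        ex = excluded_background(reference.background, reference.site_counts)
        pwm = weight_matrix(sf, ex)
        assert (np.sign(pwm.weights) == np.sign(sf.freqs - ex.freqs[:, None])).all()


class TestMotifScore:
    def test_published_odds_values(self, reference):
        # the printed PWM is the independent oracle for the scoring rule
        for motif, expected in [("CUGGAA", 2009.2156), ("CUGAAA", 646.2746)]:
            assert motif_score(reference.pwm, motif).odds_pwms == pytest.approx(
                expected, abs=0.1
            )

    def test_zero_weights_empty_sum(self):
        pwm = PositionWeightMatrix(np.zeros((4, 6)))
        s = motif_score(pwm, "CUGGAA")
        assert s.log_pwms == 0.0
        assert s.odds_pwms == 1.0

    def test_length_mismatch_rejected(self, reference):
        with pytest.raises(AlignmentError):
            motif_score(reference.pwm, "CUGGA")

    def test_odds_consistency_and_base_invariance(self, reference):
        nat = motif_score(reference.pwm, "CUGGAA")
        two = PositionWeightMatrix(reference.pwm.weights / math.log(2), 2.0)
        in_two = motif_score(two, "CUGGAA")
        assert nat.odds_pwms == pytest.approx(math.e**nat.log_pwms, rel=1e-9)
        assert in_two.odds_pwms == pytest.approx(nat.odds_pwms, rel=1e-9)
        assert in_two.log_pwms == pytest.approx(nat.log_pwms / math.log(2), abs=1e-9)

    def test_monotonicity_in_column_weight(self, reference):
        # replacing a residue by one with a larger column weight raises PWMS
        base = motif_score(reference.pwm, "CUGAAA")
        better = motif_score(reference.pwm, "CUGGAA")  # G > A at position 4
        assert reference.pwm.weights[2, 3] > reference.pwm.weights[0, 3]
        assert better.log_pwms > base.log_pwms
        assert better.odds_pwms > base.odds_pwms


class TestAlignmentScore:
    def test_single_sequence(self):
        seqs = seqset("ACGUAC")
        aln = MotifAlignment(3, (2,))
        pwm = build_pwm(seqs, aln, exclude_motif_background=False)
        score = alignment_score(pwm, seqs, aln)
        assert score.F == pytest.approx(
            motif_score(pwm, "CGU").log_pwms, abs=1e-12
        )

    def test_zero_weights_give_zero_F(self):
        seqs = seqset("ACGUAC", "GGGCCC")
        pwm = PositionWeightMatrix(np.zeros((4, 3)))
        assert alignment_score(pwm, seqs, MotifAlignment(3, (1, 2))).F == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_F_is_sum_of_per_sequence_scores(self, seed):
        rng = np.random.default_rng(seed)
        seqs = seqset(
            *(
                "".join(rng.choice(list("ACGU"), rng.integers(6, 15)))
                for _ in range(rng.integers(2, 5))
            )
        )
        width = int(rng.integers(1, 5))
        starts = tuple(
            int(rng.integers(1, rec.length - width + 2)) for rec in seqs
        )
        aln = MotifAlignment(width, starts)
        pwm = build_pwm(seqs, aln, exclude_motif_background=False)
        score = alignment_score(pwm, seqs, aln)
        total = sum(
            motif_score(pwm, aln.window(seqs, k)).log_pwms for k in range(seqs.n)
        )
        assert score.F == pytest.approx(total, abs=1e-9)
        # count conservation on the same instance
        cm = count_matrix(seqs, aln)
        assert (cm.counts.sum(axis=0) == seqs.n).all()
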