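"""PWM construction, exact DP score p-values, SNP scanning, fold changes."""

import itertools

import numpy as np
import pytest

from locuspipe import allelic_motif as mo


def brute_force_pvalue(pwm: mo.PWM, threshold_int: int) -> float:
    """Enumerate every sequence of the motif's length on the integer score
    scale; independent of the DP convolution."""
    ints, _ = mo._discretize(pwm)
    total = 0.0
    for seq in itertools.product(range(4), repeat=pwm.length):
        s = sum(ints[i, b] for i, b in enumerate(seq))
        if s >= threshold_int:
            total += float(np.prod([pwm.background[b] for b in seq]))
    return total


class TestPfmToPwm:
    def test_uniform_counts_uniform_bg_zero_matrix(self):
        pwm = mo.pfm_to_pwm(np.full((4, 4), 10.0))
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)

    def test_single_sequence_pfm_argmax(self):
        counts = np.zeros((3, 4))
        for i, b in enumerate([0, 2, 3]):  # A, G, T
            counts[i, b] = 100.0
        pwm = mo.pfm_to_pwm(counts)
        assert list(np.argmax(pwm.log_odds, axis=1)) == [0, 2, 3]

    def test_hand_computed_two_mer(self):
        counts = np.array([[3.0, 1.0, 0.0, 0.0], [0.0, 0.0, 4.0, 0.0]])
        bg = np.full(4, 0.25)
        pwm = mo.pfm_to_pwm(counts, bg, pseudocount=1.0)
        expected_00 = np.log((3 + 0.25) / 5.0) - np.log(0.25)
        assert pwm.log_odds[0, 0] == pytest.approx(expected_00)
        expected_12 = np.log((4 + 0.25) / 5.0) - np.log(0.25)
        assert pwm.log_odds[1, 2] == pytest.approx(expected_12)

    def test_all_zero_column_rejected(self):
        counts = np.array([[1.0, 1, 1, 1], [0, 0, 0, 0]])
        with pytest.raises(ValueError):
            mo.pfm_to_pwm(counts)


class TestScorePvalue:
    @pytest.fixture
    def random_pwm(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(1, 50, size=(6, 4)).astype(float)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        return mo.pfm_to_pwm(counts, bg, name="m6")

    def test_extremes(self, random_pwm):
        smin = random_pwm.log_odds.min(axis=1).sum()
        smax = random_pwm.log_odds.max(axis=1).sum()
        assert mo.score_pvalue(random_pwm, smin) == pytest.approx(1.0)
        assert mo.score_pvalue(random_pwm, smax + 1.0) == 0.0

    def test_monotone_nonincreasing(self, random_pwm):
        grid = np.linspace(
            random_pwm.log_odds.min(axis=1).sum(),
            random_pwm.log_odds.max(axis=1).sum(),
            25,
        )
        ps = [mo.score_pvalue(random_pwm, s) for s in grid]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 30, size=(6, 4)).astype(float)
        bg = rng.dirichlet(np.ones(4) * 5)
        pwm = mo.pfm_to_pwm(counts, bg)
        ints, _ = mo._discretize(pwm)
        for q in (0.2, 0.5, 0.9, 0.99):
            thr = int(np.quantile(ints.sum(axis=1), q) * 2)
            assert mo._pvalue_from_int_score(pwm, thr) == pytest.approx(
                brute_force_pvalue(pwm, thr), abs=1e-9
            )

    def test_discretization_bound_brackets_p(self, random_pwm):
        s = float(np.median(random_pwm.log_odds.sum(axis=0)))
        p, (p_lo, p_hi) = mo.score_pvalue(random_pwm, s, return_bound=True)
        assert p_lo <= p <= p_hi


class TestSnpBestHit:
    @pytest.fixture
    def pwm(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 40, size=(5, 4)).astype(float)
        return mo.pfm_to_pwm(counts, name="m5")

    def test_agrees_with_window_brute_force(self, pwm):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 25))
        snp_pos, allele = 13, "C"
        mutated = seq[: snp_pos - 1] + allele + seq[snp_pos:]
        L = pwm.length
        ints, k = mo._discretize(pwm)
        best = -np.inf
        for start in range(snp_pos - L, snp_pos):
            win = mutated[start : start + L]
            for w in (win, mo.reverse_complement(win)):
                s = sum(ints[i, "ACGT".index(b)] for i, b in enumerate(w))
                best = max(best, s)
        score, p, strand, offset = mo.snp_best_hit(pwm, seq, snp_pos, allele)
        assert score == pytest.approx(best / k)
        assert mo._pvalue_from_int_score(pwm, int(best)) == pytest.approx(p)

    def test_palindromic_pwm_strand_symmetric(self):
        # a motif equal to its own reverse complement scores both strands
        # identically, so the best hit must not depend on strand choice
        counts = np.array(
            [[10, 2, 2, 1], [1, 8, 8, 1], [1, 8, 8, 1], [1, 2, 2, 10.0]]
        )
        pwm = mo.pfm_to_pwm(counts)
        np.testing.assert_allclose(
            pwm.log_odds, pwm.reverse_complement().log_odds, atol=1e-12
        )
        seq = "ACGTACGTACGTACG"
        s_f, p_f, _, _ = mo.snp_best_hit(pwm, seq, 8, "A")
        s_r, p_r, _, _ = mo.snp_best_hit(
            pwm.reverse_complement(), seq, 8, "A"
        )
        assert s_f == pytest.approx(s_r)
        assert p_f == pytest.approx(p_r)

    def test_reverse_complement_everything_invariant(self, pwm):
        seq = "AAGGTTCCAAGGTTCCAAGGT"
        pos = 11
        s1, p1, _, _ = mo.snp_best_hit(pwm, seq, pos, "G")
        rc_pos = len(seq) - pos + 1
        s2, p2, _, _ = mo.snp_best_hit(
            pwm, mo.reverse_complement(seq), rc_pos, "C"
        )
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_perfect_match_at_snp_scores_max(self, pwm):
        consensus = "".join(
            "ACGT"[b] for b in np.argmax(pwm.log_odds, axis=1)
        )
        seq = "AAAA" + consensus + "AAAA"
        snp_pos = 5 + 2  # third base of the embedded consensus
        score, p, strand, _ = mo.snp_best_hit(pwm, seq, snp_pos, consensus[2])
        smax = pwm.log_odds.max(axis=1).sum()
        assert score == pytest.approx(smax, abs=1e-3)
        assert p == pytest.approx(mo.score_pvalue(pwm, smax), abs=1e-12)

    def test_short_flank_raises(self, pwm):
        with pytest.raises(ValueError, match="flank"):
            mo.snp_best_hit(pwm, "ACGTACG", 2, "A")


class TestFoldChange:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            (2.08e-3, 8.70e-5, 23.91),
            (8.16e-4, 2.15e-5, 37.95),
        ],
    )
    def test_printed_pairs(self, p1, p2, expected):
        fold, stronger = mo.fold_change_from_pvalues(p1, p2, "G", "A")
        assert fold == pytest.approx(expected, rel=1e-3)
        assert stronger == "A"

    def test_equal_pvalues_unity(self):
        fold, _ = mo.fold_change_from_pvalues(0.01, 0.01)
        assert fold == 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            mo.fold_change_from_pvalues(0.0, 0.5)


class TestRanking:
    def make_report(self, motif, p1, p2):
        fold, stronger = mo.fold_change_from_pvalues(p1, p2, "G", "A")
        return mo.AlleleMotifReport(
            snp_id="rs", motif=motif, allele1="G", allele2="A",
            p_allele1=p1, p_allele2=p2, fold_change=fold,
            stronger_allele=stronger, hit1=(0, "+", 1), hit2=(0, "+", 1),
        )

    def test_printed_pairs_rank_order(self):
        # the seven AP-1-family pairs for the enhancer SNP: the pair with
        # p-ratio ~87 must rank first
        pairs = {
            "FOSB": (1.18e-4, 2.93e-5),
            "FOS": (5.73e-4, 2.74e-5),
            "FOSL1": (4.32e-4, 4.94e-6),
            "FOSL2": (8.16e-4, 2.15e-5),
            "JUNB": (8.00e-4, 2.47e-5),
            "JUND": (9.47e-4, 2.28e-5),
            "JUN": (8.40e-4, 2.68e-5),
        }
        reports = [self.make_report(m, *ps) for m, ps in pairs.items()]
        ranked = mo.rank_disrupted_motifs(reports)
        assert ranked[0].motif == "FOSL1"

    def test_empty_and_identity_filter(self):
        assert mo.rank_disrupted_motifs([]) == []
        reports = [self.make_report("X", 1e-3, 1e-4)]
        assert mo.rank_disrupted_motifs(reports, fold_min=1.0) == reports
        assert mo.rank_disrupted_motifs(reports, fold_min=100.0) == []
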