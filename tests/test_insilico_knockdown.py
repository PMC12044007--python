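"""TMM normalization, quartile split, NB exact test, BH FDR, preranked GSEA."""

import numpy as np
import pandas as pd
import pytest

from locuspipe import insilico_knockdown as kd
from locuspipe import synthetic_data as sd

# Factors computed with edgeR::calcNormFactors (method="TMM") on the exact
# matrix the small_counts fixture regenerates; independent oracle.
EDGER_TMM = [1.04323, 0.8596437, 1.02652, 1.045159, 1.039326]

# edgeR::exactTestBySmallP on the group sums of the first ten genes of the
# deterministic matrix below, dispersion 0.15/4 (four equalized samples per
# group collapse to one NB observation each).
EDGER_SMALLP = [
    8.77780279369e-05, 5.18164013067e-06, 6.65523610227e-08,
    9.14702343744e-08, 5.18818007965e-07, 1.0, 9.28178580968e-01,
    1.0, 5.71717437951e-01, 6.10085267266e-02,
]


def exact_fixture():
    rng = np.random.default_rng(7)
    mu = rng.lognormal(3.5, 1, size=60)
    r = 1 / 0.15
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(60, 8))
    counts[:5, :4] = rng.negative_binomial(
        r, r / (r + 4 * mu[:5, None]), size=(5, 4)
    )
    return pd.DataFrame(
        counts, index=[f"g{i}" for i in range(60)],
        columns=[f"s{j}" for j in range(8)],
    )


class TestFilterExpressed:
    def test_strict_threshold(self):
        counts = pd.DataFrame(
            np.array(
                [
                    [0] * 21 + [5] * 79,
                    [0] * 20 + [5] * 80,
                    [5] * 100,
                ]
            ),
            index=["zero21", "zero20", "dense"],
            columns=[f"s{j}" for j in range(100)],
        )
        kept = kd.filter_expressed(counts)
        assert list(kept.index) == ["zero20", "dense"]

    def test_all_nonzero_identity(self):
        counts = pd.DataFrame(np.ones((5, 10)), dtype=int)
        pd.testing.assert_frame_equal(kd.filter_expressed(counts), counts)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame(
            np.tile(np.arange(1, 101)[:, None], (1, 4)),
            columns=list("abcd"),
        )
        np.testing.assert_allclose(kd.tmm_factors(counts), 1.0, atol=1e-12)

    def test_pure_depth_difference_unit_factors(self):
        rng = np.random.default_rng(5)
        base = rng.integers(1, 500, size=200)
        counts = pd.DataFrame({"ref": base, "double": base * 2})
        np.testing.assert_allclose(kd.tmm_factors(counts), 1.0, atol=1e-9)

    def test_matches_edger_oracle(self, small_counts):
        ours = kd.tmm_factors(small_counts).to_numpy()
        np.testing.assert_allclose(ours, EDGER_TMM, rtol=0.01)

    def test_log_factors_sum_to_zero(self, small_counts):
        f = kd.tmm_factors(small_counts)
        assert np.sum(np.log(f)) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            kd.tmm_factors(counts)


class TestQuartileSplit:
    def test_quartile_sizes(self):
        for n, k in [(328, 82), (9, 2), (100, 25)]:
            counts = pd.DataFrame(
                np.arange(n)[None, :] + 1.0,
                index=["drv"],
                columns=[f"s{j}" for j in range(n)],
            )
            low, high = kd.quartile_split(counts, "drv")
            assert len(low) == len(high) == k
            assert not set(low) & set(high)

    def test_monotone_labels(self):
        counts = pd.DataFrame(
            np.arange(12)[None, :] + 1.0,
            index=["drv"],
            columns=[f"s{j:02d}" for j in range(12)],
        )
        low, high = kd.quartile_split(counts, "drv")
        assert low == ["s00", "s01", "s02"]
        assert high == ["s09", "s10", "s11"]

    def test_errors(self):
        counts = pd.DataFrame(np.ones((1, 7)), index=["drv"])
        with pytest.raises(ValueError):
            kd.quartile_split(counts, "drv")
        with pytest.raises(KeyError):
            kd.quartile_split(
                pd.DataFrame(np.ones((1, 20)), index=["x"]), "drv"
            )


class TestExactTest:
    def test_matches_edger_small_p_oracle(self):
        counts = exact_fixture()
        s1 = counts.iloc[:, :4].sum(axis=1).to_numpy()
        s2 = counts.iloc[:, 4:].sum(axis=1).to_numpy()
        for i in range(10):
            ours = kd._exact_nb_pvalue(int(s1[i]), int(s2[i]), 4, 4, 0.15)
            assert ours == pytest.approx(EDGER_SMALLP[i], rel=1e-6)

    def test_group_relabel_symmetry(self):
        counts = exact_fixture()
        a = [f"s{j}" for j in range(4)]
        b = [f"s{j}" for j in range(4, 8)]
        de_ab = kd.nb_exact_test(counts, a, b, dispersion=0.15)
        de_ba = kd.nb_exact_test(counts, b, a, dispersion=0.15)
        np.testing.assert_allclose(
            de_ab.table["p"], de_ba.table["p"], rtol=1e-9
        )
        np.testing.assert_allclose(
            de_ab.table["log2fc"], -de_ba.table["log2fc"], atol=1e-9
        )

    def test_zero_gene_handled(self):
        counts = exact_fixture()
        counts.iloc[10, :] = 0
        de = kd.nb_exact_test(
            counts, [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)],
            dispersion=0.1,
        )
        assert de.table.iloc[10]["p"] == 1.0
        assert de.table.iloc[10]["log2fc"] == 0.0

    def test_symmetric_split_p_one(self):
        assert kd._exact_nb_pvalue(30, 30, 4, 4, 0.1) == pytest.approx(1.0)

    def test_dispersion_recovered_and_power(self):
        rng = np.random.default_rng(9)
        mu = np.full(150, 100.0)
        phi = 0.08
        r = 1 / phi
        a = rng.negative_binomial(r, r / (r + mu[:, None]), size=(150, 20))
        b = rng.negative_binomial(r, r / (r + mu[:, None]), size=(150, 20))
        b[:30] = rng.negative_binomial(
            r, r / (r + 4 * mu[:30, None]), size=(30, 20)
        )
        counts = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"g{i}" for i in range(150)],
            columns=[f"s{j}" for j in range(40)],
        )
        de = kd.nb_exact_test(
            counts, [f"s{j}" for j in range(20)], [f"s{j}" for j in range(20, 40)]
        )
        assert de.dispersion == pytest.approx(phi, rel=0.5)
        planted = de.table.iloc[:30]
        assert (planted["fdr"] < 0.05).mean() > 0.9

    def test_small_groups_rejected(self):
        counts = exact_fixture()
        with pytest.raises(ValueError):
            kd.nb_exact_test(counts, ["s0"], ["s1", "s2"])


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(
            kd.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_cases(self):
        assert kd.bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(kd.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_brute_force_oracle(self):
        def step_up(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(kd.bh_fdr(p), step_up(p), atol=1e-12)

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        assert np.all(kd.bh_fdr(p) >= p - 1e-15)


class TestSelection:
    def test_boundary_semantics(self):
        table = pd.DataFrame(
            {
                "log2fc": [0.5, 0.51, -0.9, 0.2],
                "p": [0.001] * 4,
                "fdr": [0.01, 0.01, 0.01, 0.2],
            },
            index=["at_lfc", "pass", "neg_pass", "high_fdr"],
        )
        assert kd.de_gene_selection(table, log2fc_min=0.5) == ["pass", "neg_pass"]
        assert kd.de_gene_selection(table) == ["at_lfc", "pass", "neg_pass"]
        assert kd.de_gene_selection(table, fdr_max=1.0, log2fc_min=None) == list(
            table.index
        )


def brute_force_es(weights, member_mask):
    """Running-sum ES evaluated at every rank; independent of the
    hit-position shortcut in the implementation."""
    w = np.abs(weights)
    n = len(w)
    m = member_mask.sum()
    hit = np.where(member_mask, w, 0.0)
    denom = hit.sum() if hit.sum() > 0 else m
    running = np.cumsum(hit / denom - (~member_mask) / (n - m))
    return running[np.argmax(np.abs(running))]


class TestGSEA:
    def test_top_genes_near_maximal_es(self):
        rng = np.random.default_rng(12)
        ranked = pd.Series(
            np.sort(rng.standard_normal(300))[::-1],
            index=[f"G{i}" for i in range(300)],
        )
        res = kd.gsea_preranked(
            ranked, {"top": [f"G{i}" for i in range(10)]}, n_perm=100, seed=1
        )
        assert res.table.loc["top", "es"] > 0.9

    def test_es_matches_brute_force(self):
        rng = np.random.default_rng(13)
        weights = np.sort(rng.standard_normal(200))[::-1]
        for _ in range(5):
            mask = np.zeros(200, dtype=bool)
            mask[rng.choice(200, 15, replace=False)] = True
            ours = kd._enrichment_score(weights, np.where(mask)[0])
            assert ours == pytest.approx(brute_force_es(weights, mask), abs=1e-12)

    def test_small_sets_skipped(self):
        rng = np.random.default_rng(14)
        ranked = pd.Series(
            rng.standard_normal(100), index=[f"G{i}" for i in range(100)]
        )
        res = kd.gsea_preranked(
            ranked, {"tiny": ["G1", "G2"]}, n_perm=50, seed=2
        )
        assert len(res.table) == 0

    def test_planted_set_recovered(self):
        found = 0
        trials = 10
        for seed in range(trials):
            counts, truth = sd.simulate_rnaseq(
                n_genes=400, n_samples=120, planted_sets={"UP": 25},
                planted_log2fc=1.5, seed=700 + seed,
            )
            de, gsea, selected = kd.insilico_knockdown(
                counts, "DRIVER", gene_sets=truth.gene_sets, n_perm=200,
                seed=seed, fdr_max=1.1,
            )
            row = gsea.table.loc["UP"]
            # driver-low vs driver-high contrast: planted-up genes fall when
            # the driver falls, so the set enriches negatively on log2(low/high)
            found += (row["fdr"] < 0.1) and (row["es"] < 0)
        assert found >= 0.9 * trials


class TestEndToEnd:
    def test_null_matrix_no_discoveries(self):
        counts, _ = sd.simulate_rnaseq(
            n_genes=300, n_samples=120, planted_sets=None, seed=55
        )
        de, _, selected = kd.insilico_knockdown(counts, "DRIVER")
        assert len(selected) <= max(2, 0.01 * len(de.table))
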