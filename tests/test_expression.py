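"""Symbol collapsing, contrasts, categories, z-scoring and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synergykit import (CategoryFilterConfig, ExpressionMatrix, GeneSet,
                        classify_combination_categories, collapse_to_symbols,
                        enrichment_score, fold_changes, gsea_permutation_test,
                        rank_by_class_difference, threshold_gene_lists,
                        venn_counts, zscore_rows)


def tiny_matrix(values, samples=None, conditions=None, mapping=None):
    samples = samples or ["V1", "V2", "A1", "A2", "B1", "B2", "C1", "C2"]
    conditions = conditions or {"V1": "vehicle", "V2": "vehicle",
                                "A1": "drug_a", "A2": "drug_a",
                                "B1": "drug_b", "B2": "drug_b",
                                "C1": "combination", "C2": "combination"}
    df = pd.DataFrame(values, columns=samples)
    return ExpressionMatrix(values=df, sample_conditions=conditions,
                            qualifier_to_symbol=mapping)


def brute_force_es(scores, hit_mask, p=1.0):
    """Independent cumulative-walk oracle for the running-sum ES."""
    w = np.abs(scores) ** p
    tot = w[hit_mask].sum()
    n, k = len(scores), hit_mask.sum()
    running, cum = [], 0.0
    for i in range(n):
        cum += w[i] / tot if hit_mask[i] else -1.0 / (n - k)
        running.append(cum)
    running = np.array(running)
    return running[np.argmax(np.abs(running))]


class TestCollapse:
    def test_max_mean_qualifier_kept(self):
        df = pd.DataFrame({"s1": [7.0, 9.2], "s2": [7.2, 9.4]},
                          index=["q_low", "q_high"])
        mat = ExpressionMatrix(
            values=df,
            sample_conditions={"s1": "vehicle", "s2": "vehicle"},
            qualifier_to_symbol={"q_low": "GATA2", "q_high": "GATA2"})
        out = collapse_to_symbols(mat)
        assert list(out.values.index) == ["GATA2"]
        assert out.values.loc["GATA2", "s1"] == 9.2

    def test_identity_when_one_qualifier_per_symbol(self):
        df = pd.DataFrame({"s1": [1.0, 2.0]}, index=["q1", "q2"])
        mat = ExpressionMatrix(values=df, sample_conditions={"s1": "vehicle"},
                               qualifier_to_symbol={"q1": "A", "q2": "B"})
        out = collapse_to_symbols(mat)
        assert out.values.shape == (2, 1)

    def test_row_count_equals_distinct_mapped_symbols(self, rng):
        n_q = 60
        quals = [f"q{i}" for i in range(n_q)]
        symbols = {q: f"S{rng.integers(0, 20)}" for q in quals[:50]}  # 10 unmapped
        df = pd.DataFrame(rng.normal(7, 1, size=(n_q, 2)), index=quals,
                          columns=["s1", "s2"])
        mat = ExpressionMatrix(values=df,
                               sample_conditions={"s1": "vehicle", "s2": "drug_a"},
                               qualifier_to_symbol=symbols)
        out = collapse_to_symbols(mat)
        assert len(out.values) == len(set(symbols.values()))

    def test_empty_mapping_raises(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["q1"])
        mat = ExpressionMatrix(values=df, sample_conditions={"s1": "vehicle"},
                               qualifier_to_symbol={})
        with pytest.raises(ValueError):
            collapse_to_symbols(mat)


class TestFoldChanges:
    def test_two_log2_units_is_fourfold(self):
        mat = tiny_matrix([[5, 5, 7, 7, 5, 5, 5, 5]])
        fc = fold_changes(mat)
        assert fc["fc_a"].iloc[0] == pytest.approx(4.0)
        assert fc["fc_b"].iloc[0] == pytest.approx(1.0)

    def test_sample_order_invariance(self, rng):
        vals = rng.normal(7, 1, size=(5, 8))
        mat = tiny_matrix(vals)
        perm = rng.permutation(mat.values.columns)
        mat_perm = ExpressionMatrix(values=mat.values[perm],
                                    sample_conditions=mat.sample_conditions)
        pd.testing.assert_frame_equal(fold_changes(mat), fold_changes(mat_perm))

    def test_missing_condition_errors(self):
        df = pd.DataFrame({"V1": [1.0], "A1": [1.0]})
        mat = ExpressionMatrix(values=df, sample_conditions={
            "V1": "vehicle", "A1": "drug_a"})
        with pytest.raises(ValueError):
            fold_changes(mat)


class TestThresholdLists:
    def test_boundary_is_inclusive(self):
        fc = pd.DataFrame({"fc_a": [2.0, 1.9, 0.5]}, index=["g1", "g2", "g3"])
        lists = threshold_gene_lists(fc)
        assert lists["fc_a"]["up"] == {"g1"}
        assert lists["fc_a"]["down"] == {"g3"}

    def test_no_change_gives_empty_lists(self):
        fc = pd.DataFrame({"fc_a": [1.0, 1.0]}, index=["g1", "g2"])
        lists = threshold_gene_lists(fc)
        assert not lists["fc_a"]["up"] and not lists["fc_a"]["down"]

    def test_inverting_fold_changes_swaps_lists(self, rng):
        fc = pd.DataFrame({"fc_a": rng.lognormal(0, 1, 50)},
                          index=[f"g{i}" for i in range(50)])
        lists = threshold_gene_lists(fc)
        inverted = threshold_gene_lists(1.0 / fc)
        assert lists["fc_a"]["up"] == inverted["fc_a"]["down"]
        assert lists["fc_a"]["down"] == inverted["fc_a"]["up"]


class TestVenn:
    def test_worked_example(self):
        counts = venn_counts({"a", "b", "c"}, {"b", "c", "d"}, {"c", "e"})
        assert counts["c_only"] == 1     # exclusive to the third set: {e}
        assert counts["abc"] == 1        # {c}
        assert counts["union"] == 5

    def test_identical_sets_all_triple(self):
        counts = venn_counts({"x", "y"}, {"x", "y"}, {"x", "y"})
        assert counts["abc"] == 2
        assert sum(v for k, v in counts.items()
                   if k not in ("abc", "union")) == 0

    def test_regions_sum_to_union(self, rng):
        universe = np.arange(200)
        for _ in range(20):
            a, b, c = (set(rng.choice(universe, rng.integers(0, 80)))
                       for _ in range(3))
            counts = venn_counts(a, b, c)
            regions = sum(v for k, v in counts.items() if k != "union")
            assert regions == counts["union"] == len(a | b | c)


class TestCategories:
    @pytest.mark.parametrize("fa,fb,fab,expected", [
        (1.0, 1.0, 4.0, "A"),
        (1.0, 1.0, 0.25, "B"),
        (2.5, 1.0, 4.0, "C"),
        (0.4, 1.0, 0.2, "D"),
        (1.0, 2.5, 4.0, "E"),
        (1.0, 0.4, 0.2, "F"),
        (2.5, 2.5, 8.0, "G"),
        (0.4, 0.4, 0.1, "H"),
        (1.7, 1.0, 4.0, "none"),   # between band and change threshold
        (2.5, 1.0, 2.6, "none"),   # amplification below the 1.25x margin
        (1.0, 1.0, 1.0, "none"),
    ])
    def test_definitions(self, fa, fb, fab, expected):
        fc = pd.DataFrame({"fc_a": [fa], "fc_b": [fb], "fc_ab": [fab]},
                          index=["g"])
        assert classify_combination_categories(fc).iloc[0] == expected

    def test_partition_is_exclusive_and_order_invariant(self, rng):
        fc = pd.DataFrame({
            "fc_a": rng.lognormal(0, 1, 300),
            "fc_b": rng.lognormal(0, 1, 300),
            "fc_ab": rng.lognormal(0, 1.5, 300)},
            index=[f"g{i}" for i in range(300)])
        cats = classify_combination_categories(fc)
        shuffled = fc.sample(frac=1, random_state=3)
        cats_shuffled = classify_combination_categories(shuffled)
        pd.testing.assert_series_equal(cats.loc[shuffled.index], cats_shuffled)

    def test_invalid_filters_rejected(self):
        with pytest.raises(ValueError):
            CategoryFilterConfig(t_change=0.5)


class TestZScore:
    def test_worked_row(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z, flags = zscore_rows(df)
        assert z.loc["g"].tolist() == pytest.approx([-1.22474487, 0.0, 1.22474487])
        assert not flags["g"]

    def test_constant_row_zeroed_and_flagged(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g"], columns=list("abc"))
        z, flags = zscore_rows(df)
        assert (z.loc["g"] == 0).all() and flags["g"]

    def test_rows_standardised(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 6)))
        z, _ = zscore_rows(df)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.var(axis=1, ddof=0), 1, atol=1e-12)


class TestRanking:
    def test_difference_of_means(self):
        df = pd.DataFrame({"a1": [8.0], "a2": [8.0], "b1": [6.0], "b2": [6.0]},
                          index=["g"])
        ranked = rank_by_class_difference(df, ["a1", "a2"], ["b1", "b2"])
        assert ranked["g"] == pytest.approx(2.0)

    def test_antisymmetry(self, rng):
        df = pd.DataFrame(rng.normal(7, 1, size=(20, 4)),
                          index=[f"g{i:02d}" for i in range(20)],
                          columns=["a1", "a2", "b1", "b2"])
        fwd = rank_by_class_difference(df, ["a1", "a2"], ["b1", "b2"])
        rev = rank_by_class_difference(df, ["b1", "b2"], ["a1", "a2"])
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy()[::-1])

    def test_invariant_to_global_shift(self, rng):
        df = pd.DataFrame(rng.normal(7, 1, size=(20, 4)),
                          index=[f"g{i:02d}" for i in range(20)],
                          columns=["a1", "a2", "b1", "b2"])
        fwd = rank_by_class_difference(df, ["a1", "a2"], ["b1", "b2"])
        shifted = rank_by_class_difference(df + 5.0, ["a1", "a2"], ["b1", "b2"])
        assert list(fwd.index) == list(shifted.index)
        assert np.allclose(fwd.to_numpy(), shifted.to_numpy())


class TestEnrichmentScore:
    @staticmethod
    def ranked(scores, names=None):
        names = names or [f"g{i}" for i in range(len(scores))]
        return pd.Series(scores, index=names, dtype=float)

    def test_single_top_hit(self):
        es = enrichment_score(self.ranked([5, 4, 3, 2, 1]), {"g0"})
        assert es.es == pytest.approx(1.0)
        assert es.peak_index == 0

    def test_single_bottom_hit_frozen_from_oracle(self):
        """Set = bottom-ranked gene: the walk loses 1/4 per miss four times,
        reaching -1.0 just before the hit (value frozen from the brute-force
        oracle below)."""
        scores = np.array([5.0, 4, 3, 2, 1])
        hits = np.array([False, False, False, False, True])
        oracle = brute_force_es(scores, hits)
        assert oracle == pytest.approx(-1.0)
        es = enrichment_score(self.ranked(scores), {"g4"})
        assert es.es == pytest.approx(oracle)
        assert es.es < 0

    def test_matches_brute_force_walk_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 200))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, max(2, n // 3)))
            members = rng.choice(n, size=k, replace=False)
            hits = np.zeros(n, dtype=bool)
            hits[members] = True
            names = [f"g{i}" for i in range(n)]
            es = enrichment_score(pd.Series(scores, index=names),
                                  {names[i] for i in members})
            assert es.es == pytest.approx(brute_force_es(scores, hits), abs=1e-12)

    def test_degenerate_sets_rejected(self):
        r = self.ranked([3, 2, 1])
        with pytest.raises(ValueError):
            enrichment_score(r, {"absent"})
        with pytest.raises(ValueError):
            enrichment_score(r, {"g0", "g1", "g2"})


class TestGseaPermutation:
    def test_planted_top_set_significant(self, rng):
        n = 2000
        scores = pd.Series(np.sort(rng.normal(size=n))[::-1],
                           index=[f"g{i}" for i in range(n)])
        planted = GeneSet("planted", frozenset(scores.index[:40]))
        decoys = [GeneSet(f"d{i}", frozenset(rng.choice(scores.index, 40,
                                                        replace=False)))
                  for i in range(4)]
        res = gsea_permutation_test(scores, [planted] + decoys, n_perm=1000,
                                    seed=5)
        planted_res = res[0]
        assert planted_res.nes > 1.0
        assert planted_res.fdr < 0.05

    def test_reproducible_given_seed(self, rng):
        scores = pd.Series(np.sort(rng.normal(size=300))[::-1],
                           index=[f"g{i}" for i in range(300)])
        gs = [GeneSet("s", frozenset(rng.choice(scores.index, 20, replace=False)))]
        a = gsea_permutation_test(scores, gs, n_perm=200, seed=9)
        b = gsea_permutation_test(scores, gs, n_perm=200, seed=9)
        assert a[0] == b[0]

    def test_null_p_values_uniform(self):
        """Random gene sets on a random ranking give uniform nominal
        p-values (KS check)."""
        rng = np.random.default_rng(17)
        n = 800
        scores = pd.Series(np.sort(rng.normal(size=n))[::-1],
                           index=[f"g{i}" for i in range(n)])
        sets = [GeneSet(f"s{i}", frozenset(rng.choice(scores.index, 25,
                                                      replace=False)))
                for i in range(150)]
        res = gsea_permutation_test(scores, sets, n_perm=300, seed=23)
        ks = stats.kstest([r.p_nominal for r in res], "uniform").statistic
        assert ks < 0.12
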