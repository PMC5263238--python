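"""Differential-expression operators: frozen hand values and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainaging import diffexpr, synthetic
from brainaging.diffexpr import (
    BreadthThresholds,
    ProbeGroup,
    anova_aging,
    assign_age_group,
    assign_age_groups,
    breadth_table,
    classify_regional_breadth,
    fdr_adjust,
    fold_change,
    overrepresentation_test,
    run_de,
    select_top_genes,
    summarize_gene_level,
)


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age,expected",
        [(16, "young"), (44, "young"), (45, "middle"), (74, "middle"),
         (75, "old"), (102, "old"), (106, "old")],
    )
    def test_boundaries(self, age, expected):
        assert assign_age_group(age) == expected

    def test_below_sixteen_rejected(self):
        with pytest.raises(ValueError):
            assign_age_group(15)
        with pytest.raises(ValueError):
            assign_age_groups([30, 12])

    def test_vectorized_matches_scalar(self):
        ages = np.arange(16, 107)
        assert all(assign_age_groups(ages) == [assign_age_group(a) for a in ages])


class TestGeneLevelSummary:
    def _group(self, tid, rows):
        return ProbeGroup(tid, pd.DataFrame(rows, columns=["s1", "s2"]))

    def test_single_probe_set_is_identity(self):
        g = self._group("t1", [[1.0, 2.0]])
        out = summarize_gene_level([g])
        assert out.loc["t1"].tolist() == [1.0, 2.0]

    def test_odd_count_takes_middle_value(self):
        g = self._group("t1", [[1.0, 0.0], [5.0, 0.0], [100.0, 0.0]])
        assert summarize_gene_level([g]).loc["t1", "s1"] == 5.0

    def test_even_count_averages_middle_pair(self):
        g = self._group("t1", [[2.0, 0.0], [4.0, 0.0]])
        assert summarize_gene_level([g]).loc["t1", "s1"] == 3.0

    def test_empty_group_skipped(self):
        empty = ProbeGroup("t0", pd.DataFrame(columns=["s1", "s2"]))
        out = summarize_gene_level([empty, self._group("t1", [[1.0, 2.0]])])
        assert list(out.index) == ["t1"]


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        matrix = pd.DataFrame([[1, 2, 3, 1, 2, 3, 1, 2, 3]], index=["g"])
        labels = ["young"] * 3 + ["middle"] * 3 + ["old"] * 3
        res = anova_aging(matrix, labels)
        assert res.loc["g", "F"] == 0.0
        assert res.loc["g", "p"] == 1.0

    def test_perfect_separation_floors_p(self):
        matrix = pd.DataFrame([[0, 0, 0, 0, 3, 3]], index=["g"], dtype=float)
        labels = ["young", "young", "middle", "middle", "old", "old"]
        res = anova_aging(matrix, labels)
        assert np.isinf(res.loc["g", "F"])
        assert res.loc["g", "p"] == 0.0

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.standard_normal((40, 30)))
        labels = np.array(["young"] * 10 + ["middle"] * 10 + ["old"] * 10)
        res = anova_aging(matrix, labels)
        blocks = [matrix.to_numpy()[:, labels == g] for g in ("young", "middle", "old")]
        F_ref, p_ref = stats.f_oneway(*blocks, axis=1)
        np.testing.assert_allclose(res["F"], F_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)

    def test_small_group_dropped_then_untestable(self):
        matrix = pd.DataFrame(np.arange(8.0).reshape(1, 8))
        # only one usable group after dropping singletons -> NaN
        res = anova_aging(matrix, ["young"] * 6 + ["middle", "old"])
        assert np.isnan(res.iloc[0]["F"])


class TestFdr:
    def test_all_ones(self):
        np.testing.assert_array_equal(fdr_adjust([1, 1, 1]), [1, 1, 1])

    def test_hand_computed_step_up(self):
        # q_i = min_{j>=i} p_(j) * m / j  -> all 0.04 for this ladder
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert fdr_adjust([0.005])[0] == pytest.approx(0.005)

    def test_nan_propagates_without_joining_family(self):
        q = fdr_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        # family size m = 2 for the remaining values
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.02])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFoldChange:
    def test_directions(self):
        matrix = pd.DataFrame(
            [[1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]],
            index=["up_gene", "down_gene", "flat"],
        )
        labels = ["young", "young", "old", "old"]
        fc = fold_change(matrix, labels)
        assert fc.loc["up_gene", "delta_log2"] == 1.0
        assert fc.loc["up_gene", "direction"] == "up"
        assert fc.loc["down_gene", "delta_log2"] == -2.0
        assert fc.loc["down_gene", "direction"] == "down"
        assert fc.loc["flat", "direction"] == "none"

    def test_empty_group_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValueError):
            fold_change(matrix, ["young", "young"])


class TestBreadth:
    @pytest.mark.parametrize(
        "n,expected",
        [(0, "unclassified"), (1, "region_specific"), (2, "region_selective"),
         (7, "region_selective"), (8, "multi_regional"), (9, "multi_regional"),
         (10, "cross_regional")],
    )
    def test_categories(self, n, expected):
        out = classify_regional_breadth({"g": n})
        assert out["g"] == expected

    def test_categories_partition_significant_genes(self):
        rng = np.random.default_rng(2)
        counts = {f"g{i}": int(rng.integers(0, 11)) for i in range(300)}
        cats = classify_regional_breadth(counts)
        n_sig = sum(1 for v in counts.values() if v > 0)
        assert (cats != "unclassified").sum() == n_sig
        assert set(cats.unique()) <= set(diffexpr.BREADTH_CATEGORIES) | {"unclassified"}

    def test_non_ten_regions_requires_explicit_thresholds(self):
        with pytest.raises(ValueError):
            classify_regional_breadth({"g": 3}, n_regions_total=4)
        out = classify_regional_breadth(
            {"g": 4}, n_regions_total=4,
            thresholds=BreadthThresholds(selective_min=2, multi_regional_min=3,
                                         n_regions_total=4),
        )
        assert out["g"] == "cross_regional"

    def test_invariant_to_region_ordering(self, small_study):
        table = run_de(small_study.expression, small_study.metadata)
        regions = list(table["region"].unique())
        shuffled = table.iloc[::-1].reset_index(drop=True)
        thresholds = BreadthThresholds(multi_regional_min=4, n_regions_total=len(regions))
        a = breadth_table(table, len(regions), thresholds)
        b = breadth_table(shuffled, len(regions), thresholds)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestTopGenes:
    def _table(self):
        return pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "region": "FCTX",
                "p": [0.001, 0.002, 0.002, 0.5],
                "q": [0.01, 0.01, 0.01, 0.6],
            }
        )

    def test_k1_is_argmin_q_with_tiebreaks(self):
        assert select_top_genes(self._table(), "FCTX", 1) == ["a"]

    def test_ties_broken_by_p_then_gene_id(self):
        assert select_top_genes(self._table(), "FCTX", 3) == ["a", "b", "c"]

    def test_k_beyond_table_returns_all(self):
        assert select_top_genes(self._table(), "FCTX", 10) == ["a", "b", "c", "d"]


class TestOverrepresentation:
    def test_category_equals_universe(self):
        universe = [f"g{i}" for i in range(30)]
        assert overrepresentation_test(universe[:5], universe, universe) == pytest.approx(1.0)

    def test_full_overlap_exact_value(self):
        # overlap 10 of 10 drawn from 20 with 10 special: p = 1 / C(20, 10)
        universe = [f"g{i}" for i in range(20)]
        p = overrepresentation_test(universe[:10], universe[:10], universe)
        assert p == pytest.approx(1 / 184756, rel=1e-9)

    def test_matches_brute_force_enumeration(self):
        # exact tail by enumerating all draws of size n from a 12-gene universe
        from itertools import combinations

        universe = [f"g{i}" for i in range(12)]
        category = set(universe[:5])
        gene_set = set(universe[3:9])
        observed = len(gene_set & category)
        total = hits = 0
        for draw in combinations(universe, len(gene_set)):
            total += 1
            hits += len(set(draw) & category) >= observed
        p = overrepresentation_test(gene_set, category, universe)
        assert p == pytest.approx(hits / total, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test([], [], [])


class TestRunDe:
    def test_planted_genes_detected_and_classified(self, small_study):
        table = run_de(small_study.expression, small_study.metadata)
        n_regions = table["region"].nunique()
        thresholds = BreadthThresholds(multi_regional_min=4, n_regions_total=n_regions)
        breadth = breadth_table(table, n_regions, thresholds)
        assert breadth.loc["g00000", "breadth"] == "cross_regional"
        assert breadth.loc["g00001", "breadth"] == "region_specific"
        down = table[(table.gene_id == "g00001") & (table.region == "FCTX")]
        assert down["direction"].iloc[0] == "down"

    def test_recovery_of_strong_planted_genes_by_rank(self):
        regions = ("FCTX",)
        effects = tuple(
            synthetic.PlantedEffect(f"g{i:05d}", regions, "up", 2.0) for i in range(30)
        )
        cfg = synthetic.ExpressionStudyConfig(
            n_individuals=60, regions=regions, n_genes=500,
            planted_effects=effects, missing_region_rate=0.0, seed=3,
        )
        study = synthetic.generate_expression_study(cfg)
        table = run_de(study.expression, study.metadata)
        top = set(select_top_genes(table, "FCTX", 30))
        planted = {e.gene_id for e in effects}
        assert len(top & planted) >= 28
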