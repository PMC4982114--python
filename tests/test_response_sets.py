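"""Tests for cross-model gene-set algebra and panel cross-tabulation."""

import numpy as np
import pytest

from regnetcompare.data_model import GenePanel
from regnetcompare.response_sets import (
    SpecificGeneRule,
    basal_differential,
    common_response_genes,
    panel_crosstab,
    response_enrichment_fold,
    response_similarity,
    specific_response_genes,
)

from conftest import make_table

SIG = 1e-4     # comfortably below the p < 0.001 cutoff
NS = 0.5       # not significant


def l2(fc):
    """log2 of a signed linear fold change."""
    return np.log2(fc) if fc > 0 else -np.log2(-fc)


class TestSpecificResponseGenes:
    def test_opposite_direction_specific_to_both(self):
        a = make_table("A", [("g", l2(3.0), SIG)])
        b = make_table("B", [("g", l2(-2.5), SIG)])
        res_a = specific_response_genes(a, b, direction="up")
        res_b = specific_response_genes(b, a, direction="down")
        assert res_a.genes == {"g"} and res_a.opposite_direction == {"g"}
        assert res_b.genes == {"g"}

    def test_ratio_inside_band_removed(self):
        a = make_table("A", [("g", l2(4.0), SIG)])
        b = make_table("B", [("g", l2(3.0), NS)])   # ratio 1.33 within [0.5, 2]
        res = specific_response_genes(a, b, direction="up")
        assert res.genes == set() and res.ratio_removed == {"g"}

    def test_ratio_outside_band_retained(self):
        a = make_table("A", [("g", l2(5.0), SIG)])
        b = make_table("B", [("g", l2(2.0), NS)])   # ratio 2.5 > 2
        res = specific_response_genes(a, b, direction="up")
        assert res.genes == {"g"} and res.ratio_retained == {"g"}

    def test_ratio_band_boundary_inclusive(self):
        a = make_table("A", [("g", l2(4.0), SIG)])
        b = make_table("B", [("g", l2(2.0), NS)])   # ratio exactly 2: removed
        assert specific_response_genes(a, b, direction="up").genes == set()

    def test_absent_from_b_is_specific(self):
        a = make_table("A", [("g", l2(3.0), SIG)])
        b = make_table("B", [("other", 0.0, NS)])
        res = specific_response_genes(a, b, direction="up")
        assert res.genes == {"g"} and res.absent_in_b == {"g"}

    def test_opposite_sign_fc_always_retained(self):
        a = make_table("A", [("g", l2(3.0), SIG)])
        b = make_table("B", [("g", l2(-1.2), NS)])
        res = specific_response_genes(a, b, direction="up")
        assert res.genes == {"g"}

    def test_significant_same_direction_in_b_not_specific(self):
        a = make_table("A", [("g", l2(8.0), SIG)])
        b = make_table("B", [("g", l2(2.5), SIG)])
        assert specific_response_genes(a, b, direction="up").genes == set()

    def test_bad_direction_rejected(self):
        t = make_table("A", [("g", 1.0, NS)])
        with pytest.raises(ValueError):
            specific_response_genes(t, t, direction="sideways")

    def test_mutual_specific_intersection_is_exactly_opposite_direction(self):
        rows_a = [("opp", l2(3.0), SIG), ("a_only", l2(5.0), SIG),
                  ("shared", l2(4.0), SIG), ("weak", l2(1.2), NS)]
        rows_b = [("opp", l2(-2.5), SIG), ("a_only", l2(1.1), NS),
                  ("shared", l2(3.5), SIG), ("weak", l2(1.1), NS)]
        a, b = make_table("A", rows_a), make_table("B", rows_b)
        res_ab = specific_response_genes(a, b, direction="up")
        res_ba_up = specific_response_genes(b, a, direction="up")
        res_ba_down = specific_response_genes(b, a, direction="down")
        mutual = res_ab.genes & (res_ba_up.genes | res_ba_down.genes)
        assert mutual == res_ab.opposite_direction == {"opp"}

    def test_relaxed_ratio_grows_or_preserves_specific_set(self):
        rng = np.random.default_rng(5)
        rows_a, rows_b = [], []
        for i in range(200):
            rows_a.append((f"g{i}", float(rng.normal(0, 2)), float(rng.uniform(0, 0.01))))
            rows_b.append((f"g{i}", float(rng.normal(0, 2)), float(rng.uniform(0, 1))))
        a, b = make_table("A", rows_a), make_table("B", rows_b)
        strict = specific_response_genes(a, b, SpecificGeneRule(ratio_min=2.0), "up")
        relaxed = specific_response_genes(a, b, SpecificGeneRule(ratio_min=1.33), "up")
        assert strict.genes <= relaxed.genes
        assert relaxed.ratio_removed <= strict.ratio_removed


class TestCommonResponseGenes:
    def test_same_direction_included_opposite_excluded(self):
        a = make_table("A", [("up_both", l2(3), SIG), ("flip", l2(3), SIG),
                             ("a_only", l2(3), SIG)])
        b = make_table("B", [("up_both", l2(2.5), SIG), ("flip", l2(-3), SIG),
                             ("a_only", l2(1.1), NS)])
        assert common_response_genes(a, b) == {"up_both"}

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        rows = lambda: [(f"g{i}", float(rng.normal(0, 2)),
                         float(rng.uniform(0, 0.01))) for i in range(100)]
        a, b = make_table("A", rows()), make_table("B", rows())
        assert common_response_genes(a, b) == common_response_genes(b, a)


class TestBasalDifferential:
    def test_intersection_over_comparators(self):
        c1 = make_table("RvsU1", [("hi", l2(3), SIG), ("partial", l2(3), SIG),
                                  ("lo", l2(-3), SIG)])
        c2 = make_table("RvsU2", [("hi", l2(4), SIG), ("partial", l2(1.1), NS),
                                  ("lo", l2(-2.5), SIG)])
        higher, lower = basal_differential([c1, c2])
        assert higher == {"hi"} and lower == {"lo"}

    def test_higher_lower_disjoint(self):
        rng = np.random.default_rng(2)
        tables = [make_table(f"c{j}", [(f"g{i}", float(rng.normal(0, 2)),
                                        float(rng.uniform(0, 0.01)))
                                       for i in range(100)]) for j in range(2)]
        higher, lower = basal_differential(tables)
        assert higher.isdisjoint(lower)

    def test_zero_comparators_rejected(self):
        with pytest.raises(ValueError):
            basal_differential([])


class TestResponseEnrichmentFold:
    def test_published_style_fractions(self):
        # 44 % responsive within the subset vs 12.6 % globally -> ~3.49-fold
        universe = {f"g{i}" for i in range(1000)}
        responsive = {f"g{i}" for i in range(126)}
        subset = {f"g{i}" for i in range(44)} | {f"g{i}" for i in range(900, 956)}
        res = response_enrichment_fold(subset, responsive, universe)
        assert res.subset_fraction == pytest.approx(0.44)
        assert res.global_fraction == pytest.approx(0.126)
        assert res.fold == pytest.approx(3.4921, abs=1e-3)
        assert res.p_value < 1e-6

    def test_subset_equals_universe_fold_one(self):
        universe = {f"g{i}" for i in range(50)}
        responsive = {f"g{i}" for i in range(10)}
        assert response_enrichment_fold(universe, responsive, universe).fold == 1.0

    def test_disjoint_subset_fold_zero(self):
        universe = {f"g{i}" for i in range(50)}
        res = response_enrichment_fold({"g40"}, {"g1", "g2"}, universe)
        assert res.fold == 0.0

    def test_empty_subset_flagged(self):
        universe = {"a", "b"}
        with pytest.warns(UserWarning, match="empty subset"):
            res = response_enrichment_fold(set(), {"a"}, universe)
        assert res.fold is None

    def test_random_subsets_average_fold_near_one(self):
        rng = np.random.default_rng(17)
        universe = [f"g{i}" for i in range(500)]
        responsive = set(universe[:100])
        folds = []
        for _ in range(1000):
            subset = set(rng.choice(universe, size=50, replace=False))
            folds.append(response_enrichment_fold(subset, responsive,
                                                  set(universe)).fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)


class TestPanelCrosstab:
    def test_counts_by_direction_and_measurement(self):
        panel = GenePanel("negreg", frozenset({"Cr2", "Up1", "Missing"}))
        t = make_table("M1", [("Cr2", l2(-2.1), SIG), ("Up1", l2(3.0), SIG),
                              ("other", l2(5.0), SIG)])
        ct = panel_crosstab(panel, [t])
        assert ct.per_contrast["M1"]["down"] == {"Cr2"}
        assert ct.per_contrast["M1"]["up"] == {"Up1"}
        assert ct.per_contrast["M1"]["not_measured"] == {"Missing"}
        assert ct.counts()["M1"]["down"] == 1

    def test_basal_buckets(self):
        panel = GenePanel("negreg", frozenset({"hi", "lo"}))
        basal = make_table("RvsU", [("hi", l2(3), SIG), ("lo", l2(-3), SIG)])
        ct = panel_crosstab(panel, [], [basal])
        assert ct.per_basal["RvsU"]["higher"] == {"hi"}
        assert ct.per_basal["RvsU"]["lower"] == {"lo"}

    def test_disjoint_panel_warns(self):
        panel = GenePanel("negreg", frozenset({"absent"}))
        t = make_table("M1", [("g", l2(3.0), SIG)])
        with pytest.warns(UserWarning, match="shares no genes"):
            ct = panel_crosstab(panel, [t])
        assert ct.per_contrast["M1"]["up"] == set()


class TestResponseSimilarity:
    def test_identical_tables_full_similarity(self):
        t = make_table("A", [("g1", l2(3), SIG), ("g2", l2(-3), SIG)])
        u = make_table("B", [("g1", l2(3), SIG), ("g2", l2(-3), SIG)])
        sim = response_similarity(t, u)
        assert sim["jaccard"] == 1.0 and sim["overlap_coefficient"] == 1.0

    def test_disjoint_responses_zero(self):
        a = make_table("A", [("g1", l2(3), SIG), ("g2", 0.0, NS)])
        b = make_table("B", [("g1", 0.0, NS), ("g2", l2(3), SIG)])
        sim = response_similarity(a, b)
        assert sim["jaccard"] == 0.0
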