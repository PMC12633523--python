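"""Clone calling, hierarchy, penetrance, CAR enrichment, CD4:CD8 skew."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonotrace import (
    assign_clones,
    car_ch_enrichment,
    car_population_summary,
    cd4_cd8_skew,
    gene_penetrance_rollup,
    infer_hierarchy,
    lineage_penetrance,
)
from clonotrace.single_cell import Clone
from tests.conftest import make_sc_matrix


def brute_force_partition(matrix, amplicons):
    """Oracle: group complete cells by exact mutant-set, no size filtering."""
    groups = {}
    for _, row in matrix.iterrows():
        key = frozenset(a for a in amplicons if row[a] in (1.0, 2.0))
        groups.setdefault(key, set()).add(row["cell_id"])
    return groups


class TestAssignClones:
    def test_all_wildtype_single_group(self):
        clones, unassigned = assign_clones(make_sc_matrix([set()] * 5))
        assert len(clones) == 1 and clones[0].is_wildtype
        assert clones[0].n_cells == 5 and unassigned.empty

    def test_three_patterns_three_clones(self):
        patterns = [{"A"}] * 3 + [{"B"}] * 2 + [{"A", "B"}] * 2
        clones, _ = assign_clones(make_sc_matrix(patterns))
        sets = {c.variant_set for c in clones}
        assert sets == {frozenset({"A"}), frozenset({"B"}),
                        frozenset({"A", "B"})}

    def test_min_cells_folds_singletons(self):
        patterns = [{"A"}] * 3 + [{"B"}]
        clones, unassigned = assign_clones(make_sc_matrix(patterns), min_cells=2)
        assert {c.variant_set for c in clones} == {frozenset({"A"})}
        assert list(unassigned["reason"]) == ["group_below_min_cells"]

    def test_matches_brute_force_oracle_on_random_matrix(self, rng):
        amps = [f"G{i}" for i in range(6)]
        n = 300
        geno = rng.choice([0.0, 1.0, 2.0], size=(n, len(amps)),
                          p=[0.85, 0.12, 0.03])
        patterns = [{a for j, a in enumerate(amps) if geno[i, j] > 0}
                    for i in range(n)]
        m = make_sc_matrix(patterns, amplicons=amps)
        clones, unassigned = assign_clones(m, min_cells=1)
        assert unassigned.empty
        called = {c.variant_set: set(c.cell_ids) for c in clones}
        oracle = brute_force_partition(m, amps)
        assert called == oracle

    def test_na_cell_rescued_when_unambiguous(self):
        patterns = [{"A"}] * 3 + [{"B", "C"}] * 3 + [
            {"A": 1.0, "B": np.nan, "C": 0.0}]   # consistent only with {A}
        clones, unassigned = assign_clones(make_sc_matrix(patterns))
        a_clone = next(c for c in clones if c.variant_set == frozenset({"A"}))
        assert a_clone.n_cells == 4 and unassigned.empty

    def test_ambiguous_na_cell_unassigned(self):
        # observed: mutant at A only; consistent with {A} and {A, B}
        patterns = [{"A"}] * 3 + [{"A", "B"}] * 3 + [
            {"A": 1.0, "B": np.nan, "C": 0.0}]
        clones, unassigned = assign_clones(make_sc_matrix(patterns))
        assert list(unassigned["reason"]) == ["ambiguous"]
        assert sum(c.n_cells for c in clones) == 6

    def test_all_na_cell_unassigned(self):
        patterns = [{"A"}] * 2 + [
            {"A": np.nan, "B": np.nan, "C": np.nan}]
        _, unassigned = assign_clones(make_sc_matrix(patterns))
        assert list(unassigned["reason"]) == ["all_missing"]

    def test_cell_conservation(self):
        patterns = [{"A"}] * 4 + [set()] * 5 + [{"B"}] + [
            {"A": np.nan, "B": np.nan, "C": np.nan}]
        clones, unassigned = assign_clones(make_sc_matrix(patterns))
        assert sum(c.n_cells for c in clones) + len(unassigned) == len(patterns)

    def test_hom_fraction_recorded(self):
        patterns = [{"A": 2.0}] * 2 + [{"A": 1.0}] * 2
        clones, _ = assign_clones(make_sc_matrix(patterns, amplicons=("A",)))
        clone = next(c for c in clones if not c.is_wildtype)
        assert clone.hom_fraction["A"] == pytest.approx(0.5)


def _clone(cid, variants, n=10, lineages=None, car=0):
    lineages = lineages or {"monocyte": n}
    return Clone(clone_id=cid, variant_set=frozenset(variants), n_cells=n,
                 cell_ids=[f"{cid}_{i}" for i in range(n)],
                 lineage_counts=lineages, car_pos_cells=car)


class TestHierarchy:
    def test_single_subset_edge(self):
        edges = infer_hierarchy([_clone("c1", {"A"}), _clone("c2", {"A", "B"})])
        assert len(edges) == 1
        assert edges[0].gained_variants == frozenset({"B"})

    def test_age_then_ddr_pattern(self):
        edges = infer_hierarchy([
            _clone("c1", {"DNMT3A_R882H"}),
            _clone("c2", {"DNMT3A_R882H", "PPM1D_T483fs"})])
        assert edges[0].pattern == "age_then_ddr"

    def test_sequential_tp53_pattern(self):
        edges = infer_hierarchy([
            _clone("c1", {"TP53_C176R"}),
            _clone("c2", {"TP53_C176R", "TP53_Y236N"})])
        assert edges[0].pattern == "tp53_sequential"

    def test_transitive_reduction(self):
        clones = [_clone("c1", {"A"}), _clone("c2", {"A", "B"}),
                  _clone("c3", {"A", "B", "C"})]
        edges = infer_hierarchy(clones)
        pairs = {(e.parent_clone, e.child_clone) for e in edges}
        assert pairs == {("c1", "c2"), ("c2", "c3")}  # no c1 -> c3 shortcut

    def test_independent_clones_no_edges(self):
        assert infer_hierarchy([_clone("c1", {"A"}), _clone("c2", {"B"})]) == []

    def test_dag_on_random_clone_sets(self, rng):
        import networkx as nx

        universe = list("ABCDEF")
        for trial in range(20):
            k = rng.integers(2, 8)
            sets = {frozenset(rng.choice(universe,
                                         size=rng.integers(1, 5),
                                         replace=False))
                    for _ in range(k)}
            clones = [_clone(f"c{i}", s) for i, s in enumerate(sets)]
            edges = infer_hierarchy(clones)
            g = nx.DiGraph([(e.parent_clone, e.child_clone) for e in edges])
            assert nx.is_directed_acyclic_graph(g)


class TestLineagePenetrance:
    def test_pure_myeloid_clone(self):
        pen = lineage_penetrance(_clone("c1", {"A"}, lineages={"monocyte": 10}))
        assert pen["myeloid_fraction"] == 1.0 and pen["plurality"] == "myeloid"

    def test_mixed_clone_fractions_and_plurality(self):
        pen = lineage_penetrance(_clone(
            "c1", {"A"}, n=100,
            lineages={"monocyte": 40, "other_myeloid": 20, "T_CD4": 25, "NK": 15}))
        assert pen["lymphoid_fraction"] == pytest.approx(0.4)
        assert pen["plurality"] == "myeloid"

    def test_gene_rollup_counts_lymphoid_plurality(self):
        clones = [
            _clone("c1", {"DNMT3A_a"}, lineages={"T_CD4": 8, "monocyte": 2}),
            _clone("c2", {"DNMT3A_b"}, lineages={"monocyte": 9, "B": 1}),
            _clone("c3", {"TP53_a"}, lineages={"monocyte": 10}),
        ]
        out = gene_penetrance_rollup(clones).set_index("gene")
        assert out.loc["DNMT3A", "n_clones"] == 2
        assert out.loc["DNMT3A", "n_lymphoid_plurality"] == 1
        assert out.loc["TP53", "n_lymphoid_plurality"] == 0

    def test_lineage_counts_conservation(self, rng):
        """Sum of clone lineage counts equals assigned-cell lineage totals."""
        lineages = rng.choice(["T_CD4", "T_CD8", "monocyte", "NK"], size=60)
        patterns = [{"A"}] * 20 + [{"B"}] * 20 + [set()] * 20
        m = make_sc_matrix(patterns, lineages=list(lineages))
        clones, unassigned = assign_clones(m)
        totals: dict = {}
        for c in clones:
            for k, v in c.lineage_counts.items():
                totals[k] = totals.get(k, 0) + v
        assigned = m[~m["cell_id"].isin(unassigned["cell_id"])]
        assert totals == assigned["lineage"].value_counts().to_dict()


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    return sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9))


class TestCarEnrichment:
    def _matrix(self, a, b, c, d):
        """T-cell matrix: a CAR+clone+, b CAR+clone-, c CAR-clone+, d CAR-clone-."""
        patterns = ([{"A"}] * (a + c)) + ([set()] * (b + d))
        car = [True] * a + [False] * c + [True] * b + [False] * d
        m = make_sc_matrix(patterns, lineages=["T_CD4"] * (a + b + c + d),
                           car=car, amplicons=("A",))
        clones, _ = assign_clones(m, min_cells=1)
        clone = next(cl for cl in clones if not cl.is_wildtype)
        return m, clone

    def test_worked_2x2_against_independence_formula(self):
        a, b, c, d = 10, 10, 100, 1880
        m, clone = self._matrix(a, b, c, d)
        res = car_ch_enrichment(m, clone)
        n_t = a + b + c + d
        expected = n_t * ((a + b) / n_t) * ((a + c) / n_t)
        assert res["observed"] == a
        assert res["expected"] == pytest.approx(expected)
        assert res["ratio"] == pytest.approx(a / expected)
        assert res["fisher_p"] == pytest.approx(fisher_oracle(a, b, c, d),
                                                rel=1e-6)

    def test_clone_absent_from_car_cells(self):
        m, clone = self._matrix(0, 20, 100, 1880)
        assert car_ch_enrichment(m, clone)["ratio"] == 0.0

    def test_no_car_t_cells_skipped(self):
        m, clone = self._matrix(0, 0, 100, 1900)
        assert car_ch_enrichment(m, clone)["skipped"]

    def test_singleton_exclusion_mode(self):
        m, clone = self._matrix(1, 19, 100, 1880)
        assert car_ch_enrichment(m, clone)["observed"] == 1
        assert car_ch_enrichment(m, clone,
                                 include_singletons=False)["observed"] == 0

    def test_non_t_cells_excluded_from_denominator(self):
        m, clone = self._matrix(10, 10, 100, 1880)
        extra = make_sc_matrix([set()] * 500,
                               lineages=["monocyte"] * 500, amplicons=("A",))
        extra["cell_id"] = [f"m{i}" for i in range(500)]
        res_with = car_ch_enrichment(pd.concat([m, extra]), clone)
        res_without = car_ch_enrichment(m, clone)
        assert res_with["n_t_cells"] == res_without["n_t_cells"] == 2000
        assert res_with["ratio"] == pytest.approx(res_without["ratio"])


class TestCd4Cd8Skew:
    def _matrix(self, cd4_pos, cd8_pos, cd4_neg, cd8_neg):
        patterns = ([{"A"}] * (cd4_pos + cd8_pos)) + ([set()] * (cd4_neg + cd8_neg))
        lineages = (["T_CD4"] * cd4_pos + ["T_CD8"] * cd8_pos
                    + ["T_CD4"] * cd4_neg + ["T_CD8"] * cd8_neg)
        return make_sc_matrix(patterns, lineages=lineages, amplicons=("A",))

    def test_balanced_strata_or_one(self):
        out = cd4_cd8_skew(self._matrix(10, 10, 50, 50), stratify_by="CH")
        assert out["odds_ratio"] == pytest.approx(1.0)

    def test_worked_2x2_arithmetic(self):
        out = cd4_cd8_skew(self._matrix(20, 30, 200, 500), stratify_by="CH")
        assert out["ratio_pos"] == pytest.approx(20 / 30)
        assert out["ratio_neg"] == pytest.approx(0.4)
        assert out["odds_ratio"] == pytest.approx((20 * 500) / (30 * 200))

    def test_empty_stratum_undefined(self):
        out = cd4_cd8_skew(self._matrix(0, 0, 200, 500), stratify_by="CH")
        assert math.isnan(out["ratio_pos"])

    def test_mantel_haenszel_matches_pooled_for_one_stratum(self):
        m = self._matrix(20, 30, 200, 500)
        m["patient"] = "P0"
        out = cd4_cd8_skew(m, stratify_by="CH", patient_col="patient")
        assert out["odds_ratio_mh"] == pytest.approx(out["odds_ratio"])


class TestCarPopulationSummary:
    def test_product_like_matrix_all_car(self):
        m = make_sc_matrix([set()] * 10, lineages=["T_CD4"] * 10,
                           car=[True] * 10)
        out = car_population_summary({"product": m})
        assert out["car_fraction"].iloc[0] == 1.0
        assert out["car_t_fraction"].iloc[0] == 1.0

    def test_cd4_share_of_car_t(self):
        lineages = ["T_CD4"] * 61 + ["T_CD8"] * 2 + ["monocyte"] * 37
        car = [True] * 63 + [False] * 37
        m = make_sc_matrix([set()] * 100, lineages=lineages, car=car)
        out = car_population_summary({"s": m})
        assert out["car_cd4_fraction"].iloc[0] == pytest.approx(61 / 63)

    def test_no_car_cells_zero_markers(self):
        m = make_sc_matrix([set()] * 10)
        out = car_population_summary({"s": m})
        assert out["n_car"].iloc[0] == 0
        assert out["car_t_fraction"].iloc[0] == 0.0
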