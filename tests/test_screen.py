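import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from rhizoscreen.errors import ConfigurationError, DataError
from rhizoscreen.homology import ScoringParams, build_bitscore_matrix
from rhizoscreen.proteome import GroupAssignment
from rhizoscreen.screen import (anova_oneway, bh_fdr, detect_islands,
                                select_conserved)

SETTINGS = dict(derandomize=True, max_examples=40, deadline=None)


class TestAnova:
    def test_worked_three_group_example_is_exact(self):
        res = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.F == pytest.approx(3.0, abs=1e-12)
        # closed form for d1=2: p = (1 + F*d1/d2)^(-d2/2) = 2^-3
        assert res.p == pytest.approx(0.125, abs=1e-12)

    def test_identical_values_give_null_result(self):
        res = anova_oneway([[2, 2], [2, 2], [2, 2]])
        assert (res.F, res.p, res.degenerate) == (0.0, 1.0, True)

    def test_perfect_separation_flags_degenerate_zero_p(self):
        res = anova_oneway([[1, 1], [5, 5]])
        assert res.p == 0.0 and res.degenerate and math.isinf(res.F)

    def test_group_of_one_rejected(self):
        with pytest.raises(ConfigurationError):
            anova_oneway([[1], [2, 3]])

    @given(st.permutations([1.0, 4.0, 2.5]), st.permutations([3.0, 3.5, 9.0]))
    @settings(**SETTINGS)
    def test_permuting_within_groups_leaves_statistic_unchanged(self, g1, g2):
        base = anova_oneway([[1.0, 4.0, 2.5], [3.0, 3.5, 9.0]])
        perm = anova_oneway([list(g1), list(g2)])
        assert perm.F == pytest.approx(base.F)
        assert perm.p == pytest.approx(base.p)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            groups = [rng.normal(rng.uniform(0, 3), 1.0, rng.integers(2, 9))
                      for _ in range(rng.integers(2, 5))]
            ours = anova_oneway(groups)
            ref_f, ref_p = stats.f_oneway(*groups)
            assert ours.F == pytest.approx(ref_f, rel=1e-10)
            assert ours.p == pytest.approx(ref_p, rel=1e-8, abs=1e-12)

    @pytest.mark.parametrize("f,d1,d2", [(3.0, 2, 6), (1.7, 4, 40), (0.3, 2, 12), (9.9, 3, 21)])
    def test_tail_matches_numerical_integration(self, f, d1, d2):
        tail, _ = integrate.quad(lambda x: stats.f.pdf(x, d1, d2), f, np.inf)
        assert anova_oneway.__globals__["stats"].f.sf(f, d1, d2) == pytest.approx(tail, abs=1e-8)


class TestBhFdr:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.25], [0.25]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_hand_computed_step_up_values(self, pvals, expected):
        assert bh_fdr(pvals) == pytest.approx(expected)

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(**SETTINGS)
    def test_qvalues_dominate_pvalues_and_preserve_order(self, pvals):
        q = bh_fdr(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert bh_fdr(p) == pytest.approx(ref, rel=1e-12)


def _assignment(n=(2, 2, 2)):
    mapping = {"focal": "FOCAL"}
    for lbl, k in zip(("ACiM", "nonACiM", "nonACiR"), n):
        for i in range(k):
            mapping[f"{lbl}-{i + 1:02d}"] = lbl
    return GroupAssignment(mapping)


def _matrix(rows: dict, groups: GroupAssignment) -> pd.DataFrame:
    cols = sorted(groups.non_focal)
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


class TestSelectConserved:
    def test_flat_row_not_selected(self):
        groups = _assignment()
        mat = _matrix({"g1": [50.0] * 6}, groups)
        rec = select_conserved(mat, groups).set_index("gene")
        assert not rec.at["g1", "selected"]
        assert rec.at["g1", "F"] == 0.0

    def test_strong_acim_contrast_selected(self):
        groups = _assignment((6, 8, 6))
        row = [300, 310, 305, 308, 302, 306] + [40, 35, 42, 38, 41, 37, 39, 36] + [44, 38, 40, 42, 39, 41]
        cols = (groups.strains("ACiM") + groups.strains("nonACiM")
                + groups.strains("nonACiR"))
        mat = pd.DataFrame([row], index=["g1"], columns=cols)
        rec = select_conserved(mat, groups).set_index("gene")
        assert rec.at["g1", "q"] < 0.001
        assert rec.at["g1", "selected"]

    def test_directional_contrast_required(self):
        groups = _assignment()
        # strongly significant, but nonACiR highest -> never selected
        mat = _matrix({"g1": [50.0, 52.0, 50.0, 51.0, 300.0, 305.0]}, groups)
        rec = select_conserved(mat, groups).set_index("gene")
        assert rec.at["g1", "p"] < 0.001
        assert not rec.at["g1", "selected"]

    def test_all_zero_row_excluded_from_testing(self):
        groups = _assignment()
        mat = _matrix({"g1": [0.0] * 6, "g2": [90, 95, 20, 22, 21, 19]}, groups)
        rec = select_conserved(mat, groups).set_index("gene")
        assert not rec.at["g1", "tested"]
        assert math.isnan(rec.at["g1", "p"]) and math.isnan(rec.at["g1", "q"])
        assert rec.at["g2", "tested"]

    def test_fdr_adjusts_over_tested_rows_only(self):
        groups = _assignment()
        rows = {"dead": [0.0] * 6}
        rng = np.random.default_rng(0)
        for i in range(9):
            rows[f"g{i}"] = list(rng.uniform(50, 60, 6))
        rec = select_conserved(_matrix(rows, groups), groups).set_index("gene")
        tested = rec[rec["tested"]]
        assert bh_fdr(tested["p"].to_numpy()) == pytest.approx(tested["q"].to_numpy())

    def test_missing_group_strain_rejected(self):
        groups = _assignment()
        mat = _matrix({"g1": [1.0] * 6}, groups).drop(columns=["nonACiR-02"])
        with pytest.raises((ConfigurationError, DataError)):
            select_conserved(mat, groups)


def _order(indices, scaffold="s1"):
    return pd.DataFrame(
        {
            "strain": "focal",
            "scaffold": scaffold,
            "index": list(indices),
            "gene_id": [f"g{i}" for i in indices],
        }
    )


class TestDetectIslands:
    def test_worked_gap_rule_example(self):
        order = _order(range(12))
        islands = detect_islands({"g3", "g4", "g5", "g9"}, order, max_gap=1, min_size=2)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start, isl.end, isl.size) == (3, 6, 3)
        assert isl.genes == ("g3", "g4", "g5")

    def test_gap_parameter_controls_splitting(self):
        order = _order(range(8))
        sel = {"g3", "g4", "g6"}
        split = detect_islands(sel, order, max_gap=0, min_size=1)
        assert [(i.start, i.end) for i in split] == [(3, 5), (6, 7)]
        merged = detect_islands(sel, order, max_gap=1, min_size=1)
        assert [(i.start, i.end) for i in merged] == [(3, 7)]

    def test_no_selection_gives_no_islands(self):
        assert detect_islands(set(), _order(range(5))) == []

    def test_islands_do_not_span_scaffolds(self):
        order = pd.concat([_order([0, 1], "s1"), _order([0, 1], "s2")])
        order["gene_id"] = ["a0", "a1", "b0", "b1"]
        islands = detect_islands({"a0", "a1", "b0", "b1"}, order, max_gap=5, min_size=2)
        assert [i.scaffold for i in islands] == ["s1", "s2"]

    def test_unknown_selected_gene_rejected(self):
        with pytest.raises(DataError, match="missing"):
            detect_islands({"g99"}, _order(range(5)))

    def test_result_independent_of_selection_ordering(self):
        order = _order(range(20))
        sel = ["g2", "g3", "g5", "g11", "g12", "g13"]
        a = detect_islands(sel, order, max_gap=1, min_size=2)
        b = detect_islands(list(reversed(sel)), order, max_gap=1, min_size=2)
        assert a == b


class TestSmallScaleRecovery:
    def test_screen_recovers_planted_island_exactly(self, tiny_dataset):
        ds = tiny_dataset
        anchor = ds.proteomes[ds.focal]
        strains = [ds.proteomes[s] for s in sorted(ds.groups.non_focal)]
        mat = build_bitscore_matrix(anchor, strains, ScoringParams(), engine="sw")
        rec = select_conserved(mat, ds.groups)
        selected = set(rec.loc[rec["selected"], "gene"])
        assert selected == set(ds.island_genes_focal)
        focal_order = ds.gene_order[ds.gene_order["strain"] == ds.focal]
        islands = detect_islands(selected, focal_order)
        assert len(islands) == 1
        assert set(islands[0].genes) == selected
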