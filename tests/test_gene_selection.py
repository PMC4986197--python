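import numpy as np
import pandas as pd
import pytest

from drivermod.data_io import GroupLabels, SEG_COLUMNS
from drivermod.emd_stats import EMDResult
from drivermod.gene_selection import (
    SelectionConfig,
    build_selection,
    call_cnv_states,
    cnv_frequency_filter,
    map_segments_to_genes,
    mutation_frequency_filter,
    select_candidate_modulators,
    select_genes,
)


def _seg(rows):
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def _coords(d):
    return pd.DataFrame(
        {"chrom": [v[0] for v in d.values()], "start": [v[1] for v in d.values()], "end": [v[2] for v in d.values()]},
        index=pd.Index(list(d), name="gene"),
    )


class TestSegmentMapping:
    def test_single_covering_segment_is_exact(self):
        seg = _seg([("s1", "1", 1, 5000, 0.8)])
        coords = _coords({"gA": ("1", 100, 200)})
        out = map_segments_to_genes(seg, coords, ["s1"])
        assert out.loc["gA", "s1"] == 0.8

    def test_overlap_weighted_mean(self):
        # gene 1-1000: 400 bp at log2=1.0, 600 bp at log2=0.0 -> 0.4
        seg = _seg([("s1", "1", 1, 400, 1.0), ("s1", "1", 401, 1500, 0.0)])
        coords = _coords({"gA": ("1", 1, 1000)})
        out = map_segments_to_genes(seg, coords, ["s1"])
        assert out.loc["gA", "s1"] == pytest.approx(0.4)

    def test_no_overlap_is_missing(self):
        seg = _seg([("s1", "1", 5000, 9000, 1.0)])
        coords = _coords({"gA": ("1", 100, 200), "gB": ("2", 100, 200)})
        out = map_segments_to_genes(seg, coords, ["s1"])
        assert out.loc["gA", "s1"] != out.loc["gA", "s1"]  # NaN
        assert np.isnan(out.loc["gB", "s1"])


class TestCnvCalls:
    @pytest.mark.parametrize(
        "log2,state",
        [(0.35, 1), (0.3, 0), (-0.3, 0), (-0.9, -1), (0.0, 0), (0.30000001, 1)],
    )
    def test_threshold_boundaries_are_strict(self, log2, state):
        mat = pd.DataFrame([[log2]], index=["g"], columns=["s"])
        assert call_cnv_states(mat).loc["g", "s"] == state

    def test_missing_stays_missing(self):
        mat = pd.DataFrame([[np.nan]], index=["g"], columns=["s"])
        assert np.isnan(call_cnv_states(mat).loc["g", "s"])


def _labels(n_a, n_b):
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return GroupLabels(pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)), samples


class TestFrequencyFilters:
    def test_cnv_difference_rule(self):
        labels, samples = _labels(20, 20)
        # gene0: amp 45% vs 20% -> true; gene1: equal -> false; gene2: exactly 20% diff -> false
        calls = np.zeros((3, 40))
        calls[0, :9] = 1
        calls[0, 20:24] = 1
        calls[1, :6] = 1
        calls[1, 20:26] = 1
        calls[2, :8] = 1
        calls[2, 20:24] = 1
        flags = cnv_frequency_filter(pd.DataFrame(calls, index=["g0", "g1", "g2"], columns=samples), labels)
        assert flags.tolist() == [True, False, False]

    def test_mutation_rule_is_per_group(self):
        labels, samples = _labels(50, 100)
        mut = np.zeros((2, 150), dtype=int)
        mut[0, :2] = 1  # 4% of group A
        mut[1, 0] = 1  # 2% of A exactly, and 1/100 in B
        mut[1, 50] = 1
        flags = mutation_frequency_filter(pd.DataFrame(mut, index=["g0", "g1"], columns=samples), labels)
        assert flags.tolist() == [True, False]

    def test_unmutated_gene_not_flagged(self):
        labels, samples = _labels(5, 5)
        mut = pd.DataFrame(np.zeros((1, 10), dtype=int), index=["g0"], columns=samples)
        assert not mutation_frequency_filter(mut, labels).any()


class TestCandidateModulators:
    def test_cnv_and_mutation_routes(self):
        labels, samples = _labels(20, 20)
        calls = np.zeros((3, 40))
        calls[0, :15] = 1  # amplified in 75% of A
        calls[2, :12] = -1  # 60% of A
        mut = np.zeros((3, 40), dtype=int)
        mut[1, 20:21] = 1  # 5% of B
        mut[2, 0] = 1  # 5% of A, but cnv 60% -> still candidate via mutation
        calls_df = pd.DataFrame(calls, index=["g0", "g1", "g2"], columns=samples)
        mut_df = pd.DataFrame(mut, index=["g0", "g1", "g2"], columns=samples)
        assert select_candidate_modulators(calls_df, mut_df, labels, "A") == ["g0", "g2"]
        assert select_candidate_modulators(calls_df, mut_df, labels, "B") == ["g1"]
        # AND combiner requires both routes
        assert select_candidate_modulators(calls_df, mut_df, labels, "A", combiner="and") == []

    def test_list_depends_only_on_own_group_columns(self, rng):
        labels, samples = _labels(15, 15)
        calls = pd.DataFrame(rng.choice([-1, 0, 1], size=(10, 30)), index=[f"g{i}" for i in range(10)], columns=samples)
        mut = pd.DataFrame(rng.choice([0, 1], p=[0.9, 0.1], size=(10, 30)), index=calls.index, columns=samples)
        base = select_candidate_modulators(calls, mut, labels, "A")
        calls2, mut2 = calls.copy(), mut.copy()
        b_cols = labels.group_samples("B")
        calls2[b_cols] = rng.choice([-1, 0, 1], size=(10, 15))
        mut2[b_cols] = 1
        assert select_candidate_modulators(calls2, mut2, labels, "A") == base

    def test_threshold_monotonicity(self, rng):
        labels, samples = _labels(15, 15)
        calls = pd.DataFrame(rng.choice([-1, 0, 1], size=(30, 30)), index=[f"g{i}" for i in range(30)], columns=samples)
        mut = pd.DataFrame(rng.choice([0, 1], p=[0.8, 0.2], size=(30, 30)), index=calls.index, columns=samples)
        prev = None
        for cnv_min in (0.2, 0.4, 0.6, 0.8):
            cur = set(select_candidate_modulators(calls, mut, labels, "A", mut_min=1.0, cnv_min=cnv_min))
            if prev is not None:
                assert cur <= prev
            prev = cur


def _emd_result(qmap):
    table = pd.DataFrame({"emd_score": 1.0, "q_value": pd.Series(qmap)})
    return EMDResult(table=table, n_permutations=10, seed=0)


class TestBuildSelection:
    def test_union_of_disjoint_criteria(self):
        emd_e = _emd_result({"g1": 0.05, "g2": 0.5, "g3": 0.9, "g4": 0.9})
        emd_c = _emd_result({"g1": 0.9, "g2": 0.02, "g3": 0.9, "g4": 0.9})
        cnv_flag = pd.Series({"g3": True, "g1": False, "g2": False, "g4": False})
        mut_flag = pd.Series({"g4": True, "g1": False, "g2": False, "g3": False})
        res = build_selection(emd_e, emd_c, cnv_flag, mut_flag, SelectionConfig())
        assert sorted(res.selected_genes) == ["g1", "g2", "g3", "g4"]
        assert res.flags.loc["g1"].tolist() == [True, False, False, False]

    def test_gene_failing_everything_not_selected(self):
        emd = _emd_result({"g1": 0.05, "g2": 0.5})
        flag = pd.Series({"g1": False, "g2": False})
        res = build_selection(emd, emd, flag, flag, SelectionConfig())
        assert "g2" not in res.selected_genes

    def test_empty_union_is_hard_error(self):
        emd = _emd_result({"g1": 0.9})
        flag = pd.Series({"g1": False})
        with pytest.raises(ValueError, match="relax"):
            build_selection(emd, emd, flag, flag, SelectionConfig())


class TestSelectGenes:
    def test_funnel_recovers_planted_structure(self, comparative_dataset):
        ds = comparative_dataset
        res = select_genes(ds.bundle, SelectionConfig())
        # planted modulators are aberrant at high frequency in their group:
        # they must enter the gene list and the right candidate list
        ga, gb = ds.bundle.groups
        for m in ds.truth.modulators_for(ga):
            assert m in res.candidate_modulators[ga]
        for m in ds.truth.group_specific[gb]:
            assert m not in res.candidate_modulators[ga]
        # only modules driven in one group differ between conditions; the
        # shared-driver module is identically distributed and may be rejected
        group_specific_modules = {p.module_id for p in ds.truth.programs if len(p.driving_groups) == 1}
        driven = [g for g, mod in ds.truth.gene_module.items() if mod in group_specific_modules]
        frac = np.mean([g in set(res.selected_genes) for g in driven])
        assert frac > 0.5
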