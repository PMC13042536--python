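"""PASS triage: flexible regions, the two filter ways, union semantics,
prediction scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from passdesign import study
from passdesign.msa import DeltaPFM
from passdesign.mutations import AMINO_ACIDS, parse_mutation
from passdesign.passfilter import (
    IMPROVED,
    FlexibilityProfile,
    MissingScoreError,
    evaluate_predictions,
    flexible_regions,
    pass_select,
    way1_filter,
    way2_filter,
)
from passdesign.synthetic import gen_rmsf


def make_dpfm(values_by_pos_res, length=400):
    """Dense all-zero ∆PFM overridden at the given (position, residue)."""
    positions = np.arange(1, length + 1)
    values = np.zeros((length, 20))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for (pos, res), v in values_by_pos_res.items():
        values[pos - 1, aa_index[res]] = v
    return DeltaPFM(positions=positions, values=values, n_thermo=10, n_nonthermo=10)


class TestFlexibleRegions:
    def test_single_planted_window_recovered(self):
        prof = gen_rmsf(60, [(18, 24)], high=0.25, low=0.10, noise=0.0)
        assert flexible_regions(prof) == [(18, 24)]

    def test_all_low_profile_empty(self):
        prof = gen_rmsf(40, [], high=0.25, low=0.0, noise=0.0)
        assert flexible_regions(prof) == []

    def test_short_run_discarded_by_min_run(self):
        rmsf = np.full(20, 0.1)
        rmsf[9] = 0.5
        prof = FlexibilityProfile(positions=np.arange(1, 21), rmsf_nm=rmsf)
        assert flexible_regions(prof, min_run=3) == []
        assert flexible_regions(prof, min_run=1) == [(10, 10)]

    def test_boundary_equality_excluded(self):
        rmsf = np.full(10, 0.2)  # exactly at cutoff -> not flexible
        prof = FlexibilityProfile(positions=np.arange(1, 11), rmsf_nm=rmsf)
        assert flexible_regions(prof, cutoff=0.2) == []

    def test_window_touching_profile_end(self):
        prof = gen_rmsf(30, [(26, 30)], high=0.3, low=0.1)
        assert flexible_regions(prof) == [(26, 30)]

    def test_invalid_cutoff(self):
        prof = gen_rmsf(10, [])
        with pytest.raises(ValueError):
            flexible_regions(prof, cutoff=0.0)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_intervals_disjoint_and_above_cutoff(self, seed):
        """Brute-force oracle: every reported position exceeds the cutoff,
        intervals are maximal, sorted and disjoint."""
        rng = np.random.default_rng(seed)
        rmsf = rng.uniform(0.0, 0.4, size=80)
        prof = FlexibilityProfile(positions=np.arange(1, 81), rmsf_nm=rmsf)
        regions = flexible_regions(prof, cutoff=0.2, min_run=2)
        prev_end = 0
        for lo, hi in regions:
            assert lo > prev_end
            assert all(rmsf[p - 1] > 0.2 for p in range(lo, hi + 1))
            # maximality: neighbours below cutoff
            if lo > 1:
                assert rmsf[lo - 2] <= 0.2
            if hi < 80:
                assert rmsf[hi] <= 0.2
            prev_end = hi


class TestWayFilters:
    def test_way1_membership(self):
        regions = [(18, 24), (333, 336)]
        candidates = [parse_mutation(m) for m in ("K21Q", "A200G", "E335D")]
        kept = way1_filter(candidates, regions)
        assert [str(m) for m in kept] == ["K21Q", "E335D"]

    def test_way1_empty_region_list(self):
        assert way1_filter([parse_mutation("K21Q")], []) == []

    @pytest.mark.parametrize(
    "ddg,dpfm_v,kept",
        [(-1.0, 0.2, True), (-1.0, -0.2, False), (0.0, 0.5, False), (-1.0, 0.0, False)],
    )
    def test_way2_strict_inequalities(self, ddg, dpfm_v, kept):
        m = parse_mutation("E84T")
        dpfm = make_dpfm({(84, "T"): dpfm_v})
        result = way2_filter([m], {m: ddg}, dpfm)
        assert (m in result) is kept

    def test_way2_negative_control_flips_dpfm_condition(self):
        m = parse_mutation("E84T")
        dpfm = make_dpfm({(84, "T"): -0.3})
        assert way2_filter([m], {m: -1.0}, dpfm, negative_control=True) == [m]

    def test_way2_missing_score_lists_mutation(self):
        m = parse_mutation("E84T")
        with pytest.raises(MissingScoreError, match="E84T"):
            way2_filter([m], {}, make_dpfm({}))


class TestPassSelect:
    def test_union_equals_individual_filters(self):
        """Oracle equivalence: selection = way1 ∪ way2 on a mixed fixture."""
        prof = gen_rmsf(400, [(18, 24), (333, 336)], high=0.25, low=0.1)
        candidates = [parse_mutation(m) for m in ("K21Q", "W6L", "A200G", "E335D")]
        ddg = {m: -1.0 for m in candidates}
        dpfm = make_dpfm({(6, "L"): 0.3, (200, "G"): -0.1})
        report = pass_select(candidates, prof, ddg, dpfm)
        regions = flexible_regions(prof)
        expected = set(way1_filter(candidates, regions)) | set(
            way2_filter(candidates, ddg, dpfm)
        )
        assert set(report[report.selected].mutation) == {str(m) for m in expected}
        assert (report.selected == (report.way1_selected | report.way2_selected)).all()

    def test_candidate_passing_both_ways_counted_once(self):
        prof = gen_rmsf(100, [(18, 24)], high=0.25, low=0.1)
        m = parse_mutation("K21Q")
        report = pass_select([m], prof, {m: -2.0}, make_dpfm({(21, "Q"): 0.5}))
        assert len(report) == 1
        assert report.selected.sum() == 1
        assert "Way 1" in report.rationale[0] and "Way 2" in report.rationale[0]

    def test_no_candidates_empty_report(self):
        prof = gen_rmsf(50, [(10, 15)])
        report = pass_select([], prof, {}, make_dpfm({}))
        assert len(report) == 0

    def test_selected_rows_have_rationale(self):
        prof = gen_rmsf(100, [(18, 24)], high=0.3, low=0.1)
        cands = [parse_mutation("K21Q"), parse_mutation("A80G")]
        report = pass_select(cands, prof, {m: -1.0 for m in cands}, make_dpfm({}))
        assert (report.loc[report.selected, "rationale"] != "").all()


class TestEvaluatePredictions:
    def test_study_outcome_lists_reproduce_published_rates(self):
        stab, destab, outcomes = study.pass_outcomes()
        result = evaluate_predictions(stab, destab, outcomes)
        assert result.n_predicted_stabilizing == 34
        assert result.n_confirmed == 30
        assert round(result.tp_rate, 1) == 88.2
        assert round(result.tn_rate, 1) == 88.2

    def test_all_confirmed_gives_100(self):
        ms = [parse_mutation("A1G"), parse_mutation("C2S")]
        result = evaluate_predictions(ms, [], {m: IMPROVED for m in ms})
        assert result.tp_rate == 100.0

    def test_missing_outcome_raises(self):
        m = parse_mutation("A1G")
        with pytest.raises(KeyError):
            evaluate_predictions([m], [], {})


def test_tp_rate_monotone_in_planted_signal():
    """Stronger planted ∆∆G separation can only improve the confirmed
    fraction of way-2 selections (trend over seeds)."""
    from passdesign.synthetic import gen_ddg

    candidates = [
        parse_mutation(f"A{p}G") for p in range(1, 41)
    ]
    planted = candidates[:20]
    dpfm = make_dpfm({(m.position, "G"): 0.5 for m in candidates}, length=50)
    rates = []
    for effect in (0.2, 1.0, 4.0):
        confirmed = []
        for seed in range(20):
            ddg, truth = gen_ddg(candidates, planted, effect=effect, noise=1.0, seed=seed)
            kept = way2_filter(candidates, ddg, dpfm)
            if kept:
                confirmed.append(np.mean([truth[m] for m in kept]))
        rates.append(np.mean(confirmed))
    assert rates[0] <= rates[1] + 0.05 <= rates[2] + 0.10
    assert rates[2] > rates[0]
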