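"""Evaluation battery: summaries, RMSE, correlation curves, diagnostics."""

import math

import numpy as np
import pytest

from irtcat import (
    CATConfig,
    CATResult,
    CATSimulation,
    DataError,
    SyntheticSpec,
    compare_static_short_form,
    correlation_by_length,
    correlation_curve,
    length_summary,
    rmse,
    scenario_summary,
    se_reduction_analysis,
    secondary_rule_diagnostics,
    top_information_subset,
)


def make_result(rid, thetas, ses, stop_reason="se_reached", responses=None):
    n = len(thetas)
    return CATResult(
        respondent_id=rid,
        administered=tuple(f"i{k}" for k in range(n)),
        responses=tuple(responses or [1] * n),
        interim_thetas=tuple(thetas),
        interim_ses=tuple(ses),
        final_theta=thetas[-1],
        final_se=ses[-1],
        stop_reason=stop_reason,
    )


# --- rmse ---


def test_rmse_values():
    assert rmse([1.0, -0.5], [1.0, -0.5]) == 0.0
    assert rmse([0.3, -0.4], [0.0, 0.0]) == pytest.approx(math.sqrt(0.125), abs=1e-12)
    base = rmse([0.3, -0.4], [0.0, 0.0])
    assert rmse([0.6, -0.8], [0.0, 0.0]) == pytest.approx(2 * base, abs=1e-12)
    with pytest.raises(DataError):
        rmse([1.0], [1.0, 2.0])
    with pytest.raises(DataError):
        rmse([], [])


# --- correlation by length ---


def test_correlation_identity_at_full_exhaustion():
    spec = SyntheticSpec(n_respondents=40, n_items=8, seed=21)
    model = CATSimulation.from_synthetic(spec, config=CATConfig(se_threshold=0.0, max_items=8))
    res = model.fit()
    assert res.correlation_by_length(8) == pytest.approx(1.0, abs=1e-12)


def test_correlation_matches_textbook_formula():
    rng = np.random.default_rng(13)
    full = rng.normal(0, 1, 20)
    finals = full + rng.normal(0, 0.3, 20)
    results = [make_result(f"r{i}", [finals[i]], [0.5]) for i in range(20)]
    r = correlation_by_length(results, full, 1)
    x, y = finals, full
    hand = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r == pytest.approx(hand, abs=1e-12)


def test_correlation_carry_forward():
    # respondent 0 stopped after 1 item: its final theta is carried to k=2
    results = [
        make_result("a", [0.5], [0.4]),
        make_result("b", [0.1, 0.8], [0.6, 0.4]),
        make_result("c", [-0.2, -1.0], [0.6, 0.4]),
    ]
    full = np.array([0.6, 0.9, -1.1])
    r2 = correlation_by_length(results, full, 2)
    direct = np.corrcoef([0.5, 0.8, -1.0], full)[0, 1]
    assert r2 == pytest.approx(direct, abs=1e-15)
    curve = correlation_curve(results, full)
    assert list(curve["k"]) == [1, 2]


def test_correlation_errors():
    results = [make_result("a", [0.5], [0.4]), make_result("b", [0.5], [0.4])]
    with pytest.raises(DataError):
        correlation_by_length(results, np.array([1.0, 2.0]), 0)
    with pytest.raises(DataError):
        correlation_by_length(results, np.array([1.0, 2.0]), 1)  # zero variance in CAT thetas


# --- length summary ---


def test_length_summary_constant():
    results = [make_result(f"r{i}", [0.0] * 10, [0.5] * 10) for i in range(4)]
    s = length_summary(results)
    assert s == {"mean": 10.0, "sd": 0.0, "min": 10, "max": 10, "median": 10.0, "q1": 10.0, "q3": 10.0}


def test_length_summary_order_statistics():
    lengths = [6, 8, 10, 12, 14]
    results = [make_result(f"r{i}", [0.0] * n, [0.5] * n) for i, n in enumerate(lengths)]
    s = length_summary(results)
    assert s["median"] == 10.0
    # brute-force check against sorted order statistics (linear interpolation)
    arr = np.sort(np.array(lengths, dtype=float))
    assert s["q1"] == float(np.percentile(arr, 25))
    assert s["q3"] == float(np.percentile(arr, 75))
    assert s["mean"] == pytest.approx(np.mean(lengths))
    assert s["sd"] == pytest.approx(np.std(lengths))  # population denominator


# --- secondary stopping rule diagnostics ---


def test_secondary_rule_all_se_reached():
    results = [make_result(f"r{i}", [0.0], [0.4]) for i in range(5)]
    d = secondary_rule_diagnostics(results)
    assert d["counts"] == {"se_reached": 5, "max_items": 0}
    assert d["n_capped"] == 0
    assert d["prop_theta_above_plus1"] is None


def test_secondary_rule_tail_proportions():
    results = [
        make_result("a", [-1.5], [0.55], "max_items"),
        make_result("b", [1.5], [0.52], "max_items"),
        make_result("c", [0.1], [0.45]),
        make_result("d", [0.2], [0.44]),
    ]
    d = secondary_rule_diagnostics(results)
    assert d["counts"] == {"se_reached": 2, "max_items": 2}
    assert d["prop_theta_below_minus1"] == 0.5
    assert d["prop_theta_above_plus1"] == 0.5
    assert d["capped_se_mean"] == pytest.approx(0.535)
    assert (d["capped_se_min"], d["capped_se_max"]) == (0.52, 0.55)


def test_capped_cases_concentrate_in_tails():
    spec = SyntheticSpec(n_respondents=300, n_items=22, seed=42)
    res = CATSimulation.from_synthetic(spec).fit(se_threshold=0.50, max_items=15)
    capped = [r for r in res.results if r.stop_reason == "max_items"]
    assert capped, "expected some sessions to hit the item cap"
    mean_abs_capped = np.mean([abs(r.final_theta) for r in capped])
    mean_abs_all = np.mean(np.abs(res.thetas))
    assert mean_abs_capped > mean_abs_all


# --- SE reduction per additional item ---


def test_se_reduction_all_dropping():
    ses = [0.9 - 0.05 * k for k in range(5)]
    results = [make_result(f"r{i}", [0.0] * 5, ses) for i in range(3)]
    tab = se_reduction_analysis(results, delta=0.01)
    assert list(tab["step"]) == [1, 2, 3, 4]
    assert (tab["prop_reduction_gt_delta"] == 1.0).all()
    assert (tab["n_continuing"] == 3).all()


def test_se_reduction_empty_denominator_absent():
    results = [make_result("a", [0.0, 0.1], [0.6, 0.5]), make_result("b", [0.0, 0.1], [0.6, 0.5])]
    tab = se_reduction_analysis(results)
    assert list(tab["step"]) == [1]  # nobody took a 3rd item: no step-2 row


def test_se_reduction_manual_traces():
    results = [
        make_result("a", [0.0] * 3, [0.80, 0.70, 0.695]),  # drop 0.10 then 0.005
        make_result("b", [0.0] * 3, [0.80, 0.795, 0.70]),  # drop 0.005 then 0.095
        make_result("c", [0.0] * 2, [0.80, 0.70]),  # stopped after 2
    ]
    tab = se_reduction_analysis(results, delta=0.01).set_index("step")
    assert tab.loc[1, "n_continuing"] == 3
    assert tab.loc[1, "prop_reduction_gt_delta"] == pytest.approx(2 / 3)
    assert tab.loc[2, "n_continuing"] == 2
    assert tab.loc[2, "prop_reduction_gt_delta"] == pytest.approx(1 / 2)


# --- static short form comparison ---


@pytest.fixture(scope="module")
def cohort():
    spec = SyntheticSpec(n_respondents=150, n_items=22, seed=42)
    return CATSimulation.from_synthetic(spec)


def test_static_full_bank_is_perfect(cohort):
    _, r = compare_static_short_form(
        cohort.matrix, cohort.bank, cohort.bank.item_ids, cohort.config
    )
    assert r == pytest.approx(1.0, abs=1e-12)


def test_static_single_weak_item_is_poor(cohort):
    info0 = cohort.bank.information_matrix(np.array([0.0]))[:, 0]
    weakest = cohort.bank[int(np.argmin(info0))].item_id
    _, r_weak = compare_static_short_form(cohort.matrix, cohort.bank, [weakest], cohort.config)
    assert r_weak < 0.8


def test_static_form_below_length_matched_cat(cohort):
    res = cohort.fit(se_threshold=0.50, max_items=15)
    subset = top_information_subset(cohort.bank, 10)
    _, r_static = compare_static_short_form(cohort.matrix, cohort.bank, subset, cohort.config)
    assert r_static <= res.correlation_by_length(10)


def test_static_unknown_ids_rejected(cohort):
    with pytest.raises(DataError):
        compare_static_short_form(cohort.matrix, cohort.bank, ["nope"], cohort.config)


def test_correlation_curve_rises_to_one_under_exhaustion(cohort):
    res = cohort.fit(se_threshold=0.0, max_items=22)
    curve = res.correlation_curve()
    assert curve["r"].iloc[-1] == pytest.approx(1.0, abs=1e-12)
    # non-decreasing on average: later steps add information
    diffs = np.diff(curve["r"].to_numpy())
    assert diffs.mean() > 0
    assert curve["r"].iloc[-1] >= curve["r"].iloc[0]


# --- scenario summary assembly ---


def test_scenario_summary_invariants(cohort):
    res = cohort.fit(se_threshold=0.50, max_items=15)
    s = res.summary()
    assert s.length_min <= s.length_median <= s.length_max
    assert s.length_min <= s.length_q1 <= s.length_q3 <= s.length_max
    assert s.length_sd >= 0 and s.rmse_vs_full_length >= 0
    assert s.n_respondents == 150
    row = s.to_row()
    assert row["scenario"] == "SE0.5_max15"
    assert "RMSE" in str(s)
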