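"""Challenge scoring harness: labels, AUCs, weighting, bootstrap, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmrisk import (
    RiskPrediction,
    ThresholdGrid,
    auc_at_threshold,
    bac,
    bayes_factor,
    bootstrap_wiauc,
    evaluate_model,
    iauc,
    iauc_curve,
    km_estimate,
    label_high_risk,
    rank_models,
    weighted_metric,
)
from mmrisk.evaluate import EvaluationResult, _mann_whitney_auc
from mmrisk.errors import (
    MissingPredictionError,
    NegativeTimeError,
    UndefinedMetricError,
)

from conftest import make_survival


def pred(scores, surv, model="m", cohort="C"):
    return RiskPrediction(model, cohort,
                          pd.Series(np.asarray(scores, float), index=surv.index))


def brute_force_auc(scores, labels):
    """Exhaustive pair enumeration oracle."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# grid


def test_default_grid_has_53_weekly_thresholds():
    grid = ThresholdGrid()
    t = grid.thresholds()
    assert len(t) == 53
    assert t[0] == 12.0 and t[-1] <= 24.0 and t[-1] > 24.0 - grid.step_months
    assert np.allclose(np.diff(t), 7.0 / 30.4375)


@pytest.mark.parametrize(
    "kwargs",
    [dict(start_months=19.0), dict(step_months=0.0),
     dict(start_months=12.0, end_months=30.0)],
)
def test_invalid_grids_rejected(kwargs):
    with pytest.raises(ValueError):
        ThresholdGrid(**kwargs)


# ---------------------------------------------------------------------------
# labels


def test_high_risk_labels_at_18_months():
    surv = make_survival([12.0, 20.0, 10.0], [1, 0, 0])
    labels, evaluable = label_high_risk(surv, 18.0)
    assert labels.tolist() == [1, 0, 0]
    assert evaluable.tolist() == [True, True, False]


def test_event_exactly_at_threshold_is_low_risk():
    surv = make_survival([18.0], [1])
    labels, evaluable = label_high_risk(surv, 18.0)
    assert labels.tolist() == [0] and evaluable.tolist() == [True]


def test_negative_times_rejected():
    surv = make_survival([5.0, 3.0], [1, 1])
    surv.loc[surv.index[0], "pfs_months"] = -2.0
    with pytest.raises(NegativeTimeError):
        label_high_risk(surv, 18.0)


# ---------------------------------------------------------------------------
# AUC


def test_auc_printed_example_075():
    surv = make_survival([5, 30, 8, 25], [1, 0, 1, 0])
    p = pred([0.9, 0.8, 0.3, 0.1], surv)
    assert auc_at_threshold(p, surv, 18.0) == pytest.approx(0.75, abs=1e-12)


def test_auc_perfect_and_all_ties():
    surv = make_survival([5, 30, 8, 25], [1, 0, 1, 0])
    assert auc_at_threshold(pred([1, 0, 1, 0], surv), surv, 18.0) == 1.0
    assert auc_at_threshold(pred([2, 2, 2, 2], surv), surv, 18.0) == 0.5


def test_auc_undefined_when_a_class_is_empty():
    surv = make_survival([30, 25], [0, 0])
    assert auc_at_threshold(pred([1, 2], surv), surv, 18.0) is None


def test_missing_prediction_for_evaluable_patient_is_named():
    surv = make_survival([5, 30], [1, 0], patient_ids=["pa", "pb"])
    p = RiskPrediction("m", "C", pd.Series([0.3], index=["pa"]))
    with pytest.raises(MissingPredictionError, match="pb"):
        auc_at_threshold(p, surv, 18.0)


def test_auc_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(5, 50))
        times = rng.uniform(0, 36, n)
        events = (rng.random(n) > rng.uniform(0, 0.5)).astype(int)
        scores = np.round(rng.standard_normal(n), 1)  # force some ties
        surv = make_survival(times, events)
        labels, evaluable = label_high_risk(surv, 18.0)
        expected = brute_force_auc(scores[evaluable.to_numpy()],
                                   labels.to_numpy()[evaluable.to_numpy()])
        got = auc_at_threshold(pred(scores, surv), surv, 18.0)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# iAUC


def constant_auc_data():
    """AUC = 0.7 at every grid threshold: all events before 12 months or
    follow-up past 24, so labels never change over the grid."""
    times = [5, 5, 5, 5, 5, 30, 30, 30, 30]
    events = [1, 1, 1, 1, 1, 0, 0, 0, 0]
    surv = make_survival(times, events)
    scores = [9, 8, 7, 4.5, 0, 6, 5, 4, 3]  # 14 of 20 pairs won
    return pred(scores, surv), surv


def test_iauc_constant_auc_construction():
    p, surv = constant_auc_data()
    assert iauc(p, surv) == pytest.approx(0.7, abs=1e-12)


def test_iauc_perfect_ranking_is_one():
    times = np.linspace(1, 40, 30)
    surv = make_survival(times, np.ones(30, int))
    assert iauc(pred(-times, surv), surv) == pytest.approx(1.0, abs=1e-12)


def test_iauc_invariant_under_monotone_transforms():
    rng = np.random.default_rng(7)
    times = rng.uniform(0, 40, 80)
    events = (rng.random(80) > 0.25).astype(int)
    surv = make_survival(times, events)
    scores = rng.standard_normal(80)
    base = iauc(pred(scores, surv), surv)
    assert iauc(pred(np.exp(scores), surv), surv) == pytest.approx(base, abs=1e-12)
    from scipy.stats import rankdata

    assert iauc(pred(rankdata(scores), surv), surv) == pytest.approx(base, abs=1e-12)


def test_negating_scores_flips_every_threshold_auc():
    rng = np.random.default_rng(9)
    times = rng.uniform(0, 40, 60)
    events = (rng.random(60) > 0.2).astype(int)
    surv = make_survival(times, events)
    scores = rng.standard_normal(60)
    _, a = iauc_curve(pred(scores, surv), surv)
    _, b = iauc_curve(pred(-scores, surv), surv)
    for x, y in zip(a, b):
        if x is None:
            assert y is None
        else:
            assert y == pytest.approx(1.0 - x, abs=1e-12)


def test_iauc_all_thresholds_undefined_errors():
    surv = make_survival([30, 31], [0, 0])
    with pytest.raises(UndefinedMetricError):
        iauc(pred([1, 2], surv), surv)


# ---------------------------------------------------------------------------
# weighting and BAC


def test_weighted_metric_examples():
    assert weighted_metric([(0.9, 5)]) == 0.9
    assert weighted_metric([(0.8, 3), (0.6, 1)]) == pytest.approx(0.78)
    assert weighted_metric([(0.7, 2), (0.5, 2)]) == pytest.approx(0.6)
    with pytest.raises(UndefinedMetricError):
        weighted_metric([(0.7, 0), (0.5, 0)])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(st.floats(0, 1), st.integers(0, 20)),
        min_size=1, max_size=6,
    ).filter(lambda lst: any(n > 0 for _, n in lst))
)
def test_weighted_metric_is_convex_combination(pairs):
    value = weighted_metric(pairs)
    used = [m for m, n in pairs if n > 0]
    assert min(used) - 1e-12 <= value <= max(used) + 1e-12


def test_bac_examples():
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    ev = np.ones(8, bool)
    assert bac(labels, labels, ev) == 1.0
    assert bac(np.ones(8, int), labels, ev) == 0.5
    # TP 3, FN 1, TN 2, FP 2 -> (0.75 + 0.5)/2
    calls = np.array([1, 1, 1, 0, 1, 1, 0, 0])
    assert bac(calls, labels, ev) == pytest.approx(0.625)


def test_bac_undefined_when_class_absent():
    assert bac(np.array([1, 0]), np.array([1, 1]), np.ones(2, bool)) is None


# ---------------------------------------------------------------------------
# bootstrap + Bayes factor + ranking


def two_cohort_setup(seed=0, n=120):
    rng = np.random.default_rng(seed)
    cohorts, preds = [], []
    from mmrisk.simulate import Cohort

    for cid in ("CA", "CB"):
        times = rng.uniform(0, 40, n)
        events = (rng.random(n) > 0.2).astype(int)
        surv = make_survival(times, events,
                             patient_ids=[f"{cid}-{i}" for i in range(n)])
        expr = pd.DataFrame(
            rng.standard_normal((3, n)),
            index=pd.Index(["G0", "G1", "G2"], name="gene_id"),
            columns=surv.index,
        )
        clin = pd.DataFrame(
            {"age": rng.uniform(40, 80, n), "iss": rng.integers(1, 4, n),
             "sex": ["F"] * n, "t414": [False] * n}, index=surv.index,
        )
        cohorts.append(Cohort(cid, expr, clin, surv))
        good = -times + 0.5 * rng.standard_normal(n)
        preds.append(RiskPrediction("good", cid, pd.Series(good, index=surv.index)))
        preds.append(RiskPrediction("rand", cid,
                                    pd.Series(rng.standard_normal(n),
                                              index=surv.index)))
    return cohorts, preds


def test_bootstrap_identity_resample_equals_point_wiauc():
    cohorts, preds = two_cohort_setup()
    draws = bootstrap_wiauc(preds, cohorts, B=1, seed=0, resample=False)
    ev = evaluate_model("good", preds, cohorts)
    assert draws["good"][0] == pytest.approx(ev.wiauc, abs=1e-12)


def test_bootstrap_pairing_identical_models_identical_draws():
    cohorts, preds = two_cohort_setup()
    clones = [RiskPrediction("clone", p.cohort_id, p.scores.copy())
              for p in preds if p.model_id == "good"]
    draws = bootstrap_wiauc(preds + clones, cohorts, B=40, seed=3)
    assert np.array_equal(draws["good"], draws["clone"])


def test_bootstrap_is_deterministic_under_seed():
    cohorts, preds = two_cohort_setup()
    a = bootstrap_wiauc(preds, cohorts, B=20, seed=11)
    b = bootstrap_wiauc(preds, cohorts, B=20, seed=11)
    assert np.array_equal(a["good"], b["good"])


def test_bootstrap_sd_tracks_sampling_variability():
    """Bootstrap SD of wiAUC within a factor of 2 of the SD across fresh
    simulated cohorts of the same size."""
    from mmrisk import SimulationConfig, simulate_cohort

    def score_and_iauc(seed):
        config = SimulationConfig(
            n_cohorts=1, patients_per_cohort=[200], n_genes=4,
            planted_effects=[], seed=seed,
        )
        cohort = simulate_cohort(config, 0)
        rng = np.random.default_rng(seed + 5000)
        scores = (-cohort.survival["pfs_months"].to_numpy()
                  + 15 * rng.standard_normal(200))
        return cohort, pd.Series(scores, index=cohort.survival.index)

    cohort, scores = score_and_iauc(0)
    p = RiskPrediction("m", cohort.cohort_id, scores)
    draws = bootstrap_wiauc([p], [cohort], B=200, seed=1)["m"]
    fresh = []
    for seed in range(1, 51):
        c2, s2 = score_and_iauc(seed)
        fresh.append(iauc(RiskPrediction("m", c2.cohort_id, s2), c2.survival))
    ratio = np.std(draws) / np.std(fresh)
    assert 0.5 < ratio < 2.0


def test_bayes_factor_examples():
    x = np.linspace(0.5, 0.7, 200)
    assert bayes_factor(x, x) == 1.0  # even tie split
    top = np.zeros(200)
    other = np.zeros(200)
    top[:150] = 1.0  # top wins 150, loses 50
    other[150:] = 1.0
    assert bayes_factor(top, other) == pytest.approx(3.0)
    assert bayes_factor(np.ones(50), np.zeros(50)) == math.inf
    with pytest.raises(ValueError):
        bayes_factor(np.ones(3), np.ones(4))


def test_bayes_factor_reciprocity_without_ties():
    rng = np.random.default_rng(1)
    a = rng.standard_normal(500)
    b = a + rng.standard_normal(500) * 0.3 + 0.1
    assert bayes_factor(a, b) * bayes_factor(b, a) == pytest.approx(1.0)


def make_result(model_id, wiauc, wbac, draws):
    return EvaluationResult(model_id, [], wiauc, wbac,
                            bootstrap_wiaucs=np.asarray(draws, float))


def test_rank_single_model():
    ranked = rank_models([make_result("only", 0.7, 0.6, [0.7] * 10)])
    assert ranked[0].final_rank == 1 and ranked[0].tied_with_top


def test_tie_broken_by_wbac():
    draws = np.linspace(0.6, 0.8, 100)
    a = make_result("modelA", 0.70001, 0.55, draws)
    b = make_result("modelB", 0.70000, 0.65, draws.copy())
    ranked = rank_models([a, b])
    assert ranked[0].model_id == "modelB" and ranked[0].final_rank == 1
    assert ranked[1].model_id == "modelA"


def test_dominated_model_never_ranks_first():
    top_draws = np.full(100, 0.8)
    low_draws = np.full(100, 0.6)
    a = make_result("a_top", 0.8, 0.1, top_draws)
    b = make_result("b_low", 0.6, 0.99, low_draws)
    ranked = rank_models([a, b])
    assert ranked[0].model_id == "a_top"
    assert not ranked[1].tied_with_top
    assert ranked[1].bayes_factor_vs_top == math.inf


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_no_censoring_midpoint():
    surv = make_survival([1, 2, 3, 4], [1, 1, 1, 1])
    kmf = km_estimate(surv)
    assert float(kmf.predict(2.5)) == pytest.approx(0.5)


def test_km_all_censored_is_flat_one():
    surv = make_survival([3, 5, 7], [0, 0, 0])
    kmf = km_estimate(surv)
    assert float(kmf.predict(6.9)) == 1.0


def test_km_matches_hand_computed_product_limit():
    # events at 2 (1 of 6 at risk), 4 (1 of 4), 7 (1 of 2); censored at 3, 6, 9
    surv = make_survival([2, 3, 4, 6, 7, 9], [1, 0, 1, 0, 1, 0])
    kmf = km_estimate(surv)
    assert float(kmf.predict(2.5)) == pytest.approx(5 / 6)
    assert float(kmf.predict(5.0)) == pytest.approx(5 / 6 * 3 / 4)
    assert float(kmf.predict(8.0)) == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
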