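"""Concordance, effect sizes, Stouffer combination and gene ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmrisk import (
    PlantedEffect,
    SimulationConfig,
    cindex_to_z,
    concordance_index,
    concordance_se,
    correlation_by_subgroup,
    rank_genes,
    simulate_challenge,
    simulate_cohort,
    stouffer_combine,
)
from mmrisk.errors import UndefinedMetricError

from conftest import make_survival


def brute_force_cindex(values, times, events):
    """Exhaustive enumeration over comparable pairs (oracle)."""
    n = len(values)
    num = npairs = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (
                (times[i] < times[j] and events[i] == 1)
                or (times[i] == times[j] and events[i] == 1 and events[j] == 0)
            )
            if not comparable:
                continue
            npairs += 1
            if values[i] > values[j]:
                num += 1.0
            elif values[i] == values[j]:
                num += 0.5
    return (num / npairs if npairs else None), int(npairs)


def test_single_concordant_pair():
    surv = make_survival([5, 10], [1, 1])
    c, n = concordance_index([2.0, 1.0], surv)
    assert c == 1.0 and n == 1


def test_constant_values_give_half():
    surv = make_survival([5, 10, 15], [1, 1, 1])
    c, _ = concordance_index([3.0, 3.0, 3.0], surv)
    assert c == 0.5


def test_matches_brute_force_with_censoring():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = int(rng.integers(5, 30))
        times = np.round(rng.uniform(0, 20, n), 0)  # forces tied times
        events = (rng.random(n) > 0.35).astype(int)
        values = np.round(rng.standard_normal(n), 1)
        surv = make_survival(times, events)
        expected, npairs = brute_force_cindex(values, times, events)
        if expected is None:
            with pytest.raises(UndefinedMetricError):
                concordance_index(values, surv)
            continue
        c, n_pairs = concordance_index(values, surv)
        assert n_pairs == npairs
        assert c == pytest.approx(expected, abs=1e-12)


def test_matches_lifelines_orientation():
    from lifelines.utils import concordance_index as ll_ci

    rng = np.random.default_rng(6)
    n = 150
    times = rng.uniform(0, 30, n)
    events = (rng.random(n) > 0.3).astype(int)
    values = rng.standard_normal(n)
    surv = make_survival(times, events)
    c, _ = concordance_index(values, surv)
    # lifelines scores higher prediction = longer survival; ours is risk-oriented
    assert c == pytest.approx(ll_ci(times, -values, events), abs=1e-12)


def test_antisymmetry_for_tie_free_values():
    rng = np.random.default_rng(3)
    times = rng.uniform(0, 30, 40)
    events = (rng.random(40) > 0.3).astype(int)
    values = rng.standard_normal(40)
    surv = make_survival(times, events)
    c_plus, _ = concordance_index(values, surv)
    c_minus, _ = concordance_index(-values, surv)
    assert c_plus + c_minus == pytest.approx(1.0, abs=1e-12)


def test_zero_comparable_pairs_is_an_error():
    surv = make_survival([5, 10], [0, 0])
    with pytest.raises(UndefinedMetricError):
        concordance_index([1.0, 2.0], surv)


# ---------------------------------------------------------------------------
# z effect sizes


def test_c_equal_half_maps_to_z_zero():
    surv = make_survival([1, 2, 3, 4], [1, 1, 1, 1])
    values = [1.0, 2.0, 2.0, 1.0]
    c, _ = concordance_index(values, surv)
    assert c == 0.5
    assert cindex_to_z(c, values, surv) == 0.0


def test_degenerate_data_zero_variance_errors():
    surv = make_survival([1, 2, 3], [1, 1, 1])
    with pytest.raises(UndefinedMetricError):
        cindex_to_z(0.5, [1.0, 1.0, 1.0], surv)


def test_null_z_calibration_1000_genes():
    """Null simulation, 1000 genes, n=300: mean z within +-0.05, SD in
    [0.9, 1.1] — validates the Noether-type variance."""
    config = SimulationConfig(
        n_cohorts=1, patients_per_cohort=[300], n_genes=1000,
        planted_effects=[], beta_age=0.0, beta_iss=0.0, seed=21,
    )
    cohort = simulate_cohort(config, 0)
    table = rank_genes([cohort], weighting="unweighted")
    z = table.table["z_C00"].to_numpy()
    assert abs(z.mean()) < 0.05
    assert 0.9 < z.std() < 1.1


def test_z_se_close_to_jackknife_on_small_fixture():
    """Noether SE within 15% of the delete-one jackknife SE at n=10."""
    times = np.array([16.0, 14.0, 9.0, 27.0, 11.0, 17.0, 5.0, 3.0, 25.0, 5.0])
    events = np.array([0, 1, 0, 1, 0, 0, 1, 1, 0, 0])
    values = np.array([-1.5, -0.7, -0.5, -1.5, -1.2, 1.5, -1.0, -0.9, -1.4, 1.2])
    surv = make_survival(times, events)
    se = concordance_se(values, surv)
    loo = []
    for i in range(10):
        keep = np.arange(10) != i
        c_i, _ = concordance_index(values[keep],
                                   make_survival(times[keep], events[keep]))
        loo.append(c_i)
    loo = np.asarray(loo)
    se_jack = np.sqrt((len(loo) - 1) / len(loo) * np.sum((loo - loo.mean()) ** 2))
    assert se == pytest.approx(se_jack, rel=0.15)


# ---------------------------------------------------------------------------
# Stouffer


def test_stouffer_closed_forms():
    assert stouffer_combine([1.7]) == pytest.approx(1.7)
    assert stouffer_combine([2.0, 2.0, 2.0, 2.0]) == pytest.approx(4.0)
    assert stouffer_combine([1.0, -1.0], [3.0, 1.0]) == pytest.approx(
        2.0 / np.sqrt(10.0)
    )
    with pytest.raises(UndefinedMetricError):
        stouffer_combine([1.0, 2.0], [0.0, 0.0])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    z=st.lists(st.floats(-4, 4), min_size=1, max_size=6),
    c=st.floats(0.1, 9.0),
    s=st.floats(0.1, 9.0),
)
def test_stouffer_homogeneity(z, c, s):
    w = [1.0 + i for i in range(len(z))]
    base = stouffer_combine(z, w)
    assert stouffer_combine([s * v for v in z], w) == pytest.approx(
        s * base, abs=1e-9
    )
    assert stouffer_combine(z, [c * v for v in w]) == pytest.approx(
        base, abs=1e-9
    )


# ---------------------------------------------------------------------------
# rank_genes


@pytest.fixture(scope="module")
def planted_cohorts():
    config = SimulationConfig(
        n_cohorts=3, patients_per_cohort=[150] * 3, n_genes=100,
        planted_effects=[PlantedEffect(1, 0.9)], seed=31,
        within_negative_corr=0.0,
    )
    train, _ = simulate_challenge(config, 3, 0)
    return train


def test_planted_gene_ranks_first(planted_cohorts):
    table = rank_genes(planted_cohorts, endpoint="pfs")
    assert table.rank_of("PHF19") == 1
    assert table.table.loc["PHF19", "meta_z"] > 4


def test_os_endpoint_keeps_planted_gene_high(planted_cohorts):
    table = rank_genes(planted_cohorts, endpoint="os")
    assert table.rank_of("PHF19") <= 10


def test_weighting_modes_and_weights_recorded(planted_cohorts):
    weighted = rank_genes(planted_cohorts, weighting="high_risk_count")
    unweighted = rank_genes(planted_cohorts, weighting="unweighted")
    assert all(v == 1.0 for v in unweighted.cohort_weights.values())
    assert all(v > 1 for v in weighted.cohort_weights.values())
    assert weighted.rank_of("PHF19") == 1 and unweighted.rank_of("PHF19") == 1


def test_rank_invariant_under_gene_order_permutation(planted_cohorts):
    import dataclasses

    rng = np.random.default_rng(0)
    perm = rng.permutation(100)
    shuffled = [
        dataclasses.replace(c, expression=c.expression.iloc[perm])
        for c in planted_cohorts
    ]
    a = rank_genes(planted_cohorts).table["rank"]
    b = rank_genes(shuffled).table["rank"]
    assert (a.sort_index() == b.sort_index()).all()


def test_ranks_are_a_permutation(planted_cohorts):
    table = rank_genes(planted_cohorts)
    assert sorted(table.table["rank"]) == list(range(1, 101))


def test_quantile_normalization_mode_runs(planted_cohorts):
    table = rank_genes(planted_cohorts, normalization="quantile")
    assert table.rank_of("PHF19") <= 5


def test_empty_gene_intersection_errors(planted_cohorts):
    import dataclasses

    renamed = dataclasses.replace(
        planted_cohorts[0],
        expression=planted_cohorts[0].expression.set_axis(
            [f"X{i}" for i in range(100)]
        ),
    )
    with pytest.raises(UndefinedMetricError):
        rank_genes([renamed, planted_cohorts[1]])


# ---------------------------------------------------------------------------
# subgroup correlation


def test_self_correlation_is_one(small_config):
    cohort = simulate_cohort(small_config, 0)
    res = correlation_by_subgroup(cohort, "MMSET", "MMSET")
    assert res.r_negative == pytest.approx(1.0)
    assert res.n_positive + res.n_negative == cohort.n_patients


def test_orthogonal_vectors_give_zero(small_config):
    cohort = simulate_cohort(small_config, 0)
    expr = cohort.expression.copy()
    n = cohort.n_patients
    a = np.zeros(n)
    b = np.zeros(n)
    a[: n // 2] = (-1.0) ** np.arange(n // 2)  # mean-zero, orthogonal to b
    b[n // 2:] = (-1.0) ** np.arange(n - n // 2)
    expr.loc["G0002"] = a
    expr.loc["G0003"] = b
    import dataclasses

    clin = cohort.clinical.copy()
    clin["t414"] = False
    c2 = dataclasses.replace(cohort, expression=expr, clinical=clin)
    res = correlation_by_subgroup(c2, "G0002", "G0003")
    assert res.r_negative == pytest.approx(0.0, abs=1e-12)


def test_small_subgroup_flagged_undefined(small_config):
    import dataclasses

    cohort = simulate_cohort(small_config, 0)
    clin = cohort.clinical.copy()
    clin["t414"] = False
    clin.iloc[0, clin.columns.get_loc("t414")] = True
    c2 = dataclasses.replace(cohort, clinical=clin)
    res = correlation_by_subgroup(c2, "MMSET", "PHF19")
    assert res.r_positive is None and res.n_positive == 1
    assert res.r_negative is not None
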