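import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avidex import biomarker_stats as bs


# --- enrichment ratio -------------------------------------------------------


def test_enrichment_ratio():
    assert bs.enrichment_ratio(2.0, 1.0) == 2.0
    assert bs.enrichment_ratio(3.7, 3.7) == 1.0
    with pytest.raises(ValueError):
        bs.enrichment_ratio(1.0, 0.0)


# --- normality gate ---------------------------------------------------------


def test_ks_gate_accepts_normal_rejects_exponential():
    rng = np.random.default_rng(10)
    assert bs.ks_normality(rng.normal(size=1000)).p_value > 0.05
    assert bs.ks_normality(rng.exponential(size=1000)).p_value < 0.001


def test_ks_preconditions():
    with pytest.raises(ValueError):
        bs.ks_normality([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        bs.ks_normality([1.0] * 10)


def test_compare_groups_gate_selects_test():
    rng = np.random.default_rng(11)
    normal_a = rng.normal(0, 1, 50)
    normal_b = rng.normal(0.3, 1, 50)
    assert bs.compare_groups(normal_a, normal_b).test_name == "t"
    heavy_a = rng.lognormal(6, 1.2, 200)
    heavy_b = rng.lognormal(6.5, 1.2, 200)
    assert bs.compare_groups(heavy_a, heavy_b).test_name == "mann_whitney"


def test_compare_groups_identical_samples():
    res = bs.compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.p_value > 0.9


def test_mwu_exact_small_sample():
    # complete separation of 3 vs 3: exact two-sided p = 2/20
    res = bs.compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res.test_name == "mann_whitney"
    assert res.p_value == pytest.approx(0.1, abs=1e-12)


def _exact_mwu_pvalue(a, b):
    """Two-sided MWU p by enumeration of all allocations (no ties)."""
    a = np.asarray(a)
    b = np.asarray(b)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = (a[:, None] > b[None, :]).sum()
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        g = pooled[list(combo)]
        r = np.delete(pooled, list(combo))
        us.append((g[:, None] > r[None, :]).sum())
    us = np.array(us)
    mean_u = n1 * (len(pooled) - n1) / 2
    return np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("n1,n2", [(3, 4), (4, 5), (4, 8)])
def test_mwu_matches_exact_enumeration(seed, n1, n2):
    # groups below the KS gate's minimum always route to Mann-Whitney,
    # where scipy uses the exact null for small tie-free samples
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, n1)
    b = rng.normal(0.8, 1, n2)
    res = bs.compare_groups(a, b)
    assert res.test_name == "mann_whitney"
    assert res.p_value == pytest.approx(_exact_mwu_pvalue(a, b), abs=1e-9)


# --- ROC AUC ----------------------------------------------------------------


def test_auc_examples():
    assert bs.empirical_auc([4, 5], [1, 2, 3]) == 1.0
    assert bs.empirical_auc([1, 2, 3], [1, 2, 3]) == 0.5
    assert bs.empirical_auc([2, 4], [1, 3]) == 0.75
    with pytest.raises(ValueError):
        bs.empirical_auc([], [1.0])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    pos=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=25),
    neg=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=25),
)
def test_auc_brute_force_and_complement(pos, neg):
    auc = bs.empirical_auc(pos, neg)
    brute = np.mean(
        [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
    )
    assert auc == pytest.approx(brute, abs=1e-12)
    assert bs.empirical_auc(neg, pos) == pytest.approx(1 - auc, abs=1e-12)


def test_auc_monotone_transform_invariance():
    rng = np.random.default_rng(12)
    pos, neg = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
    base = bs.empirical_auc(pos, neg)
    assert bs.empirical_auc(np.exp(pos), np.exp(neg)) == pytest.approx(base)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(13)
    pos, neg = rng.normal(1, 1, 25), rng.normal(0, 1, 35)
    y = np.r_[np.ones(25), np.zeros(35)]
    assert bs.empirical_auc(pos, neg) == pytest.approx(
        roc_auc_score(y, np.r_[pos, neg])
    )


# --- Kaplan-Meier -----------------------------------------------------------


def _records(times, events, markers=None):
    markers = markers if markers is not None else [0.0] * len(times)
    return [
        bs.SurvivalRecord(t, e, m) for t, e, m in zip(times, events, markers)
    ]


def test_km_hand_examples():
    km = bs.km_estimate(_records([1, 2, 3], [True] * 3))
    np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    km2 = bs.km_estimate(_records([1, 2], [False, True]))
    assert km2.survival_at(1) == 1.0
    assert km2.survival_at(2) == 0.0
    km3 = bs.km_estimate(_records([1, 2, 3], [False] * 3))
    assert km3.times.size == 0


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(14)
    times = rng.exponential(10, 80)
    km = bs.km_estimate(_records(times, [True] * 80))
    for t in np.quantile(times, [0.1, 0.5, 0.9]):
        assert km.survival_at(t) == pytest.approx(np.mean(times > t), abs=1e-12)


def test_km_matches_lifelines_with_censoring():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(15)
    times = rng.exponential(10, 60)
    events = rng.uniform(size=60) < 0.7
    km = bs.km_estimate(_records(times, events))
    kmf = KaplanMeierFitter().fit(times, events)
    for t in [1.0, 5.0, 15.0]:
        assert km.survival_at(t) == pytest.approx(
            float(kmf.predict(t)), abs=1e-9
        )


# --- log-rank ---------------------------------------------------------------


def test_logrank_identical_groups_null():
    g = _records([1, 2, 3, 4], [True] * 4)
    res = bs.logrank_test(g, list(g))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_separated_groups():
    a = _records([1, 2, 3], [True] * 3)
    b = _records([10, 20, 30], [True] * 3)
    assert bs.logrank_test(a, b).p_value < 0.05


def test_logrank_single_shared_time_symmetric():
    a = _records([5.0], [True])
    b = _records([5.0], [True])
    assert bs.logrank_test(a, b).statistic == pytest.approx(0.0, abs=1e-12)


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(16)
    ta, tb = rng.exponential(10, 40), rng.exponential(18, 35)
    ea = rng.uniform(size=40) < 0.8
    eb = rng.uniform(size=35) < 0.8
    ours = bs.logrank_test(_records(ta, ea), _records(tb, eb))
    theirs = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
    assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)


def test_logrank_equals_cox_score_without_ties():
    rng = np.random.default_rng(17)
    a = _records(rng.exponential(10, 30), [True] * 30)
    b = _records(rng.exponential(25, 30), [True] * 30)
    lr = bs.logrank_test(a, b)
    score = bs.logrank_from_cox_score(a, b)
    assert lr.statistic == pytest.approx(score, abs=1e-6)


# --- median split -----------------------------------------------------------


def test_median_split_examples():
    recs = _records([1] * 4, [True] * 4, markers=[1, 2, 3, 4])
    high, low = bs.median_split(recs)
    assert sorted(r.marker for r in high) == [3, 4]
    assert sorted(r.marker for r in low) == [1, 2]


def test_median_split_odd_n_median_goes_high():
    recs = _records([1] * 5, [True] * 5, markers=[1, 2, 3, 4, 5])
    high, low = bs.median_split(recs)
    assert 3 in {r.marker for r in high}
    assert len(high) == 3 and len(low) == 2


def test_median_split_fifteen_records():
    recs = _records([1] * 15, [True] * 15, markers=list(range(15)))
    high, low = bs.median_split(recs)
    assert (len(high), len(low)) == (8, 7)


def test_median_split_degenerate():
    with pytest.raises(ValueError):
        bs.median_split(_records([1, 2], [True, True], markers=[5, 5]))


# --- Cox --------------------------------------------------------------------


def test_cox_null_hr_near_one():
    recs = bs.simulate_cohort(
        200, 1.0, seed=6, marker_low=(0, 0), marker_high=(1, 0),
        censor_horizon_months=1e9,
    )
    fit = bs.cox_univariate(recs, binary=True)
    assert 0.8 <= fit.hr <= 1.25


def test_cox_recovers_binary_hr_two():
    recs = bs.simulate_cohort(
        500, 2.0, seed=1, marker_low=(0, 0), marker_high=(1, 0),
        censor_horizon_months=1e9,
    )
    fit = bs.cox_univariate(recs, binary=True)
    assert fit.converged
    assert abs(fit.hr - 2.0) / 2.0 <= 0.15


def test_cox_matches_lifelines():
    import pandas as pd
    from lifelines import CoxPHFitter

    # tie-free data (no administrative censoring) so Efron == Breslow
    recs = bs.simulate_cohort(150, 3.0, seed=9, censor_horizon_months=1e9)
    df = pd.DataFrame(
        {
            "t": [r.time for r in recs],
            "e": [r.event for r in recs],
            "x": [r.marker for r in recs],
        }
    )
    theirs = CoxPHFitter().fit(df, "t", "e")
    ours = bs.cox_univariate(recs, binary=False)
    # lifelines stops at its own (looser) gradient tolerance
    assert ours.beta == pytest.approx(float(theirs.params_["x"]), abs=5e-4)
    assert ours.se == pytest.approx(float(theirs.standard_errors_["x"]), abs=5e-4)


def test_cox_monotone_likelihood_flagged():
    # events perfectly ordered by the covariate -> diverging beta
    recs = _records(
        [1, 2, 3, 4, 5, 6], [True] * 6, markers=[6, 5, 4, 3, 2, 1]
    )
    fit = bs.cox_univariate(recs, binary=False)
    assert not fit.converged
    assert 10.0 <= abs(fit.beta) <= 20.0


def test_cox_preconditions():
    with pytest.raises(ValueError):
        bs.cox_univariate(_records([1, 2], [True, False], markers=[1, 2]))


# --- Schoenfeld power -------------------------------------------------------


def test_schoenfeld_null_hr():
    assert bs.schoenfeld_power(1.0, 100) == pytest.approx(0.025, abs=1e-3)


def test_schoenfeld_printed_powers():
    assert round(bs.schoenfeld_power(8.861, 5), 2) == 0.68
    assert round(bs.schoenfeld_power(8.861, 6), 2) == 0.76


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    d=st.integers(1, 200),
    hr=st.floats(1.01, 50.0),
)
def test_schoenfeld_monotone(d, hr):
    assert bs.schoenfeld_power(hr, d + 1) >= bs.schoenfeld_power(hr, d)
    assert bs.schoenfeld_power(hr * 1.5, d) >= bs.schoenfeld_power(hr, d)


def test_schoenfeld_domain():
    with pytest.raises(ValueError):
        bs.schoenfeld_power(-1.0, 5)
    with pytest.raises(ValueError):
        bs.schoenfeld_power(2.0, 0)
    with pytest.raises(ValueError):
        bs.schoenfeld_power(2.0, 5, p_alloc=1.0)


def test_simulate_cohort_deterministic():
    a = bs.simulate_cohort(30, 2.0, seed=21)
    b = bs.simulate_cohort(30, 2.0, seed=21)
    assert [(r.time, r.event, r.marker) for r in a] == [
        (r.time, r.event, r.marker) for r in b
    ]
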