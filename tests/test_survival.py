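import numpy as np
import pandas as pd
import pytest

from drivenet import io as omio
from drivenet.network import PairScore
from drivenet.survival import (
    SingularInformationError,
    adjusted_cox,
    cox_partial_loglik,
    evaluate_pairs,
    fit_cox,
    km_estimate,
    logrank_test,
    pair_risk_score,
    td_auc,
    univariate_screen,
)


def grid_cox(x, time, event, lo=-5.0, hi=5.0, step=1e-3):
    """Independent maximizer of the Breslow partial likelihood (1 covariate)."""
    betas = np.arange(lo, hi + step / 2, step)
    ll = [cox_partial_loglik(np.asarray(x)[:, None], time, event, np.array([b]))
          for b in betas]
    return betas[int(np.argmax(ll))]


# ---------------------------------------------------------------------------
# Cox


def test_cox_matches_grid_oracle_on_small_datasets(rng):
    datasets = [
        # the worked example: times 1..4, all events, alternating covariate
        (np.array([1.0, 0.0, 1.0, 0.0]), np.array([1.0, 2, 3, 4]), np.ones(4)),
        (np.array([0.0, 1.0, 0.0, 1.0, 1.0]), np.array([2.0, 2, 3, 5, 6]),
         np.array([1, 1, 0, 1, 1])),
        (np.array([0.5, -1.0, 0.0, 2.0, 1.0, -0.5]), np.array([3.0, 1, 4, 2, 5, 6]),
         np.array([1, 1, 1, 0, 1, 0])),
    ]
    for x, t, e in datasets:
        fit = fit_cox(x[:, None], t, e)
        assert fit.converged
        assert abs(fit.beta[0] - grid_cox(x, t, e)) <= 2e-3

    worked = fit_cox(datasets[0][0][:, None], datasets[0][1], datasets[0][2])
    assert worked.beta[0] == pytest.approx(0.9403, abs=2e-3)


def test_cox_null_covariate_recovery(rng):
    n = 400
    x = rng.normal(size=n)
    t = rng.exponential(100.0, size=n)
    e = np.ones(n)
    fit = fit_cox(x[:, None], t, e)
    assert abs(fit.beta[0]) < 3 * fit.se[0]
    assert fit.hr_low[0] <= fit.hr[0] <= fit.hr_high[0]


def test_cox_parameter_recovery_under_ph_model(rng):
    n = 1000
    x = rng.normal(size=n)
    t_event = rng.exponential(1.0 / np.exp(0.7 * x))
    t_cens = rng.exponential(np.quantile(t_event, 0.8), size=n)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    fit = fit_cox(x[:, None], time, event)
    assert fit.converged
    assert fit.beta[0] == pytest.approx(0.7, abs=3 * fit.se[0])


def test_cox_matches_lifelines(rng):
    """Independent cross-check against lifelines.

    Tie-free times, where the Breslow likelihood used here coincides with
    lifelines' Efron handling.
    """
    from lifelines import CoxPHFitter

    n = 80
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.4, size=n).astype(float)
    t = rng.exponential(50.0 / np.exp(0.5 * x1 - 0.3 * x2))
    e = rng.random(n) < 0.8
    df = pd.DataFrame({"t": t, "e": e.astype(int), "x1": x1, "x2": x2})
    cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    fit = fit_cox(df[["x1", "x2"]], t, e)
    np.testing.assert_allclose(fit.beta, cph.params_[["x1", "x2"]], atol=1e-5)
    np.testing.assert_allclose(fit.se, cph.standard_errors_[["x1", "x2"]], atol=1e-5)


def test_cox_error_modes():
    with pytest.raises(ValueError, match="constant"):
        fit_cox(np.ones((5, 1)), np.arange(1.0, 6), np.ones(5))
    with pytest.raises(ValueError, match="event"):
        fit_cox(np.arange(5.0)[:, None], np.arange(1.0, 6), np.zeros(5))
    # perfectly collinear design -> singular information
    x = np.arange(6.0)
    with pytest.raises(SingularInformationError):
        fit_cox(np.column_stack([x, 2 * x]), np.arange(1.0, 7), np.ones(6))
    # complete separation: flagged, not silently reported as converged
    x = np.array([1.0, 1, 1, 0, 0, 0])
    t = np.array([1.0, 2, 3, 10, 11, 12])
    fit = fit_cox(x[:, None], t, np.ones(6))
    assert not fit.converged


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_worked_example():
    curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
    assert curve.survival[0] == pytest.approx(2 / 3)
    assert curve.survival[-1] == pytest.approx(0.0)
    assert curve.at(2.5) == pytest.approx(2 / 3)
    assert curve.at(0.5) == 1.0


def test_km_degenerate_cases(rng):
    all_censored = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert all_censored.times.size == 0 and all_censored.at(99) == 1.0
    # no censoring: equals the empirical survivor function
    t = rng.exponential(10, size=50)
    curve = km_estimate(t, np.ones(50))
    for q in np.quantile(t, [0.2, 0.5, 0.9]):
        assert curve.at(q) == pytest.approx((t > q).mean())
    # nonincreasing in [0, 1]
    assert (np.diff(curve.survival) <= 1e-12).all()
    assert ((curve.survival >= 0) & (curve.survival <= 1)).all()


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter

    t = np.ceil(rng.exponential(20, size=60))
    e = rng.random(60) < 0.7
    curve = km_estimate(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for tau in curve.times:
        assert curve.at(tau) == pytest.approx(
            float(kmf.survival_function_at_times(tau).iloc[0]), abs=1e-10
        )


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_worked_example():
    time = np.array([1.0, 2, 3, 4, 5, 6])
    event = np.ones(6)
    group = np.array(["a", "a", "a", "b", "b", "b"])
    chi2, p = logrank_test(time, event, group)
    assert chi2 == pytest.approx(5.0516, abs=1e-3)
    assert p == pytest.approx(0.0246, abs=1e-3)


def test_logrank_identical_groups_and_errors():
    t = np.array([1.0, 2, 3, 1, 2, 3])
    e = np.ones(6)
    g = np.array(list("aaabbb"))
    chi2, p = logrank_test(t, e, g)
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
    with pytest.raises(ValueError, match="two groups"):
        logrank_test(t, e, np.array(list("aaaaaa")))
    with pytest.raises(ValueError, match="event"):
        logrank_test(t, np.zeros(6), g)


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    t = np.ceil(rng.exponential(20, size=80))
    e = rng.random(80) < 0.8
    g = rng.random(80) < 0.5
    chi2, p = logrank_test(t, e, np.where(g, "hi", "lo"))
    ref = ll_logrank(t[g], t[~g], e[g], e[~g])
    assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
    assert p == pytest.approx(ref.p_value, abs=1e-8)


# ---------------------------------------------------------------------------
# risk scores and pair evaluation


def _mini_clinical(n, rng, times=None, events=None):
    samples = [f"T{i:03d}" for i in range(n)]
    return omio.ClinicalTable(
        table=pd.DataFrame(
            {
                "os_time": times if times is not None else rng.exponential(1000, n) + 1,
                "os_event": events if events is not None else rng.integers(0, 2, n),
                "age_group": rng.choice(["young", "old"], n),
                "er": rng.choice(["pos", "neg"], n),
                "pr": rng.choice(["pos", "neg"], n),
                "stage": rng.choice(["early", "late"], n),
            },
            index=pd.Index(samples, name="sample"),
        )
    )


def test_pair_risk_score_median_split(small_cohort):
    cohort, truth = small_cohort
    prog = pair_risk_score(cohort.expression, cohort.clinical, truth.surv_pair)
    assert not prog.dropped
    n = len(prog.risk_group)
    n_high = (prog.risk_group == "high").sum()
    assert abs(n_high - n / 2) <= 0.5  # continuous scores: an even split
    # high-risk group dies faster
    clin = cohort.clinical.table
    hi = prog.risk_group == "high"
    rate_hi = clin.loc[hi[hi].index, "os_event"].mean()
    rate_lo = clin.loc[hi[~hi].index, "os_event"].mean()
    assert rate_hi > rate_lo


def test_risk_score_invariant_to_expression_shift(small_cohort):
    """Adding a constant to one gene's expression changes nothing downstream."""
    cohort, truth = small_cohort
    base = pair_risk_score(cohort.expression, cohort.clinical, truth.surv_pair)
    shifted_values = cohort.expression.values.copy()
    shifted_values.loc[truth.surv_pair[0]] += 7.5
    shifted = omio.ExpressionMatrix(values=shifted_values, group=cohort.expression.group)
    other = pair_risk_score(shifted, cohort.clinical, truth.surv_pair)
    assert (base.risk_group == other.risk_group).all()
    np.testing.assert_allclose(base.beta, other.beta, atol=1e-6)


def test_adjusted_cox_collinearity_and_null_confounding(rng):
    n = 120
    clin = _mini_clinical(n, rng, events=np.ones(n, dtype=int))
    risk = pd.Series(rng.random(n) < 0.5, index=clin.table.index).map(
        {True: "high", False: "low"}
    )
    from drivenet.survival import PairPrognosis

    prog = PairPrognosis(driver="a", drg="b", risk_group=risk)
    fit = adjusted_cox(prog, clin)
    assert "risk_high" in fit.names
    # covariates independent of outcome: adjusted ~ unadjusted within 3 SE
    t = clin.table["os_time"].to_numpy()
    e = clin.table["os_event"].to_numpy()
    unadj = fit_cox((risk == "high").to_numpy(float)[:, None], t, e)
    i = fit.names.index("risk_high")
    assert abs(fit.beta[i] - unadj.beta[0]) < 3 * unadj.se[0]

    # risk group perfectly collinear with stage -> singular information
    clin2 = _mini_clinical(n, rng, events=np.ones(n, dtype=int))
    risk2 = pd.Series(
        np.where(clin2.table["stage"] == "late", "high", "low"),
        index=clin2.table.index,
    )
    prog2 = PairPrognosis(driver="a", drg="b", risk_group=risk2)
    with pytest.raises(SingularInformationError):
        adjusted_cox(prog2, clin2)


def test_univariate_screen_threshold(small_cohort):
    cohort, truth = small_cohort
    genes = list(truth.surv_pair) + [g for g in cohort.expression.genes[-5:]]
    kept = univariate_screen(cohort.expression, cohort.clinical, genes)
    assert set(truth.surv_pair) <= kept  # planted genes pass p < 0.1
    everything = univariate_screen(cohort.expression, cohort.clinical, genes,
                                   p_thresh=1.0)
    assert set(genes) <= everything


def test_evaluate_pairs_flags_planted_not_null(small_cohort, small_network):
    cohort, truth = small_cohort
    d0, r0 = truth.surv_pair
    null_drivers = [g for g in cohort.expression.genes[300:320]]
    cands = [PairScore(d0, r0, "methylation", 0.9, 0.9, 0.9)] + [
        PairScore(d, r0 if i % 2 else "G0031", "methylation", 0.5, 0.5, 0.5)
        for i, d in enumerate(null_drivers)
    ]
    res = evaluate_pairs(cands, cohort.expression, cohort.clinical)
    planted = res[0]
    assert not planted.dropped and planted.flagged
    null_flags = [r.flagged for r in res[1:] if {r.driver, r.drg} & {d0, r0} == set()]
    assert np.mean(null_flags) <= 0.05 or sum(null_flags) <= 1
    assert evaluate_pairs([], cohort.expression, cohort.clinical) == []


# ---------------------------------------------------------------------------
# time-dependent AUC


def test_td_auc_no_censoring_is_plain_auc(rng):
    n = 100
    scores = rng.normal(size=n)
    time = rng.exponential(10, size=n)
    event = np.ones(n)
    h = np.median(time)
    cases = time <= h
    # plain Mann-Whitney of scores for the indicator time <= h
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n1 = cases.sum()
    plain = (ranks[cases].sum() - n1 * (n1 + 1) / 2) / (n1 * (n - n1))
    assert td_auc(scores, time, event, h) == pytest.approx(plain, abs=1e-12)


def test_td_auc_perfect_and_null(rng):
    n = 200
    time = rng.exponential(10, size=n)
    event = np.ones(n)
    assert td_auc(-time, time, event, np.median(time)) == 1.0
    aucs = [
        td_auc(rng.normal(size=n), time, event, np.median(time)) for _ in range(200)
    ]
    se = np.std(aucs) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 0.5) < 3 * se
    # no cases before horizon -> undefined
    assert td_auc(rng.normal(size=n), time, event, time.min() / 2) is None


def test_td_auc_matches_sksurv(rng):
    """Cross-check the IPCW estimator against scikit-survival."""
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    n = 300
    x = rng.normal(size=n)
    t_event = rng.exponential(10.0 / np.exp(0.8 * x))
    t_cens = rng.exponential(15.0, size=n)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    y = Surv.from_arrays(event=event, time=time)
    horizon = np.quantile(time, 0.5)
    ref_auc, _ = cumulative_dynamic_auc(y, y, x, [horizon])
    ours = td_auc(x, time, event, horizon)
    assert ours == pytest.approx(float(ref_auc[0]), abs=0.02)
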