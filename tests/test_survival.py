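"""Cox fitting against brute-force oracles; C-index, log-rank, KM, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reopair import synthetic as syn
from reopair.io import SurvivalCohort
from reopair.survival import (
    bh_adjust,
    concordance_index,
    cox_hr_binary,
    cox_univariate,
    km_curve,
    logrank_test,
    screen_survival_genes,
)


def efron_loglik(beta, x, time, event):
    """Brute-force Efron partial log-likelihood (independent of the fitter)."""
    ll = 0.0
    for tt in np.unique(time[event == 1]):
        dead = (time == tt) & (event == 1)
        risk = time >= tt
        d = int(dead.sum())
        w = np.exp(beta * x)
        s0r, s0d = w[risk].sum(), w[dead].sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(s0r - (l / d) * s0d)
    return ll


def test_cox_matches_partial_likelihood_grid(four_sample_cohort):
    x = np.array([0.5, 1.0, -0.5, -1.0])
    fit = cox_univariate(x, four_sample_cohort)
    grid = np.arange(-5.0, 5.0, 1e-4)
    lls = [efron_loglik(b, x, four_sample_cohort.time, four_sample_cohort.event)
           for b in grid]
    assert fit.converged
    assert abs(fit.beta - grid[int(np.argmax(lls))]) < 1e-3


def test_cox_matches_grid_on_censored_tied_fixture():
    cohort = SurvivalCohort(
        tuple("abcdef"),
        np.array([3.0, 3.0, 5.0, 7.0, 7.0, 9.0]),
        np.array([1, 1, 0, 1, 1, 0]),
    )
    x = np.array([1.2, -0.3, 0.8, -1.0, 0.1, 0.5])
    fit = cox_univariate(x, cohort)
    grid = np.arange(-5.0, 5.0, 1e-4)
    lls = [efron_loglik(b, x, cohort.time, cohort.event) for b in grid]
    assert abs(fit.beta - grid[int(np.argmax(lls))]) < 1e-3


def test_cox_agrees_with_lifelines(four_sample_cohort):
    from lifelines import CoxPHFitter

    x = np.array([0.5, 1.0, -0.5, -1.0])
    fit = cox_univariate(x, four_sample_cohort)
    df = pd.DataFrame(
        {"t": four_sample_cohort.time, "e": four_sample_cohort.event, "x": x}
    )
    cph = CoxPHFitter().fit(df, "t", "e")
    assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-3)
    assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)


def test_cox_constant_covariate_is_degenerate(four_sample_cohort):
    fit = cox_univariate(np.ones(4), four_sample_cohort)
    assert fit.beta == 0.0
    assert fit.p == 1.0
    assert not fit.converged
    assert fit.reason == "degenerate"


def test_cox_negating_covariate_negates_beta(four_sample_cohort):
    x = np.array([0.5, 1.0, -0.5, -1.0])
    a = cox_univariate(x, four_sample_cohort)
    b = cox_univariate(-x, four_sample_cohort)
    assert a.beta == pytest.approx(-b.beta, abs=1e-12)
    assert a.p == pytest.approx(b.p, abs=1e-12)


def test_cox_requires_events():
    cohort = SurvivalCohort(("a", "b"), np.array([1.0, 2.0]), np.array([0, 0]))
    with pytest.raises(ValueError, match="events"):
        cox_univariate(np.array([0.0, 1.0]), cohort)


def test_cox_flags_separation():
    # perfectly ordered covariate with all events: monotone likelihood
    cohort = SurvivalCohort(
        tuple("abcdef"),
        np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        np.ones(6, dtype=int),
    )
    fit = cox_univariate(np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0]), cohort)
    assert not fit.converged
    assert fit.reason == "separation"
    assert np.isnan(fit.p)


def test_bh_hand_example():
    assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


@given(st.permutations(list(range(6))))
@settings(deadline=None, max_examples=20, derandomize=True)
def test_bh_is_order_equivariant(perm):
    p = np.array([0.001, 0.2, 0.04, 0.9, 0.5, 0.011])
    direct = bh_adjust(p)
    permuted = bh_adjust(p[perm])
    assert np.allclose(permuted, direct[perm])


def test_concordance_index_worked_cases():
    all_events = SurvivalCohort(
        ("a", "b", "c"), np.array([1.0, 2.0, 3.0]), np.ones(3, dtype=int)
    )
    assert concordance_index([3, 2, 1], all_events) == 1.0
    assert concordance_index([5, 5, 5], all_events) == 0.5
    censored = SurvivalCohort(
        ("a", "b", "c", "d"),
        np.array([1.0, 2.0, 3.0, 4.0]),
        np.array([1, 1, 0, 1]),
    )
    assert concordance_index([4, 1, 3, 2], censored) == pytest.approx(3 / 5)


def test_concordance_index_brute_force_random_instances():
    """C equals an exhaustive pair loop on 50 random 8-sample instances."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        t = rng.uniform(1, 10, size=8)
        e = rng.integers(0, 2, size=8)
        if e.sum() == 0:
            e[0] = 1
        r = rng.normal(size=8)
        cohort = SurvivalCohort(tuple(f"s{i}" for i in range(8)), t, e)
        conc = ties = comp = 0
        for i in range(8):
            for j in range(8):
                if t[i] < t[j] and e[i] == 1:
                    comp += 1
                    if r[i] > r[j]:
                        conc += 1
                    elif r[i] == r[j]:
                        ties += 1
        assert concordance_index(r, cohort) == pytest.approx(
            (conc + 0.5 * ties) / comp
        )


def test_concordance_negation_flips_c_without_ties():
    rng = np.random.default_rng(3)
    t = rng.uniform(1, 10, size=12)
    e = rng.integers(0, 2, size=12)
    e[0] = 1
    r = rng.normal(size=12)
    cohort = SurvivalCohort(tuple(f"s{i}" for i in range(12)), t, e)
    assert concordance_index(r, cohort) == pytest.approx(
        1.0 - concordance_index(-r, cohort)
    )


def _logrank_oracle(t, e, g):
    """Observed-minus-expected over event times, by hand."""
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & (g == "high")).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (g == "high")).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_matches_hand_computation():
    t = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    e = np.array([1, 1, 0, 1, 1, 1])
    g = np.array(["high", "low", "high", "low", "high", "low"])
    cohort = SurvivalCohort(tuple(f"s{i}" for i in range(6)), t, e)
    chi2, p = logrank_test(g, cohort)
    assert chi2 == pytest.approx(_logrank_oracle(t, e, g), rel=1e-6)


def test_logrank_is_symmetric_and_null_on_identical_groups():
    t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    e = np.array([1, 0, 1, 1, 0, 1])
    g = np.array(["high"] * 3 + ["low"] * 3)
    cohort = SurvivalCohort(tuple(f"s{i}" for i in range(6)), t, e)
    chi2, p = logrank_test(g, cohort)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    swapped = np.where(g == "high", "low", "high")
    chi2b, _ = logrank_test(swapped, cohort)
    assert chi2 == pytest.approx(chi2b, abs=1e-12)


def test_km_closed_forms():
    no_events = SurvivalCohort(("a", "b"), np.array([1.0, 2.0]), np.array([0, 0]))
    km = km_curve(no_events)
    assert (km["survival"] == 1.0).all()

    both = SurvivalCohort(("a", "b"), np.array([1.0, 2.0]), np.array([1, 1]))
    km = km_curve(both)
    surv = dict(zip(km["time"], km["survival"]))
    assert surv[1.0] == pytest.approx(0.5)
    assert surv[2.0] == pytest.approx(0.0)

    censored_tail = SurvivalCohort(
        ("a", "b", "c"), np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0])
    )
    km = km_curve(censored_tail)
    assert km["survival"].iloc[-1] == pytest.approx(2 / 3)


def test_cox_hr_binary_inverts_under_group_swap():
    rng = np.random.default_rng(3)
    t = rng.exponential(10, size=200)
    e = np.ones(200, dtype=int)
    g = np.where(rng.uniform(size=200) < 0.5, "high", "low")
    cohort = SurvivalCohort(tuple(f"s{i}" for i in range(200)), t, e)
    hr, ci, p = cox_hr_binary(g, cohort)
    assert abs(np.log(hr)) < 0.3  # null data
    swapped = np.where(g == "high", "low", "high")
    hr2, _, p2 = cox_hr_binary(swapped, cohort)
    assert hr2 == pytest.approx(1.0 / hr, rel=1e-9)
    assert p2 == pytest.approx(p, rel=1e-9)


def test_cox_hr_binary_rejects_single_group():
    cohort = SurvivalCohort(("a", "b"), np.array([1.0, 2.0]), np.array([1, 1]))
    with pytest.raises(ValueError):
        cox_hr_binary(["high", "high"], cohort)


def test_screen_recovers_most_planted_genes():
    """12 planted genes at |beta| = 1, n = 250: the univariate screen finds
    nearly all of them with the correct sign at FDR < 0.2. (Univariate
    coefficients are attenuated by the other planted genes acting as
    frailty, so recovery below 100% is expected.)"""
    planted = {f"G{i:04d}": (1.0 if i % 2 else -1.0) for i in range(1, 13)}
    cfg = syn.TissueSimConfig(
        n_genes=300, n_samples=250, beta_map=planted,
        baseline=syn.ExponentialBaseline(0.015), censor_horizon=120.0, seed=1,
    )
    expr, cohort, _ = syn.simulate_tissue(cfg)
    table, signed = screen_survival_genes(expr, cohort, 0.2)
    correct = sum(
        1 for g in planted
        if g in signed and signed.sign(g) == (1 if planted[g] > 0 else -1)
    )
    assert correct >= 10
    # and no planted gene is called with the wrong sign
    wrong = sum(
        1 for g in planted
        if g in signed and signed.sign(g) != (1 if planted[g] > 0 else -1)
    )
    assert wrong == 0


def test_screen_null_simulation_calls_almost_nothing():
    """Empty beta map: the screen calls <= 2% of genes on average (20 seeds)."""
    rates = []
    for seed in range(20):
        cfg = syn.TissueSimConfig(
            n_genes=150, n_samples=100, beta_map={},
            baseline=syn.ExponentialBaseline(0.02),
            censor_horizon=120.0, seed=300 + seed,
        )
        expr, cohort, _ = syn.simulate_tissue(cfg)
        _, signed = screen_survival_genes(expr, cohort, 0.2)
        rates.append(len(signed) / 150)
    assert np.mean(rates) <= 0.02


def test_screen_fdr_one_returns_all_informative_genes():
    cfg = syn.TissueSimConfig(
        n_genes=30, n_samples=60, beta_map={},
        baseline=syn.ExponentialBaseline(0.02), censor_horizon=120.0, seed=2,
    )
    expr, cohort, _ = syn.simulate_tissue(cfg)
    table, signed = screen_survival_genes(expr, cohort, 1.0)
    assert len(signed) == len(table) == 30
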