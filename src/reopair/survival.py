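"""Survival-analysis primitives: univariate Cox screening, BH adjustment,
Harrell's C-index, log-rank test, Kaplan–Meier curves, binary-group hazard
ratios.

The univariate Cox fit is a dedicated single-covariate Newton–Raphson
maximizer of the Efron partial likelihood. A bespoke fit is used because the
screening stages call it tens of thousands of times (every gene, then every
candidate gene pair); general-purpose fitters carry per-call overhead that
dominates at that scale. Efron tie handling matches the defaults of the
major survival libraries, which also serve as independent cross-checks in
the test suite. P-values are two-sided Wald.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SignedGeneList, SurvivalCohort, align_samples

logger = logging.getLogger(__name__)

SCORE_TOL = 1e-9
MAX_ITER = 50
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox fit: log hazard ratio per covariate unit with Wald stats."""

    beta: float
    se: float
    z: float
    p: float
    converged: bool
    reason: str = ""


def _efron_quantities(
    beta: float,
    x: np.ndarray,
    order: np.ndarray,
    time_sorted: np.ndarray,
    event_sorted: np.ndarray,
) -> tuple[float, float, float]:
    """Log partial likelihood, score and information under Efron ties.

    Inputs are pre-sorted by ascending time; suffix sums give the risk-set
    aggregates in O(n).
    """
    xs = x[order]
    eta = beta * xs
    w = np.exp(eta)
    # suffix sums over the risk set {j : t_j >= t_i}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xs)[::-1])[::-1]
    s2 = np.cumsum((w * xs * xs)[::-1])[::-1]

    ll = 0.0
    score = 0.0
    info = 0.0
    n = len(xs)
    i = 0
    while i < n:
        j = i
        while j < n and time_sorted[j] == time_sorted[i]:
            j += 1
        ev = event_sorted[i:j].astype(bool)
        d = int(ev.sum())
        if d > 0:
            xd = xs[i:j][ev]
            wd = w[i:j][ev]
            s0d = wd.sum()
            s1d = (wd * xd).sum()
            s2d = (wd * xd * xd).sum()
            ll += beta * xd.sum()
            for l in range(d):
                f = l / d
                phi0 = s0[i] - f * s0d
                phi1 = s1[i] - f * s1d
                phi2 = s2[i] - f * s2d
                ll -= np.log(phi0)
                score -= phi1 / phi0
                info += phi2 / phi0 - (phi1 / phi0) ** 2
            score += xd.sum()
        i = j
    return ll, score, info


def cox_univariate(
    x: Sequence[float] | np.ndarray, cohort: SurvivalCohort
) -> CoxFit:
    """Fit a single-covariate Cox proportional-hazards model.

    Returns a degenerate fit (beta 0, p 1, ``converged=False``) for a
    constant covariate, and flags monotone-likelihood separation
    (|beta| escaping past 15 during iteration) as non-converged with the
    beta clamped and p undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (cohort.n_samples,):
        raise ValueError(
            f"covariate length {x.shape} does not match cohort "
            f"({cohort.n_samples} samples)"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    if cohort.n_events < 1:
        raise ValueError("cohort has no events; Cox model is not identifiable")
    if np.ptp(x) == 0.0:
        return CoxFit(0.0, np.nan, np.nan, 1.0, False, "degenerate")

    # center for numerical stability; the partial likelihood is shift-invariant
    xc = x - x.mean()
    order = np.argsort(cohort.time, kind="stable")
    ts = cohort.time[order]
    es = cohort.event[order]

    beta = 0.0
    ll, score, info = _efron_quantities(beta, xc, order, ts, es)
    for _ in range(MAX_ITER):
        if abs(score) < SCORE_TOL:
            break
        if info <= 0:
            return CoxFit(np.sign(score) * SEPARATION_BETA, np.nan, np.nan,
                          np.nan, False, "separation")
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _efron_quantities(new_beta, xc, order, ts, es)
        # step-halving safeguard
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _efron_quantities(
                new_beta, xc, order, ts, es
            )
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > SEPARATION_BETA:
            return CoxFit(
                float(np.clip(beta, -SEPARATION_BETA, SEPARATION_BETA)),
                np.nan, np.nan, np.nan, False, "separation",
            )
    converged = abs(score) < SCORE_TOL
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    z = beta / se if se and np.isfinite(se) else np.nan
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
    p = min(max(p, np.nextafter(0, 1)), 1.0) if np.isfinite(p) else p
    return CoxFit(float(beta), float(se), float(z), p, bool(converged),
                  "" if converged else "max_iter")


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_survival_genes(
    expr: ExpressionMatrix,
    cohort: SurvivalCohort,
    fdr: float,
) -> tuple[pd.DataFrame, SignedGeneList]:
    """Univariate Cox per gene with BH adjustment across all tested genes.

    Returns the full screen table (gene, beta, se, z, p, q) over genes whose
    fit is informative, and the signed list of genes passing ``q < fdr``
    with sign(beta). Degenerate or separated genes are excluded and logged.
    ``fdr >= 1`` returns every tested gene.
    """
    if not 0 < fdr:
        raise ValueError("fdr must be positive")
    expr, cohort = align_samples(expr, cohort)
    rows = []
    n_skipped = 0
    values = expr.values.to_numpy()
    for i, gene in enumerate(expr.gene_ids):
        fit = cox_univariate(values[i], cohort)
        if not fit.converged and fit.reason in ("degenerate", "separation"):
            n_skipped += 1
            continue
        rows.append((gene, fit.beta, fit.se, fit.z, fit.p))
    if n_skipped:
        logger.info("screen_survival_genes: excluded %d degenerate/separated genes",
                    n_skipped)
    if not rows:
        raise ValueError("no informative genes to screen")
    table = pd.DataFrame(rows, columns=["gene", "beta", "se", "z", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    if fdr >= 1.0:
        hits = table
    else:
        hits = table[table["q"] < fdr]
    signed = SignedGeneList(
        {
            row.gene: (1 if row.beta > 0 else -1)
            for row in hits.itertuples()
            if row.beta != 0
        }
    )
    return table, signed


def concordance_index(
    risk: Sequence[float] | np.ndarray, cohort: SurvivalCohort
) -> float:
    """Harrell's C: pair (i, j) is comparable iff t_i < t_j and i had the
    event; concordant iff risk_i > risk_j; tied predicted risks count 0.5."""
    risk = np.asarray(risk, dtype=float)
    if risk.shape != (cohort.n_samples,):
        raise ValueError("risk length must match cohort")
    t, e = cohort.time, cohort.event
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (check event/censoring pattern)")
    conc = int((comparable & (risk[:, None] > risk[None, :])).sum())
    ties = int((comparable & (risk[:, None] == risk[None, :])).sum())
    return (conc + 0.5 * ties) / n_comp


def _split_groups(
    groups: Sequence[str], cohort: SurvivalCohort
) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    if groups.shape != (cohort.n_samples,):
        raise ValueError("group labels must match cohort length")
    labels = set(groups.tolist())
    if not labels <= {"high", "low"}:
        raise ValueError(f"group labels must be 'high'/'low', got {sorted(labels)}")
    if len(labels) < 2:
        raise ValueError("both risk groups must be non-empty")
    return groups == "high", groups == "low"


def logrank_test(
    groups: Sequence[str], cohort: SurvivalCohort
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square, p)."""
    hi, lo = _split_groups(groups, cohort)
    if cohort.n_events < 1:
        raise ValueError("no events; log-rank test undefined")
    res = _lifelines_logrank(
        cohort.time[hi], cohort.time[lo],
        event_observed_A=cohort.event[hi], event_observed_B=cohort.event[lo],
    )
    return float(res.test_statistic), float(res.p_value)


def km_curve(cohort: SurvivalCohort) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate as a step table.

    One row per distinct observed time with columns time, n_at_risk,
    n_events, survival; survival starts at 1 and is non-increasing.
    """
    if cohort.n_samples == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.time, cohort.event)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "n_at_risk": table["at_risk"].to_numpy(dtype=int),
            "n_events": table["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    )
    # drop lifelines' synthetic t=0 row unless a real observation sits there
    if out.iloc[0]["time"] == 0.0 and 0.0 not in set(cohort.time.tolist()):
        out = out.iloc[1:].reset_index(drop=True)
    return out


def cox_hr_binary(
    groups: Sequence[str], cohort: SurvivalCohort
) -> tuple[float, tuple[float, float], float]:
    """Hazard ratio of high- vs low-risk group with Wald 95% CI and p-value."""
    hi, _ = _split_groups(groups, cohort)
    fit = cox_univariate(hi.astype(float), cohort)
    hr = float(np.exp(fit.beta))
    if np.isfinite(fit.se):
        ci = (float(np.exp(fit.beta - 1.96 * fit.se)),
              float(np.exp(fit.beta + 1.96 * fit.se)))
    else:
        ci = (np.nan, np.nan)
    return hr, ci, fit.p
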