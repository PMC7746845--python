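"""Relative-expression-ordering (REO) gene-pair signature engine.

A REO indicator compares two genes *within* one sample: it is 1 when the
first gene is expressed strictly above the second. Because it only uses the
within-sample ordering, it is invariant to any strictly increasing
per-sample transform of the expression values — the property that makes
pair signatures portable across platforms and batches.

Signature construction has two steps:

1. *Pair screening* — all C(n, 2) indicators over the candidate genes are
   tested against relapse-free survival with a univariate Cox model; pairs
   passing a BH threshold form Set 2, each orientation-normalized so that
   "gene_hi above gene_lo" carries beta > 0 (votes high risk).
2. *Combination optimization* — every non-empty subset of Set 2 is scored:
   a sample is called low risk when at least half of the subset's rules
   show the sensitivity-associated ordering (indicator 0), and the subset
   maximizing Harrell's C of the resulting binary risk label is the
   signature (Set 3). Ties prefer smaller subsets, then lexicographic rule
   order. A greedy forward search is available for Set 2 sizes where
   exhaustive enumeration is infeasible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SurvivalCohort, align_samples
from .survival import (
    bh_adjust,
    concordance_index,
    cox_hr_binary,
    cox_univariate,
    km_curve,
    logrank_test,
)

logger = logging.getLogger(__name__)

VOTE_RULE = "at_least_half_sensitive_low"
#: exhaustive subset enumeration is refused above this Set 2 size unless
#: the caller bounds the subset size (2^20 - 1 subsets is the accepted max)
MAX_EXHAUSTIVE = 20
_CHUNK = 16384


@dataclass(frozen=True)
class GenePairRule:
    """Oriented gene pair: expressing ``gene_hi`` above ``gene_lo`` votes
    high risk (Cox beta of that indicator is positive)."""

    gene_hi: str
    gene_lo: str
    beta: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.gene_hi == self.gene_lo:
            raise ValueError("a pair rule needs two distinct genes")

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_hi, self.gene_lo)


@dataclass(frozen=True)
class PairSignature:
    """A set of pair rules plus the at-least-half majority-vote rule."""

    rules: tuple[GenePairRule, ...]
    vote_rule: str = VOTE_RULE

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("signature needs >= 1 rule")
        unordered = [frozenset(r.genes) for r in self.rules]
        if len(set(unordered)) != len(unordered):
            raise ValueError("duplicate gene pairs in signature")
        object.__setattr__(self, "rules", tuple(self.rules))

    @property
    def genes(self) -> set[str]:
        return {g for r in self.rules for g in r.genes}

    def to_dict(self) -> dict:
        return {
            "rules": [
                {"gene_hi": r.gene_hi, "gene_lo": r.gene_lo,
                 "beta": r.beta, "p": r.p, "q": r.q}
                for r in self.rules
            ],
            "vote_rule": self.vote_rule,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "PairSignature":
        rules = tuple(
            GenePairRule(r["gene_hi"], r["gene_lo"], r["beta"], r["p"], r["q"])
            for r in payload["rules"]
        )
        return cls(rules, payload.get("vote_rule", VOTE_RULE))

    @classmethod
    def from_json(cls, path: str | Path) -> "PairSignature":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SetLedger:
    """Bookkeeping of the signature search: Set 1 size (all pairs), Set 2
    (survival-associated pairs) and, once optimized, Set 3 with its C."""

    set1_size: int
    set2: tuple[GenePairRule, ...]
    set3: PairSignature | None = None
    set3_cindex: float | None = None


def pair_indicator(expr: ExpressionMatrix, a: str, b: str) -> np.ndarray:
    """Within-sample ordering indicator: 1 iff Expr(a) > Expr(b) strictly.

    Equal values yield 0 (the sensitive-leaning call); ties have measure
    zero on continuous data and are counted by callers that care.
    """
    va = expr.gene_values(a)
    vb = expr.gene_values(b)
    return (va > vb).astype(int)


def _indicator_matrix(
    expr: ExpressionMatrix, genes: Sequence[str]
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    values = expr.values.loc[list(genes)].to_numpy()
    pairs = list(combinations(range(len(genes)), 2))
    ind = np.empty((len(pairs), values.shape[1]), dtype=np.int8)
    for r, (i, j) in enumerate(pairs):
        ind[r] = values[i] > values[j]
    return ind, pairs


def screen_pairs(
    expr: ExpressionMatrix,
    cohort: SurvivalCohort,
    candidates: Sequence[str],
    fdr: float = 0.10,
) -> SetLedger:
    """Step 1: Cox-screen all candidate gene-pair indicators against survival.

    Builds all C(n, 2) indicators (Set 1), drops constant ones (logged),
    fits a univariate Cox model per remaining pair, BH-adjusts across tested
    pairs and keeps q < fdr (Set 2), orientation-normalizing each retained
    pair so beta > 0.
    """
    candidates = list(dict.fromkeys(candidates))
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate genes")
    missing = [g for g in candidates if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"candidate genes absent from matrix: {missing}")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    expr_al, cohort_al = align_samples(expr, cohort)
    ind, pairs = _indicator_matrix(expr_al, candidates)
    set1_size = len(pairs)

    tested: list[tuple[int, "CoxFit"]] = []
    n_constant = 0
    n_failed = 0
    for r in range(set1_size):
        row = ind[r]
        if row.min() == row.max():
            n_constant += 1
            continue
        fit = cox_univariate(row.astype(float), cohort_al)
        if not fit.converged or not np.isfinite(fit.p):
            n_failed += 1
            continue
        tested.append((r, fit))
    if n_constant:
        logger.info("screen_pairs: dropped %d constant indicators", n_constant)
    if n_failed:
        logger.info("screen_pairs: dropped %d non-converged pair fits", n_failed)
    if not tested:
        raise ValueError("no testable gene pairs (all indicators constant)")

    qvals = bh_adjust([fit.p for _, fit in tested])
    rules = []
    for (r, fit), q in zip(tested, qvals):
        if q < fdr:
            i, j = pairs[r]
            a, b = candidates[i], candidates[j]
            if fit.beta >= 0:
                rules.append(GenePairRule(a, b, fit.beta, fit.p, float(q)))
            else:
                rules.append(GenePairRule(b, a, -fit.beta, fit.p, float(q)))
    return SetLedger(set1_size=set1_size, set2=tuple(rules))


def vote_classify(
    expr: ExpressionMatrix, signature: PairSignature
) -> np.ndarray:
    """Majority-vote risk call per sample.

    A rule votes "sensitive" when its risk-oriented indicator is 0 (the
    gene_lo-above-gene_hi ordering, associated with lower hazard). A sample
    is low risk iff sensitive votes >= half the rules (inclusive), else
    high risk. Returns an array of 'high'/'low' aligned with the matrix
    samples.
    """
    missing = sorted(signature.genes - set(expr.gene_ids))
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing}")
    n_rules = len(signature.rules)
    risk_votes = np.zeros(expr.n_samples, dtype=int)
    for rule in signature.rules:
        risk_votes += pair_indicator(expr, rule.gene_hi, rule.gene_lo)
    sensitive_votes = n_rules - risk_votes
    low = sensitive_votes * 2 >= n_rules
    return np.where(low, "low", "high")


def _comparable_structure(cohort: SurvivalCohort) -> tuple[np.ndarray, int]:
    t, e = cohort.time, cohort.event
    a = ((t[:, None] < t[None, :]) & (e[:, None] == 1)).astype(np.float64)
    return a, int(a.sum())


def _binary_cindex_batch(
    risk: np.ndarray, a: np.ndarray, n_comp: int
) -> np.ndarray:
    """Harrell's C for a batch of binary risk vectors (rows) against the
    comparable-pair matrix ``a`` (a[i, j] = 1 iff pair (i, j) comparable)."""
    r = risk.astype(np.float64)
    # conc_c = sum_ij a[i, j] * r_i * (1 - r_j); ties fill the remainder at 0.5
    conc = ((r @ a) * (1.0 - r)).sum(axis=1)
    disc = (((1.0 - r) @ a) * r).sum(axis=1)
    return 0.5 + (conc - disc) / (2.0 * n_comp)


def optimize_combination(
    set2: Sequence[GenePairRule],
    expr: ExpressionMatrix,
    cohort: SurvivalCohort,
    max_size: int | None = None,
) -> tuple[PairSignature, float]:
    """Step 2: exhaustive subset search maximizing Harrell's C.

    Every non-empty subset of Set 2 (up to ``max_size`` rules) is classified
    by majority vote and scored by the C-index of the binary risk label
    (high = 1). The argmax is returned; ties are broken toward smaller
    subsets, then lexicographic rule order (subsets are enumerated in that
    order and only strict improvements replace the incumbent). Set 2 sizes
    above 20 require ``max_size`` to bound the search.
    """
    rules = list(set2)
    if not rules:
        raise ValueError("Set 2 is empty; nothing to optimize")
    if len(rules) > MAX_EXHAUSTIVE and max_size is None:
        raise ValueError(
            f"Set 2 has {len(rules)} pairs: exhaustive enumeration of "
            f"2^{len(rules)}-1 subsets is infeasible. Pass max_size to bound "
            "subset size, or use greedy_combination()."
        )
    expr_al, cohort_al = align_samples(expr, cohort)
    genes_missing = sorted(
        {g for r in rules for g in r.genes} - set(expr_al.gene_ids)
    )
    if genes_missing:
        raise ValueError(f"rule genes absent from matrix: {genes_missing}")

    ind = np.stack(
        [pair_indicator(expr_al, r.gene_hi, r.gene_lo) for r in rules]
    ).astype(np.float64)
    a, n_comp = _comparable_structure(cohort_al)
    if n_comp == 0:
        raise ValueError("no comparable pairs for the C-index")

    k_max = len(rules) if max_size is None else min(max_size, len(rules))
    n_subsets = sum(comb(len(rules), k) for k in range(1, k_max + 1))
    logger.info("optimize_combination: enumerating %d subsets", n_subsets)

    best_c = -np.inf
    best_subset: tuple[int, ...] | None = None
    batch_subsets: list[tuple[int, ...]] = []

    def flush(batch: list[tuple[int, ...]]) -> None:
        nonlocal best_c, best_subset
        if not batch:
            return
        risk = np.empty((len(batch), ind.shape[1]))
        for bi, subset in enumerate(batch):
            votes = ind[list(subset)].sum(axis=0)
            k = len(subset)
            # low risk iff sensitive votes (k - votes) >= k/2  <=>  votes <= k/2
            risk[bi] = (votes * 2 > k).astype(float)
        cs = _binary_cindex_batch(risk, a, n_comp)
        for bi, c in enumerate(cs):
            if c > best_c + 1e-12:
                best_c = float(c)
                best_subset = batch[bi]

    for k in range(1, k_max + 1):
        for subset in combinations(range(len(rules)), k):
            batch_subsets.append(subset)
            if len(batch_subsets) >= _CHUNK:
                flush(batch_subsets)
                batch_subsets = []
    flush(batch_subsets)

    if best_subset is None:
        raise ValueError("no subset produced a valid C-index")
    signature = PairSignature(tuple(rules[i] for i in best_subset))
    return signature, best_c


def greedy_combination(
    set2: Sequence[GenePairRule],
    expr: ExpressionMatrix,
    cohort: SurvivalCohort,
) -> tuple[PairSignature, float]:
    """Greedy forward fallback for large Set 2: repeatedly add the rule that
    most improves the C-index until no addition improves it."""
    rules = list(set2)
    if not rules:
        raise ValueError("Set 2 is empty; nothing to optimize")
    expr_al, cohort_al = align_samples(expr, cohort)
    ind = np.stack(
        [pair_indicator(expr_al, r.gene_hi, r.gene_lo) for r in rules]
    ).astype(np.float64)
    a, n_comp = _comparable_structure(cohort_al)

    chosen: list[int] = []
    best_c = -np.inf
    remaining = set(range(len(rules)))
    while remaining:
        cand = sorted(remaining)
        risk = np.empty((len(cand), ind.shape[1]))
        for bi, idx in enumerate(cand):
            subset = chosen + [idx]
            votes = ind[subset].sum(axis=0)
            risk[bi] = (votes * 2 > len(subset)).astype(float)
        cs = _binary_cindex_batch(risk, a, n_comp)
        bi = int(np.argmax(cs))
        if cs[bi] <= best_c + 1e-12:
            break
        best_c = float(cs[bi])
        chosen.append(cand[bi])
        remaining.discard(cand[bi])
    if not chosen:
        raise ValueError("greedy search found no improving rule")
    return PairSignature(tuple(rules[i] for i in sorted(chosen))), best_c


@dataclass(frozen=True)
class SignatureEvaluation:
    """Survival separation of the signature's risk groups on one cohort."""

    n_high: int
    n_low: int
    hr: float
    hr_ci95: tuple[float, float]
    hr_p: float
    logrank_chi2: float
    logrank_p: float
    km_high: pd.DataFrame | None
    km_low: pd.DataFrame | None


def evaluate_signature(
    signature: PairSignature,
    expr: ExpressionMatrix,
    cohort: SurvivalCohort,
) -> SignatureEvaluation:
    """Classify a cohort and measure RFS separation (HR, log-rank, KM).

    With every sample in one group the metrics are NaN (warning) but group
    sizes are still reported.
    """
    expr_al, cohort_al = align_samples(expr, cohort)
    groups = vote_classify(expr_al, signature)
    hi = groups == "high"
    n_high, n_low = int(hi.sum()), int((~hi).sum())
    if n_high == 0 or n_low == 0:
        warnings.warn(
            "all samples fell in one risk group; survival metrics undefined",
            stacklevel=2,
        )
        km = km_curve(cohort_al)
        return SignatureEvaluation(
            n_high, n_low, np.nan, (np.nan, np.nan), np.nan, np.nan, np.nan,
            km if n_high else None, km if n_low else None,
        )
    hr, ci, hr_p = cox_hr_binary(groups, cohort_al)
    chi2, lr_p = logrank_test(groups, cohort_al)
    km_high = km_curve(cohort_al.subset(
        [s for s, g in zip(cohort_al.sample_ids, groups) if g == "high"]))
    km_low = km_curve(cohort_al.subset(
        [s for s, g in zip(cohort_al.sample_ids, groups) if g == "low"]))
    return SignatureEvaluation(
        n_high, n_low, hr, ci, hr_p, chi2, lr_p, km_high, km_low
    )
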