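"""SAM-style moderated differential expression between resistant and
sensitive groups with permutation-based per-gene q-values.

The statistic is d_g = (mean_resistant − mean_sensitive) / (s_g + s0),
where s_g is the two-group pooled standard error and s0 a small positive
"fudge factor" that stabilizes low-variance genes. The null distribution of
|d| comes from group-label permutations: every distinct label assignment is
enumerated when that is no more work than the requested Monte-Carlo count
(e.g. 3 vs 3 designs have only C(6,3) = 20 assignments), removing
Monte-Carlo noise at typical cell-line sample sizes.

Per-gene q-values use the median false-call count over permutations,
q_g = median_perm #{|d*| >= |d_g|} / #{observed |d| >= |d_g|},
clipped to [0, 1] and made monotone non-increasing in |d|; the null
proportion pi0 is fixed at 1 (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import RESISTANT, SENSITIVE, ExpressionMatrix, GroupDesign, SignedGeneList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamResult:
    """Per-gene SAM statistics; ``q`` is NaN until permutation FDR is run."""

    table: pd.DataFrame  # columns: gene, d, s, sign, q
    s0: float

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def _group_matrices(
    expr: ExpressionMatrix, design: GroupDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    design.require_two_per_group()
    sens = design.samples_with(SENSITIVE)
    res = design.samples_with(RESISTANT)
    missing = [s for s in (*sens, *res) if s not in set(expr.sample_ids)]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing}")
    values = expr.values
    x = values.loc[:, sens + res].to_numpy()
    labels = np.array([0] * len(sens) + [1] * len(res))
    return x, labels, np.asarray(values.index)


def _d_stats(
    x: np.ndarray, resistant_mask: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """d and pooled-SE arrays for one label assignment (columns = samples)."""
    a = x[:, resistant_mask]
    b = x[:, ~resistant_mask]
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * ss / (na + nb - 2))
    denom = s + s0
    if np.any(denom == 0):
        raise ValueError(
            "zero-variance gene with s0 = 0; supply a positive s0"
        )
    return diff / denom, s


def _tusher_s0(x: np.ndarray, resistant_mask: np.ndarray) -> float:
    """Exchangeability fudge factor: the percentile of {s_g} minimizing the
    coefficient of variation of window-wise mad(d) across the |d| scale."""
    d_raw, s = _d_stats(x, resistant_mask, s0=float(np.finfo(float).tiny))
    diff = d_raw * (s + np.finfo(float).tiny)  # numerator back out
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_windows = 10 if len(s) >= 100 else max(2, len(s) // 10)
    if n_windows < 2:
        return float(np.median(s))
    # window genes by their pooled SE quantile
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    best_s0, best_cv = None, np.inf
    for s0 in candidates:
        d = diff / (s + s0)
        mads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (s >= lo) & (s <= hi)
            if sel.sum() >= 2:
                dw = d[sel]
                mads.append(np.median(np.abs(dw - np.median(dw))))
        mads = np.asarray(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    if best_s0 is None:
        best_s0 = float(np.median(s))
    return best_s0


def _resolve_s0(x: np.ndarray, resistant_mask: np.ndarray, s0) -> float:
    if s0 == "auto":
        return _tusher_s0(x, resistant_mask)
    s0 = float(s0)
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    return s0


def sam_statistics(
    expr: ExpressionMatrix, design: GroupDesign, s0: float | str = "auto"
) -> SamResult:
    """Moderated difference statistics d (resistant minus sensitive).

    ``s0="auto"`` selects the Tusher-style exchangeability constant from the
    pooled-SE percentiles; pass an explicit value to override.
    """
    x, labels, genes = _group_matrices(expr, design)
    mask = labels == 1
    s0_val = _resolve_s0(x, mask, s0)
    d, s = _d_stats(x, mask, s0_val)
    table = pd.DataFrame(
        {
            "gene": genes,
            "d": d,
            "s": s,
            "sign": np.sign(d).astype(int),
            "q": np.nan,
        }
    )
    return SamResult(table, s0_val)


def _distinct_assignments(n_total: int, n_resistant: int) -> int:
    from math import comb

    return comb(n_total, n_resistant)


def sam_fdr(
    expr: ExpressionMatrix,
    design: GroupDesign,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | str = "auto",
) -> SamResult:
    """SAM statistics plus permutation q-values.

    All distinct label assignments are enumerated when their count is at
    most ``n_perm`` (logged as exhaustive mode); otherwise ``n_perm``
    uniform random assignments are drawn.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    x, labels, genes = _group_matrices(expr, design)
    mask = labels == 1
    n_res = int(mask.sum())
    n_total = len(labels)
    s0_val = _resolve_s0(x, mask, s0)
    d_obs, s = _d_stats(x, mask, s0_val)
    abs_obs = np.abs(d_obs)

    n_exhaustive = _distinct_assignments(n_total, n_res)
    if n_exhaustive <= n_perm:
        logger.info(
            "sam_fdr: exhaustive permutation mode (%d distinct assignments)",
            n_exhaustive,
        )
        assignments = []
        for idx in combinations(range(n_total), n_res):
            m = np.zeros(n_total, dtype=bool)
            m[list(idx)] = True
            assignments.append(m)
    else:
        rng = np.random.default_rng(seed)
        assignments = []
        for _ in range(n_perm):
            idx = rng.choice(n_total, size=n_res, replace=False)
            m = np.zeros(n_total, dtype=bool)
            m[idx] = True
            assignments.append(m)

    # observed-call counts: #{|d| >= |d_g|}
    order = np.argsort(abs_obs)
    sorted_abs = abs_obs[order]
    n_genes = len(abs_obs)
    obs_calls = n_genes - np.searchsorted(sorted_abs, abs_obs, side="left")

    null_calls = np.empty((len(assignments), n_genes))
    for pi, m in enumerate(assignments):
        d_null, _ = _d_stats(x, m, s0_val)
        abs_null = np.sort(np.abs(d_null))
        null_calls[pi] = n_genes - np.searchsorted(abs_null, abs_obs, side="left")
    median_false = np.median(null_calls, axis=0)

    q = np.clip(median_false / obs_calls, 0.0, 1.0)
    # enforce monotone non-increasing q in |d|
    desc = np.argsort(-abs_obs, kind="stable")
    q[desc] = np.maximum.accumulate(q[desc])

    table = pd.DataFrame(
        {
            "gene": genes,
            "d": d_obs,
            "s": s,
            "sign": np.sign(d_obs).astype(int),
            "q": q,
        }
    )
    return SamResult(table, s0_val)


def select_degs(result: SamResult, fdr: float) -> SignedGeneList:
    """Signed DEG list at a q-value cutoff (``q < fdr``; sign = sign(d)).

    ``fdr >= 1`` selects every gene with a nonzero statistic.
    """
    if fdr <= 0:
        raise ValueError("fdr must be positive")
    t = result.table
    if fdr >= 1.0:
        hits = t[t["d"] != 0]
    else:
        if t["q"].isna().any():
            raise ValueError("q-values absent; run sam_fdr first")
        hits = t[(t["q"] < fdr) & (t["d"] != 0)]
    return SignedGeneList(dict(zip(hits["gene"], hits["sign"].astype(int))))
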