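"""Signed-gene-list concordance between analyses (e.g. tissue survival genes
vs cell-line DEGs).

For two analyses that each tag genes as up/risk (+1) or down/protective
(−1), the consistency ratio is k/n where n is the number of overlapping
genes and k the number with the same direction. Under the null of unrelated
directions each overlapping gene agrees with probability 1/2, so the
significance of the observed k is the one-sided binomial upper tail
P(X >= k), X ~ Binomial(n, 1/2). The test is one-sided by construction:
only above-chance consistency is evidence that one analysis reproduces the
other.

The tail is computed exactly — by rational arithmetic for n <= 64, and by a
log-space sum of binomial pmf terms for larger n — so that panel-scale
overlaps (thousands of genes) with tails near 1e-16 do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import SignedGeneList
from .survival import bh_adjust

#: tails below this are displayed as "<1.00E-16" (the float is retained)
DISPLAY_FLOOR = 1e-16


@dataclass(frozen=True)
class ConcordanceResult:
    """Overlap size n, consistent count k, ratio k/n and binomial tail p."""

    n_overlap: int
    n_consistent: int
    ratio: float
    p: float
    p_adj: float | None = None


def binomial_tail(n: int, k: int) -> float:
    """Exact one-sided tail P(X >= k) for X ~ Binomial(n, 1/2).

    Exact rational summation for n <= 64; stable log-space summation of
    pmf terms otherwise (values near 1e-16 retain full relative accuracy).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    if n <= 64:
        return float(Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n))
    def log_tail(lo: int, hi: int) -> float:
        i = np.arange(lo, hi + 1)
        terms = (
            gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
            - n * np.log(2.0)
        )
        return float(logsumexp(terms))

    # sum the smaller side of the distribution: full relative accuracy for
    # tiny tails and monotone behavior for tails near 1
    if k > n / 2:
        return float(min(1.0, np.exp(log_tail(k, n))))
    return float(max(0.0, -np.expm1(log_tail(0, k - 1))))


def format_pvalue(p: float) -> str:
    """Scientific-notation display with the sub-1e-16 floor convention."""
    if p < DISPLAY_FLOOR:
        return "<1.00E-16"
    return f"{p:.2E}"


def overlap_consistency(
    tissue: SignedGeneList, cell: SignedGeneList
) -> ConcordanceResult:
    """Concordance of two signed gene lists over their gene intersection."""
    if len(tissue) == 0 or len(cell) == 0:
        raise ValueError("signed gene lists must be non-empty")
    shared = tissue.genes & cell.genes
    if not shared:
        raise ValueError("no overlapping genes; consistency ratio undefined")
    n = len(shared)
    k = sum(1 for g in shared if tissue.sign(g) == cell.sign(g))
    return ConcordanceResult(n, k, k / n, binomial_tail(n, k))


def evaluate_panel(
    tissue: SignedGeneList, panel: dict[str, SignedGeneList]
) -> pd.DataFrame:
    """Concordance of one tissue list against a named panel of cell-line lists.

    BH adjustment is applied across the panel members with a non-empty
    overlap; members with no overlapping genes appear as NA rows and are
    excluded from the BH family.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    rows = []
    for name, cell in panel.items():
        try:
            res = overlap_consistency(tissue, cell)
            rows.append((name, res.n_overlap, res.n_consistent, res.ratio, res.p))
        except ValueError:
            rows.append((name, 0, 0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["dataset", "n_overlap", "n_consistent", "ratio", "p"]
    )
    table["p_adj"] = np.nan
    tested = table["p"].notna()
    if tested.any():
        table.loc[tested, "p_adj"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    return table


def pairwise_dataset_consistency(
    panel: dict[str, SignedGeneList]
) -> pd.DataFrame:
    """Concordance over all C(m, 2) unordered pairs of panel members.

    Reports raw one-sided binomial p per pair (no multiplicity adjustment).
    """
    names = list(panel)
    if len(names) < 2:
        raise ValueError("need >= 2 panel members for pairwise comparison")
    rows = []
    for a, b in combinations(names, 2):
        try:
            res = overlap_consistency(panel[a], panel[b])
            rows.append((a, b, res.n_overlap, res.n_consistent, res.ratio, res.p))
        except ValueError:
            rows.append((a, b, 0, 0, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["dataset_a", "dataset_b", "n_overlap", "n_consistent",
                 "ratio", "p"],
    )
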