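"""Hypergeometric over-representation analysis of a gene list against a
gene-set collection (e.g. KEGG pathways in GMT form).

For a background of N genes, a query of n genes of interest, a set with m
members in the background and k query genes in the set, the enrichment
p-value is the hypergeometric upper tail P(X >= k). The background is the
set of genes actually measured (the expression matrix), not the genome;
each gene set is intersected with the background before m is counted.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection
from .survival import bh_adjust

logger = logging.getLogger(__name__)


def hypergeom_tail(N: int, n: int, m: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, m, n)."""
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"need m, n within [0, N]; got N={N}, n={n}, m={m}")
    if not 0 <= k <= min(n, m):
        raise ValueError(f"need 0 <= k <= min(n, m); got k={k}, n={n}, m={m}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def enrich(
    query: Sequence[str],
    background: Sequence[str],
    sets: GeneSetCollection,
    fdr: float = 0.2,
) -> pd.DataFrame:
    """Over-representation table over all sets with background members.

    Query genes outside the background are dropped (logged). Returns one row
    per tested set: set_id, N, n, m, k, p, q, significant (q < fdr); sets
    with no background member are omitted.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    bg = list(dict.fromkeys(background))
    if len(bg) < 10:
        raise ValueError("background must contain >= 10 genes")
    bg_set = set(bg)
    q_in = [g for g in dict.fromkeys(query) if g in bg_set]
    n_dropped = len(set(query)) - len(q_in)
    if n_dropped:
        logger.info("enrich: dropped %d query genes absent from background",
                    n_dropped)
    if not q_in:
        raise ValueError("query is empty after restricting to the background")
    N, n = len(bg), len(q_in)
    q_set = set(q_in)
    rows = []
    for set_id in sets.set_ids:
        members = [g for g in sets.genes_of(set_id) if g in bg_set]
        m = len(members)
        if m == 0:
            continue
        k = len(q_set.intersection(members))
        rows.append((set_id, N, n, m, k, hypergeom_tail(N, n, m, k)))
    table = pd.DataFrame(rows, columns=["set_id", "N", "n", "m", "k", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < fdr
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = np.nan
        table["significant"] = pd.Series(dtype=bool)
    return table
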