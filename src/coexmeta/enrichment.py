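"""Gene-set over-representation with Benjamini-Hochberg correction.

Local replacement for web-based annotation services: a gene list is tested
against each set of a GMT collection (functional categories or TF -> target
sets) with the upper-tail hypergeometric probability

    p = sum_{j >= k} C(K, j) C(N-K, n-j) / C(N, n)

over a stated gene universe, followed by BH adjustment across the emitted
rows. An optional EASE-style variant replaces k by k-1 before the tail
probability. Sets with no overlap are omitted from the output and from the
BH family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection
from .errors import StatisticsError


@dataclass
class EnrichmentRow:
    """One tested set: overlap k of K in a list of n over universe N."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    significant: bool


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n), computed stably by scipy."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise StatisticsError(f"inconsistent counts K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise StatisticsError(f"k={k} outside [0, min(K, n)={min(K, n)}]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatisticsError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def enrich_collection(
    gene_list,
    collection: GeneSetCollection,
    universe,
    ease: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each set of ``collection``.

    Sets are intersected with the universe; rows are emitted only for sets
    overlapping the list (k >= 1), BH-adjusted over those rows and sorted by
    ascending adjusted p. With ``ease=True`` the tail uses max(k-1, 0)
    (DAVID's conservative EASE score).
    """
    universe = set(universe)
    genes = set(gene_list)
    if not universe:
        raise StatisticsError("empty universe")
    if not genes:
        raise StatisticsError("empty gene list")
    if not genes <= universe:
        raise StatisticsError(
            f"gene list not contained in universe; e.g. "
            f"{sorted(genes - universe)[:5]}"
        )
    N = len(universe)
    n = len(genes)
    rows = []
    for term in collection.names():
        members = collection.genes(term) & universe
        K = len(members)
        k = len(members & genes)
        if k == 0 or K == 0:
            continue
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeometric_upper(k_eff, K, n, N)
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] <= alpha
        out = out.sort_values(["p_adj", "p", "term"], kind="stable")
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out.reset_index(drop=True)
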