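"""Gene-set overrepresentation and signature-overlap statistics.

The overrepresentation statistic is the one-sided hypergeometric upper
tail (equivalently one-sided Fisher's exact): drawing ``n`` query genes
from a universe of ``N`` containing ``K`` set members, the p-value is
``P(X >= k)`` for the observed overlap ``k``. Multiple testing across a
collection is controlled with the Benjamini–Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n)."""
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # sf is computed stably in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _prepare_query(query, universe) -> tuple[list[str], set[str]]:
    universe_list = list(dict.fromkeys(str(g) for g in universe))
    if not universe_list:
        raise ValueError("universe is empty")
    universe_set = set(universe_list)
    query_list = list(dict.fromkeys(str(g) for g in query))
    in_universe = [g for g in query_list if g in universe_set]
    dropped = len(query_list) - len(in_universe)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) outside the universe dropped")
    return in_universe, universe_set


def enrich_sets(
    query, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of the query in every gene set.

    Sets are intersected with the universe; query genes outside the
    universe are dropped with a warning. Rows are sorted by ascending p,
    ties by set name. Columns: set, k, K, n, N, p, q, description.
    """
    query_in, universe_set = _prepare_query(query, universe)
    N = len(universe_set)
    n = len(query_in)
    query_set = set(query_in)

    rows = []
    for name, members in collection.items():
        members_in = set(members) & universe_set
        K = len(members_in)
        k = len(query_set & members_in)
        p = hypergeometric_tail(k, K, n, N)
        rows.append((name, k, K, n, N, p, collection.descriptions.get(name, "")))
    df = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p", "description"]
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df[["set", "k", "K", "n", "N", "p", "q", "description"]]


def signature_overlap(
    query, signatures: GeneSetCollection, universe
) -> pd.DataFrame:
    """Overlap of the query with each response signature, with significance.

    Like :func:`enrich_sets` but also reports the overlapping gene
    identities (comma-separated, sorted) so the shared genes can be
    inspected directly.
    """
    query_in, universe_set = _prepare_query(query, universe)
    N = len(universe_set)
    n = len(query_in)
    query_set = set(query_in)

    rows = []
    for name, members in signatures.items():
        members_in = set(members) & universe_set
        K = len(members_in)
        overlap = sorted(query_set & members_in)
        k = len(overlap)
        p = hypergeometric_tail(k, K, n, N)
        rows.append((name, k, K, n, N, p, ",".join(overlap)))
    df = pd.DataFrame(
        rows, columns=["signature", "k", "K", "n", "N", "p", "overlap_genes"]
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "signature"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df[["signature", "k", "K", "n", "N", "p", "q", "overlap_genes"]]
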