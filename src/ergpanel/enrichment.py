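"""Over-representation analysis with Benjamini-Hochberg FDR.

For a query gene list (e.g. the up-regulated panel) and an annotated gene
set, the overlap k is tested against the one-sided hypergeometric upper
tail P(X >= k) over a stated gene universe. Q-values come from the BH
step-up procedure over the collection, and reporting keeps the top
categories below the FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet


class OraResult(NamedTuple):
    n_universe: int   # N
    n_set: int        # K, after intersection with the universe
    n_query: int      # n
    n_overlap: int    # k
    p: float


def ora_test(query: Iterable[str], gene_set: Iterable[str],
             universe: Iterable[str]) -> OraResult:
    """One-sided hypergeometric over-representation test.

    The gene set is intersected with the universe before testing; the query
    must be a subset of the universe (error naming the first offender).
    """
    universe_set = set(universe)
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene list")
    if not universe_set:
        raise ValueError("empty gene universe")
    outside = sorted(query_set - universe_set)
    if outside:
        raise ValueError(
            f"query gene {outside[0]!r} is not in the universe")
    members = set(gene_set) & universe_set
    n_total = len(universe_set)
    n_members = len(members)
    n_query = len(query_set)
    n_overlap = len(query_set & members)
    # P(X >= k) for X ~ Hypergeometric(N, K, n)
    p = float(stats.hypergeom.sf(n_overlap - 1, n_total, n_members, n_query))
    return OraResult(n_universe=n_total, n_set=n_members, n_query=n_query,
                     n_overlap=n_overlap, p=min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted Q-values, original order kept."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def enrich_collection(query: Iterable[str],
                      collection: Mapping[str, GeneSet],
                      universe: Iterable[str]) -> pd.DataFrame:
    """ORA of a query against every set in a collection, BH-adjusted.

    Returns a frame (set, N, K, n, k, enrichment_ratio, p, q) in the
    collection's order. The enrichment ratio is (k/n)/(K/N), NaN for sets
    with no members in the universe.
    """
    universe_list = list(dict.fromkeys(universe))
    rows = []
    for name, gene_set in collection.items():
        result = ora_test(query, gene_set.genes, universe_list)
        if result.n_set:
            ratio = ((result.n_overlap / result.n_query)
                     / (result.n_set / result.n_universe))
        else:
            ratio = np.nan
        rows.append({"set": name, "N": result.n_universe, "K": result.n_set,
                     "n": result.n_query, "k": result.n_overlap,
                     "enrichment_ratio": ratio, "p": result.p})
    frame = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k",
                                        "enrichment_ratio", "p"])
    frame["q"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else []
    return frame


def top_categories(results: pd.DataFrame, fdr_threshold: float = 0.05,
                   top_n: int = 10) -> pd.DataFrame:
    """Categories with q < fdr_threshold, ascending q (ties: larger
    enrichment ratio, then set name), truncated to ``top_n``."""
    kept = results[results["q"] < fdr_threshold].copy()
    kept["_neg_ratio"] = -kept["enrichment_ratio"].fillna(0.0)
    kept = kept.sort_values(["q", "_neg_ratio", "set"], kind="mergesort")
    kept = kept.drop(columns="_neg_ratio").head(top_n)
    return kept.reset_index(drop=True)
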