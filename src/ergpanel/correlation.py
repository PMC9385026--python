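"""Reproducibility of replicate expression profiles over gene panels.

Pearson correlation (R) between two replicates' log2 expression profiles,
restricted to a gene set, with the standard two-sided p-value from the
t-transform with n-2 degrees of freedom. The nested-set table repeats the
comparison between a reference replicate and every other replicate over
the top-s genes of a stability ranking for a sequence of set sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .stability import StabilityRecord


@dataclass(frozen=True)
class CorrelationResult:
    label_a: str
    label_b: str
    set_label: str
    set_size: int
    r: float
    p: float  # NaN when size < 3


def profile_correlation(profile_a: pd.Series, profile_b: pd.Series,
                        gene_set: Sequence[str],
                        label_a: str = "a", label_b: str = "b",
                        set_label: str = "") -> CorrelationResult:
    """Pearson R between two log2 expression profiles over ``gene_set``.

    Raises ``KeyError`` naming the first gene missing from either profile,
    and ``ValueError`` for sets smaller than 2. The p-value is defined only
    for sets of at least 3 genes (NaN otherwise).
    """
    genes = list(gene_set)
    if len(genes) < 2:
        raise ValueError(f"gene set must have >= 2 genes, got {len(genes)}")
    for label, profile in ((label_a, profile_a), (label_b, profile_b)):
        for gene in genes:
            if gene not in profile.index:
                raise KeyError(
                    f"gene {gene!r} missing from profile {label!r}")
    x = profile_a.loc[genes].to_numpy(dtype=float)
    y = profile_b.loc[genes].to_numpy(dtype=float)
    if len(genes) == 2:
        r = float(np.corrcoef(x, y)[0, 1])
        p = math.nan
    else:
        result = stats.pearsonr(x, y)
        r, p = float(result.statistic), float(result.pvalue)
    return CorrelationResult(label_a=label_a, label_b=label_b,
                             set_label=set_label, set_size=len(genes),
                             r=r, p=p)


def nested_set_correlation(
        reference: pd.Series,
        others: Mapping[str, pd.Series],
        ranked: Sequence[StabilityRecord],
        sizes: Sequence[int],
        reference_label: str = "ref") -> pd.DataFrame:
    """R between the reference profile and each other profile, over the
    top-s ranked genes for each size s.

    Returns a frame (pair, set_size, r, p) ordered by set size descending,
    then pair label. A size exceeding the ranking length is an error naming
    the size.
    """
    if not others:
        raise ValueError("nested_set_correlation needs >= 1 other profile")
    ranked_genes = [r.gene for r in ranked]
    for size in sizes:
        if size > len(ranked_genes):
            raise ValueError(
                f"set size {size} exceeds the {len(ranked_genes)}-gene ranking")
        if size < 2:
            raise ValueError(f"set size {size} too small for correlation")
    rows = []
    for size in sorted(sizes, reverse=True):
        subset = ranked_genes[:size]
        for label in sorted(others):
            result = profile_correlation(
                reference, others[label], subset,
                label_a=reference_label, label_b=label,
                set_label=f"top{size}")
            rows.append({"pair": f"{reference_label}-{label}",
                         "set_size": size, "r": result.r, "p": result.p})
    return pd.DataFrame(rows, columns=["pair", "set_size", "r", "p"])
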