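"""Per-gene expression response: log2 ratios, significance, volcano tables.

FPKM values are log2-transformed with a pseudocount; the response of a gene
is the vector of per-replicate-pair log2(treated/control) ratios, its mean
("fold change") and a two-sided Welch t-test p-value comparing the log2
levels of the two arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import ExpressionExperiment

VOLCANO_VARIANTS = ("pvalue", "cv")
CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_NS = "not-significant"


def log2_with_pseudocount(fpkm, pseudocount: float):
    """log2(fpkm + pseudocount), elementwise.

    ``pseudocount`` may be 0 only when every value is strictly positive.
    """
    fpkm = np.asarray(fpkm, dtype=float)
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount!r}")
    if np.any(fpkm < 0):
        raise ValueError("negative FPKM value")
    if pseudocount == 0 and np.any(fpkm == 0):
        raise ValueError("zero FPKM with zero pseudocount is undefined")
    result = np.log2(fpkm + pseudocount)
    return result if result.ndim else float(result)


def per_gene_test(treated_log2, control_log2) -> float:
    """Two-sided Welch two-sample t-test p-value on log2 values.

    Degenerate inputs: if both arms have zero variance the p-value is 1.0
    when the means are equal and 0.0 otherwise.
    """
    t = np.asarray(treated_log2, dtype=float)
    c = np.asarray(control_log2, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("per_gene_test needs at least 2 values per arm")
    if np.var(t, ddof=1) == 0 and np.var(c, ddof=1) == 0:
        return 1.0 if t.mean() == c.mean() else 0.0
    return float(stats.ttest_ind(t, c, equal_var=False).pvalue)


@dataclass(frozen=True)
class ResponseProfiles:
    """Per-gene response over an experiment.

    Attributes
    ----------
    ratios
        Gene x replicate frame of paired log2(treated/control) ratios.
    summary
        Gene-indexed frame with columns ``mean_log2_ratio``,
        ``sd_log2_ratio``, ``p_value``, ``mean_control_fpkm`` and
        ``mean_treated_fpkm``.
    """

    ratios: pd.DataFrame
    summary: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.summary.index

    @property
    def n_replicates(self) -> int:
        return self.ratios.shape[1]


def response_profile(experiment: ExpressionExperiment,
                     config: RunConfig) -> ResponseProfiles:
    """Compute per-replicate log2 ratios and per-gene mean/SD/p-value.

    Ratios pair treated and control replicates by column position:
    ratio_i = log2(treated_i + pc) - log2(control_i + pc).
    """
    if experiment.n_replicates < 2:
        raise ValueError("response_profile needs at least 2 replicate pairs")
    pc = config.pseudocount
    log_t = log2_with_pseudocount(experiment.treated, pc)
    log_c = log2_with_pseudocount(experiment.control, pc)
    ratios = log_t - log_c

    mean = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=1)

    # Vectorised Welch test across genes, with the degenerate-variance
    # convention applied afterwards. scipy warns about near-constant rows
    # (e.g. a replicated control arm); those p-values are overwritten below.
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pvals = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False).pvalue
    var_t = log_t.var(axis=1, ddof=1)
    var_c = log_c.var(axis=1, ddof=1)
    both_flat = (var_t == 0) & (var_c == 0)
    equal_means = log_t.mean(axis=1) == log_c.mean(axis=1)
    pvals = np.where(both_flat, np.where(equal_means, 1.0, 0.0), pvals)

    genes = list(experiment.gene_ids)
    labels = list(experiment.replicate_labels)
    summary = pd.DataFrame(
        {"mean_log2_ratio": mean,
         "sd_log2_ratio": sd,
         "p_value": pvals,
         "mean_control_fpkm": experiment.control.mean(axis=1),
         "mean_treated_fpkm": experiment.treated.mean(axis=1)},
        index=pd.Index(genes, name="gene"))
    return ResponseProfiles(
        ratios=pd.DataFrame(ratios, index=summary.index, columns=labels),
        summary=summary)


def classify_volcano(mean_log2_ratio: float, p_value: float,
                     alpha: float) -> str:
    if p_value < alpha and mean_log2_ratio > 0:
        return CLASS_UP
    if p_value < alpha and mean_log2_ratio < 0:
        return CLASS_DOWN
    return CLASS_NS


def volcano_table(profiles: ResponseProfiles, variant: str,
                  alpha: float,
                  cv: Optional[pd.Series] = None) -> pd.DataFrame:
    """Build a plot-ready volcano table.

    ``variant="pvalue"`` puts -log10(p) on the Y axis; ``variant="cv"``
    puts the stability statistic there (supplied per gene via ``cv``;
    genes without a defined CV get NaN). Class is assigned from the
    p-value and the sign of the mean log2 ratio in both variants.
    """
    if variant not in VOLCANO_VARIANTS:
        raise ValueError(
            f"unknown volcano variant {variant!r}; expected one of "
            f"{VOLCANO_VARIANTS}")
    summary = profiles.summary
    if variant == "pvalue":
        with np.errstate(divide="ignore"):
            y = -np.log10(summary["p_value"].to_numpy())
        y_kind = "neg_log10_p"
    else:
        if cv is None:
            raise ValueError("variant 'cv' requires a per-gene cv series")
        y = cv.reindex(summary.index).to_numpy()
        y_kind = "cv"
    classes = [classify_volcano(m, p, alpha)
               for m, p in zip(summary["mean_log2_ratio"], summary["p_value"])]
    table = pd.DataFrame(
        {"gene": summary.index,
         "log2fc": summary["mean_log2_ratio"].to_numpy(),
         "y_value": y,
         "y_kind": y_kind,
         "class": classes})
    return table.sort_values("gene", kind="mergesort").reset_index(drop=True)
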