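"""Stability statistic and panel selection.

The stability of a gene's response is the coefficient of variation
CV = |SD/Av| of its per-replicate log2(treated/control) ratios: the sample
standard deviation over the arithmetic mean, in absolute value. Lower CV
means a more reproducible response. Genes are ranked by ascending CV and a
marker panel of the most stable up- and down-responders is selected after
filtering on significance, fold change and expression level.

Genes whose mean ratio is within ``epsilon`` of zero have an undefined CV;
they are flagged, excluded from rankings, and can never enter a panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .response import ResponseProfiles, log2_with_pseudocount

logger = logging.getLogger(__name__)

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"


class CVStat(NamedTuple):
    av: float
    sd: float
    cv: float  # NaN when undefined
    defined: bool


def cv_statistic(values: Sequence[float], epsilon: float = 1e-8) -> CVStat:
    """Mean, sample SD (n-1 denominator) and CV = |SD/Av| of a vector.

    The CV is undefined (NaN, ``defined=False``) when |Av| < ``epsilon``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"cv_statistic needs >= 2 values, got {arr.size}")
    av = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if abs(av) < epsilon:
        return CVStat(av=av, sd=sd, cv=math.nan, defined=False)
    return CVStat(av=av, sd=sd, cv=abs(sd / av), defined=True)


@dataclass(frozen=True)
class StabilityRecord:
    gene: str
    av: float
    sd: float
    cv: float
    cv_defined: bool
    rank: Optional[int] = None
    direction: str = DIRECTION_NONE
    flags: tuple[str, ...] = ()


def stability_records(profiles: ResponseProfiles,
                      config: RunConfig) -> list[StabilityRecord]:
    """One stability record per gene, in the profiles' gene order.

    With ``config.cv_on == "ratios"`` (default) the statistic is computed
    on the per-replicate log2 ratios; with ``"log2_expression"`` it is
    computed on the treated arm's per-replicate log2(FPKM + pc) levels.
    """
    if config.cv_on != "ratios":
        # Treated log2 levels are not recoverable from ratios alone; callers
        # wanting cv_on='log2_expression' pass the treated log2 matrix to
        # stability_records_from_matrix instead.
        raise ValueError(
            "cv_on='log2_expression' requires stability_records_from_matrix "
            "with the treated log2 matrix")
    records = []
    for gene, row in zip(profiles.genes, profiles.ratios.to_numpy()):
        stat = cv_statistic(row, epsilon=config.epsilon)
        records.append(_record_from_stat(gene, stat))
    return records


def stability_records_from_matrix(matrix: pd.DataFrame,
                                  config: RunConfig) -> list[StabilityRecord]:
    """Stability records computed on an arbitrary gene x replicate matrix
    (e.g. treated log2 expression levels for ``cv_on='log2_expression'``)."""
    records = []
    for gene, row in zip(matrix.index, matrix.to_numpy()):
        stat = cv_statistic(row, epsilon=config.epsilon)
        records.append(_record_from_stat(str(gene), stat))
    return records


def _record_from_stat(gene: str, stat: CVStat) -> StabilityRecord:
    if not stat.defined:
        direction = DIRECTION_NONE
        flags = ("near_zero_mean",)
    else:
        direction = DIRECTION_UP if stat.av > 0 else DIRECTION_DOWN
        flags = ()
    return StabilityRecord(gene=gene, av=stat.av, sd=stat.sd, cv=stat.cv,
                           cv_defined=stat.defined, direction=direction,
                           flags=flags)


def _rank_key(record: StabilityRecord):
    # Ties broken by larger |Av|, then gene symbol; fixture records without
    # a printed Av sort as |Av| = 0.
    abs_av = abs(record.av) if math.isfinite(record.av) else 0.0
    return (record.cv, -abs_av, record.gene)


def rank_by_stability(
        records: Sequence[StabilityRecord]) -> list[StabilityRecord]:
    """Rank by ascending CV; undefined-CV records are excluded (their count
    is logged, not an error). Ranks are assigned 1..n."""
    defined = [r for r in records if r.cv_defined]
    n_excluded = len(records) - len(defined)
    if n_excluded:
        logger.info("rank_by_stability: excluded %d records with undefined CV",
                    n_excluded)
    ordered = sorted(defined, key=_rank_key)
    return [replace(r, rank=i) for i, r in enumerate(ordered, start=1)]


def mean_cv_by_set(ranked: Sequence[StabilityRecord],
                   sizes: Sequence[int]) -> pd.DataFrame:
    """Mean and SD of the CV over the top-s ranked genes, per size s.

    SD uses the sample (n-1) convention; a single-gene set reports SD 0.
    """
    cvs = np.array([r.cv for r in ranked], dtype=float)
    rows = []
    for size in sizes:
        if size < 1 or size > len(ranked):
            raise ValueError(
                f"set size {size} out of range for {len(ranked)} ranked genes")
        prefix = cvs[:size]
        sd = float(prefix.std(ddof=1)) if size > 1 else 0.0
        rows.append({"set_size": size, "mean_cv": float(prefix.mean()),
                     "sd_cv": sd})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PanelSelection:
    """Result of the up/down panel selection.

    ``up`` and ``down`` are CV-ascending lists of records; ``top_k`` is the
    k lowest-CV records of their union. ``warnings`` flags directions with
    fewer qualifying candidates than requested.
    """

    up: tuple[StabilityRecord, ...]
    down: tuple[StabilityRecord, ...]
    top_k: tuple[StabilityRecord, ...]
    n_candidates: int
    warnings: tuple[str, ...]
    config: RunConfig

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self.up + self.down]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        top_genes = {r.gene for r in self.top_k}
        for panel, records in (("up", self.up), ("down", self.down)):
            for record in records:
                rows.append({
                    "gene": record.gene, "av": record.av, "sd": record.sd,
                    "cv": record.cv, "rank": record.rank,
                    "direction": record.direction, "panel": panel,
                    "in_top_k": record.gene in top_genes,
                    "flags": ";".join(record.flags)})
        return pd.DataFrame(rows, columns=["gene", "av", "sd", "cv", "rank",
                                           "direction", "panel", "in_top_k",
                                           "flags"])


def select_panel(profiles: ResponseProfiles,
                 records: Sequence[StabilityRecord],
                 config: RunConfig) -> PanelSelection:
    """Select the most stable up- and down-responders.

    Candidate filter: p < alpha, |Av| >= fc_threshold, mean control-arm
    FPKM >= expression_floor, CV defined. Among up-candidates (Av > 0) the
    ``n_up`` lowest-CV genes are taken; symmetrically for down. A shortage
    in either direction returns all qualifying genes plus a warning flag.
    """
    summary = profiles.summary
    by_gene = {r.gene: r for r in records}
    missing = [g for g in summary.index if g not in by_gene]
    if missing:
        raise ValueError(
            f"stability records missing for genes: {missing[:5]}")

    candidates = []
    for gene in summary.index:
        record = by_gene[gene]
        row = summary.loc[gene]
        if (record.cv_defined
                and row["p_value"] < config.alpha
                and abs(record.av) >= config.fc_threshold
                and row["mean_control_fpkm"] >= config.expression_floor):
            candidates.append(record)

    ups = sorted((r for r in candidates if r.av > 0), key=_rank_key)
    downs = sorted((r for r in candidates if r.av < 0), key=_rank_key)

    warnings = []
    if len(ups) < config.n_up:
        warnings.append(
            f"only {len(ups)} up-regulated candidates for n_up={config.n_up}")
    if len(downs) < config.n_down:
        warnings.append(
            f"only {len(downs)} down-regulated candidates for "
            f"n_down={config.n_down}")
    up_panel = ups[:config.n_up]
    down_panel = downs[:config.n_down]
    union = sorted(up_panel + down_panel, key=_rank_key)
    top_k = union[:config.top_k]
    return PanelSelection(up=tuple(up_panel), down=tuple(down_panel),
                          top_k=tuple(top_k), n_candidates=len(candidates),
                          warnings=tuple(warnings), config=config)
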