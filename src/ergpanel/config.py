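"""Run configuration for the ERG panel pipeline.

A single frozen dataclass carries every tunable threshold so that each
report can be stamped with the exact settings (and seed) that produced it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

#: Allowed values for :attr:`RunConfig.cv_on`.
CV_ON_CHOICES = ("ratios", "log2_expression")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and sizes for selection, testing and reporting.

    Parameters
    ----------
    pseudocount
        Added to FPKM before log2-transforming; guards genes with zero
        expression in one arm.
    n_up, n_down
        Sizes of the up- and down-regulated halves of the selected panel.
    top_k
        Size of the small high-stability sub-panel taken from the union of
        the up and down panels.
    fc_threshold
        Minimum absolute mean log2 ratio for a candidate gene
        (0.585 corresponds to a 1.5-fold change).
    expression_floor
        Minimum mean control-arm FPKM for a candidate gene.
    alpha
        Per-gene significance level for the treated-vs-control test.
    fdr_threshold
        BH Q-value cutoff for reported enrichment categories.
    top_n_categories
        Number of enrichment categories reported per direction.
    epsilon
        Genes whose mean log2 ratio is below this in absolute value have an
        undefined coefficient of variation and never enter a ranking.
    cv_on
        Quantity the stability statistic is computed on: per-replicate log2
        treated/control ratios (``"ratios"``, default) or per-replicate
        treated log2 expression levels (``"log2_expression"``).
    seed
        Seed for any stochastic step; recorded in every output.
    """

    pseudocount: float = 1.0
    n_up: int = 150
    n_down: int = 150
    top_k: int = 30
    fc_threshold: float = 0.585
    expression_floor: float = 1.0
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    top_n_categories: int = 10
    epsilon: float = 1e-8
    cv_on: str = "ratios"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pseudocount", "fc_threshold", "expression_floor",
                     "alpha", "fdr_threshold", "epsilon"):
            value = getattr(self, name)
            if not value >= 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")
        for name in ("n_up", "n_down", "top_k", "top_n_categories"):
            value = getattr(self, name)
            if not (isinstance(value, int) and value >= 1):
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha!r}")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError(
                f"fdr_threshold must lie in (0, 1], got {self.fdr_threshold!r}")
        if self.cv_on not in CV_ON_CHOICES:
            raise ValueError(
                f"cv_on must be one of {CV_ON_CHOICES}, got {self.cv_on!r}")
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    @property
    def panel_size(self) -> int:
        return self.n_up + self.n_down

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        """Canonical (sorted-key) JSON used to stamp reports."""
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, mapping: dict, *, require_all: bool = False
                  ) -> "RunConfig":
        """Build a config from a mapping.

        With ``require_all=True`` (used when a caller supplies a complete
        configuration, e.g. a config file) every field must be present;
        the first missing one is named in the error.
        """
        unknown = [f for f in mapping if f not in cls.__dataclass_fields__]
        if unknown:
            raise ValueError(f"unknown RunConfig fields: {unknown}")
        if require_all:
            for name in cls.__dataclass_fields__:
                if name not in mapping:
                    raise ValueError(f"missing RunConfig field: {name!r}")
        known = {f: mapping[f] for f in cls.__dataclass_fields__ if f in mapping}
        return cls(**known)
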