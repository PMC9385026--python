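"""Rule-based ER-subtype classification from ChIP peak evidence.

A gene is called ERα-bound when its ERα peak-significance score with
estradiol strictly exceeds the score without estradiol, and ERβ-bound when
the ERβ signal-to-noise ratio strictly exceeds 1.0 (S = mean of the two
ChIP replicate signals, N = the input-control signal; peaks counted within
±10 kb of the transcription start site). The two binary calls combine into
four classes: ERα-specific, ERβ-specific, ERα/β (both), or other (neither).

Both rules use strict inequalities: a gene with S/N exactly 1.0 is
ERβ-negative, and a gene scoring 0 vs 0 is ERα-negative.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Canonical subtype labels.
ER_ALPHA = "ERalpha"
ER_BETA = "ERbeta"
ER_ALPHA_BETA = "ERalpha/beta"
OTHER = "other"
SUBTYPES = (ER_ALPHA, ER_BETA, ER_ALPHA_BETA, OTHER)

#: Documented provenance of the evidence scores.
TSS_WINDOW_KB = 10.0


@dataclass(frozen=True)
class PeakEvidence:
    """ChIP peak evidence for one gene.

    ``q_minus``/``q_plus`` are opaque ERα peak-significance scores without
    and with estradiol (larger = more significant); ``sn_ratio`` is the ERβ
    signal-to-noise ratio, NaN when undefined (zero input signal).
    """

    gene: str
    q_minus: float
    q_plus: float
    sn_ratio: float
    note: str = field(default=f"peaks within +/-{TSS_WINDOW_KB:g} kb of TSS")

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("empty gene symbol in peak evidence")
        for name in ("q_minus", "q_plus"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{self.gene}: {name} must be finite and >= 0, got {value!r}")
        if not math.isnan(self.sn_ratio):
            if not math.isfinite(self.sn_ratio) or self.sn_ratio < 0:
                raise ValueError(
                    f"{self.gene}: sn_ratio must be finite and >= 0 "
                    f"(or NaN when undefined), got {self.sn_ratio!r}")

    @property
    def sn_defined(self) -> bool:
        return not math.isnan(self.sn_ratio)


@dataclass(frozen=True)
class SubtypeCall:
    gene: str
    alpha_bound: bool
    beta_bound: bool
    subtype: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = classify_subtype(self.alpha_bound, self.beta_bound)
        if self.subtype != expected:
            raise ValueError(
                f"{self.gene}: subtype {self.subtype!r} inconsistent with "
                f"flags (expected {expected!r})")


def alpha_binding_call(q_minus: float, q_plus: float) -> bool:
    """ERα binding is positive iff the +E2 score strictly exceeds the -E2
    score."""
    for name, value in (("q_minus", q_minus), ("q_plus", q_plus)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value!r}")
    return q_plus > q_minus


def sn_ratio(rep1_signal: float, rep2_signal: float,
             input_signal: float) -> float:
    """S/N = mean(rep1, rep2) / input. Returns NaN when the input signal is
    zero (undefined, reported rather than dropped)."""
    for name, value in (("rep1_signal", rep1_signal),
                        ("rep2_signal", rep2_signal),
                        ("input_signal", input_signal)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value!r}")
    if input_signal == 0:
        return math.nan
    return ((rep1_signal + rep2_signal) / 2.0) / input_signal


def beta_binding_call(sn: float) -> bool:
    """ERβ binding is positive iff the S/N ratio strictly exceeds 1.0.

    An undefined (NaN) ratio yields a negative call; callers propagate the
    undefined flag on the resulting :class:`SubtypeCall`.
    """
    if math.isnan(sn):
        return False
    if sn < 0:
        raise ValueError(f"sn_ratio must be >= 0, got {sn!r}")
    return sn > 1.0


def classify_subtype(alpha_flag: bool, beta_flag: bool) -> str:
    if alpha_flag and beta_flag:
        return ER_ALPHA_BETA
    if alpha_flag:
        return ER_ALPHA
    if beta_flag:
        return ER_BETA
    return OTHER


def call_gene(evidence: PeakEvidence) -> SubtypeCall:
    alpha = alpha_binding_call(evidence.q_minus, evidence.q_plus)
    beta = beta_binding_call(evidence.sn_ratio)
    flags = () if evidence.sn_defined else ("sn_undefined",)
    return SubtypeCall(gene=evidence.gene, alpha_bound=alpha,
                       beta_bound=beta,
                       subtype=classify_subtype(alpha, beta), flags=flags)


def classify_panel(
        evidence: Sequence[PeakEvidence],
) -> tuple[list[SubtypeCall], dict[str, int]]:
    """Classify every record; returns calls sorted by gene symbol and the
    counts over the four classes (every class present, zero-filled).

    Raises ``ValueError`` on a duplicated gene.
    """
    seen: set[str] = set()
    for record in evidence:
        if record.gene in seen:
            raise ValueError(f"duplicate gene in evidence: {record.gene!r}")
        seen.add(record.gene)
    calls = sorted((call_gene(r) for r in evidence), key=lambda c: c.gene)
    counts = Counter(c.subtype for c in calls)
    return calls, {s: counts.get(s, 0) for s in SUBTYPES}
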