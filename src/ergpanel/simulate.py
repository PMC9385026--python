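"""Synthetic expression experiments, peak evidence and gene sets.

The generator emulates the study design the analysis assumes: paired
treated/control arms with six replicates, log-normal FPKM noise (additive
Gaussian noise on the log2 scale), and four planted gene classes —
stable up-responders, stable down-responders, unstable responders, and
non-responders. Placing the noise on the log2 ratio scale makes the
CV-of-ratios stability statistic directly controllable: a stable responder
with effect 2 and ratio noise SD 0.1 has expected CV near 0.05, an
unstable one near 0.5.

Per gene, a single control log2-FPKM level is drawn from the baseline
distribution and shared across replicates; each treated replicate adds the
gene's true log2 effect plus Gaussian class noise. Peak evidence and gene
sets are generated consistently with the planted labels so the classifier
and enrichment stages can be closed-loop tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionExperiment, GeneSet, GeneSetCollection
from .subtype import (ER_ALPHA, ER_ALPHA_BETA, ER_BETA, OTHER, SUBTYPES,
                      PeakEvidence)

CLASS_STABLE_UP = "stable_up"
CLASS_STABLE_DOWN = "stable_down"
CLASS_UNSTABLE = "unstable_responder"
CLASS_NON_RESPONDER = "non_responder"
GENE_CLASSES = (CLASS_STABLE_UP, CLASS_STABLE_DOWN, CLASS_UNSTABLE,
                CLASS_NON_RESPONDER)

#: Subtype mix used when planting ChIP evidence labels, close to the
#: observed split of ER-binding classes among estrogen-responsive genes.
SUBTYPE_PROBS = {ER_ALPHA: 0.35, ER_BETA: 0.07, ER_ALPHA_BETA: 0.48,
                 OTHER: 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    Defaults mirror the emulated study design: six treated/control
    replicate pairs, roughly 26,000 assayable genes of which 150 stable
    up- and 150 stable down-responders, a mean absolute log2 effect of 2
    for responders, tight (0.1) ratio noise for stable genes and wide
    (1.0) noise for unstable ones. Tests scale ``n_genes`` and the class
    fractions down.
    """

    n_genes: int = 26000
    n_replicates: int = 6
    frac_up: float = 150 / 26000
    frac_down: float = 150 / 26000
    frac_unstable: float = 0.01
    effect_size: float = 2.0
    effect_spread: float = 0.5
    stable_sigma: float = 0.1
    unstable_sigma: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_replicates < 2:
            raise ValueError(
                f"n_replicates must be >= 2, got {self.n_replicates}")
        for name in ("frac_up", "frac_down", "frac_unstable"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.frac_up + self.frac_down + self.frac_unstable > 1:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("stable_sigma", "unstable_sigma", "effect_spread",
                     "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stable_sigma == 0 and self.unstable_sigma == 0:
            pass  # allowed: the zero-noise limit is a documented test case

    def class_counts(self) -> dict[str, int]:
        n_up = round(self.frac_up * self.n_genes)
        n_down = round(self.frac_down * self.n_genes)
        n_unstable = round(self.frac_unstable * self.n_genes)
        n_rest = self.n_genes - n_up - n_down - n_unstable
        if n_rest < 0:
            raise ValueError("rounded class counts exceed n_genes")
        return {CLASS_STABLE_UP: n_up, CLASS_STABLE_DOWN: n_down,
                CLASS_UNSTABLE: n_unstable, CLASS_NON_RESPONDER: n_rest}


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-gene truth: class label, true log2 effect, and the
    subtype label used when simulating peak evidence."""

    table: pd.DataFrame  # index gene; columns gene_class, true_log2_effect, subtype

    def __post_init__(self) -> None:
        bad = set(self.table["gene_class"]) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        bad = set(self.table["subtype"]) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")

    def genes_in_class(self, *classes: str) -> list[str]:
        mask = self.table["gene_class"].isin(classes)
        return list(self.table.index[mask])

    @property
    def responders(self) -> list[str]:
        return self.genes_in_class(CLASS_STABLE_UP, CLASS_STABLE_DOWN,
                                   CLASS_UNSTABLE)

    @property
    def stable_responders(self) -> list[str]:
        return self.genes_in_class(CLASS_STABLE_UP, CLASS_STABLE_DOWN)


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_experiment(
        config: SimulationConfig) -> tuple[ExpressionExperiment, GroundTruth]:
    """Draw a paired treated/control FPKM experiment plus its ground truth.

    Identical config (including seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.class_counts()
    classes = np.array(
        [CLASS_STABLE_UP] * counts[CLASS_STABLE_UP]
        + [CLASS_STABLE_DOWN] * counts[CLASS_STABLE_DOWN]
        + [CLASS_UNSTABLE] * counts[CLASS_UNSTABLE]
        + [CLASS_NON_RESPONDER] * counts[CLASS_NON_RESPONDER])
    rng.shuffle(classes)
    n = config.n_genes
    genes = _gene_names(n)

    magnitudes = np.abs(rng.normal(config.effect_size, config.effect_spread,
                                   size=n))
    signs = np.where(classes == CLASS_STABLE_UP, 1.0,
                     np.where(classes == CLASS_STABLE_DOWN, -1.0,
                              rng.choice([-1.0, 1.0], size=n)))
    effects = np.where(classes == CLASS_NON_RESPONDER, 0.0,
                       signs * magnitudes)
    sigmas = np.where(classes == CLASS_UNSTABLE, config.unstable_sigma,
                      config.stable_sigma)

    control_log2 = rng.normal(config.baseline_mean, config.baseline_sd,
                              size=n)
    noise = rng.normal(0.0, 1.0, size=(n, config.n_replicates))
    treated_log2 = (control_log2[:, None] + effects[:, None]
                    + sigmas[:, None] * noise)
    control = np.repeat(2.0 ** control_log2[:, None], config.n_replicates,
                        axis=1)
    treated = 2.0 ** treated_log2

    labels = tuple(f"rep{i}" for i in range(1, config.n_replicates + 1))
    experiment = ExpressionExperiment(gene_ids=tuple(genes), treated=treated,
                                      control=control,
                                      replicate_labels=labels)

    subtype_names = list(SUBTYPE_PROBS)
    subtype_p = np.array([SUBTYPE_PROBS[s] for s in subtype_names])
    subtype_p = subtype_p / subtype_p.sum()
    subtypes = rng.choice(subtype_names, size=n, p=subtype_p)

    truth = GroundTruth(table=pd.DataFrame(
        {"gene_class": classes, "true_log2_effect": effects,
         "subtype": subtypes}, index=pd.Index(genes, name="gene")))
    return experiment, truth


def simulate_peak_evidence(truth: GroundTruth, seed: int,
                           genes: Sequence[str] | None = None,
                           ) -> list[PeakEvidence]:
    """Draw peak-evidence records consistent with the planted subtypes.

    ERα-positive labels get q_plus strictly above q_minus; ERβ-positive
    labels get S/N strictly above 1.0; negatives get the complements.
    Magnitudes span the ranges seen in published evidence tables
    (significance scores up to a few thousand, S/N up to the low tens).
    """
    rng = np.random.default_rng(seed)
    table = truth.table if genes is None else truth.table.loc[list(genes)]
    records = []
    for gene, row in table.iterrows():
        label = row["subtype"]
        if label not in SUBTYPES:
            raise ValueError(f"unknown subtype label {label!r} for {gene!r}")
        alpha_positive = label in (ER_ALPHA, ER_ALPHA_BETA)
        beta_positive = label in (ER_BETA, ER_ALPHA_BETA)
        if alpha_positive:
            q_minus = float(np.floor(rng.uniform(0, 1300)))
            q_plus = q_minus + float(np.ceil(rng.uniform(30, 3500)))
        else:
            q_minus = float(np.floor(rng.uniform(0, 5))) * float(
                rng.uniform() < 0.3)
            q_plus = float(np.floor(rng.uniform(0, q_minus + 1)))
            q_plus = min(q_plus, q_minus)
        if beta_positive:
            sn = float(rng.uniform(1.05, 33.0))
        else:
            sn = float(rng.uniform(0.0, 1.0))
        records.append(PeakEvidence(gene=str(gene), q_minus=q_minus,
                                    q_plus=q_plus, sn_ratio=sn))
    return records


def simulate_gene_sets(truth: GroundTruth, n_sets: int,
                       enriched_fraction: float, seed: int,
                       set_size: int = 50) -> GeneSetCollection:
    """Draw gene sets, one of which over-samples planted responders.

    ``enriched_fraction`` in (0, 1] is the fraction of the designated set
    ("responder_module") drawn from responder genes; the remainder, and all
    other sets, are sampled uniformly without replacement from the full
    gene universe. Setting it to the background responder share yields an
    unenriched control.
    """
    if n_sets < 1:
        raise ValueError(f"n_sets must be >= 1, got {n_sets}")
    if not 0 < enriched_fraction <= 1:
        raise ValueError(
            f"enriched_fraction must lie in (0, 1], got {enriched_fraction!r}")
    universe = list(truth.table.index)
    if set_size > len(universe):
        raise ValueError(
            f"set_size {set_size} exceeds the {len(universe)}-gene universe")
    rng = np.random.default_rng(seed)
    responders = truth.responders
    collection = GeneSetCollection()

    n_resp = min(round(enriched_fraction * set_size), len(responders))
    chosen = list(rng.choice(responders, size=n_resp, replace=False))
    # Fill from non-responders so the set's responder share equals
    # enriched_fraction; spill over into unchosen responders only if the
    # universe leaves no other option.
    non_responders = [g for g in universe
                      if g not in set(responders)]
    pool = non_responders if len(non_responders) >= set_size - n_resp else \
        [g for g in universe if g not in set(chosen)]
    filler = list(rng.choice(pool, size=set_size - n_resp, replace=False))
    collection.add(GeneSet(name="responder_module",
                           description="planted responder-enriched set",
                           genes=tuple(sorted(chosen + filler))))
    for i in range(2, n_sets + 1):
        members = rng.choice(universe, size=set_size, replace=False)
        collection.add(GeneSet(name=f"random_set_{i:02d}",
                               description="uniformly sampled set",
                               genes=tuple(sorted(members))))
    return collection


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", float_format="%.17g")


def read_ground_truth(path) -> GroundTruth:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return GroundTruth(table=table)
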