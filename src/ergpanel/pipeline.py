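"""End-to-end pipeline driver.

Runs the full analysis in the order the stages build on each other:
response profiles and volcano tables, stability ranking and panel
selection, nested-set correlation, ER-subtype classification of peak
evidence, and over-representation of the selected panels. Every written
table is stamped with the run configuration (including the seed), and
identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import correlation, enrichment, io, response, simulate, stability
from . import subtype as subtype_mod
from .config import RunConfig

logger = logging.getLogger(__name__)

#: Nested set sizes for the correlation evaluation; sizes exceeding the
#: ranking are dropped per run.
DEFAULT_NESTED_SIZES = (203, 174, 150, 120, 90, 60, 30)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@contextmanager
def _stage(name: str):
    logger.info("pipeline stage: %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


@dataclass
class PipelineResult:
    config: RunConfig
    profiles: response.ResponseProfiles
    panel: stability.PanelSelection
    ranked: list[stability.StabilityRecord]
    subtype_counts: Optional[dict[str, int]]
    paths: dict[str, Path]


def run_full_pipeline(
        config: RunConfig,
        out_dir,
        *,
        experiment: Optional[io.ExpressionExperiment] = None,
        sim_config: Optional[simulate.SimulationConfig] = None,
        truth: Optional[simulate.GroundTruth] = None,
        evidence: Optional[Sequence[subtype_mod.PeakEvidence]] = None,
        gene_sets: Optional[io.GeneSetCollection] = None,
        nested_sizes: Sequence[int] = DEFAULT_NESTED_SIZES,
) -> PipelineResult:
    """Run every stage and write the report bundle under ``out_dir``.

    Either an ``experiment`` (with optional ``evidence``/``gene_sets``) or
    a ``sim_config`` must be supplied. In synthetic mode, peak evidence
    for the small panel and gene-set collections are simulated from the
    ground truth when not given explicitly (seeds derived from
    ``config.seed``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = out_dir / name
        io.write_report(frame, path, config, **kwargs)
        paths[name] = path

    with _stage("input"):
        if experiment is None:
            if sim_config is None:
                raise ValueError(
                    "either an experiment or a sim_config is required")
            experiment, truth = simulate.simulate_experiment(sim_config)

    with _stage("response"):
        profiles = response.response_profile(experiment, config)

    with _stage("stability"):
        records = stability.stability_records(profiles, config)
        ranked = stability.rank_by_stability(records)
        panel = stability.select_panel(profiles, records, config)
        for warning in panel.warnings:
            logger.warning("panel selection: %s", warning)
        ranked_frame = pd.DataFrame(
            [{"gene": r.gene, "av": r.av, "sd": r.sd, "cv": r.cv,
              "rank": r.rank, "direction": r.direction,
              "flags": ";".join(r.flags)} for r in ranked])
        _write("stability_ranking.tsv", ranked_frame)
        _write("panel.tsv", panel.to_frame())
        sizes = [s for s in nested_sizes if s <= len(ranked)]
        if sizes:
            _write("mean_cv_by_set.tsv", stability.mean_cv_by_set(ranked, sizes))

    with _stage("volcano"):
        cv_series = pd.Series({r.gene: r.cv for r in records})
        _write("volcano_pvalue.tsv",
               response.volcano_table(profiles, "pvalue", config.alpha))
        _write("volcano_cv.tsv",
               response.volcano_table(profiles, "cv", config.alpha,
                                      cv=cv_series))

    with _stage("correlation"):
        log_t = response.log2_with_pseudocount(experiment.treated,
                                               config.pseudocount)
        labels = list(experiment.replicate_labels)
        frames = pd.DataFrame(log_t, index=list(experiment.gene_ids),
                              columns=labels)
        sizes = [s for s in nested_sizes if 2 <= s <= len(ranked)]
        if sizes and len(labels) >= 2:
            table = correlation.nested_set_correlation(
                frames[labels[0]],
                {lab: frames[lab] for lab in labels[1:]},
                ranked, sizes, reference_label=labels[0])
            _write("nested_correlation.tsv", table)

    subtype_counts = None
    with _stage("subtype"):
        if evidence is None and truth is not None and panel.top_k:
            evidence = simulate.simulate_peak_evidence(
                truth, seed=config.seed + 1,
                genes=[r.gene for r in panel.top_k])
        if evidence is not None:
            calls, subtype_counts = subtype_mod.classify_panel(evidence)
            calls_frame = pd.DataFrame(
                [{"gene": c.gene,
                  "alpha_bound": "+" if c.alpha_bound else "-",
                  "beta_bound": "+" if c.beta_bound else "-",
                  "subtype": c.subtype, "flags": ";".join(c.flags)}
                 for c in calls])
            _write("subtype_calls.tsv", calls_frame)
            counts_frame = pd.DataFrame(
                [{"subtype": s, "count": subtype_counts[s]}
                 for s in subtype_mod.SUBTYPES])
            _write("subtype_counts.tsv", counts_frame)

    with _stage("enrichment"):
        if gene_sets is None and truth is not None:
            gene_sets = simulate.simulate_gene_sets(
                truth, n_sets=10, enriched_fraction=0.8,
                seed=config.seed + 2,
                set_size=min(50, experiment.n_genes))
        if gene_sets:
            universe = [
                g for g, floor_ok in zip(
                    profiles.genes,
                    profiles.summary["mean_control_fpkm"]
                    >= config.expression_floor)
                if floor_ok]
            for direction, panel_records in (("up", panel.up),
                                             ("down", panel.down)):
                query = [r.gene for r in panel_records]
                if not query:
                    continue
                results = enrichment.enrich_collection(query, gene_sets,
                                                       universe)
                _write(f"enrichment_{direction}.tsv", results)
                _write(f"enrichment_{direction}_top.tsv",
                       enrichment.top_categories(
                           results, config.fdr_threshold,
                           config.top_n_categories))

    return PipelineResult(config=config, profiles=profiles, panel=panel,
                          ranked=ranked, subtype_counts=subtype_counts,
                          paths=paths)
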