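"""Packaged reference tables.

Two small published tables ship with the package as plain TSV:

* the CV ranking of the 30-gene estrogen-responsive panel derived from
  replicated RNA-seq of estradiol-treated MCF-7 cells (rank, gene symbol,
  CV = |SD/Av| of the log2 response ratios), and
* the ChIP peak evidence for the 29 protein-coding genes of that panel
  (ERα peak-significance scores without/with estradiol within ±10 kb of
  the TSS, ERβ S/N ratio, and the reported receptor-subtype label). The
  panel's one long non-coding RNA has no usable evidence and is absent.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .stability import StabilityRecord
from .subtype import PeakEvidence

_PACKAGE = "ergpanel.data"


def _data_path(name: str):
    return resources.files(_PACKAGE).joinpath(name)


def load_cv_ranking() -> pd.DataFrame:
    """The published 30-gene CV ranking as a frame (rank, gene, cv)."""
    with resources.as_file(_data_path("erg30_cv_ranking.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def cv_ranking_records() -> list[StabilityRecord]:
    """The CV ranking as stability records.

    Only the CV itself is published, so Av and SD are NaN; the ranking
    tie-break treats a missing |Av| as zero.
    """
    frame = load_cv_ranking()
    return [StabilityRecord(gene=row.gene, av=math.nan, sd=math.nan,
                            cv=float(row.cv), cv_defined=True)
            for row in frame.itertuples()]


def load_chip_evidence() -> list[PeakEvidence]:
    """The 29-gene ChIP peak-evidence table as records."""
    frame = _chip_frame()
    return [PeakEvidence(gene=row.gene, q_minus=float(row.q_minus),
                         q_plus=float(row.q_plus),
                         sn_ratio=float(row.sn_ratio))
            for row in frame.itertuples()]


def load_reported_subtypes() -> dict[str, str]:
    """Gene -> published receptor-subtype label for the 29 evidence rows."""
    frame = _chip_frame()
    return dict(zip(frame["gene"], frame["reported_subtype"]))


def _chip_frame() -> pd.DataFrame:
    with resources.as_file(_data_path("erg29_chip_evidence.tsv")) as path:
        return pd.read_csv(path, sep="\t")
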