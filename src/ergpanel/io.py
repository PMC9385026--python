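"""Readers and writers for the pipeline's tabular formats.

Expression matrices are tab-separated text: first column the gene symbol,
header row of replicate labels, numeric FPKM body. Gene sets use the GMT
dialect (set name, description, tab-separated members). ChIP peak evidence
is a headered TSV with either a precomputed S/N ratio or the raw
rep1/rep2/input signals it is computed from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .subtype import PeakEvidence, sn_ratio

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionExperiment:
    """Paired treated/control FPKM matrices sharing a gene index.

    Replicates are paired by column position: treated column *i* and control
    column *i* form replicate pair *i*.
    """

    gene_ids: tuple[str, ...]
    treated: np.ndarray  # genes x replicates, FPKM
    control: np.ndarray
    replicate_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        treated = np.asarray(self.treated, dtype=float)
        control = np.asarray(self.control, dtype=float)
        object.__setattr__(self, "treated", treated)
        object.__setattr__(self, "control", control)
        n_genes = len(self.gene_ids)
        if len(set(self.gene_ids)) != n_genes:
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise ValueError(f"duplicate gene identifier: {g!r}")
                seen.add(g)
        if any(not g for g in self.gene_ids):
            raise ValueError("empty gene identifier")
        if treated.shape != (n_genes, len(self.replicate_labels)):
            raise ValueError(
                f"treated matrix shape {treated.shape} does not match "
                f"{n_genes} genes x {len(self.replicate_labels)} replicates")
        if control.shape != treated.shape:
            raise ValueError(
                f"control matrix shape {control.shape} does not match treated "
                f"shape {treated.shape}: arms must have identical replicate counts")
        for name, arr in (("treated", treated), ("control", control)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} matrix contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} matrix contains negative FPKM values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_labels)

    def arm_frame(self, arm: str) -> pd.DataFrame:
        matrix = {"treated": self.treated, "control": self.control}[arm]
        return pd.DataFrame(matrix, index=list(self.gene_ids),
                            columns=list(self.replicate_labels))

    @classmethod
    def from_frames(cls, treated: pd.DataFrame,
                    control: pd.DataFrame) -> "ExpressionExperiment":
        """Pair two gene x replicate frames into one experiment.

        Both frames must cover the same genes; the control frame is aligned
        to the treated frame's row order. Replicate labels are taken from
        the treated frame.
        """
        if treated.shape[1] != control.shape[1]:
            raise ValueError(
                f"arm replicate counts differ: treated has {treated.shape[1]}, "
                f"control has {control.shape[1]}")
        missing = [g for g in treated.index if g not in control.index]
        if missing:
            raise ValueError(
                f"genes missing from control arm: {missing[:5]}")
        if len(control.index) != len(treated.index):
            extra = [g for g in control.index if g not in set(treated.index)]
            raise ValueError(f"genes missing from treated arm: {extra[:5]}")
        control = control.loc[treated.index]
        return cls(gene_ids=tuple(treated.index),
                   treated=treated.to_numpy(dtype=float),
                   control=control.to_numpy(dtype=float),
                   replicate_labels=tuple(str(c) for c in treated.columns))

    @classmethod
    def from_files(cls, treated_path, control_path) -> "ExpressionExperiment":
        return cls.from_frames(read_expression_matrix(treated_path),
                               read_expression_matrix(control_path))


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a gene x replicate FPKM matrix from headered TSV.

    Raises
    ------
    ValueError
        On a duplicated gene identifier (named in the message) or a
        non-numeric cell (row and column named).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False)
    frame.index = frame.index.astype(str)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifier in {path}: {dup[0]!r}")
    numeric = {}
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].astype(str).str.strip().ne("nan")
        if bad.any():
            gene = frame.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value in {path} at gene {gene!r}, "
                f"column {col!r}: {frame.loc[gene, col]!r}")
        # float() is correctly rounded; pandas' fast parser is not, which
        # would break exact write/read round-trips.
        numeric[col] = frame[col].map(float)
    return pd.DataFrame(numeric, index=frame.index)


def write_expression_matrix(frame: pd.DataFrame, path) -> None:
    """Write a gene x replicate matrix to the TSV dialect read back by
    :func:`read_expression_matrix`. Full float precision is preserved."""
    frame = frame.copy()
    frame.index.name = frame.index.name or "gene"
    frame.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection(dict):
    """Mapping of set name -> :class:`GeneSet` preserving file order."""

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self:
            raise ValueError(f"duplicate gene-set name: {gene_set.name!r}")
        self[gene_set.name] = gene_set


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; members are de-duplicated within each set.

    Raises ``ValueError`` naming the line number for a line with fewer than
    three tab-separated fields.
    """
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members)")
            name, description, *members = fields
            unique = tuple(dict.fromkeys(m for m in members if m))
            collection.add(GeneSet(name=name, description=description,
                                   genes=unique))
    return collection


def write_gmt(collection: Mapping[str, GeneSet], path) -> None:
    with open(path, "w") as handle:
        for gene_set in collection.values():
            handle.write("\t".join([gene_set.name, gene_set.description,
                                    *gene_set.genes]) + "\n")


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks skipped."""
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")


# ---------------------------------------------------------------------------
# ChIP peak evidence
# ---------------------------------------------------------------------------

_EVIDENCE_SCORE_COLS = ("q_minus", "q_plus")
_EVIDENCE_RAW_COLS = ("rep1", "rep2", "input")


def read_peak_evidence(path) -> list[PeakEvidence]:
    """Read a peak-evidence table into :class:`PeakEvidence` records.

    The TSV must carry columns ``gene``, ``q_minus``, ``q_plus`` and either
    ``sn_ratio`` or the raw ``rep1``/``rep2``/``input`` signals from which
    the S/N ratio is computed. Supplying both forms is rejected as
    ambiguous. Extra columns are ignored.
    """
    frame = pd.read_csv(path, sep="\t")
    frame.columns = [str(c).strip() for c in frame.columns]
    required = ("gene",) + _EVIDENCE_SCORE_COLS
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_sn = "sn_ratio" in frame.columns
    has_raw = all(c in frame.columns for c in _EVIDENCE_RAW_COLS)
    if has_sn and any(c in frame.columns for c in _EVIDENCE_RAW_COLS):
        raise ValueError(
            f"{path}: both sn_ratio and raw rep1/rep2/input signals present "
            "- ambiguous evidence table")
    if not has_sn and not has_raw:
        raise ValueError(
            f"{path}: need either an sn_ratio column or all of "
            f"{_EVIDENCE_RAW_COLS}")

    records: list[PeakEvidence] = []
    for _, row in frame.iterrows():
        gene = str(row["gene"])
        numeric_cols = list(_EVIDENCE_SCORE_COLS)
        numeric_cols += ["sn_ratio"] if has_sn else list(_EVIDENCE_RAW_COLS)
        for col in numeric_cols:
            value = float(row[col])
            if not np.isfinite(value):
                raise ValueError(
                    f"{path}: non-finite {col} for gene {gene!r}")
            if value < 0:
                raise ValueError(
                    f"{path}: negative {col} ({value}) for gene {gene!r}")
        if has_sn:
            sn = float(row["sn_ratio"])
        else:
            sn = sn_ratio(float(row["rep1"]), float(row["rep2"]),
                          float(row["input"]))
        records.append(PeakEvidence(gene=gene,
                                    q_minus=float(row["q_minus"]),
                                    q_plus=float(row["q_plus"]),
                                    sn_ratio=sn))
    return records


def write_peak_evidence(records: Sequence[PeakEvidence], path) -> None:
    frame = pd.DataFrame(
        {"gene": [r.gene for r in records],
         "q_minus": [r.q_minus for r in records],
         "q_plus": [r.q_plus for r in records],
         "sn_ratio": [r.sn_ratio for r in records]})
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Stamped reports
# ---------------------------------------------------------------------------

def write_report(frame: pd.DataFrame, path, config, *,
                 index: bool = False, float_format: str = "%.10g") -> None:
    """Write a report table stamped with the producing configuration.

    The first line is a ``#``-prefixed comment holding the canonical JSON of
    the run configuration (including the seed), so every number in the file
    is reproducible from the file alone.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        handle.write(f"# ergpanel-config: {config.to_json()}\n")
        frame.to_csv(handle, sep="\t", index=index, float_format=float_format)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
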