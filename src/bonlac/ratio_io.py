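"""Reading MaxQuant-dialect protein-group tables and orienting SILAC ratios.

MaxQuant reports one normalized heavy/medium (H/M) ratio per protein group
per replicate experiment.  Because the isotope labels are alternated between
biological replicates (a "label swap"), the raw H/M ratio of a swapped
replicate is control/affected rather than affected/control and must be
inverted before replicates can be pooled.  This module reads the
proteinGroups dialect, removes artifact rows (decoy "REV__" hits, potential
contaminants, site-only identifications), and orients every ratio into a
single affected-over-control (APP/PS1 : WT) convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ReplicateDesign",
    "LabelDesign",
    "RatioTable",
    "FilterReport",
    "RatioTableError",
    "DesignError",
    "read_protein_groups",
    "orient_ratios",
    "write_oriented_tsv",
    "read_oriented_tsv",
]

#: default regex capturing the replicate name from a MaxQuant ratio column
RATIO_COLUMN_PATTERN = r"Ratio H/M normalized (?P<replicate>.+)"

PROTEIN_ID_COLUMN = "Protein IDs"
GENE_COLUMN = "Gene names"
REVERSE_COLUMN = "Reverse"
CONTAMINANT_COLUMN = "Potential contaminant"
ONLY_SITE_COLUMN = "Only identified by site"

ORIENTATIONS = ("forward", "swapped")


class RatioTableError(ValueError):
    """Malformed or inconsistent ratio table input."""


class DesignError(ValueError):
    """Label design does not match the ratio table."""


@dataclass(frozen=True)
class ReplicateDesign:
    """Channel assignment of one replicate experiment.

    ``forward`` means the affected genotype carries the heavy channel, so the
    raw H/M ratio is already affected/control; ``swapped`` means it must be
    inverted.
    """

    replicate_id: str
    orientation: str
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise DesignError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )


@dataclass(frozen=True)
class LabelDesign:
    """Per-replicate channel assignments for one cohort."""

    replicates: tuple[ReplicateDesign, ...]

    def __post_init__(self) -> None:
        ids = [r.replicate_id for r in self.replicates]
        if len(set(ids)) != len(ids):
            raise DesignError(f"duplicate replicate ids in design: {ids}")

    @property
    def replicate_ids(self) -> list[str]:
        return [r.replicate_id for r in self.replicates]

    def orientation_of(self, replicate_id: str) -> str:
        for r in self.replicates:
            if r.replicate_id == replicate_id:
                return r.orientation
        raise DesignError(f"replicate {replicate_id!r} not in design")

    def flipped(self) -> "LabelDesign":
        """The design with every replicate's swap flag inverted."""
        flip = {"forward": "swapped", "swapped": "forward"}
        return LabelDesign(
            tuple(
                ReplicateDesign(r.replicate_id, flip[r.orientation], r.cohort)
                for r in self.replicates
            )
        )

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, str]]) -> "LabelDesign":
        return cls(
            tuple(
                ReplicateDesign(
                    str(rec["replicate_id"]),
                    str(rec["orientation"]),
                    str(rec.get("cohort", "")),
                )
                for rec in records
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"replicate_id", "orientation"}
        if not required.issubset(df.columns):
            raise DesignError(
                f"design file needs columns {sorted(required)}, has {list(df.columns)}"
            )
        return cls.from_records(df.to_dict("records"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_records(doc["replicates"] if isinstance(doc, dict) else doc)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"replicate_id": r.replicate_id, "orientation": r.orientation, "cohort": r.cohort}
                for r in self.replicates
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class FilterReport:
    """Counts of artifact rows removed while reading a protein-group table."""

    reverse: int = 0
    contaminant: int = 0
    only_site: int = 0

    @property
    def total(self) -> int:
        return self.reverse + self.contaminant + self.only_site


@dataclass
class RatioTable:
    """Per-protein, per-replicate fold-change ratios with missing entries.

    ``data`` is indexed by the protein-group leading identifier with one
    float column per replicate (NaN = not quantified).  ``genes`` carries the
    gene symbol annotation.  ``oriented`` records whether label swaps have
    been resolved into the affected/control convention.
    """

    data: pd.DataFrame
    genes: pd.Series = field(default=None)  # type: ignore[assignment]
    oriented: bool = False
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = pd.Series("", index=self.data.index, name="gene")
        self.genes = self.genes.reindex(self.data.index).fillna("")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise RatioTableError(f"duplicate protein ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        present = ~np.isnan(values)
        if np.any(values[present] <= 0) or np.any(np.isinf(values[present])):
            raise RatioTableError("present ratios must be strictly positive and finite")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_replicates(self) -> int:
        return self.data.shape[1]

    def ratios_of(self, protein_id: str) -> np.ndarray:
        return self.data.loc[protein_id].to_numpy(dtype=float)


def _leading_id(protein_ids: str) -> str:
    return str(protein_ids).split(";")[0].strip()


def _is_flagged(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip() == "+"


def read_protein_groups(
    path: str | Path,
    column_pattern: str = RATIO_COLUMN_PATTERN,
    drop_only_site: bool = True,
) -> tuple[RatioTable, FilterReport]:
    """Read a proteinGroups-dialect TSV into a raw (unoriented) ratio table.

    Rows flagged as reverse-database hits or potential contaminants are
    always removed; rows identified only by a modification site are removed
    by default (``drop_only_site``).  Ratio cells that are empty, ``NaN`` or
    ``0`` become missing — a zero SILAC ratio is non-physical and denotes a
    failed quantification.

    Returns the table and a :class:`FilterReport` of removed row counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if PROTEIN_ID_COLUMN not in df.columns:
        raise RatioTableError(f"missing required column {PROTEIN_ID_COLUMN!r}")

    pattern = re.compile(column_pattern)
    ratio_cols: dict[str, str] = {}
    for col in df.columns:
        m = pattern.fullmatch(col)
        if m:
            ratio_cols[col] = m.group("replicate") if "replicate" in m.groupdict() else col
    if not ratio_cols:
        raise RatioTableError(
            f"no ratio columns matching {column_pattern!r} in header: {list(df.columns)}"
        )

    report = FilterReport()
    if REVERSE_COLUMN in df.columns:
        flagged = _is_flagged(df[REVERSE_COLUMN])
        report.reverse = int(flagged.sum())
        df = df[~flagged]
    if CONTAMINANT_COLUMN in df.columns:
        flagged = _is_flagged(df[CONTAMINANT_COLUMN])
        report.contaminant = int(flagged.sum())
        df = df[~flagged]
    if drop_only_site and ONLY_SITE_COLUMN in df.columns:
        flagged = _is_flagged(df[ONLY_SITE_COLUMN])
        report.only_site = int(flagged.sum())
        df = df[~flagged]

    index = df[PROTEIN_ID_COLUMN].map(_leading_id)
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()
        raise RatioTableError(f"duplicate protein ids after filtering: {dups}")

    ratios = pd.DataFrame(index=pd.Index(index, name="protein_id"))
    for col, rep in ratio_cols.items():
        values = pd.to_numeric(df[col], errors="coerce")  # ""/"NaN" -> missing
        values = values.mask(values == 0)  # "0" export variant means missing
        ratios[rep] = values.to_numpy()

    genes = (
        df[GENE_COLUMN].fillna("").map(_leading_id)
        if GENE_COLUMN in df.columns
        else pd.Series("", index=df.index)
    )
    genes = pd.Series(genes.to_numpy(), index=ratios.index, name="gene")
    return RatioTable(data=ratios, genes=genes, oriented=False), report


def orient_ratios(raw: RatioTable, design: LabelDesign) -> RatioTable:
    """Resolve label swaps into the affected/control ratio convention.

    Forward replicates pass through unchanged; swapped replicates are
    inverted element-wise.  Missing stays missing.
    """
    missing = set(raw.replicate_ids) - set(design.replicate_ids)
    if missing:
        raise DesignError(f"replicates without a design row: {sorted(missing)}")
    data = raw.data.copy()
    for rep in data.columns:
        if design.orientation_of(rep) == "swapped":
            data[rep] = 1.0 / data[rep]
    return RatioTable(data=data, genes=raw.genes.copy(), oriented=True, cohort=raw.cohort)


def write_oriented_tsv(table: RatioTable, path: str | Path) -> None:
    """Write the canonical oriented ratio TSV (protein, gene, one column per replicate)."""
    out = table.data.copy()
    out.insert(0, "gene", table.genes)
    out.to_csv(path, sep="\t", index=True, index_label="protein_id")


def read_oriented_tsv(path: str | Path, cohort: str = "") -> RatioTable:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    genes = df.pop("gene").fillna("") if "gene" in df.columns else None
    return RatioTable(data=df.astype(float), genes=genes, oriented=True, cohort=cohort)
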