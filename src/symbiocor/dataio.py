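"""Readers, writers and validated containers for count matrices, sample
metadata and functional annotation.

All tabular files are tab-separated UTF-8 with a header row; lines starting
with ``#`` are ignored.  Count matrices are genes x samples with the first
column named ``gene_id``.  Genes that are zero in every sample are retained
through I/O; stages that need to drop them do so explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("symbiocor")

ORGANISMS = ("host", "symA", "symB")
STATUSES = ("singleA", "singleB", "mixed")


class ValidationError(ValueError):
    """Raised when an input table violates the format contract."""


class AlignmentError(ValueError):
    """Raised when matrices share no samples."""


@dataclass
class CountMatrix:
    """Nonnegative integer read counts for one organism, genes x samples."""

    organism: str
    counts: pd.DataFrame  # index = gene_id, columns = sample_id

    def __post_init__(self) -> None:
        if self.organism not in ORGANISMS:
            raise ValidationError(
                f"organism must be one of {ORGANISMS}, got {self.organism!r}"
            )
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at gene {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}"
                )
            self.counts = df.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def restrict_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise ValidationError(f"samples not in matrix: {sorted(missing)}")
        return CountMatrix(self.organism, self.counts.loc[:, list(sample_ids)])


@dataclass
class SampleTable:
    """Per-sample metadata: culture of origin, infection status, replicate."""

    table: pd.DataFrame  # columns: sample_id, culture, status, replicate

    REQUIRED = ("sample_id", "culture", "status", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[
                self.table["sample_id"].duplicated(), "sample_id"
            ].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        bad = set(self.table["status"]) - set(STATUSES)
        if bad:
            raise ValidationError(
                f"unknown status values {sorted(bad)}; expected {STATUSES}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def status_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["status"].iloc[0]

    def samples_with_status(self, *statuses: str) -> list[str]:
        mask = self.table["status"].isin(statuses)
        return list(self.table.loc[mask, "sample_id"])

    def restrict(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        order = {s: i for i, s in enumerate(sample_ids)}
        keep = keep.sort_values("sample_id", key=lambda s: s.map(order))
        return SampleTable(keep.reset_index(drop=True))


@dataclass
class AnnotationMap:
    """gene -> KEGG ortholog -> pathway mapping.

    ``gene_to_ko`` may omit genes (unannotated); every pathway referenced by
    an ortholog must exist in ``pathway_names``.
    """

    gene_to_ko: dict[str, str]
    ko_to_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    pathway_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        referenced = set().union(*self.ko_to_pathways.values()) if self.ko_to_pathways else set()
        unknown = referenced - set(self.pathway_names)
        if unknown:
            raise ValidationError(
                f"pathways referenced but not defined: {sorted(unknown)}"
            )

    def genes_in_pathway(self, pathway_id: str, gene_ids: Iterable[str]) -> list[str]:
        """Genes among ``gene_ids`` whose ortholog maps to ``pathway_id``."""
        out = []
        for g in gene_ids:
            ko = self.gene_to_ko.get(g)
            if ko is not None and pathway_id in self.ko_to_pathways.get(ko, frozenset()):
                out.append(g)
        return out

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.pathway_names)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_counts(path: str | Path, organism: str) -> CountMatrix:
    """Read a gene x sample count TSV into a validated :class:`CountMatrix`.

    Sample order is preserved from the file header.
    """
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise ValidationError(
            f"{path}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_id")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValidationError(f"{path}: ragged or missing values in rows {rows}")
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric count: {exc}") from exc
    return CountMatrix(organism, numeric)


def write_counts(matrix: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    return path


def read_sample_table(path: str | Path) -> SampleTable:
    df = _read_tsv(path)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    return SampleTable(df)


def write_sample_table(meta: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    meta.table.to_csv(path, sep="\t", index=False)
    return path


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read a flat annotation TSV: gene_id, ko, pathway_id, pathway_name.

    One row per (gene, pathway) link; rows with empty ko are unannotated
    genes and ignored.
    """
    df = _read_tsv(path)
    required = {"gene_id", "ko", "pathway_id", "pathway_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: annotation missing columns {sorted(missing)}")
    gene_to_ko: dict[str, str] = {}
    ko_to_pathways: dict[str, set[str]] = {}
    pathway_names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if pd.isna(row.ko):
            continue
        gene_to_ko[row.gene_id] = row.ko
        if not pd.isna(row.pathway_id):
            ko_to_pathways.setdefault(row.ko, set()).add(row.pathway_id)
            pathway_names[row.pathway_id] = row.pathway_name
    return AnnotationMap(
        gene_to_ko,
        {k: frozenset(v) for k, v in ko_to_pathways.items()},
        pathway_names,
    )


def write_annotation(ann: AnnotationMap, path: str | Path) -> Path:
    rows = []
    for gene, ko in ann.gene_to_ko.items():
        pws = sorted(ann.ko_to_pathways.get(ko, frozenset()))
        if not pws:
            rows.append((gene, ko, "", ""))
        for pw in pws:
            rows.append((gene, ko, pw, ann.pathway_names[pw]))
    pd.DataFrame(rows, columns=["gene_id", "ko", "pathway_id", "pathway_name"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def align_samples(
    matrices: Sequence[CountMatrix], meta: SampleTable
) -> tuple[list[CountMatrix], SampleTable]:
    """Restrict matrices and metadata to shared samples, in a canonical order.

    The canonical order is the metadata row order restricted to the common
    set, so the result does not depend on the order of ``matrices``.
    Samples present in a matrix but absent from the metadata are dropped
    with a warning.
    """
    common = set(meta.sample_ids)
    for m in matrices:
        extra = set(m.sample_ids) - set(meta.sample_ids)
        if extra:
            logger.warning(
                "%s: dropping %d sample(s) missing from metadata: %s",
                m.organism, len(extra), sorted(extra),
            )
        common &= set(m.sample_ids)
    if not common:
        raise AlignmentError("no sample ids shared by all matrices and metadata")
    order = [s for s in meta.sample_ids if s in common]
    return [m.restrict_samples(order) for m in matrices], meta.restrict(order)
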