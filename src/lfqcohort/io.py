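"""Readers/writers and validated in-memory containers for cohort tables.

All on-disk artifacts are tab-separated text. Intensity matrices are wide
(one row per protein or peptide, one column per sample); a value of exactly
0 encodes "missing / not quantified". Identifiers are case-sensitive and
matched exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DuplicateIdError, FormatError, ShapeError

VALID_GROUPS = ("MGS1", "MGS2", "QC")
EXCLUSION_REASONS = ("none", "blood_contamination", "aberrant_intensity")


@dataclass
class IntensityMatrix:
    """Non-negative protein(or peptide) x sample intensity matrix.

    Parameters
    ----------
    data:
        DataFrame with accession strings as index and sample ids as columns.
        Values are raw MS intensities; 0 means not quantified.
    level:
        Either ``"protein"`` or ``"peptide"``.
    """

    data: pd.DataFrame
    level: str = "protein"

    def __post_init__(self) -> None:
        if self.level not in ("protein", "peptide"):
            raise FormatError(f"unknown matrix level {self.level!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate row ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups[:5]}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ShapeError(
                f"matrix needs >=1 row and >=2 samples, got {self.data.shape}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric cells in intensity matrix")
        if np.isnan(values).any():
            raise FormatError("NaN cells in intensity matrix (use 0 for missing)")
        if (values < 0).any():
            raise FormatError("negative intensities are not allowed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.data.loc[:, list(sample_ids)].copy(), self.level)

    def subset_proteins(self, protein_ids: Iterable[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.data.loc[list(protein_ids), :].copy(), self.level)


@dataclass
class SampleMetadata:
    """Per-sample group label, run order and exclusion status."""

    table: pd.DataFrame  # index: sample_id; columns: group, run_order, excluded, exclusion_reason

    def __post_init__(self) -> None:
        required = {"group", "run_order"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if "excluded" not in self.table.columns:
            self.table["excluded"] = False
        if "exclusion_reason" not in self.table.columns:
            self.table["exclusion_reason"] = "none"
        self.table.index.name = "sample_id"
        if self.table.index.has_duplicates:
            raise DuplicateIdError("duplicate sample ids in metadata")
        bad_groups = set(self.table["group"]) - set(VALID_GROUPS)
        if bad_groups:
            raise FormatError(f"unknown group labels: {sorted(bad_groups)}")
        bad_reasons = set(self.table["exclusion_reason"]) - set(EXCLUSION_REASONS)
        if bad_reasons:
            raise FormatError(f"unknown exclusion reasons: {sorted(bad_reasons)}")
        run_order = self.table["run_order"]
        if run_order.duplicated().any():
            raise FormatError("run_order values must be unique")
        if (run_order < 1).any():
            raise FormatError("run_order values must be positive")
        mismatch = self.table["excluded"] != (self.table["exclusion_reason"] != "none")
        if mismatch.any():
            raise FormatError("excluded flag must match exclusion_reason != 'none'")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def qc_ids(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "QC"])

    def group_ids(self, group: str, include_excluded: bool = False) -> list[str]:
        mask = self.table["group"] == group
        if not include_excluded:
            mask &= ~self.table["excluded"]
        return list(self.table.index[mask])

    def with_exclusions(self, reasons: Mapping[str, str]) -> "SampleMetadata":
        """Return a copy with the given sample_id -> exclusion_reason applied."""
        table = self.table.copy()
        for sid, reason in reasons.items():
            if reason not in EXCLUSION_REASONS:
                raise FormatError(f"unknown exclusion reason {reason!r}")
            table.loc[sid, "exclusion_reason"] = reason
            table.loc[sid, "excluded"] = reason != "none"
        return SampleMetadata(table)


@dataclass
class AnnotationMap:
    """Accession -> set of category terms (e.g. cellular-component labels)."""

    mapping: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, terms in self.mapping.items():
            for t in terms:
                if not isinstance(t, str) or not t:
                    raise FormatError(f"empty/invalid term for accession {acc!r}")

    def terms_of(self, accession: str) -> set[str]:
        return self.mapping.get(accession, set())

    def with_term(self, term: str) -> set[str]:
        return {acc for acc, terms in self.mapping.items() if term in terms}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.mapping.values():
            out |= terms
        return out


def read_matrix(path: str | Path, level: str = "protein") -> IntensityMatrix:
    """Read a wide TSV intensity matrix.

    First column header must be ``protein_id`` (or ``peptide_id``); remaining
    headers are sample ids. Empty cells become 0 (missing).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, index_col=0)
    if df.index.name not in ("protein_id", "peptide_id"):
        raise FormatError(
            f"first column must be 'protein_id' or 'peptide_id', got {df.index.name!r}"
        )
    # pandas mangles duplicate headers to 'x.1'; detect from the raw header line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header[1:])) != len(header[1:]):
        raise DuplicateIdError("duplicate sample ids in header")
    df = df.fillna(0.0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    df.index.name = None
    return IntensityMatrix(df, level=level)


def write_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write a matrix as wide TSV, reals at 6 significant digits."""
    df = matrix.data.copy()
    df.index.name = "protein_id" if matrix.level == "protein" else "peptide_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV (sample_id, group, run_order[, exclusion])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, index_col="sample_id")
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a long TSV of (accession <tab> term) pairs."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if list(df.columns[:2]) != ["accession", "term"]:
        raise FormatError("annotation TSV must have columns 'accession', 'term'")
    mapping: dict[str, set[str]] = {}
    for acc, term in zip(df["accession"], df["term"]):
        if not isinstance(term, str) or not term:
            raise FormatError(f"empty term for accession {acc!r}")
        mapping.setdefault(acc, set()).add(term)
    return AnnotationMap(mapping)


def write_annotations(annotations: AnnotationMap, path: str | Path) -> None:
    rows = [
        {"accession": acc, "term": term}
        for acc in sorted(annotations.mapping)
        for term in sorted(annotations.mapping[acc])
    ]
    pd.DataFrame(rows, columns=["accession", "term"]).to_csv(path, sep="\t", index=False)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular report deterministically.

    Columns keep their order, floats are printed at 6 significant digits and
    NaN serializes as ``NA`` so re-reading reproduces values to printed
    precision.
    """
    report.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
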