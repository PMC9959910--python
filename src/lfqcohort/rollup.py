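"""Peptide-to-protein rollup: global normalization, peptide outlier
exclusion, and sum aggregation.

The rollup follows ion-current LFQ practice: per-sample totals are equalized
to the median total ("global normalization"), peptides whose sample profile
disagrees with the consensus of their protein's other peptides are excluded,
and protein intensity is the sum of the surviving peptides. The outlier rule
(median-profile Pearson correlation below ``r_min``, applied only to
proteins with at least ``min_peptides`` peptides and peptides sharing at
least 4 quantified samples with the consensus) is this package's explicit
definition; both thresholds are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError
from .io import IntensityMatrix


@dataclass
class RollupResult:
    proteins: IntensityMatrix
    excluded_peptides: set[str]
    untestable_peptides: set[str]
    dropped_proteins: list[str]
    scaling_factors: pd.Series


def normalize_global(peptides: IntensityMatrix) -> tuple[IntensityMatrix, pd.Series]:
    """Scale each sample so its total non-zero intensity equals the median total.

    Zeros (missing values) stay zero. Returns the scaled matrix and the
    per-sample scaling factors.
    """
    totals = peptides.data.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise DegenerateSampleError(f"all-zero sample(s): {bad}")
    target = float(totals.median())
    factors = target / totals
    scaled = peptides.data * factors
    return IntensityMatrix(scaled, level=peptides.level), factors.rename("scaling_factor")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def detect_peptide_outliers(
    peptides: IntensityMatrix,
    peptide_to_protein: pd.Series,
    min_peptides: int = 3,
    r_min: float = 0.2,
) -> tuple[set[str], set[str]]:
    """Flag peptides discordant with their protein's consensus profile.

    For each protein with >= ``min_peptides`` peptides, each peptide is
    correlated (Pearson, over samples where both are non-zero, requiring >=4
    shared samples) against the per-sample median profile of the protein's
    *other* peptides. Peptides with r < ``r_min`` are excluded. Returns
    (excluded ids, untestable ids); untestable peptides are retained.
    """
    excluded: set[str] = set()
    untestable: set[str] = set()
    df = peptides.data
    for protein, group in peptide_to_protein.groupby(peptide_to_protein):
        pep_ids = list(group.index)
        if len(pep_ids) < min_peptides:
            continue
        block = df.loc[pep_ids].to_numpy()
        for i, pid in enumerate(pep_ids):
            others = np.delete(block, i, axis=0)
            with warnings.catch_warnings(), np.errstate(invalid="ignore"):
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.where(
                    (others > 0).any(axis=0),
                    np.nanmedian(np.where(others > 0, others, np.nan), axis=0),
                    0.0,
                )
            mask = (block[i] > 0) & (med > 0)
            if mask.sum() < 4:
                untestable.add(pid)
                continue
            r = _pearson(block[i][mask], med[mask])
            if np.isnan(r):
                untestable.add(pid)
            elif r < r_min:
                excluded.add(pid)
    return excluded, untestable


def aggregate_protein(
    peptides: IntensityMatrix,
    peptide_to_protein: pd.Series,
    excluded: set[str] | None = None,
) -> tuple[IntensityMatrix, list[str]]:
    """Sum surviving peptide intensities per protein and sample.

    Proteins whose peptides were all excluded are dropped and listed.
    """
    excluded = excluded or set()
    keep = [p for p in peptides.data.index if p not in excluded]
    dropped = sorted(
        set(peptide_to_protein.unique())
        - set(peptide_to_protein.loc[keep].unique())
    )
    summed = peptides.data.loc[keep].groupby(peptide_to_protein.loc[keep]).sum()
    summed = summed.loc[[p for p in peptide_to_protein.unique() if p in summed.index]]
    summed.index.name = None
    return IntensityMatrix(summed, level="protein"), dropped


def rollup(
    peptides: IntensityMatrix,
    peptide_to_protein: pd.Series,
    min_peptides: int = 3,
    r_min: float = 0.2,
) -> RollupResult:
    """Full rollup: normalize -> exclude outlier peptides -> aggregate."""
    normalized, factors = normalize_global(peptides)
    excluded, untestable = detect_peptide_outliers(
        normalized, peptide_to_protein, min_peptides=min_peptides, r_min=r_min
    )
    proteins, dropped = aggregate_protein(normalized, peptide_to_protein, excluded)
    return RollupResult(
        proteins=proteins,
        excluded_peptides=excluded,
        untestable_peptides=untestable,
        dropped_proteins=dropped,
        scaling_factors=factors,
    )
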