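"""Dataset-level quantification quality and pooled-QC reproducibility metrics.

Covers the cohort summary statistics (missing-data-free fraction, dynamic
range, TOP-N intensity share) and the pooled-QC monitoring scheme: proteins
are ranked by mean QC intensity, split into a high-abundance stratum (top
``high_fraction`` by count) and a low-abundance remainder, and per-stratum
coefficient-of-variation summaries and inter-run Pearson correlation
matrices are reported. Zeros are treated as missing throughout (excluded,
never imputed), so correlations are pairwise-complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientReplicatesError
from .io import IntensityMatrix


@dataclass
class StratumCV:
    median_cv_percent: float
    sd_cv_percent: float
    n_proteins: int
    protein_ids: list[str]


@dataclass
class QCReport:
    missing_free_fraction: float
    dynamic_range_log10: float
    mean_proteins_per_sample: float
    top_n: int
    top_n_share_percent: float
    stratified_cv: dict[str, StratumCV]
    n_dropped: int
    correlation: dict[str, pd.DataFrame]


def missing_free_fraction(matrix: IntensityMatrix) -> float:
    """Fraction of proteins quantified (non-zero) in every sample."""
    return float((matrix.values > 0).all(axis=1).mean())


def dynamic_range(matrix: IntensityMatrix) -> float:
    """log10(max/min) of per-protein mean non-zero intensity.

    All-zero rows are ignored; fewer than 2 usable rows is degenerate.
    """
    values = matrix.values
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.where(
            (values > 0).any(axis=1),
            np.nanmean(np.where(values > 0, values, np.nan), axis=1),
            np.nan,
        )
    usable = means[~np.isnan(means)]
    if usable.size < 2:
        raise DegenerateInputError("need >=2 proteins with non-zero mean")
    return float(np.log10(usable.max() / usable.min()))


def mean_proteins_per_sample(matrix: IntensityMatrix) -> float:
    """Average number of proteins with a non-zero value per sample."""
    return float((matrix.values > 0).sum(axis=0).mean())


def top_n_share(matrix: IntensityMatrix, n: int) -> float:
    """Percent of the grand total carried by the n highest-total proteins."""
    totals = matrix.values.sum(axis=1)
    if n > totals.size:
        raise DegenerateInputError(f"n={n} exceeds protein count {totals.size}")
    top = np.sort(totals)[::-1][:n].sum()
    return float(100.0 * top / totals.sum())


def _protein_cv_percent(qc_values: np.ndarray) -> np.ndarray:
    """Per-protein CV%% over non-zero QC values; NaN if <3 non-zero values."""
    masked = np.where(qc_values > 0, qc_values, np.nan)
    n = (~np.isnan(masked)).sum(axis=1)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(masked, axis=1)
        sd = np.nanstd(masked, axis=1, ddof=1)
        cv = 100.0 * sd / mean
    cv[n < 3] = np.nan
    return cv


def stratified_cv(
    matrix: IntensityMatrix,
    qc_sample_ids: list[str],
    high_fraction: float = 0.75,
) -> tuple[dict[str, StratumCV], int]:
    """Median +/- sd of per-protein QC-replicate CV%% in two abundance strata.

    Proteins are ranked by mean non-zero QC intensity; the top
    ``high_fraction`` (by protein count, after dropping proteins with <3
    non-zero QC values) form the "high" stratum, the rest the "low" stratum.
    Returns (strata, number of dropped proteins).
    """
    if len(qc_sample_ids) < 3:
        raise InsufficientReplicatesError("need >=3 QC runs for CV monitoring")
    qc = matrix.data.loc[:, qc_sample_ids].to_numpy()
    cv = _protein_cv_percent(qc)
    masked = np.where(qc > 0, qc, np.nan)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        abundance = np.nanmean(masked, axis=1)
    usable = ~np.isnan(cv)
    n_dropped = int((~usable).sum())
    ids = np.array(matrix.protein_ids)[usable]
    cv_u = cv[usable]
    ab_u = abundance[usable]
    order = np.argsort(-ab_u, kind="stable")  # descending abundance
    n_high = int(round(high_fraction * order.size))
    strata = {}
    for name, idx in (("high", order[:n_high]), ("low", order[n_high:])):
        vals = cv_u[idx]
        strata[name] = StratumCV(
            median_cv_percent=float(np.median(vals)) if vals.size else np.nan,
            sd_cv_percent=float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            n_proteins=int(vals.size),
            protein_ids=list(ids[idx]),
        )
    return strata, n_dropped


def qc_correlation(
    matrix: IntensityMatrix,
    qc_sample_ids: list[str],
    stratum_protein_ids: list[str],
    min_shared: int = 10,
) -> pd.DataFrame:
    """Pairwise-complete Pearson r of log10 QC intensities within a stratum.

    Pairs sharing fewer than ``min_shared`` quantified proteins get NaN.
    """
    sub = matrix.data.loc[stratum_protein_ids, qc_sample_ids].to_numpy()
    k = len(qc_sample_ids)
    out = np.full((k, k), np.nan)
    for i in range(k):
        out[i, i] = 1.0
        for j in range(i + 1, k):
            mask = (sub[:, i] > 0) & (sub[:, j] > 0)
            if mask.sum() < min_shared:
                continue
            x = np.log10(sub[mask, i])
            y = np.log10(sub[mask, j])
            if x.std() == 0 or y.std() == 0:
                continue
            out[i, j] = out[j, i] = float(np.corrcoef(x, y)[0, 1])
    return pd.DataFrame(out, index=qc_sample_ids, columns=qc_sample_ids)


def qc_report(
    matrix: IntensityMatrix,
    qc_sample_ids: list[str],
    top_n: int = 3,
    high_fraction: float = 0.75,
) -> QCReport:
    """Assemble the full QC report for a cohort matrix."""
    strata, n_dropped = stratified_cv(matrix, qc_sample_ids, high_fraction)
    correlation = {
        name: qc_correlation(matrix, qc_sample_ids, s.protein_ids)
        for name, s in strata.items()
    }
    return QCReport(
        missing_free_fraction=missing_free_fraction(matrix),
        dynamic_range_log10=dynamic_range(matrix),
        mean_proteins_per_sample=mean_proteins_per_sample(matrix),
        top_n=top_n,
        top_n_share_percent=top_n_share(matrix, top_n),
        stratified_cv=strata,
        n_dropped=n_dropped,
        correlation=correlation,
    )


def qc_report_frame(report: QCReport) -> pd.DataFrame:
    """Flatten a QCReport into a tidy key/value table for writing."""
    rows = [
        ("missing_free_fraction", report.missing_free_fraction),
        ("dynamic_range_log10", report.dynamic_range_log10),
        ("mean_proteins_per_sample", report.mean_proteins_per_sample),
        (f"top{report.top_n}_share_percent", report.top_n_share_percent),
        ("n_dropped_proteins", report.n_dropped),
    ]
    for name, s in report.stratified_cv.items():
        rows.append((f"{name}_stratum_median_cv_percent", s.median_cv_percent))
        rows.append((f"{name}_stratum_sd_cv_percent", s.sd_cv_percent))
        rows.append((f"{name}_stratum_n_proteins", s.n_proteins))
    return pd.DataFrame(rows, columns=["metric", "value"])
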