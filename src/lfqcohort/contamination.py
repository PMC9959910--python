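"""Blood-contamination sample qualification.

Each sample is scored by the share of its total MS intensity carried by
blood marker proteins (erythrocyte-, platelet-specific markers and serum
albumin). Samples whose total marker share strictly exceeds the panel
threshold are flagged as blood-contaminated; samples with aberrantly high
total intensity (beyond median + k * 1.4826 * MAD, one-sided) are flagged
separately. Flagged samples are excluded, never imputed, and intra-group
protein CV is reported before and after exclusion to quantify the gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    InsufficientSamplesError,
    PanelMismatchError,
)
from .io import IntensityMatrix, SampleMetadata
from .simulate import MARKER_CLASSES


@dataclass
class ContaminationPanel:
    """Marker accessions per contamination class plus the share threshold."""

    class_markers: dict[str, list[str]]
    threshold_percent: float = 10.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_percent < 100:
            raise ValueError("threshold_percent must lie in (0, 100)")
        seen: set[str] = set()
        for cls, accs in self.class_markers.items():
            overlap = seen & set(accs)
            if overlap:
                raise ValueError(f"marker classes must be disjoint: {sorted(overlap)}")
            seen |= set(accs)

    @property
    def all_markers(self) -> list[str]:
        return [a for accs in self.class_markers.values() for a in accs]


def full_panel() -> ContaminationPanel:
    """16-marker panel (7 erythrocyte + 8 platelet + albumin), 10% cutoff."""
    return ContaminationPanel(
        class_markers={c: list(a) for c, a in MARKER_CLASSES.items()},
        threshold_percent=10.0,
        name="full16",
    )


def simplified_panel() -> ContaminationPanel:
    """Hemoglobin + albumin panel with a 5% cutoff."""
    return ContaminationPanel(
        class_markers={
            "erythrocyte": ["HBA", "HBB", "HBD"],
            "albumin": ["ALBU"],
        },
        threshold_percent=5.0,
        name="hb-albu",
    )


BUILTIN_PANELS = {"full16": full_panel, "hb-albu": simplified_panel}


@dataclass
class ContaminationReport:
    shares: pd.DataFrame  # per-sample class shares, total share, flags
    excluded_samples: list[str]
    missing_markers: list[str]
    marker_fold_changes: pd.DataFrame
    intra_group_cv_before: dict[str, float] = field(default_factory=dict)
    intra_group_cv_after: dict[str, float] = field(default_factory=dict)


def marker_share(matrix: IntensityMatrix, panel: ContaminationPanel) -> pd.DataFrame:
    """Per-sample, per-class marker intensity share (percent of sample total).

    Panel accessions absent from the matrix contribute 0 and are reported via
    the ``missing_markers`` attribute on the returned frame. A panel with no
    accession in the matrix at all is an error (all shares would silently be
    zero).
    """
    present = [a for a in panel.all_markers if a in matrix.data.index]
    if not present:
        raise PanelMismatchError("no panel accession present in the matrix")
    totals = matrix.data.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise DegenerateSampleError(f"all-zero sample(s): {bad}")
    out = pd.DataFrame(index=matrix.sample_ids)
    for cls, accs in panel.class_markers.items():
        rows = [a for a in accs if a in matrix.data.index]
        class_sum = matrix.data.loc[rows].sum(axis=0) if rows else 0.0
        out[f"share_{cls}"] = 100.0 * class_sum / totals
    out["total_share_percent"] = out.sum(axis=1)
    out.attrs["missing_markers"] = sorted(set(panel.all_markers) - set(present))
    return out


def flag_blood_outliers(shares: pd.DataFrame, panel: ContaminationPanel) -> pd.Series:
    """Blood flag: total marker share strictly above the panel threshold."""
    return shares["total_share_percent"] > panel.threshold_percent


def flag_aberrant_intensity(
    matrix: IntensityMatrix, k_mad: float = 3.0
) -> pd.Series:
    """Flag samples with aberrantly high total intensity.

    One-sided robust rule: total > median + k_mad * 1.4826 * MAD. With zero
    MAD no sample is flagged.
    """
    totals = matrix.data.sum(axis=0)
    if totals.size < 5:
        raise InsufficientSamplesError("need >=5 samples for aberrant screening")
    med = float(totals.median())
    mad = float((totals - med).abs().median())
    if mad == 0:
        return pd.Series(False, index=totals.index)
    return totals > med + k_mad * 1.4826 * mad


def marker_fold_changes(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    panel: ContaminationPanel,
    elevated_ratio: float = 1.1,
) -> pd.DataFrame:
    """Group2/group1 ratio of mean marker intensity, on non-excluded samples.

    Markers with ratio >= ``elevated_ratio`` are flagged "elevated"; absent
    markers get an NA ratio.
    """
    g1 = metadata.group_ids("MGS1")
    g2 = metadata.group_ids("MGS2")
    if not g1 or not g2:
        raise InsufficientSamplesError("both donor groups must be present")
    rows = []
    for cls, accs in panel.class_markers.items():
        for acc in accs:
            if acc in matrix.data.index:
                m1 = float(matrix.data.loc[acc, g1].mean())
                m2 = float(matrix.data.loc[acc, g2].mean())
                ratio = m2 / m1 if m1 > 0 else np.nan
            else:
                ratio = np.nan
            rows.append(
                {
                    "marker": acc,
                    "class": cls,
                    "ratio_g2_g1": ratio,
                    "elevated": bool(ratio >= elevated_ratio)
                    if not np.isnan(ratio)
                    else False,
                }
            )
    return pd.DataFrame(rows)


def intra_group_cv(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    use_excluded: bool = False,
) -> dict[str, float]:
    """Median per-protein CV%% within each donor group.

    Per protein and group the CV is computed over non-zero values (>=3
    required, else the protein is skipped for that group). With
    ``use_excluded`` the excluded samples are kept in.
    """
    out: dict[str, float] = {}
    for group in ("MGS1", "MGS2"):
        ids = metadata.group_ids(group, include_excluded=use_excluded)
        if len(ids) < 3:
            raise InsufficientSamplesError(f"group {group} has <3 samples")
        vals = matrix.data.loc[:, ids].to_numpy()
        masked = np.where(vals > 0, vals, np.nan)
        n = (~np.isnan(masked)).sum(axis=1)
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            cv = 100.0 * np.nanstd(masked, axis=1, ddof=1) / np.nanmean(masked, axis=1)
        cv = cv[n >= 3]
        out[group] = float(np.nanmedian(cv))
    return out


def qualify(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    panel: ContaminationPanel | None = None,
    k_mad: float = 3.0,
) -> tuple[ContaminationReport, SampleMetadata]:
    """Full qualification: score, flag, exclude, and report CV before/after.

    QC injections are never candidates for exclusion. Returns the report and
    updated metadata with exclusion flags applied.
    """
    panel = panel or full_panel()
    cohort_ids = [
        s for s in metadata.sample_ids if metadata.table.loc[s, "group"] != "QC"
    ]
    cohort = matrix.subset_samples(cohort_ids)
    shares = marker_share(cohort, panel)
    blood = flag_blood_outliers(shares, panel)
    aberrant = flag_aberrant_intensity(cohort, k_mad=k_mad)
    shares["blood_flag"] = blood
    shares["aberrant_flag"] = aberrant
    shares["excluded"] = blood | aberrant

    reasons = {}
    for sid in cohort_ids:
        if blood[sid]:
            reasons[sid] = "blood_contamination"
        elif aberrant[sid]:
            reasons[sid] = "aberrant_intensity"
    updated = metadata.with_exclusions(reasons)

    cv_before = intra_group_cv(matrix, metadata, use_excluded=True)
    cv_after = intra_group_cv(matrix, updated, use_excluded=False)
    folds = marker_fold_changes(matrix, updated, panel)
    report = ContaminationReport(
        shares=shares,
        excluded_samples=sorted(reasons),
        missing_markers=shares.attrs.get("missing_markers", []),
        marker_fold_changes=folds,
        intra_group_cv_before=cv_before,
        intra_group_cv_after=cv_after,
    )
    return report, updated


def report_frame(report: ContaminationReport) -> pd.DataFrame:
    """Per-sample share/flag table suitable for write_report."""
    df = report.shares.copy()
    df.insert(0, "sample_id", df.index)
    return df.reset_index(drop=True)
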