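"""Synthetic LC-MS cohort generator.

Emulates the statistical structure of a large label-free quantification
(LFQ) cohort: a wide dynamic range of protein abundances, intra-group
biological variability, abundance-dependent technical noise anchored on
pooled-QC replicate behaviour, detection-limit (missing-not-at-random)
dropout, blood-marker contamination spikes in a minority of samples, and
pooled QC injections at fixed run intervals.

The generative model, with every draw taken from one seeded generator:

1. Per-protein base abundance: log10 uniform over ``[0, dynamic_range_log10]``,
   exponentiated. A uniform log10 base directly controls the realized
   orders-of-magnitude span.
2. Biological variation: one mean-1 log-normal factor per (protein, sample)
   with coefficient of variation ``biological_cv``. Group-2 samples of true
   altered proteins are additionally multiplied by ``2**true_log2_effect``.
3. Technical noise: a mean-1 log-normal factor per (protein, sample) whose
   CV is interpolated linearly in log10 base abundance between
   ``technical_cv_low`` (anchored at the lowest abundance decile) and
   ``technical_cv_high`` (anchored at the top quartile), clipped to the
   anchor values outside that range.
4. Contamination: for spiked samples the marker-class rows are rescaled so
   the class's share of the sample total equals the configured share.
5. Aberrant samples: the whole column is multiplied by a scale factor.
6. Pooled QC runs: the per-protein mean of the clean (pre-contamination,
   pre-aberrant) cohort signal plus fresh technical noise, one column per
   injection, inserted every ``qc_interval`` positions in run order.
7. Missingness: values below a detection limit are set to 0; the limit is
   found by quantile search on the realized matrix so that the fraction of
   proteins with no zeros matches ``missing_free_target``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import AnnotationMap, IntensityMatrix, SampleMetadata

#: Blood contamination marker accessions, by class.
MARKER_CLASSES: dict[str, tuple[str, ...]] = {
    "erythrocyte": ("HBA", "HBB", "HBD", "CAH1", "CAH2", "CATA", "PRDX2"),
    "platelet": ("TSP1", "MYH9", "TPM4", "TLN", "VINC", "ACTN1", "FLNA", "ACTB"),
    "albumin": ("ALBU",),
}
ALL_MARKERS: tuple[str, ...] = tuple(
    acc for accs in MARKER_CLASSES.values() for acc in accs
)


@dataclass
class SimulationConfig:
    n_proteins: int = 600
    n_group1: int = 10
    n_group2: int = 12
    n_qc_runs: int = 3
    qc_interval: int = 10
    dynamic_range_log10: float = 7.3
    biological_cv: float = 0.40
    technical_cv_high: float = 0.10
    technical_cv_low: float = 0.18
    missing_free_target: float = 0.947
    ap_fraction: float = 0.022
    ap_log2_effects: tuple[float, float] = (0.25, 1.0)
    mito_fraction: float = 0.15
    baseline_marker_share: float = 0.043
    contamination_spikes: list[tuple[int, dict[str, float]]] = field(default_factory=list)
    aberrant_samples: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_group1 < 3 or self.n_group2 < 3:
            raise ConfigError("each group needs at least 3 samples")
        if self.dynamic_range_log10 <= 0:
            raise ConfigError("dynamic_range_log10 must be positive")
        for name in (
            "biological_cv",
            "technical_cv_high",
            "technical_cv_low",
            "missing_free_target",
            "ap_fraction",
            "mito_fraction",
            "baseline_marker_share",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.ap_log2_effects
        if self.ap_fraction > 0 and lo < 0.25:
            raise ConfigError("planted |log2 effect| for true APs must be >= 0.25")
        if lo > hi:
            raise ConfigError("ap_log2_effects must be (min, max) with min <= max")
        if self.n_proteins < len(ALL_MARKERS) + 2:
            raise ConfigError("n_proteins too small to host the marker panel")
        n_cohort = self.n_group1 + self.n_group2
        for idx, shares in self.contamination_spikes:
            if not 0 <= idx < n_cohort:
                raise ConfigError(f"spike sample index {idx} out of range")
            bad = set(shares) - set(MARKER_CLASSES)
            if bad:
                raise ConfigError(f"unknown contamination classes: {sorted(bad)}")
            if sum(shares.values()) >= 1:
                raise ConfigError("summed contamination shares must be < 1")
        for idx, scale in self.aberrant_samples:
            if not 0 <= idx < n_cohort:
                raise ConfigError(f"aberrant sample index {idx} out of range")
            if scale <= 0:
                raise ConfigError("aberrant scale must be positive")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery testing."""

    proteins: pd.DataFrame  # index accession; base_abundance, is_true_ap, true_log2_effect, is_mito, marker_class
    samples: pd.DataFrame  # index sample_id; share_<class>, is_aberrant
    detection_limit: float

    def true_ap_ids(self) -> list[str]:
        return list(self.proteins.index[self.proteins["is_true_ap"]])


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Configuration mirroring the full study cohort scale.

    5941 proteins, 32 + 45 donor samples, 5 pooled-QC injections every 20
    runs, 7.3 orders of magnitude of abundance, 40% biological CV, 10%/18%
    technical CV anchors, 94.7% missing-data-free proteins, 15% of proteins
    annotated mitochondrial, six blood-contaminated samples above the 10%
    threshold and one aberrantly scaled sample.
    """
    return SimulationConfig(
        n_proteins=5941,
        n_group1=32,
        n_group2=45,
        n_qc_runs=5,
        qc_interval=20,
        dynamic_range_log10=7.3,
        biological_cv=0.40,
        technical_cv_high=0.10,
        technical_cv_low=0.18,
        missing_free_target=0.947,
        ap_fraction=0.022,
        ap_log2_effects=(0.25, 1.0),
        mito_fraction=0.15,
        contamination_spikes=[
            (3, {"erythrocyte": 0.12}),
            (17, {"erythrocyte": 0.16}),
            (36, {"erythrocyte": 0.13}),
            (48, {"erythrocyte": 0.11, "albumin": 0.03}),
            (60, {"erythrocyte": 0.18}),
            (71, {"erythrocyte": 0.12, "platelet": 0.03}),
        ],
        aberrant_samples=[(55, 3.0)],
        seed=seed,
    )


def desk_config(seed: int = 0) -> SimulationConfig:
    """Reduced preset (600 proteins, 10 + 12 samples) for fast tests."""
    return SimulationConfig(
        n_proteins=600,
        n_group1=10,
        n_group2=12,
        n_qc_runs=3,
        qc_interval=10,
        contamination_spikes=[(2, {"erythrocyte": 0.12}), (15, {"erythrocyte": 0.15})],
        aberrant_samples=[(18, 3.0)],
        seed=seed,
    )


def _lognormal_factors(rng: np.random.Generator, cv: np.ndarray | float, shape) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV (vectorized)."""
    cv = np.asarray(cv, dtype=float)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    return np.exp(rng.standard_normal(shape) * sigma - sigma2 / 2.0)


def _technical_cv(base: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Per-protein technical CV, linear in log10 abundance between anchors."""
    x = np.log10(base)
    x_lo = np.quantile(x, 0.10)
    x_hi = np.quantile(x, 0.75)
    if np.isclose(x_lo, x_hi):
        return np.full_like(x, (cfg.technical_cv_low + cfg.technical_cv_high) / 2)
    t = np.clip((x - x_lo) / (x_hi - x_lo), 0.0, 1.0)
    return cfg.technical_cv_low + t * (cfg.technical_cv_high - cfg.technical_cv_low)


def _detection_limit(values: np.ndarray, target: float) -> float:
    """Detection limit such that ~target of proteins keep all values above it."""
    mins = np.sort(values.min(axis=1))
    n = mins.size
    n_zeroed = n - int(round(target * n))
    if n_zeroed <= 0:
        return 0.0
    limit = float(mins[n_zeroed])
    if limit <= 0:
        raise ConfigError("missing_free_target infeasible: non-positive detection limit")
    return limit


def _run_sequence(cohort_ids: list[str], qc_ids: list[str], interval: int) -> list[str]:
    """Interleave QC injections every `interval` runs (first run is a QC)."""
    order: list[str] = []
    ci, qi = 0, 0
    pos = 0
    while ci < len(cohort_ids) or qi < len(qc_ids):
        if qi < len(qc_ids) and (pos % interval == 0 or ci >= len(cohort_ids)):
            order.append(qc_ids[qi])
            qi += 1
        else:
            order.append(cohort_ids[ci])
            ci += 1
        pos += 1
    return order


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, SampleMetadata, AnnotationMap, CohortTruth]:
    """Generate one cohort: matrix, metadata, annotations and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_p = config.n_proteins
    n1, n2 = config.n_group1, config.n_group2
    n_cohort = n1 + n2

    protein_ids = list(ALL_MARKERS) + [
        f"P{i:05d}" for i in range(1, n_p - len(ALL_MARKERS) + 1)
    ]
    marker_idx = np.arange(len(ALL_MARKERS))
    marker_class = np.array(
        [c for c, accs in MARKER_CLASSES.items() for _ in accs]
        + ["none"] * (n_p - len(ALL_MARKERS))
    )

    # (1) base abundances, uniform in log10; the non-marker exponents are
    # affinely rescaled so the design span equals dynamic_range_log10 exactly
    expo = rng.uniform(0.0, config.dynamic_range_log10, size=n_p)
    non_marker = np.arange(len(ALL_MARKERS), n_p)
    e = expo[non_marker]
    expo[non_marker] = (e - e.min()) / (e.max() - e.min()) * config.dynamic_range_log10
    base = 10.0**expo
    # Blood markers are highly abundant proteins; pin them near the top of
    # the range (capped at the non-marker maximum, so they never extend the
    # realized span) with their pooled share at the baseline contamination
    # level, split near-equally across the 16 accessions.
    s0 = config.baseline_marker_share
    if s0 > 0:
        other_total = base[non_marker].sum()
        weights = _lognormal_factors(rng, 0.05, marker_idx.size)
        weights /= weights.sum()
        base[marker_idx] = np.minimum(
            (s0 / (1 - s0)) * other_total * weights, base[non_marker].max()
        )

    # planted group effects (markers and their rows never carry true effects)
    is_true_ap = np.zeros(n_p, dtype=bool)
    true_effect = np.zeros(n_p)
    n_ap = int(round(config.ap_fraction * n_p))
    if n_ap > 0:
        candidates = np.arange(len(ALL_MARKERS), n_p)
        ap_idx = rng.choice(candidates, size=n_ap, replace=False)
        lo, hi = config.ap_log2_effects
        mags = rng.uniform(lo, hi, size=n_ap)
        signs = rng.choice([-1.0, 1.0], size=n_ap)
        is_true_ap[ap_idx] = True
        true_effect[ap_idx] = mags * signs

    # annotations: mitochondrion per config; two common compartments for texture
    is_mito = rng.random(n_p) < config.mito_fraction
    is_cyto = rng.random(n_p) < 0.43
    is_membrane = rng.random(n_p) < 0.27
    mapping: dict[str, set[str]] = {}
    for i, acc in enumerate(protein_ids):
        terms = set()
        if is_mito[i]:
            terms.add("mitochondrion")
        if is_cyto[i]:
            terms.add("cytosol")
        if is_membrane[i]:
            terms.add("plasma membrane")
        if terms:
            mapping[acc] = terms
    annotations = AnnotationMap(mapping)

    # (2)+(3) signal = base * group effect * biological * technical noise
    tech_cv = _technical_cv(base, config)
    bio = _lognormal_factors(rng, config.biological_cv, (n_p, n_cohort))
    tech = _lognormal_factors(rng, tech_cv[:, None], (n_p, n_cohort))
    effect_mult = np.ones((n_p, n_cohort))
    effect_mult[:, n1:] = 2.0 ** true_effect[:, None]
    signal = base[:, None] * effect_mult * bio * tech

    # pooled QC columns from the clean cohort signal + fresh technical noise
    pool = signal.mean(axis=1)
    qc_tech = _lognormal_factors(rng, tech_cv[:, None], (n_p, config.n_qc_runs))
    qc_cols = pool[:, None] * qc_tech

    # (5) contamination spikes: rescale marker classes to the target share,
    # compositionally (the column total is preserved, so extra blood signal
    # displaces tissue signal as it does in a fixed-load LC-MS injection)
    cohort = signal.copy()
    share_truth = pd.DataFrame(
        0.0,
        index=range(n_cohort),
        columns=[f"share_{c}" for c in MARKER_CLASSES],
    )
    for idx, shares in config.contamination_spikes:
        col = cohort[:, idx]
        orig_total = col.sum()
        spiked_rows = {
            c: np.array([protein_ids.index(a) for a in MARKER_CLASSES[c]])
            for c in shares
        }
        fixed_mask = np.ones(n_p, dtype=bool)
        for rows in spiked_rows.values():
            fixed_mask[rows] = False
        fixed_total = col[fixed_mask].sum()
        new_total = fixed_total / (1.0 - sum(shares.values()))
        for c, s in shares.items():
            rows = spiked_rows[c]
            col[rows] *= (s * new_total) / col[rows].sum()
        col *= orig_total / new_total
        for c, s in shares.items():
            share_truth.loc[idx, f"share_{c}"] = s

    # (6) aberrant whole-column intensity scaling
    is_aberrant = np.zeros(n_cohort, dtype=bool)
    for idx, scale in config.aberrant_samples:
        cohort[:, idx] *= scale
        is_aberrant[idx] = True

    # (7) detection-limit missingness across cohort + QC columns
    full = np.concatenate([cohort, qc_cols], axis=1)
    limit = _detection_limit(full, config.missing_free_target)
    full[full < limit] = 0.0

    # identifiers, run order (cohort order randomized, QC interleaved)
    cohort_ids = [f"M1_{i + 1:02d}" for i in range(n1)] + [
        f"M2_{i + 1:02d}" for i in range(n2)
    ]
    qc_ids = [f"QC{i + 1}" for i in range(config.n_qc_runs)]
    shuffled = [cohort_ids[i] for i in rng.permutation(n_cohort)]
    run_seq = _run_sequence(shuffled, qc_ids, config.qc_interval)
    run_order = {sid: i + 1 for i, sid in enumerate(run_seq)}

    all_ids = cohort_ids + qc_ids
    df = pd.DataFrame(full, index=protein_ids, columns=all_ids)
    df = df.loc[:, sorted(all_ids, key=lambda s: run_order[s])]
    matrix = IntensityMatrix(df, level="protein")

    meta = pd.DataFrame(
        {
            "group": ["MGS1"] * n1 + ["MGS2"] * n2 + ["QC"] * config.n_qc_runs,
            "run_order": [run_order[s] for s in all_ids],
            "excluded": False,
            "exclusion_reason": "none",
        },
        index=pd.Index(all_ids, name="sample_id"),
    )
    metadata = SampleMetadata(meta.loc[df.columns])

    proteins = pd.DataFrame(
        {
            "base_abundance": base,
            "is_true_ap": is_true_ap,
            "true_log2_effect": true_effect,
            "is_mito": is_mito,
            "marker_class": marker_class,
        },
        index=pd.Index(protein_ids, name="accession"),
    )
    samples = share_truth.copy()
    samples.index = pd.Index(cohort_ids, name="sample_id")
    samples["is_aberrant"] = is_aberrant
    truth = CohortTruth(proteins=proteins, samples=samples, detection_limit=limit)
    return matrix, metadata, annotations, truth


def peptide_mode(
    matrix: IntensityMatrix,
    n_peptides: int = 4,
    efficiency_cv: float = 0.5,
    n_outlier_peptides: int = 0,
    seed: int = 0,
) -> tuple[IntensityMatrix, pd.Series]:
    """Split each protein row into peptide rows with fixed ionization efficiencies.

    Each peptide's intensity is the protein intensity times a per-peptide
    multiplicative efficiency held constant across samples, so summing
    peptides recovers the protein profile exactly up to a constant. With
    ``n_outlier_peptides`` > 0, that many randomly chosen peptides per
    protein are given a shuffled (discordant) sample profile to exercise
    outlier detection. Returns the peptide matrix and a peptide -> protein map.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pep_ids = []
    parent = []
    values = matrix.values
    n_s = values.shape[1]
    for i, prot in enumerate(matrix.protein_ids):
        eff = _lognormal_factors(rng, efficiency_cv, n_peptides)
        outliers = (
            rng.choice(n_peptides, size=n_outlier_peptides, replace=False)
            if n_outlier_peptides
            else np.array([], dtype=int)
        )
        for k in range(n_peptides):
            profile = values[i] * eff[k]
            if k in outliers:
                profile = profile[rng.permutation(n_s)]
            rows.append(profile)
            pep_ids.append(f"{prot}_pep{k + 1}")
            parent.append(prot)
    pep_df = pd.DataFrame(np.array(rows), index=pep_ids, columns=matrix.sample_ids)
    return (
        IntensityMatrix(pep_df, level="peptide"),
        pd.Series(parent, index=pep_ids, name="protein_id"),
    )
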