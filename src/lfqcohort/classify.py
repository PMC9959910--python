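"""Supervised classification and ordination of the altered-protein signature.

Random forest and radial-kernel SVM are benchmarked with stratified 10-fold
cross-validation repeated 3 times on log2 protein intensities (missing
values median-imputed inside each training fold only, to avoid leakage).
Both models see identical folds derived deterministically from the seed.
Feature importance is permutation-based "mean decrease in accuracy" for the
random forest and a model-independent ROC filter (|AUC - 0.5| * 2) for the
SVM, both rescaled to [0, 100]. The TOP-k importance overlap between the two
models identifies a consensus marker shortlist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigError, DegenerateInputError, StratificationError
from .io import IntensityMatrix


@dataclass
class ClassifierConfig:
    folds: int = 10
    repeats: int = 3
    ntree: int = 1000
    mtry: int | None = None  # None -> floor(sqrt(p))
    cost: float = 1.0
    kernel: str = "rbf"


@dataclass
class ClassifierReport:
    resample_accuracies: dict[str, np.ndarray]
    mean_accuracy: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    importance: dict[str, pd.Series]
    tuning: dict[str, dict]
    folds: int
    repeats: int
    seed: int
    overlap_k: int | None = None
    overlap_set: list[str] = field(default_factory=list)


def _design(matrix: IntensityMatrix) -> tuple[np.ndarray, list[str]]:
    """Samples x features design of log2 intensities; zeros become NaN."""
    v = matrix.values.T
    x = np.where(v > 0, np.log2(np.where(v > 0, v, 1.0)), np.nan)
    return x, matrix.protein_ids


def _impute_train_median(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    tr = np.where(np.isnan(train), med, train)
    te = np.where(np.isnan(test), med, test)
    return tr, te


def fold_assignments(
    labels: np.ndarray, folds: int, repeats: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified fold splits — a pure function of (labels, seed)."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class ({counts.min()}) cannot stratify {folds} folds"
        )
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(np.zeros((y.size, 1)), y))
    for train_idx, _ in splits:
        if np.unique(y[train_idx]).size < 2:
            raise StratificationError("a class is absent from a training fold")
    return splits


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF width from the median pairwise Euclidean distance on the fold."""
    d = pdist(x)
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    sigma = float(np.median(d))
    return 1.0 / (2.0 * sigma**2)


def _roc_auc_filter(x: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Per-feature |AUC - 0.5| * 2 class-separation score (rank/Mann-Whitney).

    Missing values are ignored per feature; constant features score 0.
    """
    scores = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j]
        ok = ~np.isnan(col)
        v, lab = col[ok], y01[ok]
        n1, n0 = int(lab.sum()), int((1 - lab).sum())
        if n1 == 0 or n0 == 0 or np.unique(v).size < 2:
            continue
        ranks = pd.Series(v).rank().to_numpy()
        auc = (ranks[lab == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        scores[j] = abs(auc - 0.5) * 2.0
    return scores


def _scale_importance(raw: np.ndarray, ids: list[str]) -> pd.Series:
    s = np.clip(raw, 0.0, None)
    top = s.max()
    if top > 0:
        s = 100.0 * s / top
    return pd.Series(s, index=ids, name="importance")


def run_classifiers(
    matrix: IntensityMatrix,
    labels: np.ndarray | list[str],
    config: ClassifierConfig | None = None,
    seed: int = 0,
    compute_importance: bool = True,
) -> ClassifierReport:
    """Cross-validate RF and SVM on the feature matrix and score importance.

    ``matrix`` holds the selected features (e.g. the APs) as rows; labels are
    per-sample class strings aligned with the matrix columns.
    """
    config = config or ClassifierConfig()
    x, feature_ids = _design(matrix)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ConfigError(f"need exactly 2 classes, got {classes.size}")
    y01 = (y == classes[1]).astype(int)
    p = x.shape[1]
    mtry = config.mtry if config.mtry is not None else max(1, int(np.sqrt(p)))
    if mtry > p:
        raise ConfigError(f"mtry={mtry} exceeds feature count {p}")
    splits = fold_assignments(y, config.folds, config.repeats, seed)

    rng = np.random.default_rng(seed)
    acc = {"RF": [], "SVM": []}
    rf_mda = np.zeros(p)  # mean decrease in accuracy, accumulated
    rf_mda_n = 0
    for train_idx, test_idx in splits:
        tr, te = _impute_train_median(x[train_idx], x[test_idx])
        ytr, yte = y01[train_idx], y01[test_idx]
        rf = RandomForestClassifier(
            n_estimators=config.ntree,
            max_features=mtry,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(tr, ytr)
        base = float((rf.predict(te) == yte).mean())
        acc["RF"].append(base)
        if compute_importance:
            # permutation importance on the held-out fold
            for j in range(p):
                perm = te.copy()
                perm[:, j] = rng.permutation(perm[:, j])
                rf_mda[j] += base - float((rf.predict(perm) == yte).mean())
            rf_mda_n += 1
        svm = SVC(
            C=config.cost,
            kernel=config.kernel,
            gamma=_median_heuristic_gamma(tr) if config.kernel == "rbf" else "scale",
        ).fit(tr, ytr)
        acc["SVM"].append(float((svm.predict(te) == yte).mean()))

    n_res = len(splits)
    resamples = {m: np.array(v) for m, v in acc.items()}
    mean_acc = {m: float(v.mean()) for m, v in resamples.items()}
    ci95 = {}
    for m, v in resamples.items():
        half = 1.96 * v.std(ddof=1) / np.sqrt(n_res)
        ci95[m] = (mean_acc[m] - half, mean_acc[m] + half)

    if compute_importance:
        importance = {
            "RF": _scale_importance(rf_mda / rf_mda_n, feature_ids),
            "SVM": _scale_importance(_roc_auc_filter(x, y01), feature_ids),
        }
    else:
        importance = {}
    return ClassifierReport(
        resample_accuracies=resamples,
        mean_accuracy=mean_acc,
        ci95=ci95,
        importance=importance,
        tuning={
            "RF": {"ntree": config.ntree, "mtry": mtry},
            "SVM": {"cost": config.cost, "kernel": config.kernel},
        },
        folds=config.folds,
        repeats=config.repeats,
        seed=seed,
    )


def top_overlap(imp_rf: pd.Series, imp_svm: pd.Series, k: int = 30) -> list[str]:
    """Features in both models' TOP-k importance lists.

    Ties break by descending score then lexicographic feature id, so the
    selection is deterministic.
    """
    if len(imp_rf) < k or len(imp_svm) < k:
        raise ConfigError(f"need >= {k} scored features in both models")

    def top_k(s: pd.Series) -> set[str]:
        df = s.rename("score").rename_axis("feature").reset_index()
        df = df.sort_values(["score", "feature"], ascending=[False, True], kind="stable")
        return set(df["feature"].head(k))

    return sorted(top_k(imp_rf) & top_k(imp_svm))


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # per-sample component scores
    explained_variance: tuple[float, float]
    labels: list[str]
    method: str


def _standardized_design(matrix: IntensityMatrix) -> np.ndarray:
    x, _ = _design(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(x, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    x = np.where(np.isnan(x), med, x)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def ordinate(
    matrix: IntensityMatrix,
    labels: np.ndarray | list[str],
    method: str = "pca",
) -> OrdinationResult:
    """PCA (SVD of the standardized design) or 2-component PLS-DA scores."""
    y = np.asarray(labels)
    if matrix.data.shape[1] < 3:
        raise DegenerateInputError("ordination needs >=3 samples")
    x = _standardized_design(matrix)
    n = x.shape[0]
    if method == "pca":
        xc = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(xc, full_matrices=False)
        scores = u[:, :2] * s[:2]
        total = (s**2).sum()
        ev = (float(s[0] ** 2 / total), float(s[1] ** 2 / total) if s.size > 1 else 0.0)
    elif method == "plsda":
        classes = np.unique(y)
        y01 = (y == classes[-1]).astype(float)
        pls = PLSRegression(n_components=2, scale=False).fit(x, y01 - y01.mean())
        scores = pls.x_scores_
        xc = x - x.mean(axis=0)
        total = (xc**2).sum()
        ev_list = []
        for c in range(2):
            t = scores[:, c : c + 1]
            p_load = xc.T @ t / float((t * t).sum())
            ev_list.append(float(((t @ p_load.T) ** 2).sum() / total))
        ev = (ev_list[0], ev_list[1])
    else:
        raise ConfigError(f"unknown ordination method {method!r}")
    df = pd.DataFrame(
        scores[:, :2], index=matrix.sample_ids, columns=["comp1", "comp2"]
    )
    return OrdinationResult(
        scores=df, explained_variance=ev, labels=list(y), method=method
    )


@dataclass
class HeatmapResult:
    grid: pd.DataFrame  # z-scored proteins x samples, reordered by dendrograms
    row_order: list[str]
    col_order: list[str]
    linkage_method: str = "ward"


def cluster_heatmap(
    matrix: IntensityMatrix, labels: np.ndarray | list[str] | None = None
) -> HeatmapResult:
    """Ward/Euclidean hierarchical clustering of z-scored rows and samples."""
    if matrix.data.shape[0] < 2 or matrix.data.shape[1] < 2:
        raise DegenerateInputError("heatmap needs >=2 rows and >=2 columns")
    v = matrix.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance row(s) z-scored to 0")
    sd[sd == 0] = 1.0
    z = (v - mu) / sd
    row_link = hierarchy.ward(pdist(z))
    col_link = hierarchy.ward(pdist(z.T))
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    grid = pd.DataFrame(z, index=matrix.protein_ids, columns=matrix.sample_ids)
    grid = grid.iloc[row_order, col_order]
    return HeatmapResult(
        grid=grid,
        row_order=list(grid.index),
        col_order=list(grid.columns),
    )
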