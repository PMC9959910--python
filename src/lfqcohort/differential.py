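"""Altered-protein calling and annotation-term enrichment.

Proteins are tested between the two donor groups with Welch's unequal-
variance t-test on log2 intensities (zeros, i.e. missing values, removed
first; at least 3 quantified values per group required). The reported
fold change is the log2 ratio of raw-intensity group means. A protein is an
altered protein (AP) when p < alpha (strict); APs are categorised as
up/down when |log2 ratio| strictly exceeds ``lfc_cut``, otherwise
"ns_direction". Term over-representation among APs is a hypergeometric
upper-tail test against the quantified universe with Benjamini-Hochberg
control across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyQueryError, TermNotFoundError
from .io import AnnotationMap, IntensityMatrix, SampleMetadata


@dataclass
class DifferentialTable:
    results: pd.DataFrame  # per-protein statistics, see call_aps
    n_dropped: int
    alpha: float
    lfc_cut: float

    def ap_ids(self) -> list[str]:
        return list(self.results.index[self.results["is_ap"]])


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Welch-Satterthwaite df, p).

    t = (mx - my) / sqrt(sx^2/nx + sy^2/ny), two-sided p from the t
    distribution. Fewer than 3 values in either group -> (nan, nan, nan).
    Degenerate zero-variance inputs: equal means -> (0, nan, 1); unequal
    means -> (+/-inf, nan, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 3 or ny < 3:
        return (np.nan, np.nan, np.nan)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        if mx == my:
            return (0.0, np.nan, 1.0)
        return (np.inf if mx > my else -np.inf, np.nan, 0.0)
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (float(t), float(df), float(p))


def _masked_welch(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch on log2 of non-zero values, row-wise.

    Returns (t, df, p, n_used_a, n_used_b); rows with <3 usable values in
    either group get NaN statistics.
    """
    la = np.where(a > 0, np.log2(np.where(a > 0, a, 1.0)), np.nan)
    lb = np.where(b > 0, np.log2(np.where(b > 0, b, 1.0)), np.nan)
    na = (~np.isnan(la)).sum(axis=1)
    nb = (~np.isnan(lb)).sum(axis=1)
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(la, axis=1)
        mb = np.nanmean(lb, axis=1)
        va = np.nanvar(la, axis=1, ddof=1)
        vb = np.nanvar(lb, axis=1, ddof=1)
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = (na < 3) | (nb < 3)
    t[bad] = df[bad] = p[bad] = np.nan
    # zero-variance degeneracies
    degen = (~bad) & (se2 == 0)
    t[degen & (ma == mb)] = 0.0
    p[degen & (ma == mb)] = 1.0
    p[degen & (ma != mb)] = 0.0
    return t, df, p, na, nb


def call_aps(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    alpha: float = 0.05,
    lfc_cut: float = 0.25,
) -> DifferentialTable:
    """Welch-test every protein between MGS1 and MGS2 and categorise.

    Uses only non-excluded cohort samples. Statistics run on log2 of
    non-zero intensities; the log2 ratio is taken on raw group means.
    Proteins testable in neither direction (under 3 quantified values in a
    group) are dropped and counted.
    """
    g1 = metadata.group_ids("MGS1")
    g2 = metadata.group_ids("MGS2")
    a = matrix.data.loc[:, g1].to_numpy(dtype=float)
    b = matrix.data.loc[:, g2].to_numpy(dtype=float)
    t, df, p, na, nb = _masked_welch(a, b)

    masked_a = np.where(a > 0, a, np.nan)
    masked_b = np.where(b > 0, b, np.nan)
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_g1 = np.nanmean(masked_a, axis=1)
        mean_g2 = np.nanmean(masked_b, axis=1)
        log2_ratio = np.log2(mean_g2 / mean_g1)

    res = pd.DataFrame(
        {
            "mean_g1": mean_g1,
            "mean_g2": mean_g2,
            "log2_ratio": log2_ratio,
            "t_stat": -t,  # report direction as group2 - group1
            "df": df,
            "p_value": p,
            "n_g1": na,
            "n_g2": nb,
        },
        index=matrix.data.index,
    )
    testable = ~res["p_value"].isna()
    n_dropped = int((~testable).sum())
    res = res[testable].copy()
    res["is_ap"] = res["p_value"] < alpha
    category = np.where(
        ~res["is_ap"],
        "not_significant",
        np.where(
            res["log2_ratio"] > lfc_cut,
            "up",
            np.where(res["log2_ratio"] < -lfc_cut, "down", "ns_direction"),
        ),
    )
    res["category"] = category
    return DifferentialTable(results=res, n_dropped=n_dropped, alpha=alpha, lfc_cut=lfc_cut)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserving.

    NaN inputs propagate NaN and do not count toward the number of tests.
    Adjusted values are monotonized and clipped to [p, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, pv[order], 1.0)
    unsorted = np.empty(m)
    unsorted[order] = adj
    out[ok] = unsorted
    return out


def enrich_terms(
    ap_ids: list[str],
    universe_ids: list[str],
    annotations: AnnotationMap,
    min_universe_count: int = 3,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each term among the APs.

    For a term carried by K of the N universe proteins and k of the n APs,
    p = P[X >= k] with X ~ Hypergeom(N, K, n), and
    fold_enrichment = (k/n) / (K/N). Terms with K < ``min_universe_count``
    are skipped (listed in the frame attrs). BH FDR across tested terms.
    """
    if not ap_ids:
        raise EmptyQueryError("empty AP set")
    universe = set(universe_ids)
    aps = set(ap_ids)
    if not aps <= universe:
        raise ValueError("ap_ids must be a subset of universe_ids")
    N, n = len(universe), len(aps)
    rows, skipped = [], []
    for term in sorted(annotations.all_terms()):
        carriers = annotations.with_term(term) & universe
        K = len(carriers)
        if K < min_universe_count:
            skipped.append(term)
            continue
        k = len(carriers & aps)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": (k / n) / (K / N),
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "fold_enrichment", "p_value"]
    )
    if len(table):
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    else:
        table["fdr"] = []
    table.attrs["skipped_terms"] = skipped
    return table


def ap_compartment_summary(
    ap_ids: list[str],
    universe_ids: list[str],
    annotations: AnnotationMap,
    term: str,
) -> dict[str, float]:
    """Counts and percentages of a compartment term among APs and universe.

    Percentages are reported both raw and rounded to the nearest integer
    (display convention).
    """
    if term not in annotations.all_terms():
        raise TermNotFoundError(f"term {term!r} not in annotation map")
    carriers = annotations.with_term(term)
    k = len(carriers & set(ap_ids))
    K = len(carriers & set(universe_ids))
    pct_ap = 100.0 * k / len(ap_ids)
    pct_uni = 100.0 * K / len(universe_ids)
    return {
        "count_in_aps": k,
        "percent_in_aps": pct_ap,
        "percent_in_aps_rounded": int(round(pct_ap)),
        "count_in_universe": K,
        "percent_in_universe": pct_uni,
        "percent_in_universe_rounded": int(round(pct_uni)),
    }
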