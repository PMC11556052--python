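"""The statistical evaluation layer.

Descriptive statistics (sample SD, standard error, median, quartiles),
one-sample Kolmogorov–Smirnov normality testing against a normal with
moments estimated from the data, the Mann–Whitney U rank test, Pearson
correlations of every feature against age with t-transform p-values, and
the pairwise feature-correlation heatmap matrix.

Note that the KS test with estimated parameters yields anti-conservative
p-values (the Lilliefors situation); it is provided as the reporting
convention of this pipeline, which does not gate any decision on it.
Feature-vs-age correlations are reported without multiple-testing
correction by default; a Holm adjustment is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import FEATURE_NAMES, FEATURE_REGISTRY, FeatureVector

#: Reporting convention for flagging significance.
ALPHA = 0.05


@dataclass(frozen=True)
class DescriptiveSummary:
    mean: float
    standard_error: float
    sd: float
    median: float
    min: float
    max: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("quantile ordering violated")


def describe(values: Sequence[float]) -> DescriptiveSummary:
    """Descriptive summary with sample (n−1) SD and linear-interp quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("describe requires at least 2 values")
    sd = float(v.std(ddof=1))
    return DescriptiveSummary(
        mean=float(v.mean()),
        standard_error=sd / math.sqrt(v.size),
        sd=sd,
        median=float(np.median(v)),
        min=float(v.min()),
        max=float(v.max()),
        q1=float(np.percentile(v, 25)),
        q3=float(np.percentile(v, 75)),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-transform p-value (n−2 df).

    Constant input yields the (NaN, NaN) undefined sentinel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson requires at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """One-sample KS statistic against a normal with estimated mean/SD."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("ks_normality requires at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return math.nan, math.nan
    res = sps.kstest(v, "norm", args=(v.mean(), sd))
    return float(res.statistic), float(res.pvalue)


#: Above this per-group size the U test switches from the exact null
#: distribution to the tie-corrected normal approximation.
_MW_EXACT_LIMIT = 20


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact for small tie-free samples; tie-corrected normal approximation
    otherwise.  Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) <= _MW_EXACT_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    adj = np.full_like(p, math.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    order = np.argsort(ps)
    m = ps.size
    running = 0.0
    out = np.empty(m)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        out[idx] = min(running, 1.0)
    adj[ok] = out
    return adj


@dataclass
class CorrelationTable:
    """Per-feature correlation with age, ordered as the feature registry."""

    table: pd.DataFrame  # columns: feature_index, name, r, p, significant

    def row(self, index: int) -> pd.Series:
        return self.table.set_index("feature_index").loc[index]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def correlation_table(
    features: Sequence[FeatureVector],
    ages: Sequence[float],
    holm: bool = False,
) -> CorrelationTable:
    """Pearson r and p of each of the 26 features against age.

    A constant feature is flagged undefined (NaN r/p) but keeps its row.
    """
    if len(features) < 3:
        raise ValueError("correlation table requires at least 3 subjects")
    if len(features) != len(ages):
        raise ValueError("features and ages differ in length")
    ages = np.asarray(ages, dtype=float)
    mat = np.stack([f.as_array() for f in features])
    rows = []
    for j, (idx, name) in enumerate(FEATURE_REGISTRY):
        col = mat[:, j]
        if np.ptp(col[~np.isnan(col)]) == 0 or np.isnan(col).all():
            r = p = math.nan
        else:
            ok = ~np.isnan(col)
            if ok.sum() < 3:
                r = p = math.nan
            else:
                r, p = pearson(col[ok], ages[ok])
        rows.append({"feature_index": idx, "name": name, "r": r, "p": p})
    df = pd.DataFrame(rows)
    if holm:
        df["p_holm"] = holm_adjust(df["p"].to_numpy())
        df["significant"] = df["p_holm"] < ALPHA
    else:
        df["significant"] = df["p"] < ALPHA
    return CorrelationTable(df)


def heatmap_matrix(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """Pairwise feature–feature Pearson matrix (symmetric, unit diagonal).

    Constant features give NaN off-diagonal entries; the diagonal is 1.
    """
    mat = np.stack([f.as_array() for f in features])
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = mat.std(axis=0)
        centered = mat - mat.mean(axis=0)
        cov = centered.T @ centered / mat.shape[0]
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=FEATURE_NAMES, columns=FEATURE_NAMES)
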