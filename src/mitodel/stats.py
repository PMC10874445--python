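"""Cohort statistics over per-sample deletion metrics.

The four deletion metrics evaluated together are the read percentages of
the three named junctions plus the cumulative top-catalog percentage; all
tests over this family carry a Bonferroni correction with family size 4.

Implemented designs: cross-platform (DNA vs RNA) Spearman/Pearson
correlation, Welch's two-sample comparison, ordinary least squares age
regression with coverage and sex (optionally diagnosis) as covariates,
one-factor repeated-measures ANOVA for paired tissues, and fold-difference
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "BONFERRONI_FAMILY",
    "METRIC_COLUMNS",
    "StatResult",
    "bonferroni",
    "platform_correlation",
    "welch_compare",
    "age_regression",
    "paired_tissue_anova",
    "fold_difference",
    "results_table",
    "InsufficientDataError",
    "SingularDesignError",
]

#: Family size for the Bonferroni correction: the four deletion metrics.
BONFERRONI_FAMILY = 4

#: Conventional metric column names for cohort tables built by this package.
METRIC_COLUMNS = (
    "pct_6335-13999",
    "pct_7816-14807",
    "pct_8471-13449",
    "cumulative_top_pct",
)


class InsufficientDataError(ValueError):
    """Too few observations for the requested test."""


class SingularDesignError(ValueError):
    """Rank-deficient regression design; names the collinear columns."""


def bonferroni(p: float, m: int = BONFERRONI_FAMILY) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


@dataclass(frozen=True)
class StatResult:
    metric: str
    method: str
    statistic: float
    p: float
    n: int
    p_bonferroni: float = field(default=None)  # type: ignore[assignment]
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_bonferroni is None:
            object.__setattr__(self, "p_bonferroni", bonferroni(self.p))

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p,
            "p_bonferroni": self.p_bonferroni,
            "n": self.n,
        }


def results_table(results: Iterable[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def _matched_vectors(
    dna: pd.DataFrame, rna: pd.DataFrame, metric: str
) -> tuple[np.ndarray, np.ndarray]:
    a = dna.set_index("sample_id")[metric]
    b = rna.set_index("sample_id")[metric]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise InsufficientDataError(
            f"platform correlation needs >= 3 matched samples, got {len(common)}"
        )
    return a.loc[common].to_numpy(float), b.loc[common].to_numpy(float)


def platform_correlation(
    dna: pd.DataFrame, rna: pd.DataFrame, metric: str
) -> tuple[StatResult, StatResult]:
    """Spearman and Pearson correlation of one metric across platforms.

    Samples are matched on ``sample_id``; each platform's metric is assumed
    already normalized to its own benchmark coverage. Returns the rank
    (Spearman, average ranks for ties) and linear (Pearson) results with
    two-sided p-values.
    """
    x, y = _matched_vectors(dna, rna, metric)
    rho, p_s = sps.spearmanr(x, y)
    r, p_p = sps.pearsonr(x, y)
    n = len(x)
    return (
        StatResult(metric, "spearman", float(rho), float(p_s), n),
        StatResult(metric, "pearson", float(r), float(p_p), n),
    )


def welch_compare(a: Sequence[float], b: Sequence[float], metric: str = "metric") -> StatResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degenerate input with zero variance in both groups and equal means is
    reported as t = 0, p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("welch_compare needs n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult(metric, "welch_t", 0.0, 1.0, len(a) + len(b))
        # identical constants differing between groups: infinitely separated
        t = np.inf if a.mean() > b.mean() else -np.inf
        return StatResult(metric, "welch_t", float(t), 0.0, len(a) + len(b))
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(metric, "welch_t", float(t), float(p), len(a) + len(b))


def _encode_design(
    table: pd.DataFrame, metric: str, predictor: str, covariates: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    cols = [predictor, *covariates]
    used = table[[metric, *cols]].copy()
    if used.isna().any().any():
        missing = used.columns[used.isna().any()].tolist()
        raise ValueError(f"missing values in columns {missing}")
    X = pd.DataFrame(index=used.index)
    for col in cols:
        series = used[col]
        if series.dtype.kind in "ifu":
            X[col] = series.astype(float)
        else:
            # treatment coding, alphabetical reference level for determinism
            levels = sorted(series.astype(str).unique())
            for lev in levels[1:]:
                X[f"{col}[{lev}]"] = (series.astype(str) == lev).astype(float)
    X.insert(0, "const", 1.0)
    return X, used[metric].astype(float)


def age_regression(
    table: pd.DataFrame,
    metric: str,
    covariates: Sequence[str] = ("mt_benchmark_coverage", "sex"),
    predictor: str = "age",
) -> StatResult:
    """OLS fit of ``metric ~ age + covariates``; reports the age slope.

    Categorical covariates are treatment-coded with the alphabetically
    first level as reference. A rank-deficient design raises
    :class:`SingularDesignError` naming the collinear columns.
    """
    X, y = _encode_design(table, metric, predictor, covariates)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise SingularDesignError(f"design is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    return StatResult(
        metric,
        "ols_age",
        float(fit.params[predictor]),
        float(fit.pvalues[predictor]),
        int(fit.nobs),
        extra={
            "stderr": float(fit.bse[predictor]),
            "t": float(fit.tvalues[predictor]),
            "conf_int": tuple(np.asarray(fit.conf_int().loc[predictor], float)),
            "r_squared": float(fit.rsquared),
        },
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    full = np.linalg.matrix_rank(X.to_numpy())
    bad = []
    for col in X.columns:
        if col == "const":
            continue
        if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == full:
            bad.append(col)
    return bad


def paired_tissue_anova(
    table: pd.DataFrame,
    metric: str,
    subject: str = "subject_id",
    within: str = "tissue",
) -> StatResult:
    """One-factor repeated-measures ANOVA across tissues within subjects.

    Subjects lacking an observation for every tissue level are dropped
    listwise with a warning. With two levels the F statistic equals the
    squared paired t statistic. A zero within-subject effect (identical
    values across tissues) is reported as F = 0, p = 1.
    """
    levels = sorted(table[within].astype(str).unique())
    counts = table.groupby(subject)[within].nunique()
    keep = counts[counts == len(levels)].index
    if len(keep) < len(counts):
        import warnings

        warnings.warn(
            f"paired_tissue_anova: dropped {len(counts) - len(keep)} unbalanced subject(s)"
        )
    sub = table[table[subject].isin(keep)]
    if sub[subject].nunique() < 2:
        raise InsufficientDataError("repeated-measures ANOVA needs >= 2 complete subjects")
    if np.allclose(sub.groupby(subject)[metric].var(ddof=0).fillna(0), 0):
        return StatResult(metric, "rm_anova", 0.0, 1.0, int(sub[subject].nunique()))
    res = AnovaRM(sub, depvar=metric, subject=subject, within=[within]).fit()
    row = res.anova_table.iloc[0]
    f, p = float(row["F Value"]), float(row["Pr > F"])
    if not np.isfinite(f):  # zero residual variance
        f, p = 0.0, 1.0
    return StatResult(
        metric, "rm_anova", f, p, int(sub[subject].nunique()),
        extra={"df_num": float(row["Num DF"]), "df_den": float(row["Den DF"])},
    )


def fold_difference(
    a: Sequence[float], b: Sequence[float], method: str = "mean_ratio"
) -> Optional[float]:
    """Fold difference of group a over group b.

    ``mean_ratio`` (default) is mean(a)/mean(b); ``median_ratio`` and
    ``geometric`` (ratio of geometric means, positive values only) are
    offered since conventions differ between studies. Returns None when the
    denominator is zero.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if method == "mean_ratio":
        num, den = a.mean(), b.mean()
    elif method == "median_ratio":
        num, den = np.median(a), np.median(b)
    elif method == "geometric":
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("geometric fold difference requires positive values")
        num, den = np.exp(np.mean(np.log(a))), np.exp(np.mean(np.log(b)))
    else:
        raise ValueError(f"unknown method {method!r}")
    if den == 0:
        return None
    return float(num / den)
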