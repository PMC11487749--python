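"""Inferential toolkit: Welch t, ANCOVA, Pearson, partial Spearman, BH-FDR.

All tests are two-sided by default. The partial Spearman estimator ranks all
variables (mid-ranks for ties) and correlates the rank residuals after
regressing out the covariate ranks; its p-value uses the t transform with
``df = n - 2 - n_covariates``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "welch_ttest",
    "ancova_group_test",
    "pearson_corr",
    "partial_spearman",
    "bh_fdr",
    "normality_screen",
]


@dataclass
class TestResult:
    """One comparison: statistic, degrees of freedom, raw and FDR-adjusted p."""

    name: str
    statistic: float
    df: float | tuple
    p_raw: float
    p_fdr: float | None = None
    effect: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError(f"{self.name}: non-finite statistic")
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError(f"{self.name}: p_raw outside [0, 1]")
        if self.p_fdr is not None and self.p_fdr < self.p_raw - 1e-12:
            raise ValueError(f"{self.name}: p_fdr below p_raw")


def _clean(x, name="sample"):
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains non-finite values")
    return x


def welch_ttest(a, b, name: str = "welch_t") -> TestResult:
    """Two-sample Welch t-test (unequal variances), two-sided p.

    Degenerate case: both samples constant with equal means gives t = 0,
    p = 1 by convention; both constant with unequal means is an error.
    """
    a, b = _clean(a, "a"), _clean(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(name, 0.0, len(a) + len(b) - 2, 1.0,
                              effect={"mean_a": a.mean(), "mean_b": b.mean()})
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        name,
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        effect={"mean_a": float(a.mean()), "mean_b": float(b.mean()),
                "n_a": len(a), "n_b": len(b)},
    )


def ancova_group_test(
    table: pd.DataFrame,
    outcome: str,
    group: str,
    covariates: list[str] | tuple = (),
    name: str | None = None,
) -> TestResult:
    """F-test for a group factor adjusting for covariates.

    Compares the full linear model (covariates + group dummies) against the
    covariates-only model; with an empty covariate set this is a one-way
    ANOVA, whose F equals the square of the pooled-variance t for two groups.
    """
    cols = [outcome, group, *covariates]
    data = table[cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    levels = pd.unique(data[group])
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    dummies = pd.get_dummies(data[group], drop_first=True).to_numpy(dtype=float)
    X_red = np.column_stack([np.ones(len(y))] + [data[c].to_numpy(dtype=float) for c in covariates])
    X_full = np.column_stack([X_red, dummies])

    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        aliased = []
        kept = np.empty((len(y), 0))
        names = ["intercept", *covariates, *[f"{group}[{l}]" for l in levels[1:]]]
        for j in range(X_full.shape[1]):
            trial = np.column_stack([kept, X_full[:, j]])
            if np.linalg.matrix_rank(trial) > kept.shape[1]:
                kept = trial
            else:
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    df_num = X_full.shape[1] - X_red.shape[1]
    df_den = len(y) - X_full.shape[1]
    if fit_full.ssr <= 1e-12 * max(1.0, float(y.var()) * len(y)):
        # degenerate design (e.g. a covariate that reproduces the outcome)
        import warnings

        warnings.warn("ANCOVA residual variance is ~0; returning F = 0", stacklevel=2)
        f, p = 0.0, 1.0
    else:
        f = ((fit_red.ssr - fit_full.ssr) / df_num) / (fit_full.ssr / df_den)
        p = float(sps.f.sf(f, df_num, df_den))
    means = data.groupby(group)[outcome].mean().to_dict()
    return TestResult(
        name or f"ancova_{outcome}", float(f), (df_num, df_den), p,
        effect={"group_means": means, "n": len(y)},
    )


def pearson_corr(x, y, name: str = "pearson") -> TestResult:
    """Pearson r with two-sided p via the t transform; reports R^2."""
    x, y = _clean(x, "x"), _clean(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult(name, float(r), len(x) - 2, float(p),
                      effect={"r_squared": float(r) ** 2, "n": len(x)})


def partial_spearman(x, y, covariates=None, name: str = "partial_spearman") -> TestResult:
    """Partial Spearman rank correlation of x and y given covariates.

    Mid-ranks for ties; covariate ranks (plus an intercept) are regressed out
    of the x and y ranks and the residuals correlated. With no covariates this
    reduces exactly to the plain Spearman rho.
    """
    x, y = _clean(x, "x"), _clean(y, "y")
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (np.size(covariates) == 0):
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("covariates not aligned to x and y")
        if not np.isfinite(Z).all():
            raise ValueError("covariates contain non-finite values")
    k = Z.shape[1]
    if n < k + 3:
        raise ValueError("need n >= n_covariates + 3 complete cases")

    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant variable after ranking")
    rz = np.column_stack([np.ones(n)] + [sps.rankdata(Z[:, j]) for j in range(k)])
    bx, *_ = np.linalg.lstsq(rz, rx, rcond=None)
    by, *_ = np.linalg.lstsq(rz, ry, rcond=None)
    ex, ey = rx - rz @ bx, ry - rz @ by
    denom = np.sqrt((ex * ex).sum() * (ey * ey).sum())
    if denom == 0:
        raise ValueError("residual ranks are constant")
    rho = float((ex * ey).sum() / denom)
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
        t = np.sign(rho) * np.inf
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(name, rho, df, p, effect={"n": n, "n_covariates": k})


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normality_screen(sample, name: str = "shapiro_wilk") -> TestResult:
    """Shapiro–Wilk normality screen (3 <= n <= 5000).

    Logged as a screening step only; nothing downstream gates on it.
    """
    x = _clean(sample)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if x.std() == 0:
        raise ValueError("constant sample")
    w, p = sps.shapiro(x)
    return TestResult(name, float(w), len(x), float(p))
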