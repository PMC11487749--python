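"""Gaussian-process normative models of gyrification and deviation Z-scores.

A normative model fits the typical trajectory of a GI measure over a
reference cohort as a Gaussian process over standardized covariates, and
expresses any subject as a deviation Z-score

    z = (y_observed - mu(x)) / sigma(x),

where ``mu`` and ``sigma`` are the GP predictive mean and *total* predictive
standard deviation (including the learned observation-noise floor, so that
held-out reference subjects score approximately N(0, 1)). Observed below
predicted gives a negative z.

Two covariate specifications are supported:

* Model 1 — post-menstrual age at scan, post-natal age at scan, sex;
* Model 2 — Model 1 plus supratentorial brain volume (STBV).

The kernel is a sum of an anisotropic RBF over the standardized covariates,
a linear (dot-product) term, and white noise — the conventional composite for
growth-curve normative models; hyperparameters maximize the marginal
likelihood with seeded multi-restart optimization.

Usage follows the Model/Results convention::

    model = GyrificationNormativeModel.from_dataframe(ref, target="gi_whole_brain", model=1)
    res = model.fit()
    z = res.z_scores(clinical)
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

MODEL1_COVARIATES = ("pma_scan", "pna_days", "sex")
MODEL2_COVARIATES = ("pma_scan", "pna_days", "sex", "stbv")

MIN_TRAIN = 20

__all__ = [
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "GyrificationNormativeModel",
    "GyrificationNormativeResults",
    "fit_normative",
    "reference_z_scores",
]


def _covariates_for(model: int):
    if model == 1:
        return MODEL1_COVARIATES
    if model == 2:
        return MODEL2_COVARIATES
    raise ValueError("model must be 1 or 2")


class GyrificationNormativeModel:
    """Normative GP model of one GI measure against demographic covariates.

    Parameters
    ----------
    endog : array, shape (n,)
        Observed GI values in the reference cohort.
    exog : array, shape (n, d)
        Covariate matrix (columns ordered as `covariate_names`).
    covariate_names : sequence of str
        Names of the covariate columns.
    seed : int
        Seed for the hyperparameter-restart optimizer.
    """

    def __init__(self, endog, exog, covariate_names, seed: int = 0):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(y) != X.shape[0]:
            raise ValueError("endog and exog have different lengths")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("non-finite values in training data")
        if len(y) < MIN_TRAIN:
            raise ValueError(f"need at least {MIN_TRAIN} reference subjects, got {len(y)}")
        names = tuple(covariate_names)
        if len(names) != X.shape[1]:
            raise ValueError("covariate_names does not match exog width")
        sd = X.std(axis=0)
        for nm, s in zip(names, sd):
            if s == 0:
                raise ValueError(f"zero-variance covariate: {nm}")
        self.endog = y
        self.exog = X
        self.covariate_names = names
        self.seed = seed
        self._x_mean = X.mean(axis=0)
        self._x_sd = sd

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        target: str = "gi_whole_brain",
        model: int | None = 1,
        covariates=None,
        seed: int = 0,
    ) -> "GyrificationNormativeModel":
        """Build from a cohort table; `model` 1 or 2 selects the covariate set,
        or pass `covariates` explicitly."""
        if covariates is None:
            covariates = _covariates_for(model)
        cols = [target, *covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"table lacks columns {missing}")
        sub = data[cols].dropna()
        obj = cls(sub[target], sub[list(covariates)], covariates, seed=seed)
        obj.target = target
        return obj

    # -- fitting -----------------------------------------------------------

    def _standardize(self, X):
        return (X - self._x_mean) / self._x_sd

    def fit(self, restarts: int = 5) -> "GyrificationNormativeResults":
        """Maximize the GP marginal likelihood (seeded multi-restart).

        The model is a linear mean function over the standardized covariates
        (fitted by least squares) with an anisotropic-RBF + white-noise GP on
        the residuals. Carrying the growth trend in the mean rather than the
        kernel matters for the clinical use case: clinical subjects are
        typically scanned at the edge of the reference covariate range, and a
        purely stationary kernel would revert to the training mean there,
        biasing the deviation scores. The RBF length-scale floor (half a
        training sd) keeps the smooth component from memorizing observation
        noise, which would deflate the predictive spread and miscalibrate
        held-out Z-scores.
        """
        if restarts < 1:
            raise ValueError("restarts must be >= 1")
        d = self.exog.shape[1]
        Xs = self._standardize(self.exog)
        design = np.column_stack([np.ones(len(Xs)), Xs])
        beta, *_ = np.linalg.lstsq(design, self.endog, rcond=None)
        resid = self.endog - design @ beta
        kernel = ConstantKernel(1.0, (1e-4, 1e3)) * RBF(
            length_scale=np.full(d, 2.0), length_scale_bounds=(0.5, 1e3)
        ) + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-8, 1e2))
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-10,
            normalize_y=True,
            n_restarts_optimizer=restarts - 1,
            random_state=self.seed,
        )
        gp.fit(Xs, resid)
        return GyrificationNormativeResults(self, gp, beta)


class GyrificationNormativeResults:
    """Fitted normative model: predictions, Z-scores, diagnostics, summary."""

    def __init__(
        self,
        model: GyrificationNormativeModel,
        gp: GaussianProcessRegressor,
        mean_coef: np.ndarray,
    ):
        self.model = model
        self.gp_ = gp
        self.mean_coef = np.asarray(mean_coef, dtype=float)
        self.log_marginal_likelihood = float(gp.log_marginal_likelihood_value_)
        self.kernel_ = gp.kernel_
        self.params = {}
        i = 0
        theta = np.exp(gp.kernel_.theta)
        for h in gp.kernel_.hyperparameters:
            if h.fixed:
                continue
            vals = theta[i : i + h.n_elements]
            self.params[h.name] = float(vals[0]) if h.n_elements == 1 else vals
            i += h.n_elements

    # -- prediction --------------------------------------------------------

    def _as_matrix(self, x) -> np.ndarray:
        names = self.model.covariate_names
        if isinstance(x, pd.DataFrame):
            missing = [c for c in names if c not in x.columns]
            if missing:
                raise ValueError(f"missing covariate columns {missing}")
            X = x[list(names)].to_numpy(dtype=float)
        else:
            X = np.asarray(x, dtype=float)
            if X.ndim == 1:
                X = X[None, :] if X.shape[0] == len(names) else X[:, None]
            if X.shape[1] != len(names):
                raise ValueError(
                    f"expected {len(names)} covariates {names}, got shape {X.shape}"
                )
        if not np.isfinite(X).all():
            raise ValueError("non-finite covariates")
        return X

    def predict(self, x):
        """Predictive mean and total predictive sd (includes noise floor)."""
        X = self._as_matrix(x)
        Xs = self.model._standardize(X)
        if np.abs(Xs).max(initial=0.0) > 5.0:
            log.warning(
                "covariates up to %.1f training sds outside the reference range; "
                "prediction is an extrapolation", float(np.abs(Xs).max()),
            )
        design = np.column_stack([np.ones(len(Xs)), Xs])
        mu, sd = self.gp_.predict(Xs, return_std=True)
        mu = mu + design @ self.mean_coef
        if (sd <= 0).any():
            raise RuntimeError("non-positive predictive sd: model invariant violated")
        return mu, sd

    def z_scores(self, data, y_observed=None) -> np.ndarray:
        """Deviation Z-scores, ``(observed - predicted) / predictive sd``.

        Either pass a DataFrame containing the covariates and the target
        column, or covariates plus an explicit `y_observed` array.
        """
        if y_observed is None:
            target = getattr(self.model, "target", None)
            if not isinstance(data, pd.DataFrame) or target is None or target not in data:
                raise ValueError("pass y_observed, or a DataFrame with the target column")
            y = data[target].to_numpy(dtype=float)
        else:
            y = np.asarray(y_observed, dtype=float).ravel()
        mu, sd = self.predict(data)
        if len(y) != len(mu):
            raise ValueError("y_observed not aligned to covariates")
        return (y - mu) / sd

    # -- diagnostics -------------------------------------------------------

    def training_z_scores(self) -> np.ndarray:
        return self.z_scores(
            pd.DataFrame(self.model.exog, columns=self.model.covariate_names),
            self.model.endog,
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Gyrification normative model (Gaussian process)",
            "=" * 48,
            f"target:            {getattr(m, 'target', '<array>')}",
            f"covariates:        {', '.join(m.covariate_names)}",
            f"n training:        {len(m.endog)}",
            f"log marginal lik.: {self.log_marginal_likelihood:.3f}",
            f"kernel:            {self.kernel_}",
            "hyperparameters:",
        ]
        for k, v in self.params.items():
            lines.append(f"    {k}: {np.array2string(np.atleast_1d(v), precision=4)}")
        tz = self.training_z_scores()
        lines.append(f"training z: mean {tz.mean():+.3f}, sd {tz.std(ddof=1):.3f}")
        return "\n".join(lines)

    def plot_trajectory(self, covariate: str = "pma_scan", ax=None, n_grid: int = 100):
        """Plot the normative mean ±1/2/3 predictive sds against one covariate,
        holding the others at their training means."""
        import matplotlib

        if ax is None:  # headless-safe default
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = self.model
        j = list(m.covariate_names).index(covariate)
        grid = np.tile(m._x_mean, (n_grid, 1))
        xs = np.linspace(m.exog[:, j].min(), m.exog[:, j].max(), n_grid)
        grid[:, j] = xs
        mu, sd = self.predict(grid)
        if ax is None:
            _, ax = plt.subplots()
        for k in (3, 2, 1):
            ax.fill_between(xs, mu - k * sd, mu + k * sd, alpha=0.15, color="C0")
        ax.plot(xs, mu, color="k", lw=1.5)
        ax.set_xlabel(covariate)
        ax.set_ylabel(getattr(m, "target", "GI"))
        return ax


# -- functional API ---------------------------------------------------------


def fit_normative(
    reference: pd.DataFrame,
    target: str = "gi_whole_brain",
    model: int = 1,
    seed: int = 0,
    restarts: int = 5,
) -> GyrificationNormativeResults:
    """Fit a normative GP on the reference cohort (Model 1 or 2 covariates)."""
    return GyrificationNormativeModel.from_dataframe(
        reference, target=target, model=model, seed=seed
    ).fit(restarts=restarts)


def reference_z_scores(
    reference: pd.DataFrame,
    target: str = "gi_whole_brain",
    model: int = 1,
    k_folds: int = 5,
    seed: int = 0,
    restarts: int = 5,
) -> np.ndarray:
    """Z-scores for reference subjects, each from a model not trained on them.

    K-fold cross-validation (shuffled, seeded); pass ``k_folds = n`` for
    leave-one-out. Clinical subjects should instead be scored by the full
    reference model (:func:`fit_normative`). Returns scores aligned to the
    input row order.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    covs = _covariates_for(model)
    sub = reference[[target, *covs]].dropna()
    n = len(sub)
    if k_folds > n:
        raise ValueError("k_folds exceeds number of complete reference rows")
    z = np.full(n, np.nan)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(sub):
        if len(train_idx) < MIN_TRAIN:
            raise ValueError(
                f"fold leaves only {len(train_idx)} training rows (< {MIN_TRAIN})"
            )
        res = GyrificationNormativeModel.from_dataframe(
            sub.iloc[train_idx], target=target, model=model, seed=seed
        ).fit(restarts=restarts)
        z[test_idx] = res.z_scores(sub.iloc[test_idx])
    out = np.full(len(reference), np.nan)
    out[reference.index.get_indexer(sub.index)] = z
    return out
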