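"""Elastic-net age clocks.

The clock is a penalized linear regression of chronological age (in years,
untransformed) on pre-selected CpG beta values. The objective is the glmnet
form

    (1/2n) * sum_i (age_i - b0 - x_i' b)^2
        + lambda * [ alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 ]

with the mixing parameter alpha fixed at 1/2 by default and the penalty
strength lambda chosen by internal 10-fold cross-validation on the training
samples. Predictors are standardized during fitting and coefficients are
reported back on the beta scale; only nonzero coefficients are retained, so
fitted clocks are sparse (tens of CpGs is typical).

:class:`EpigeneticClock` is the scikit-learn estimator; :func:`fit_clock`
and :func:`predict_age` adapt it to :class:`~pinnclock.io.Dataset` /
:class:`~pinnclock.io.ClockModel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ClockModel, Dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElasticNetConfig:
    """Fitting options for the age clock.

    alpha
        Elastic-net mixing parameter in (0, 1]; 1 = lasso. Default 0.5.
    n_internal_folds
        Folds of the internal CV that picks lambda. Default 10.
    lambda_grid
        Explicit descending grid of penalty strengths, or "auto" to derive
        ``n_lambdas`` values geometrically below the data-driven maximum.
    lambda_rule
        "min" picks the CV-MSE-minimizing lambda; "one_se" the largest
        lambda within one standard error of that minimum.
    standardize
        Standardize predictors internally (coefficients are always reported
        on the original beta scale).
    stratify_folds
        Stratify internal CV folds by age quantile (falls back to plain
        shuffled folds when bins are too small).
    """

    alpha: float = 0.5
    n_internal_folds: int = 10
    lambda_grid: tuple[float, ...] | str = "auto"
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    lambda_rule: str = "min"
    standardize: bool = True
    stratify_folds: bool = True
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_internal_folds < 2:
            raise ValueError("n_internal_folds must be >= 2")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValueError("lambda_rule must be 'min' or 'one_se'")


class EpigeneticClock(RegressorMixin, BaseEstimator):
    """Sparse elastic-net predictor of age from CpG methylation.

    Parameters mirror :class:`ElasticNetConfig`. ``X`` is samples x CpGs
    (beta values; NaN allowed — imputed with the training mean), ``y`` is
    age in years.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features_in_,)
        Dense coefficient vector on the beta scale (mostly zeros).
    lambda_ : float
        Selected penalty strength.
    feature_means_ : ndarray
        Training-set mean of every feature (used for NaN imputation).
    n_nonzero_ : int
    """

    def __init__(
        self,
        alpha: float = 0.5,
        n_internal_folds: int = 10,
        lambda_grid="auto",
        n_lambdas: int = 50,
        lambda_min_ratio: float = 0.01,
        lambda_rule: str = "min",
        standardize: bool = True,
        stratify_folds: bool = True,
        tol: float = 1e-3,
        seed: int = 0,
    ):
        self.alpha = alpha
        self.n_internal_folds = n_internal_folds
        self.lambda_grid = lambda_grid
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_rule = lambda_rule
        self.standardize = standardize
        self.stratify_folds = stratify_folds
        self.tol = tol
        self.seed = seed

    # -- internals -------------------------------------------------------
    def _cv_splits(self, y: np.ndarray):
        n = len(y)
        n_folds = min(self.n_internal_folds, n)
        if self.stratify_folds:
            # age-quantile bins; each bin must hold >= n_folds members
            n_bins = max(2, min(5, n // n_folds))
            try:
                bins = pd.qcut(y, q=n_bins, labels=False, duplicates="drop")
                counts = np.bincount(bins.astype(int))
                if counts.min() >= n_folds:
                    skf = StratifiedKFold(n_folds, shuffle=True, random_state=self.seed)
                    return list(skf.split(np.zeros(n), bins))
            except ValueError:
                pass
        kf = KFold(n_folds, shuffle=True, random_state=self.seed)
        return list(kf.split(np.zeros(n)))

    def fit(self, X, y):
        X = validate_data(self, X, ensure_all_finite="allow-nan", dtype=float, copy=True)
        # canonical memory layout: reduction order, and hence the last bits of
        # the fit, must not depend on how the caller sliced the matrix
        X = np.ascontiguousarray(X)
        y = np.asarray(y, float)
        if np.ptp(y) == 0:
            raise ValueError("constant age: cannot fit a clock")
        if len(y) < 2:
            raise ValueError("need at least two training samples")

        self.feature_means_ = np.nanmean(X, axis=0)
        # CpGs missing in every training sample carry no information; they are
        # imputed at 0.5 and flagged so callers can report them
        all_nan = ~np.isfinite(self.feature_means_)
        if all_nan.any():
            logger.warning("%d CpGs missing in all training samples; imputed at 0.5", all_nan.sum())
            self.feature_means_[all_nan] = 0.5
        self.all_missing_mask_ = all_nan
        nan_cells = ~np.isfinite(X)
        if nan_cells.any():
            X[nan_cells] = np.broadcast_to(self.feature_means_, X.shape)[nan_cells]

        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xs = (X - mu) / sd
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
            Xs = X

        splits = self._cv_splits(y)
        grid = None if self.lambda_grid == "auto" else np.sort(np.asarray(self.lambda_grid, float))[::-1]
        cv_est = ElasticNetCV(
            l1_ratio=self.alpha,
            alphas=self.n_lambdas if grid is None else grid,
            eps=self.lambda_min_ratio,
            tol=self.tol,
            cv=splits,
            max_iter=20_000,
        )
        cv_est.fit(Xs, y)

        lam = float(cv_est.alpha_)
        if self.lambda_rule == "one_se":
            mean_mse = cv_est.mse_path_.mean(axis=1)
            se = cv_est.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_est.mse_path_.shape[1])
            i_min = int(np.argmin(mean_mse))
            ok = mean_mse <= mean_mse[i_min] + se[i_min]
            lam = float(cv_est.alphas_[ok].max())
            final = ElasticNet(alpha=lam, l1_ratio=self.alpha, tol=self.tol, max_iter=20_000)
            final.fit(Xs, y)
            coef_s, icpt_s = final.coef_, float(final.intercept_)
        else:
            coef_s, icpt_s = cv_est.coef_, float(cv_est.intercept_)

        self.lambda_ = lam
        self.lambda_path_ = np.asarray(cv_est.alphas_, float)
        self.cv_mse_path_ = np.asarray(cv_est.mse_path_, float)
        self.coef_ = coef_s / sd
        self.intercept_ = icpt_s - float(self.coef_ @ mu)
        self.n_nonzero_ = int(np.count_nonzero(self.coef_))
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, ensure_all_finite="allow-nan", dtype=float, reset=False, copy=True)
        X = np.ascontiguousarray(X)
        nan_cells = ~np.isfinite(X)
        if nan_cells.any():
            X[nan_cells] = np.broadcast_to(self.feature_means_, X.shape)[nan_cells]
        return self.intercept_ + X @ self.coef_


# ---------------------------------------------------------------------------
# Dataset / ClockModel adapters
# ---------------------------------------------------------------------------

def fit_clock(
    dataset: Dataset,
    train_ids: Iterable[str],
    cpg_subset: Sequence[str],
    config: ElasticNetConfig | None = None,
) -> ClockModel:
    """Fit an elastic-net clock on the given training samples and CpG panel."""
    config = config or ElasticNetConfig()
    train_ids = [s for s in dataset.beta.columns if s in set(train_ids)]
    if not cpg_subset:
        raise ValueError("cpg_subset is empty")
    if len(train_ids) < config.n_internal_folds:
        raise ValueError(
            f"{len(train_ids)} training samples < {config.n_internal_folds} internal folds"
        )
    X = dataset.beta.loc[list(cpg_subset), train_ids].to_numpy(float).T
    y = dataset.ages(train_ids).to_numpy(float)

    est = EpigeneticClock(
        alpha=config.alpha,
        n_internal_folds=config.n_internal_folds,
        lambda_grid=config.lambda_grid,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        lambda_rule=config.lambda_rule,
        standardize=config.standardize,
        stratify_folds=config.stratify_folds,
        tol=config.tol,
        seed=config.seed,
    )
    est.fit(X, y)

    nz = np.nonzero(est.coef_)[0]
    weights = {cpg_subset[j]: float(est.coef_[j]) for j in nz}
    means = {cpg_subset[j]: float(est.feature_means_[j]) for j in nz}
    return ClockModel(
        intercept=float(est.intercept_),
        weights=weights,
        preselected_cpgs=list(cpg_subset),
        alpha=config.alpha,
        lambda_=float(est.lambda_),
        training_means=means,
        training_meta={
            "n_training_samples": len(train_ids),
            "n_internal_folds": config.n_internal_folds,
            "lambda_rule": config.lambda_rule,
            "seed": config.seed,
        },
    )


def predict_age(model: ClockModel, beta: pd.DataFrame) -> pd.Series:
    """Apply a clock to a beta matrix (CpGs x samples): years per sample.

    Missing values of a weighted CpG are imputed with its stored training
    mean; a weighted CpG absent from the matrix with no stored mean is an
    error.
    """
    pred = pd.Series(model.intercept, index=beta.columns, dtype=float)
    # fixed (sorted) accumulation order keeps predictions bit-reproducible
    # regardless of how the weights dict was built
    for cpg in sorted(model.weights):
        w = model.weights[cpg]
        if cpg in beta.index:
            x = beta.loc[cpg].astype(float)
            if x.isna().any():
                if cpg not in model.training_means:
                    raise ValueError(f"missing values for {cpg!r} and no stored training mean")
                x = x.fillna(model.training_means[cpg])
        elif cpg in model.training_means:
            logger.warning("CpG %s absent from matrix; using stored training mean", cpg)
            x = pd.Series(model.training_means[cpg], index=beta.columns)
        else:
            raise ValueError(f"weighted CpG {cpg!r} absent and no stored training mean")
        pred = pred + w * x
    return pred
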