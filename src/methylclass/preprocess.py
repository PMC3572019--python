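"""Quantile normalization and empirical-Bayes batch adjustment.

Both steps are exposed twice: as scikit-learn transformers operating on
samples x features arrays (:class:`QuantileNormalizer`, :class:`ComBat`), and
as thin domain wrappers operating on probes x samples :class:`BetaMatrix`
objects (:func:`quantile_normalize`, :func:`fit_batch_model`,
:func:`apply_batch_adjust`).

The batch adjustment is the parametric empirical-Bayes location/scale model:
each feature is standardized against a design holding batch indicators plus
biological covariates, per-batch location (gamma) and scale (delta^2)
estimates are shrunk toward batch-level normal / inverse-gamma priors whose
hyperparameters come from method-of-moments fits across features, and the
shrunken estimates are removed before restoring the grand location/scale.
Covariates (cell type) are part of the design so biological differences are
not absorbed into the batch terms.

Beta values are bounded, so the default pipeline adjusts logit-transformed
betas and maps back, clipping (and counting) any value that exits [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import BetaMatrix

logger = logging.getLogger("methylclass")


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def _quantile_normalize_columns(values: np.ndarray) -> np.ndarray:
    """Force every column of a features x samples array onto the mean
    distribution of sorted values.  Ties within a column receive the mean of
    the reference values over their rank span."""
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values, dtype=float)
    n = values.shape[0]
    cum_ref = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        # tie groups are contiguous runs in the sorted column
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [n]])
        mapped = np.empty(n)
        for a, b in zip(starts, stops):
            mapped[a:b] = (cum_ref[b] - cum_ref[a]) / (b - a)
        out[order[:, j], j] = mapped
    return out


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Map every sample's value distribution onto a common reference.

    ``fit`` stores the reference distribution (the across-sample mean of
    sorted values); ``transform`` maps each new sample's values onto it by
    rank, with tied values receiving the mean reference value over their rank
    span.  ``fit_transform`` on the training cohort therefore makes all
    column distributions identical.

    Follows the scikit-learn convention: X is samples x features.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        # operate on features x samples
        return _map_to_reference(X.T, self.reference_).T

    def fit_transform(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        if X.shape[0] == 1:
            warnings.warn("single sample: quantile normalization is the "
                          "identity", UserWarning)
            return X.copy()
        return _quantile_normalize_columns(X.T).T


def _map_to_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rank-map each column of a features x samples array onto ``reference``."""
    n = values.shape[0]
    cum_ref = np.concatenate([[0.0], np.cumsum(np.sort(reference))])
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [n]])
        mapped = np.empty(n)
        for a, b in zip(starts, stops):
            mapped[a:b] = (cum_ref[b] - cum_ref[a]) / (b - a)
        out[order[:, j], j] = mapped
    return out


def quantile_normalize(matrix: BetaMatrix) -> BetaMatrix:
    """Quantile-normalize a beta matrix across samples.

    Requires a complete matrix (impute first).  With a single sample this is
    the identity (with a warning).  Output stays in [0, 1] because the
    reference is a mean of values in [0, 1].
    """
    if matrix.n_missing:
        raise ValueError("quantile_normalize requires a complete matrix; "
                         "run impute_missing first")
    if matrix.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is the identity",
                      UserWarning)
        return matrix.copy()
    normalized = _quantile_normalize_columns(matrix.values)
    return BetaMatrix(pd.DataFrame(normalized, index=matrix.probe_ids,
                                   columns=matrix.sample_ids))


# ---------------------------------------------------------------------------
# Parametric empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters (probes x batches throughout)."""

    batches: list[str]
    feature_ids: list[str] | None
    gamma_star: np.ndarray        # shrunken per-batch location, features x batches
    delta_star: np.ndarray        # shrunken per-batch scale (variance)
    gamma_hat: np.ndarray         # raw per-batch location estimates
    delta_hat: np.ndarray         # raw per-batch variance estimates
    gamma_bar: np.ndarray         # prior mean of gamma per batch
    t2: np.ndarray                # prior variance of gamma per batch
    a_prior: np.ndarray           # inverse-gamma shape per batch
    b_prior: np.ndarray           # inverse-gamma scale per batch
    stand_mean: np.ndarray        # features x samples standardization offset
    var_pooled: np.ndarray        # features
    sample_batches: pd.Series
    identity: bool = False        # single batch: adjustment is a no-op


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_solve(s_data: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
              g_bar: float, t2: float, a: float, b: float,
              conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled posterior updates for one batch to convergence."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        # signed denominator for the location term mirrors the reference
        # EB implementation's stopping rule exactly
        change = max((np.abs(g_new - g_old) / g_old).max(),
                     (np.abs(d_new - d_old) / d_old).max())
        g_old, d_old = g_new, d_new
    return g_old, d_old


class ComBat(TransformerMixin, BaseEstimator):
    """Parametric empirical-Bayes batch-effect adjustment.

    Scikit-learn-style transformer on samples x features arrays.  Batch labels
    (and optional biological covariates to protect) are passed to ``fit``;
    ``transform`` adjusts the samples seen at fit time.

    Parameters
    ----------
    conv : float
        Convergence tolerance of the iterative EB update.
    """

    def __init__(self, conv: float = 1e-4):
        self.conv = conv

    def fit(self, X, y=None, *, batch, covariates=None):
        X = check_array(X)
        batch = pd.Series(np.asarray(batch, dtype=object),
                          index=pd.RangeIndex(len(batch)))
        if len(batch) != X.shape[0]:
            raise ValueError("batch labels must match sample count")
        self.model_ = _fit_batch_core(X.T, batch, covariates, conv=self.conv)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return _apply_batch_core(X.T, self.model_).T

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def _fit_batch_core(values: np.ndarray, batch: pd.Series,
                    covariates, conv: float = 1e-4) -> BatchModel:
    """Fit the EB model on a features x samples array.

    ``covariates`` is None or a sequence of per-sample categorical labels.
    """
    n_features, n_samples = values.shape
    batch = pd.Series(np.asarray(batch, dtype=object))
    batch_levels = list(pd.unique(batch))
    n_batches = len(batch_levels)
    if n_batches < 2:
        return BatchModel(batches=batch_levels, feature_ids=None,
                          gamma_star=np.zeros((n_features, 1)),
                          delta_star=np.ones((n_features, 1)),
                          gamma_hat=np.zeros((n_features, 1)),
                          delta_hat=np.ones((n_features, 1)),
                          gamma_bar=np.zeros(1), t2=np.ones(1),
                          a_prior=np.ones(1), b_prior=np.ones(1),
                          stand_mean=np.zeros_like(values),
                          var_pooled=np.ones(n_features),
                          sample_batches=batch, identity=True)
    counts = np.array([(batch == b).sum() for b in batch_levels])
    if (counts < 2).any():
        raise ValueError("every batch needs >=2 samples")

    # design: batch indicators + covariate dummies (reference level dropped)
    B = np.column_stack([(batch == b).to_numpy(float) for b in batch_levels])
    design = B
    if covariates is not None:
        cov = pd.Series(np.asarray(covariates, dtype=object))
        dummies = pd.get_dummies(cov, drop_first=True).to_numpy(float)
        if dummies.size:
            candidate = np.column_stack([B, dummies])
            if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
                warnings.warn("confounded design: covariate is confounded "
                              "with batch; dropping covariate", UserWarning)
            else:
                design = candidate

    # per-feature OLS against the full design
    coefs, *_ = np.linalg.lstsq(design, values.T, rcond=None)  # p x features
    fitted = design @ coefs
    resid = values.T - fitted
    var_pooled = (resid ** 2).mean(axis=0)  # features
    var_pooled = np.maximum(var_pooled, 1e-12)

    # grand (batch-size weighted) mean plus covariate contribution
    grand = (counts / n_samples) @ coefs[:n_batches]
    stand_mean = np.tile(grand[:, None], (1, n_samples))
    if design.shape[1] > n_batches:
        cov_part = design[:, n_batches:] @ coefs[n_batches:]
        stand_mean = stand_mean + cov_part.T
    s_data = (values - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((n_features, n_batches))
    delta_hat = np.empty((n_features, n_batches))
    for i, b in enumerate(batch_levels):
        cols = (batch == b).to_numpy()
        gamma_hat[:, i] = s_data[:, cols].mean(axis=1)
        delta_hat[:, i] = s_data[:, cols].var(axis=1, ddof=1)
    gamma_bar = gamma_hat.mean(axis=0)
    t2 = gamma_hat.var(axis=0, ddof=1)
    a_prior = np.array([_aprior(delta_hat[:, i]) for i in range(n_batches)])
    b_prior = np.array([_bprior(delta_hat[:, i]) for i in range(n_batches)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, b in enumerate(batch_levels):
        cols = (batch == b).to_numpy()
        g, d = _it_solve(s_data[:, cols], gamma_hat[:, i], delta_hat[:, i],
                         gamma_bar[i], t2[i], a_prior[i], b_prior[i],
                         conv=conv)
        gamma_star[:, i], delta_star[:, i] = g, d

    return BatchModel(batches=batch_levels, feature_ids=None,
                      gamma_star=gamma_star, delta_star=delta_star,
                      gamma_hat=gamma_hat, delta_hat=delta_hat,
                      gamma_bar=gamma_bar, t2=t2,
                      a_prior=a_prior, b_prior=b_prior,
                      stand_mean=stand_mean, var_pooled=var_pooled,
                      sample_batches=batch, identity=False)


def _apply_batch_core(values: np.ndarray, model: BatchModel) -> np.ndarray:
    """Adjust a features x samples array with a fitted :class:`BatchModel`."""
    if model.identity:
        return values.copy()
    if values.shape[0] != model.var_pooled.shape[0]:
        raise ValueError("feature count differs from the fitted model")
    s_data = (values - model.stand_mean) / np.sqrt(model.var_pooled)[:, None]
    adjusted = np.empty_like(s_data)
    for i, b in enumerate(model.batches):
        cols = (model.sample_batches == b).to_numpy()
        adjusted[:, cols] = ((s_data[:, cols] - model.gamma_star[:, [i]])
                             / np.sqrt(model.delta_star[:, [i]]))
    return adjusted * np.sqrt(model.var_pooled)[:, None] + model.stand_mean


# ---------------------------------------------------------------------------
# Domain wrappers on BetaMatrix (logit scale by default)
# ---------------------------------------------------------------------------

_LOGIT_EPS = 1e-6


def _to_logit(values: np.ndarray) -> np.ndarray:
    return logit(np.clip(values, _LOGIT_EPS, 1.0 - _LOGIT_EPS))


def fit_batch_model(matrix: BetaMatrix, batches: pd.Series,
                    covariate: pd.Series | None = None,
                    scale: str = "logit", conv: float = 1e-4) -> BatchModel:
    """Fit the EB batch model on a beta matrix.

    ``batches`` and ``covariate`` (typically cell type, so biological signal
    is protected) are indexed by sample ID.  ``scale`` selects whether the
    location/scale model is fitted on logit-transformed betas (default) or on
    raw betas.
    """
    if scale not in ("logit", "raw"):
        raise ValueError("scale must be 'logit' or 'raw'")
    if matrix.n_missing:
        raise ValueError("batch model requires a complete matrix")
    batches = pd.Series(batches).loc[matrix.sample_ids]
    cov = (pd.Series(covariate).loc[matrix.sample_ids].to_numpy()
           if covariate is not None else None)
    values = matrix.values if scale == "raw" else _to_logit(matrix.values)
    model = _fit_batch_core(values, batches.reset_index(drop=True), cov,
                            conv=conv)
    model.feature_ids = list(matrix.probe_ids)
    model.scale = scale  # type: ignore[attr-defined]
    model.sample_ids = list(matrix.sample_ids)  # type: ignore[attr-defined]
    return model


def apply_batch_adjust(matrix: BetaMatrix, model: BatchModel) -> BetaMatrix:
    """Apply a fitted batch model; output is clipped back into [0, 1].

    The number of clipped entries is logged.  The probe set must match the
    one the model was fitted on.
    """
    if model.feature_ids is not None and list(matrix.probe_ids) != model.feature_ids:
        raise ValueError("probe set differs from the one the batch model "
                         "was fitted on")
    scale = getattr(model, "scale", "logit")
    values = matrix.values if scale == "raw" else _to_logit(matrix.values)
    adjusted = _apply_batch_core(values, model)
    if scale == "logit":
        adjusted = expit(adjusted)
    n_clipped = int(((adjusted < 0) | (adjusted > 1)).sum())
    if n_clipped:
        logger.info("batch adjustment clipped %d values into [0, 1]", n_clipped)
    adjusted = np.clip(adjusted, 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(adjusted, index=matrix.probe_ids,
                                   columns=matrix.sample_ids))


def batch_adjust(matrix: BetaMatrix, batches: pd.Series,
                 covariate: pd.Series | None = None,
                 scale: str = "logit") -> BetaMatrix:
    """Convenience: fit and apply in one call."""
    model = fit_batch_model(matrix, batches, covariate, scale=scale)
    return apply_batch_adjust(matrix, model)
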