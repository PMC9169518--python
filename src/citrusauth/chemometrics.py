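"""Chemometric core: autoscaling, PCA, PLS1 and jackknife variable selection.

The latent-variable machinery is implemented here from first principles (the
NIPALS-style sequential extraction customary in chemometrics software);
scikit-learn supplies only the estimator interface conventions. All
estimators follow the fit/transform/predict protocol, validate their inputs
and expose fitted state through trailing-underscore attributes, so they
compose with scikit-learn pipelines and model selection.

Model selection follows "full cross-validation": leave-one-out by default,
with the optimal component count chosen as the RMSECV minimum softened by a
one-standard-error parsimony rule. Variable significance uses Martens'
uncertainty test — the jackknife variance of each regression coefficient
over the cross-validation submodels, with a two-sided t interval at 95%
confidence; a coefficient whose interval crosses zero is not significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin


class ChemometricsError(ValueError):
    pass


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ChemometricsError("X must be a 2-d array")
    return X


# ---------------------------------------------------------------------------
# Autoscaling


class Autoscaler(BaseEstimator, TransformerMixin):
    """Column-wise mean centering and unit-variance scaling.

    Constant columns cannot be autoscaled; they are dropped on transform and
    reported in ``dropped_columns_``.
    """

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[0] < 2:
            raise ChemometricsError("autoscaling needs at least two rows")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.kept_mask_ = sd > 0
        if not self.kept_mask_.any():
            raise ChemometricsError("all columns are constant")
        self.scale_ = np.where(self.kept_mask_, sd, 1.0)
        self.dropped_columns_ = np.flatnonzero(~self.kept_mask_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X)
        scaled = (X - self.mean_) / self.scale_
        return scaled[:, self.kept_mask_]

    def inverse_transform(self, X_scaled) -> np.ndarray:
        X_scaled = _as_matrix(X_scaled)
        out = np.tile(self.mean_, (X_scaled.shape[0], 1))
        out[:, self.kept_mask_] = (
            X_scaled * self.scale_[self.kept_mask_] + self.mean_[self.kept_mask_]
        )
        return out


def autoscale(X) -> tuple[np.ndarray, Autoscaler]:
    scaler = Autoscaler().fit(X)
    return scaler.transform(X), scaler


# ---------------------------------------------------------------------------
# PCA


class PCAModel(BaseEstimator, TransformerMixin):
    """Principal component analysis by singular value decomposition.

    Centers internally (pass autoscaled data for correlation-matrix PCA).
    Components are ordered by decreasing explained variance; loadings are
    orthonormal. Rank deficiency silently reduces the returned component
    count (``n_components_``).
    """

    def __init__(self, n_components: Optional[int] = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = _as_matrix(X)
        n, p = X.shape
        if n < 2:
            raise ChemometricsError("PCA needs at least two rows")
        limit = min(n - 1, p)
        requested = self.n_components if self.n_components is not None else limit
        if requested > limit:
            raise ChemometricsError(
                f"n_components={requested} exceeds min(rows-1, cols)={limit}"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s.max() * max(n, p) * np.finfo(float).eps if s.size else 0.0
        rank = int((s > tol).sum())
        k = min(requested, rank)
        self.n_components_ = k
        self.rank_deficient_ = k < requested
        self.components_ = vt[:k]
        self.singular_values_ = s[:k]
        total_var = (s ** 2).sum()
        self.explained_variance_ratio_ = (
            s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
        )
        self.scores_ = u[:, :k] * s[:k]
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return (X - self.mean_) @ self.components_.T


def pca(X, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores, loadings and explained-variance fractions of a scaled matrix."""
    model = PCAModel(n_components=n_components).fit(X)
    return model.scores_, model.components_, model.explained_variance_ratio_


# ---------------------------------------------------------------------------
# PLS1


class PLS1Regression(BaseEstimator, RegressorMixin):
    """Single-response partial least squares by sequential latent variables.

    Per component: the weight vector is the normalized covariance X'y, the
    score is the projection Xw, x- and y-loadings are least-squares
    regressions onto the score, and both X and y are deflated. Regression
    coefficients are composed across components; inputs are autoscaled and y
    centered internally, so predictions are invariant under per-column
    affine rescaling of the raw inputs.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ChemometricsError("X and y row counts differ")
        if np.std(y) == 0:
            raise ChemometricsError("y has zero variance")
        n, p = X.shape
        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if self.scale:
            self.x_scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.x_scale_ = np.ones(p)
        self.y_mean_ = y.mean()
        Xw = (X - self.x_mean_) / self.x_scale_
        yw = y - self.y_mean_

        a_max = min(self.n_components, n - 1, p)
        W = np.zeros((p, a_max))
        P = np.zeros((p, a_max))
        q = np.zeros(a_max)
        T = np.zeros((n, a_max))
        Xd, yd = Xw.copy(), yw.copy()
        a = 0
        for _ in range(a_max):
            cov = Xd.T @ yd
            norm = np.linalg.norm(cov)
            if norm < 1e-14:
                break
            w = cov / norm
            t = Xd @ w
            tt = float(t @ t)
            if tt < 1e-14:
                break
            p_load = Xd.T @ t / tt
            q_load = float(yd @ t / tt)
            W[:, a], P[:, a], q[a], T[:, a] = w, p_load, q_load, t
            Xd -= np.outer(t, p_load)
            yd -= q_load * t
            a += 1
        if a == 0:
            raise ChemometricsError("no latent variable could be extracted")
        self.n_components_ = a
        self.x_weights_ = W[:, :a]
        self.x_loadings_ = P[:, :a]
        self.y_loadings_ = q[:a]
        self.x_scores_ = T[:, :a]
        # b on the scaled space: W (P'W)^-1 q
        pw = self.x_loadings_.T @ self.x_weights_
        beta_scaled = self.x_weights_ @ np.linalg.solve(pw, self.y_loadings_)
        self.coef_scaled_ = beta_scaled
        self.coef_ = beta_scaled / self.x_scale_
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        fitted = X @ self.coef_ + self.intercept_
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r2_train_ = 1.0 - ss_res / ss_tot
        self.n_features_in_ = p
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return X @ self.coef_ + self.intercept_


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CrossValidation:
    """Full cross-validation summary for component counts 1..max."""

    rmsecv: np.ndarray  # (max_components,)
    suggested_components: int
    segments: tuple[tuple[int, ...], ...]
    submodel_coefs: np.ndarray  # (n_segments, max_components, p), original scale
    press_errors: np.ndarray  # (max_components, n_samples) held-out residuals


def _make_segments(
    n: int, segmentation: str | int, seed: Optional[int]
) -> list[np.ndarray]:
    if segmentation == "loo":
        return [np.array([i]) for i in range(n)]
    k = int(segmentation)
    if k < 2 or k > n:
        raise ChemometricsError(f"segment count {k} invalid for {n} samples")
    order = np.arange(n)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n)
    return [seg for seg in np.array_split(order, k) if seg.size]


def cross_validate(
    X,
    y,
    max_components: int,
    segmentation: str | int = "loo",
    seed: Optional[int] = None,
    scale: bool = True,
) -> CrossValidation:
    """Leave-one-out (or segmented) cross-validation of PLS1 models.

    Returns the RMSECV curve over component counts, the per-segment
    submodel coefficients (for the uncertainty test) and a parsimonious
    component suggestion: the smallest count whose mean squared error is
    within one standard error of the global minimum.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    segments = _make_segments(n, segmentation, seed)
    if len(segments) < 2:
        raise ChemometricsError("need at least two cross-validation segments")
    a_max = min(max_components, n - 2, X.shape[1])
    if a_max < 1:
        raise ChemometricsError("too few samples for cross-validation")
    errors = np.full((a_max, n), np.nan)
    coefs = np.zeros((len(segments), a_max, X.shape[1]))
    for s_idx, held in enumerate(segments):
        train = np.setdiff1d(np.arange(n), held)
        y_train = y[train]
        if np.std(y_train) == 0:
            raise ChemometricsError("a training segment has zero y variance")
        model = PLS1Regression(n_components=a_max, scale=scale).fit(
            X[train], y_train
        )
        for a in range(1, a_max + 1):
            sub = _truncate(model, a)
            errors[a - 1, held] = y[held] - (X[held] @ sub[0] + sub[1])
            coefs[s_idx, a - 1] = sub[0]
    sq = errors ** 2
    mse = np.nanmean(sq, axis=1)
    rmsecv = np.sqrt(mse)
    best = int(np.argmin(mse))
    se_best = float(np.nanstd(sq[best], ddof=1) / np.sqrt(n))
    suggested = best
    for a in range(best + 1):
        if mse[a] <= mse[best] + se_best:
            suggested = a
            break
    return CrossValidation(
        rmsecv=rmsecv,
        suggested_components=suggested + 1,
        segments=tuple(tuple(int(i) for i in seg) for seg in segments),
        submodel_coefs=coefs,
        press_errors=errors,
    )


def _truncate(model: PLS1Regression, a: int) -> tuple[np.ndarray, float]:
    """Coefficients/intercept of the fitted model truncated to a components."""
    a = min(a, model.n_components_)
    pw = model.x_loadings_[:, :a].T @ model.x_weights_[:, :a]
    beta_scaled = model.x_weights_[:, :a] @ np.linalg.solve(
        pw, model.y_loadings_[:a]
    )
    coef = beta_scaled / model.x_scale_
    intercept = model.y_mean_ - float(model.x_mean_ @ coef)
    return coef, intercept


# ---------------------------------------------------------------------------
# Martens' uncertainty test


@dataclass(frozen=True)
class UncertaintyResult:
    coef: np.ndarray  # full-model coefficients
    jackknife_variance: np.ndarray
    t_critical: float
    significant: np.ndarray  # boolean mask

    def significant_indices(self) -> np.ndarray:
        return np.flatnonzero(self.significant)


def martens_uncertainty(
    full_coefs: np.ndarray,
    submodel_coefs: np.ndarray,
    alpha: float = 0.05,
) -> UncertaintyResult:
    """Jackknife significance of PLS coefficients over CV submodels.

    The stability of a variable is the spread of its coefficient across all
    cross-validation submodels: s²_b = Σ_m (b_m − b)² · (M−1)/M. A variable
    is significant when the two-sided t interval b ± t·s_b (df = M−1) does
    not cross zero.
    """
    b = np.asarray(full_coefs, dtype=float)
    B = _as_matrix(submodel_coefs)
    m = B.shape[0]
    if m < 3:
        raise ChemometricsError("need at least three submodels")
    if B.shape[1] != b.shape[0]:
        raise ChemometricsError("submodel coefficient width mismatch")
    s2 = ((B - b) ** 2).sum(axis=0) * (m - 1) / m
    t_crit = float(stats.t.ppf(1 - alpha / 2, df=m - 1))
    s = np.sqrt(s2)
    significant = np.abs(b) > t_crit * s
    # zero jackknife variance: interval collapses to the point b
    significant = np.where(s == 0, b != 0, significant)
    return UncertaintyResult(
        coef=b, jackknife_variance=s2, t_critical=t_crit,
        significant=significant.astype(bool),
    )


@dataclass(frozen=True)
class VariableReduction:
    survivors: tuple[str, ...]  # ordered by |coefficient|, descending
    coefficients: dict[str, float]
    uncertainty: UncertaintyResult
    n_components: int


def reduce_variables(
    X,
    y,
    candidates: Sequence[str],
    max_components: int = 5,
    segmentation: str | int = "loo",
    seed: Optional[int] = None,
) -> VariableReduction:
    """PLS + full cross-validation + Martens' test over candidate variables.

    Returns the significant variables ordered by coefficient magnitude; the
    coefficient sign indicates the marker direction with respect to y.
    """
    X = _as_matrix(X)
    if len(candidates) != X.shape[1]:
        raise ChemometricsError("candidate labels must match X columns")
    if len(candidates) < 2:
        raise ChemometricsError("need at least two candidate variables")
    cv = cross_validate(X, y, max_components, segmentation, seed)
    a = cv.suggested_components
    full = PLS1Regression(n_components=a).fit(X, y)
    unc = martens_uncertainty(full.coef_, cv.submodel_coefs[:, a - 1, :])
    idx = unc.significant_indices()
    if idx.size == 0:
        raise ChemometricsError(
            "no variable is significant at the 5% level; model-free "
            "comparison of profiles is advised"
        )
    order = idx[np.argsort(-np.abs(full.coef_[idx]))]
    return VariableReduction(
        survivors=tuple(candidates[i] for i in order),
        coefficients={candidates[i]: float(full.coef_[i]) for i in order},
        uncertainty=unc,
        n_components=a,
    )
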