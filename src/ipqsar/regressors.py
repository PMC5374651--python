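"""Regression engines and Mahalanobis machinery for the GA-wrapped models.

Two regressors back the feature-selection wrappers:

* PLS1 (NIPALS, mean-centred, no unit-variance scaling by default - the
  interaction energies share units) with a tunable number of latent
  variables ``lv``; at ``lv == rank(X_centred)`` it reproduces the ordinary
  least-squares fit.
* kNN regression in which compound similarity is the Mahalanobis distance
  M = sqrt((v - mu)' Sigma^-1 (v - mu)) in the selected-feature subspace;
  a query's prediction is the unweighted mean activity of its k nearest
  training compounds (ties at the k-th distance broken by row order).

The same quadratic form scores *feature significance*: each feature's column
over compounds is a vector v, mu is the mean column over all features and
Sigma the covariance of columns across features, so an atypical interaction
pattern gets a large M.  Covariance matrices of hundreds of features in a
small-n compound space are singular, so Sigma is shrunk by default:
Sigma_reg = Sigma + lambda*I with lambda = 1e-6 * trace(Sigma)/dim.

An alternative per-compound reading of the significance vector space exists;
``feature_significance(..., compound_space=True)`` exposes it without any
fidelity claim (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

#: default shrinkage multiplier for covariance regularisation
DEFAULT_SHRINKAGE = 1e-6


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    lv: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray  # (p,) regression vector on centred data

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_pls(self, X)


def fit_pls(X: np.ndarray, y: np.ndarray, lv: int) -> PLSModel:
    """Fit PLS1 by NIPALS with ``lv`` latent variables.

    Deterministic: with univariate y each component is a closed-form power
    step, so two fits on identical input are bit-identical.  If the centred
    matrix runs out of rank before ``lv`` components the extraction stops
    early (the fit then equals the full-rank OLS solution).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X rows must match y length")
    if not 1 <= lv <= min(n - 1, p):
        raise ValueError(f"lv={lv} outside bounds [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    if not E.any():
        raise ValueError("degenerate X: all columns constant")
    r = y - y_mean

    W = np.empty((p, lv))
    P = np.empty((p, lv))
    q = np.empty(lv)
    tol = np.finfo(float).eps * max(n, p)
    scale = float(np.abs(E).max()) or 1.0
    a = 0
    while a < lv:
        w = E.T @ r
        nw = float(np.linalg.norm(w))
        if nw <= tol * scale * max(1.0, float(np.abs(r).max(initial=0.0))):
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= (tol * scale) ** 2:
            break
        W[:, a] = w
        P[:, a] = E.T @ t / tt
        q[a] = float(r @ t) / tt
        E = E - np.outer(t, P[:, a])
        r = r - q[a] * t
        a += 1
    if a == 0:
        coef = np.zeros(p)
    else:
        Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
        coef = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    return PLSModel(lv=lv, x_mean=x_mean, y_mean=y_mean, coef=coef)


def predict_pls(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.x_mean.size}"
        )
    return model.y_mean + (X - model.x_mean) @ model.coef


# ---------------------------------------------------------------------------
# Mahalanobis distance
# ---------------------------------------------------------------------------

@dataclass
class MahalanobisScorer:
    """Frozen mean vector and regularised inverse covariance."""

    mu: np.ndarray
    sigma_inv: np.ndarray
    regularization: float = 0.0

    @classmethod
    def fit(
        cls, observations: np.ndarray, shrinkage: float = DEFAULT_SHRINKAGE
    ) -> "MahalanobisScorer":
        """Estimate mu and Sigma^-1 from rows of ``observations``.

        ``shrinkage`` scales the ridge lambda = shrinkage * trace(Sigma)/dim
        added to the diagonal; pass 0 to require a non-singular Sigma.
        """
        V = np.asarray(observations, dtype=float)
        if V.ndim != 2 or V.shape[0] < 2:
            raise ValueError("need >= 2 observation rows")
        mu = V.mean(axis=0)
        sigma = np.cov(V, rowvar=False)
        sigma = np.atleast_2d(sigma)
        dim = sigma.shape[0]
        lam = shrinkage * float(np.trace(sigma)) / dim if shrinkage > 0 else 0.0
        if shrinkage > 0 and lam == 0.0:
            # zero covariance (all observations identical): any positive ridge
            # gives the correct degenerate distances (all zero)
            lam = shrinkage
        sigma_reg = sigma + lam * np.eye(dim)
        try:
            sigma_inv = np.linalg.inv(sigma_reg)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "covariance matrix is singular; fit with a positive shrinkage "
                "to regularise it"
            ) from exc
        if lam == 0.0:
            # inv() can silently succeed on numerically singular input
            cond = np.linalg.cond(sigma_reg)
            if not np.isfinite(cond) or cond > 1 / np.finfo(float).eps:
                raise np.linalg.LinAlgError(
                    "covariance matrix is singular; fit with a positive "
                    "shrinkage to regularise it"
                )
        sigma_inv = 0.5 * (sigma_inv + sigma_inv.T)
        return cls(mu=mu, sigma_inv=sigma_inv, regularization=lam)


def mahalanobis(v: np.ndarray, scorer: MahalanobisScorer) -> float:
    """M = sqrt((v - mu)' Sigma^-1 (v - mu)) >= 0."""
    d = np.asarray(v, dtype=float).ravel() - scorer.mu
    if d.size != scorer.mu.size:
        raise ValueError("v dimension does not match scorer mean")
    m2 = float(d @ scorer.sigma_inv @ d)
    return float(np.sqrt(max(m2, 0.0)))


def feature_significance(
    X: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
    compound_space: bool = False,
) -> np.ndarray:
    """Mahalanobis significance M_i of every feature column.

    Default reading: observation i is feature i's column over compounds
    (dimension n); mu/Sigma are estimated across the feature population, so
    features whose interaction pattern deviates from the bulk score high.
    ``compound_space=True`` flips the roles (observations are compound rows,
    M_i scored per compound profile) - an alternative reading, not the
    package default.
    """
    from .profiles import FeatureMatrix  # local import to avoid cycle

    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    V = X if compound_space else X.T
    if V.shape[0] < 2:
        raise ValueError("need at least 2 features (or compounds) to score")
    scorer = MahalanobisScorer.fit(V, shrinkage=shrinkage)
    diff = V - scorer.mu
    m2 = np.einsum("ij,jk,ik->i", diff, scorer.sigma_inv, diff)
    return np.sqrt(np.maximum(m2, 0.0))


# ---------------------------------------------------------------------------
# kNN with Mahalanobis compound similarity
# ---------------------------------------------------------------------------

def knn_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray,
    k: int,
    scorer: MahalanobisScorer | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> np.ndarray:
    """Unweighted k-nearest-neighbour regression under Mahalanobis distance.

    The scorer is fitted on the training compounds (in the selected-feature
    subspace) when not supplied.  Ties at the k-th distance are broken by
    training row order (stable sort).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    n = y_train.size
    if X_train.shape[0] != n:
        raise ValueError("X_train rows must match y_train length")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if scorer is None:
        scorer = MahalanobisScorer.fit(X_train, shrinkage=shrinkage)
    d = cdist(X_query, X_train, metric="mahalanobis", VI=scorer.sigma_inv)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return y_train[order].mean(axis=1)
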