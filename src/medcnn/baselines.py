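"""Comparator estimators for high-dimensional mediation.

Two simplified surrogates of established approaches:

* ``sd_based_fit`` — spectral-decomposition style: pool all features,
  rotate them into uncorrelated principal components, and treat each
  retained component as a scalar mediator in a low-dimensional regression
  system.  NIE is the sum over components of (outcome coefficient) x
  (component-on-exposure slope).

* ``reg_based_fit`` — screening + penalization style: keep the features
  most marginally associated with the outcome (sure independence
  screening), select among them with a penalized regression (lasso, or a
  minimax-concave-penalty approximation via local linear approximation),
  then refit an unpenalized outcome model on the selected features.

Both are *faithful simplifications* built for simulation benchmarking, not
line-by-line reimplementations of the published methods.  Both operate on
the pooled feature matrix, so they are exactly invariant to the within-
network column order.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso

from .datatypes import BaselineResult, MediationDataset
from .fitting import DegenerateDesignError

logger = logging.getLogger(__name__)


def _pooled(dataset: MediationDataset) -> np.ndarray:
    X = np.concatenate([np.asarray(z, dtype=float) for z in dataset.Z], axis=1)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise DegenerateDesignError("all features are constant")
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def sd_based_fit(dataset: MediationDataset,
                 variance_threshold: float = 0.9) -> BaselineResult:
    """Principal-component mediation estimator.

    Retains the smallest number of components explaining at least
    ``variance_threshold`` of the pooled variance, regresses each component
    on A (slopes b_c) and Y on A plus all components (coefficients g_c),
    and reports NIE = sum_c g_c * b_c, NDE = the A coefficient.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    X = _pooled(dataset)
    n, p = X.shape
    max_c = min(n - 2, p)
    pca = PCA(n_components=min(max_c, p), svd_solver="covariance_eigh").fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_threshold) + 1)
    if n_comp >= n - 1:
        raise ValueError(
            f"{n_comp} components retained but only {n} samples available"
        )
    S = pca.transform(X)[:, :n_comp]
    A = np.asarray(dataset.A, dtype=float)
    Y = np.asarray(dataset.Y, dtype=float)
    ones = np.ones_like(A)
    # mediator slopes: each component on (1, A)
    Xm = np.column_stack([ones, A])
    b = np.linalg.lstsq(Xm, S, rcond=None)[0][1]  # (n_comp,)
    # outcome model: Y on (1, A, S)
    Xy = np.column_stack([ones, A, S])
    coef = np.linalg.lstsq(Xy, Y, rcond=None)[0]
    nde = float(coef[1])
    nie = float(np.dot(coef[2:], b))
    return BaselineResult(method="sd_based", nie=nie, nde=nde,
                          n_components_or_selected=n_comp)


def _mcp_weights(beta: np.ndarray, lam: float, gamma: float = 3.0) -> np.ndarray:
    """MCP penalty derivative / lam, for local linear approximation."""
    w = np.clip(1.0 - np.abs(beta) / (gamma * lam), 0.0, None)
    return w


def reg_based_fit(dataset: MediationDataset, screen_size: int | None = None,
                  penalty: str = "l1") -> BaselineResult:
    """Screening + penalized-selection mediation estimator.

    Features are residualized on A (Frisch-Waugh) so the exposure itself is
    never penalized; selected features enter an unpenalized joint outcome
    model, and their mediator slopes come from per-feature regressions on A.
    An empty selection is a valid null result (NIE = 0), not an error.
    """
    if penalty not in ("l1", "mcp"):
        raise ValueError("penalty must be 'l1' or 'mcp'")
    X = _pooled(dataset)
    n, p = X.shape
    if screen_size is None:
        screen_size = min(max(2, int(round(n / math.log(n)))), p)
    if screen_size > p:
        raise ValueError(f"screen_size {screen_size} exceeds {p} features")
    A = np.asarray(dataset.A, dtype=float)
    Y = np.asarray(dataset.Y, dtype=float)

    # sure independence screening on marginal outcome association
    Yc = Y - Y.mean()
    score = np.abs(X.T @ Yc)
    keep = np.argsort(-score, kind="stable")[:screen_size]
    Xs = X[:, keep]

    # residualize Y and features on (1, A) so A stays unpenalized
    D = np.column_stack([np.ones_like(A), A])
    proj = D @ np.linalg.lstsq(D, Xs, rcond=None)[0]
    Xr = Xs - proj
    Yr = Y - D @ np.linalg.lstsq(D, Y, rcond=None)[0]

    lam = 0.05 * np.max(np.abs(Xr.T @ Yr)) / n
    lasso = Lasso(alpha=lam, fit_intercept=False, max_iter=5000)
    lasso.fit(Xr, Yr)
    beta = lasso.coef_
    if penalty == "mcp":
        # local linear approximation: reweighted lasso steps
        for _ in range(3):
            w = _mcp_weights(beta, lam)
            scale = np.where(w > 0, w, np.inf)
            Xw = Xr / scale
            lasso.fit(np.nan_to_num(Xw, posinf=0.0), Yr)
            beta = np.where(np.isinf(scale), 0.0, lasso.coef_ / scale)
    selected = np.flatnonzero(np.abs(beta) > 1e-10)
    if selected.size == 0:
        logger.warning("penalized selection kept no features; NIE reported as 0")
        ols = np.linalg.lstsq(D, Y, rcond=None)[0]
        return BaselineResult(method="reg_based", nie=0.0, nde=float(ols[1]),
                              n_components_or_selected=0)

    # unpenalized refit: Y on (1, A, selected features)
    Xy = np.column_stack([np.ones_like(A), A, Xs[:, selected]])
    coef = np.linalg.lstsq(Xy, Y, rcond=None)[0]
    nde = float(coef[1])
    # mediator slopes of each selected feature on A
    slopes = np.linalg.lstsq(D, Xs[:, selected], rcond=None)[0][1]
    nie = float(np.dot(coef[2:], slopes))
    return BaselineResult(method="reg_based", nie=nie, nde=nde,
                          n_components_or_selected=int(selected.size))
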