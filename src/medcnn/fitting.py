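"""The alternating (EM-style) estimation algorithm.

Given data (A, Y, {Z_k}) the joint loss over the IMM h and the five
regression coefficients is

    L(h) = sum_i (y_i - alpha0 - alpha1 A_i - alpha2 h(Z_i))^2
                + (h(Z_i) - beta0 - beta1 A_i)^2 .

The fit alternates two steps until the coefficients stabilize:

1. *IMM step* — with coefficients fixed, the per-sample minimizer of L in
   h(Z_i) has the closed form

       r_i = [ (y_i - alpha0 - alpha1 A_i) alpha2 + beta0 + beta1 A_i ]
             / (alpha2^2 + 1)

   and the CNN is trained toward the targets r_i (warm-started from the
   previous iteration).

2. *Regression step* — the predicted IMM is standardized and the two OLS
   regressions (h on A; Y on A and h) are refit.  The product estimate
   alpha2*beta1 — the NIE — is invariant to any affine rescaling of the
   IMM, so standardizing costs nothing and stabilizes CNN training.

Convergence is declared when the relative change of all five coefficients
between consecutive iterations falls below a percentage threshold.
Reported effects come from the training split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split

from .datatypes import (
    FitResult,
    IterationRecord,
    MediationDataset,
    MediationParams,
)
from .effects import effect_summary
from .imm import IMMModel, predict_imm, train_imm
from .preprocessing import (
    DegenerateInputError,
    column_scaler,
    reorder_features,
    standardize,
)

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """The regression design matrix is rank deficient (e.g. constant A)."""


@dataclass
class FitConfig:
    """Knobs of the alternating fit.

    ``threshold`` is the convergence criterion in percent (0.01 means
    0.01%).  ``epochs_init`` applies to the first outer iteration, whose
    CNN starts from random weights; later iterations warm-start and run
    ``epochs`` each.  The defaults mirror a full-fidelity run; the fast
    profile used by the simulation harness overrides them.
    """

    threshold: float = 0.01
    max_iter: int = 50
    test_size: float = 0.3
    epochs_init: int = 100
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    reorder: bool = True
    pooling: str = "avg"
    clip_features: float | None = 5.0
    patience: int | None = None
    lr_drops: int = 1
    val_fraction: float = 0.15
    seed: int = 0
    contrast: tuple[float, float] = (1.0, 0.0)


def med_cnn_loss(h: np.ndarray, A: np.ndarray, Y: np.ndarray,
                 params: MediationParams) -> float:
    """The joint mediation loss L(h) evaluated exactly."""
    h, A, Y = (np.asarray(v, dtype=float) for v in (h, A, Y))
    if not (len(h) == len(A) == len(Y)):
        raise ValueError("h, A and Y must have equal lengths")
    res_y = Y - params.alpha0 - params.alpha1 * A - params.alpha2 * h
    res_m = h - params.beta0 - params.beta1 * A
    return float(np.sum(res_y**2) + np.sum(res_m**2))


def compute_targets(A: np.ndarray, Y: np.ndarray,
                    params: MediationParams) -> np.ndarray:
    """Closed-form per-sample minimizer of the joint loss in h.

    Well defined for any alpha2 (alpha2 = 0 reduces to the mediator-model
    prediction beta0 + beta1*A).
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    vals = (params.alpha0, params.alpha1, params.alpha2, params.beta0, params.beta1)
    if not (np.isfinite(A).all() and np.isfinite(Y).all()
            and np.all(np.isfinite(vals))):
        raise ValueError("non-finite inputs to compute_targets")
    a2 = params.alpha2
    return ((Y - params.alpha0 - params.alpha1 * A) * a2
            + params.beta0 + params.beta1 * A) / (a2**2 + 1.0)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and covariance; raises on rank deficiency."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("rank-deficient design matrix")
    res = sm.OLS(y, X).fit()
    return res.params, res.cov_params()


def update_params(h: np.ndarray, A: np.ndarray, Y: np.ndarray) -> MediationParams:
    """Refit the two mediation regressions for a given (standardized) IMM."""
    h, A, Y = (np.asarray(v, dtype=float) for v in (h, A, Y))
    if not (len(h) == len(A) == len(Y)):
        raise ValueError("h, A and Y must have equal lengths")
    Xm = np.column_stack([np.ones_like(A), A])
    beta, cov_m = _ols(h, Xm)
    Xy = np.column_stack([np.ones_like(A), A, h])
    alpha, cov_y = _ols(Y, Xy)
    return MediationParams(
        alpha0=float(alpha[0]), alpha1=float(alpha[1]), alpha2=float(alpha[2]),
        beta0=float(beta[0]), beta1=float(beta[1]),
        cov_outcome=np.asarray(cov_y), cov_mediator=np.asarray(cov_m),
    )


def convergence_pct(prev: MediationParams, curr: MediationParams,
                    eps: float = 1e-8) -> float:
    """Max relative change (in %) over the five coefficients.

    The denominator is |previous value| floored at ``eps`` so a coefficient
    passing through zero yields a large-but-finite value instead of a
    division error.
    """
    p = prev.as_array()
    c = curr.as_array()
    denom = np.maximum(np.abs(p), eps)
    return float(np.max(np.abs(c - p) / denom) * 100.0)


def _initial_imm(Z_cat: np.ndarray) -> np.ndarray:
    """Standardized first principal component of the pooled features."""
    pc = PCA(n_components=1, svd_solver="covariance_eigh").fit_transform(Z_cat)[:, 0]
    return standardize(pc)


def fit(dataset: MediationDataset, config: FitConfig | None = None) -> FitResult:
    """Run the full alternating estimation on one dataset.

    Splits 70/30 (stratified on A), reorders features by composite
    correlation on the training split, scales columns, initializes the IMM
    from the first principal component, then alternates CNN training and
    regression updates until all five coefficients change by less than
    ``config.threshold`` percent or ``config.max_iter`` iterations.
    """
    config = config or FitConfig()
    if config.max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    A = np.asarray(dataset.A)
    Y = np.asarray(dataset.Y, dtype=float)
    n = len(A)
    if n < 50:
        raise ValueError("need at least 50 samples")
    if len(np.unique(A)) < 2:
        raise DegenerateDesignError("exposure A must contain both classes")

    idx_train, idx_test = train_test_split(
        np.arange(n), test_size=config.test_size, stratify=A,
        random_state=config.seed % (2**32),
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    # per-network preprocessing, fit on the training split only
    Z_train, Z_test = [], []
    for Zk in dataset.Z:
        Zk = np.asarray(Zk, dtype=float)
        tr, te = Zk[idx_train], Zk[idx_test]
        if config.reorder:
            order = reorder_features(tr).order
            tr, te = tr[:, order], te[:, order]
        mu, sd = column_scaler(tr)
        tr, te = (tr - mu) / sd, (te - mu) / sd
        if config.clip_features is not None:
            # heavy-tailed columns (e.g. products of squared readouts)
            # otherwise dominate the standardized inputs
            c = config.clip_features
            tr, te = np.clip(tr, -c, c), np.clip(te, -c, c)
        Z_train.append(tr)
        Z_test.append(te)
    A_tr, Y_tr = A[idx_train], Y[idx_train]

    h0 = _initial_imm(np.concatenate(Z_train, axis=1))
    params = update_params(h0, A_tr, Y_tr)

    # optional inner validation split (early stopping guards the CNN
    # against memorizing noise in the targets)
    if config.patience is not None:
        n_tr = len(A_tr)
        perm = rng.permutation(n_tr)
        n_val = max(1, int(round(config.val_fraction * n_tr)))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
    else:
        fit_idx = np.arange(len(A_tr))
        val_idx = np.empty(0, dtype=int)

    model = IMMModel(dataset.network_sizes, seed=config.seed,
                     pooling=config.pooling)
    trace: list[IterationRecord] = []
    converged = False
    h_tr = h0
    for it in range(1, config.max_iter + 1):
        r = compute_targets(A_tr, Y_tr, params)
        epochs = config.epochs_init if it == 1 else config.epochs
        validation = None
        if config.patience is not None:
            validation = ([z[val_idx] for z in Z_train], r[val_idx])
        loss = train_imm(
            model, [z[fit_idx] for z in Z_train], r[fit_idx], epochs=epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size, rng=rng,
            validation=validation, patience=config.patience,
            lr_drops=config.lr_drops,
        )
        raw = predict_imm(model, Z_train)
        try:
            h_tr = standardize(raw)
        except DegenerateInputError as err:
            raise DegenerateInputError(
                f"CNN collapsed to a constant IMM at iteration {it}"
            ) from err
        new_params = update_params(h_tr, A_tr, Y_tr)
        change = convergence_pct(params, new_params)
        params = new_params
        trace.append(IterationRecord(params=params, max_pct_change=change,
                                     train_loss=loss))
        if change < config.threshold:
            converged = True
            break
    if not converged:
        logger.warning("not converged after %d iterations (last change %.4g%%)",
                       len(trace), trace[-1].max_pct_change)

    a, a_star = config.contrast
    raw_test = predict_imm(model, Z_test)
    mu_h, sd_h = raw.mean(), raw.std(ddof=1)
    h_te = (raw_test - mu_h) / sd_h if sd_h > 0 else raw_test * 0.0
    effects = effect_summary(params, a, a_star)
    try:
        params_test = update_params(h_te, A[idx_test], Y[idx_test])
        effects_test = effect_summary(params_test, a, a_star)
    except (DegenerateDesignError, ValueError):
        effects_test = None

    return FitResult(
        params=params, effects=effects, imm_train=h_tr, imm_test=h_te,
        trace=trace, converged=converged, iterations_used=len(trace),
        train_index=idx_train, test_index=idx_test, effects_test=effects_test,
    )
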