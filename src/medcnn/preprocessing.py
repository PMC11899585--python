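"""Correlation-based feature reordering and z-scoring.

Before entering a convolutional branch, the features of a network are
reordered by a composite correlation score so that strongly inter-correlated
features sit next to each other — 1D convolutions can then exploit local
structure.  The score of feature j is the geometric mean of the absolute
Pearson correlations of j with every feature in the network (the diagonal
rho_jj = 1 included):

    score_j = ( prod_l |rho_jl| ) ** (1 / J_k)

Columns are sorted by score, descending, ties broken by original position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateInputError(ValueError):
    """A column has zero variance, so correlations are undefined."""


@dataclass
class ReorderResult:
    order: np.ndarray          # 0-based permutation; column t of `reordered`
    composite_scores: np.ndarray  # score per *original* column
    reordered: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order)


def _check_columns(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("expected an n x J matrix")
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = Z.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(
            f"zero-variance column(s) {bad.tolist()}: correlation undefined"
        )
    return Z


def composite_correlation(Z_k: np.ndarray) -> np.ndarray:
    """Geometric-mean absolute-correlation score for each feature.

    Returns a vector in [0, 1]; a feature exactly uncorrelated with any
    other feature scores 0 (a zero factor annihilates the product).
    """
    Z_k = _check_columns(Z_k)
    J = Z_k.shape[1]
    if J == 1:
        return np.ones(1)
    C = np.clip(np.abs(np.corrcoef(Z_k, rowvar=False)), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        logs = np.log(C)
    # a -inf (rho = 0) makes the mean -inf and exp gives exactly 0
    return np.exp(np.mean(logs, axis=1))


def reorder_features(Z_k: np.ndarray) -> ReorderResult:
    """Sort columns by composite correlation score, descending, stably."""
    scores = composite_correlation(Z_k)
    order = np.argsort(-scores, kind="stable")
    Z_k = np.asarray(Z_k, dtype=float)
    return ReorderResult(order=order, composite_scores=scores,
                         reordered=Z_k[:, order])


def standardize(values: np.ndarray) -> np.ndarray:
    """z-score with the sample SD (n-1 denominator).

    Raises :class:`DegenerateInputError` on a constant vector — downstream
    this signals that the CNN has collapsed to a constant output.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("expected a vector of length >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance vector cannot be standardized")
    return (v - v.mean()) / sd


def column_scaler(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and SD (population convention, floor 1e-12) to scale
    features before the CNN; fit on the training split only."""
    Z = np.asarray(Z, dtype=float)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd
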