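"""Shared containers for datasets, model parameters and results.

Conventions used throughout the package:

* The exposure ``A`` is binary (0/1), the outcome ``Y`` continuous.
* Mediator features are grouped into K "networks" (e.g. OTUs sharing a
  phylum, genes in a pathway); ``Z`` is a list of K per-network
  (n x J_k) matrices.
* The mediator regression is  E[M | A] = beta0 + beta1*A  and the outcome
  regression is  E[Y | A, M] = alpha0 + alpha1*A + alpha2*M, where M is
  either the latent scalar mediator (simulation truth) or the CNN-derived
  integrative mediation metric (IMM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Scenario = Literal["null_1", "null_2", "null_3", "alternative"]
FeatureMap = Literal["linear", "nonlinear"]


@dataclass
class SimulationConfig:
    """Full description of one simulated study condition.

    ``scenario`` encodes which causal paths are switched off:
    ``null_1`` (alpha2 = beta1 = 0), ``null_2`` (alpha2 = 0),
    ``null_3`` (beta1 = 0) and ``alternative`` (both non-zero).
    """

    scenario: Scenario = "alternative"
    alpha0: float = 1.5
    alpha1: float = 2.0
    alpha2: float = 5.0
    beta0: float = 2.0
    beta1: float = 5.0
    sigma_M: float = 2.0
    sigma_Y: float = 2.0
    n: int = 1000
    network_sizes: tuple[int, ...] = (100, 150, 120, 130, 140)
    feature_map: FeatureMap = "linear"
    interactions: bool = False
    interaction_interval: int = 5
    interaction_strength: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_M <= 0 or self.sigma_Y <= 0:
            raise ValueError("sigma_M and sigma_Y must be positive")
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        self.network_sizes = tuple(int(j) for j in self.network_sizes)
        if len(self.network_sizes) == 0 or any(j < 1 for j in self.network_sizes):
            raise ValueError("network_sizes must be non-empty positive integers")
        if self.interaction_interval < 1:
            raise ValueError("interaction_interval must be >= 1")
        # scenario constraints on the structural coefficients
        if self.scenario == "null_1":
            self.alpha2 = 0.0
            self.beta1 = 0.0
        elif self.scenario == "null_2":
            self.alpha2 = 0.0
        elif self.scenario == "null_3":
            self.beta1 = 0.0
        elif self.scenario != "alternative":
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def true_nie(self) -> float:
        """True natural indirect effect alpha2*beta1 at contrast (1, 0)."""
        return self.alpha2 * self.beta1

    @property
    def true_nde(self) -> float:
        """True natural direct effect alpha1 at contrast (1, 0)."""
        return self.alpha1


@dataclass
class MediationDataset:
    """Aligned exposure / outcome / grouped-feature data for n samples."""

    A: np.ndarray
    Y: np.ndarray
    Z: list[np.ndarray]
    sample_ids: Sequence[str] | None = None
    network_labels: Sequence[str] | None = None
    feature_labels: list[Sequence[str]] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        self.Y = np.asarray(self.Y, dtype=float)
        self.Z = [np.asarray(z, dtype=float) for z in self.Z]
        n = len(self.A)
        if len(self.Y) != n or any(z.shape[0] != n for z in self.Z):
            raise ValueError("A, Y and all feature matrices must share the sample count")
        if not np.isin(self.A, [0, 1]).all():
            raise ValueError("exposure A must be binary 0/1")
        if np.isnan(self.Y).any() or any(np.isnan(z).any() for z in self.Z):
            raise ValueError("missing values are not supported")

    @property
    def n(self) -> int:
        return len(self.A)

    @property
    def network_sizes(self) -> tuple[int, ...]:
        return tuple(z.shape[1] for z in self.Z)


@dataclass
class GeneratedDataset(MediationDataset):
    """A simulated dataset that additionally carries the latent truth."""

    M_true: np.ndarray = field(default_factory=lambda: np.empty(0))
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.M_true = np.asarray(self.M_true, dtype=float)
        if len(self.M_true) != self.n:
            raise ValueError("M_true must have length n")


@dataclass
class MediationParams:
    """Coefficients of the two simplified mediation regressions.

    ``cov_outcome`` is the OLS covariance of (alpha0, alpha1, alpha2);
    ``cov_mediator`` that of (beta0, beta1).
    """

    alpha0: float
    alpha1: float
    alpha2: float
    beta0: float
    beta1: float
    cov_outcome: np.ndarray | None = None
    cov_mediator: np.ndarray | None = None

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha0, self.alpha1, self.alpha2, self.beta0, self.beta1]
        )

    names = ("alpha0", "alpha1", "alpha2", "beta0", "beta1")


@dataclass
class FullModelParams:
    """Coefficients of the full mediation model with confounder X and an
    exposure-mediator interaction (outcome: theta0..theta4; mediator:
    beta0..beta2). Held only so the general effect formulas are computable;
    the package never fits this model."""

    theta0: float = 0.0
    theta1: float = 0.0
    theta2: float = 0.0
    theta3: float = 0.0
    theta4: float = 0.0
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0


@dataclass
class EffectEstimates:
    """Natural effect estimates at the exposure contrast ``contrast``."""

    nie: float
    nde: float
    te: float
    se_nie: float | None = None
    se_nde: float | None = None
    proportion_mediated: float | None = None
    contrast: tuple[float, float] = (1.0, 0.0)


@dataclass
class IterationRecord:
    """One outer-loop iteration: parameters, relative change, CNN loss."""

    params: MediationParams
    max_pct_change: float
    train_loss: float


@dataclass
class FitResult:
    """Everything produced by one Med-CNN fit."""

    params: MediationParams
    effects: EffectEstimates
    imm_train: np.ndarray
    imm_test: np.ndarray
    trace: list[IterationRecord]
    converged: bool
    iterations_used: int
    train_index: np.ndarray
    test_index: np.ndarray
    effects_test: EffectEstimates | None = None


@dataclass
class BaselineResult:
    """NIE/NDE from one of the comparator estimators."""

    method: Literal["sd_based", "reg_based"]
    nie: float
    nde: float
    n_components_or_selected: int
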