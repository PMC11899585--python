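"""Synthetic data generator for grouped-mediator mediation studies.

The generator emulates a study in which a binary exposure A shifts a latent
scalar mediator M, M shifts a continuous outcome Y, and M is observed only
through K networks of noisy features (each feature an affine or smooth
non-linear function of M).  Structural model:

    A_i ~ Bernoulli(0.5)
    M_i = beta0 + beta1 * A_i + eps_M,      eps_M ~ N(0, sigma_M)
    Y_i = alpha0 + alpha1 * A_i + alpha2 * M_i + eps_Y,  eps_Y ~ N(0, sigma_Y)
    Z_kji = a_kj + b_kj * f_kj(M_i) + e_kji,  e ~ N(0, 1)

with f = identity in ``linear`` mode and f cycled through a fixed dictionary
of smooth transforms in ``nonlinear`` mode.  Optionally every ``interval``-th
feature forms interacting pairs whose product is added into the following
column (see :func:`inject_interactions`).

All randomness flows through an explicit :class:`numpy.random.Generator`;
replicate r of a study seeded with s uses the independent child stream
``SeedSequence([s, r])`` so any replicate is reproducible in isolation.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import GeneratedDataset, Scenario, SimulationConfig

logger = logging.getLogger(__name__)

#: smooth transforms cycled across features in ``nonlinear`` mode
NONLINEAR_TRANSFORMS = (
    ("square", lambda x: x**2),
    ("sin", np.sin),
    ("abs", np.abs),
    ("exp5", lambda x: np.exp(x / 5.0)),
)

_DEFAULTS = dict(
    alpha0=1.5, alpha1=2.0, alpha2=5.0, beta0=2.0, beta1=5.0,
    sigma_M=2.0, sigma_Y=2.0, n=1000,
    network_sizes=(100, 150, 120, 130, 140),
)

_BETA1_GRID = (-5.0, -3.0, -1.0, 1.0, 3.0, 5.0)


def gen_exposure(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n independent Bernoulli(0.5) exposure indicators."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.binomial(1, 0.5, size=n)


def gen_mediator(
    A: np.ndarray,
    beta0: float,
    beta1: float,
    sigma_M: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent mediator M = beta0 + beta1*A + N(0, sigma_M)."""
    if sigma_M <= 0:
        raise ValueError("sigma_M must be positive")
    A = np.asarray(A)
    return beta0 + beta1 * A + rng.normal(0.0, sigma_M, size=len(A))


def gen_outcome(
    A: np.ndarray,
    M: np.ndarray,
    alpha0: float,
    alpha1: float,
    alpha2: float,
    sigma_Y: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Outcome Y = alpha0 + alpha1*A + alpha2*M + N(0, sigma_Y)."""
    if sigma_Y <= 0:
        raise ValueError("sigma_Y must be positive")
    A = np.asarray(A)
    M = np.asarray(M)
    if len(A) != len(M):
        raise ValueError(f"length mismatch: len(A)={len(A)}, len(M)={len(M)}")
    return alpha0 + alpha1 * A + alpha2 * M + rng.normal(0.0, sigma_Y, size=len(A))


def gen_network_features(
    M_true: np.ndarray,
    network_sizes: tuple[int, ...] | list[int],
    feature_map: str,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> list[np.ndarray]:
    """Generate K feature matrices, each column a noisy (non-)linear readout
    of the latent mediator.

    Loadings b_kj ~ Uniform(0.5, 1.5) with a random sign, intercepts
    a_kj ~ Uniform(-1, 1), additive feature noise N(0, noise_sd).  In
    ``nonlinear`` mode the transform applied to M cycles through
    :data:`NONLINEAR_TRANSFORMS` by within-network feature index.
    """
    network_sizes = tuple(int(j) for j in network_sizes)
    if len(network_sizes) == 0 or any(j < 1 for j in network_sizes):
        raise ValueError("network_sizes must be non-empty positive integers")
    if feature_map not in ("linear", "nonlinear"):
        raise ValueError(f"unknown feature_map {feature_map!r}")
    M_true = np.asarray(M_true, dtype=float)
    n = len(M_true)
    out: list[np.ndarray] = []
    for J in network_sizes:
        a = rng.uniform(-1.0, 1.0, size=J)
        b = rng.uniform(0.5, 1.5, size=J) * rng.choice([-1.0, 1.0], size=J)
        Z = np.empty((n, J))
        for j in range(J):
            if feature_map == "linear":
                g = M_true
            else:
                _, f = NONLINEAR_TRANSFORMS[j % len(NONLINEAR_TRANSFORMS)]
                g = f(M_true)
            Z[:, j] = a[j] + b[j] * g
        if noise_sd > 0:
            Z += rng.normal(0.0, noise_sd, size=(n, J))
        out.append(Z)
    return out


def inject_interactions(
    Z_k: np.ndarray, interval: int = 5, strength: float = 2.0
) -> np.ndarray:
    """Add pairwise feature interactions into a copy of ``Z_k``.

    Columns at 1-based positions interval, 2*interval, 3*interval, ... are
    taken as interacting pairs ((interval, 2*interval), (3*interval,
    4*interval), ...); for each pair the column immediately after its second
    member is incremented by ``strength`` times the elementwise product of
    the pair.  If the matrix is too narrow for even one modification it is
    returned unchanged with a warning.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    Z_k = np.asarray(Z_k, dtype=float)
    J = Z_k.shape[1]
    if J < 2 * interval + 1:
        logger.warning(
            "matrix with %d columns too narrow for interaction interval %d; "
            "returned unchanged",
            J,
            interval,
        )
        return Z_k.copy()
    out = Z_k.copy()
    m = 1
    while True:
        c1 = (2 * m - 1) * interval  # 1-based
        c2 = 2 * m * interval
        target = c2 + 1
        if target > J:
            break
        out[:, target - 1] += strength * Z_k[:, c1 - 1] * Z_k[:, c2 - 1]
        m += 1
    return out


def make_scenario(
    scenario_id: Scenario,
    beta1_override: float | None = None,
    **overrides,
) -> SimulationConfig:
    """Build the standard study configuration for one scenario.

    ``beta1_override`` picks the exposure-to-mediator effect size for the
    alternative scenario and must lie on the grid {-5, -3, -1, 1, 3, 5}.
    Any other field (n, feature_map, interactions, seed, ...) may be set via
    keyword overrides.
    """
    if scenario_id not in ("null_1", "null_2", "null_3", "alternative"):
        raise ValueError(f"unknown scenario {scenario_id!r}")
    kw = dict(_DEFAULTS)
    kw.update(overrides)
    if beta1_override is not None:
        if scenario_id != "alternative":
            raise ValueError("beta1_override only applies to the alternative scenario")
        if float(beta1_override) not in _BETA1_GRID:
            raise ValueError(f"beta1_override must be one of {_BETA1_GRID}")
        kw["beta1"] = float(beta1_override)
    return SimulationConfig(scenario=scenario_id, **kw)


def generate_dataset(config: SimulationConfig) -> GeneratedDataset:
    """Draw one full dataset (A, M, Y, Z) from a study configuration."""
    rng = np.random.default_rng(config.seed)
    A = gen_exposure(config.n, rng)
    M = gen_mediator(A, config.beta0, config.beta1, config.sigma_M, rng)
    Y = gen_outcome(A, M, config.alpha0, config.alpha1, config.alpha2,
                    config.sigma_Y, rng)
    Z = gen_network_features(M, config.network_sizes, config.feature_map, rng)
    if config.interactions:
        Z = [
            inject_interactions(z, config.interaction_interval,
                                config.interaction_strength)
            for z in Z
        ]
    return GeneratedDataset(A=A, Y=Y, Z=Z, M_true=M, config=config)


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Independent, individually reproducible seed stream for one replicate."""
    return np.random.SeedSequence([int(master_seed), int(replicate)])


def replicate_config(
    config: SimulationConfig, master_seed: int, replicate: int
) -> SimulationConfig:
    """Copy of ``config`` whose seed is the replicate's own substream."""
    child = replicate_seed(master_seed, replicate).generate_state(1)[0] % (2**31)
    kw = {k: getattr(config, k) for k in (
        "scenario", "alpha0", "alpha1", "alpha2", "beta0", "beta1",
        "sigma_M", "sigma_Y", "n", "network_sizes", "feature_map",
        "interactions", "interaction_interval", "interaction_strength",
    )}
    return SimulationConfig(seed=int(child), **kw)
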