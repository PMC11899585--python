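"""Replicate runner: Monte-Carlo bias / SD benchmarking of the estimators.

For each replicate a fresh dataset is generated, every requested method is
fit, and the NIE / NDE estimates are pooled into bias (mean minus truth),
sample SD, and the Monte-Carlo standard error of the bias (SD / sqrt(reps)).
Replicates use disjoint, individually reproducible seed streams derived
from a single master seed, so reports are fully reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .baselines import reg_based_fit, sd_based_fit
from .datatypes import SimulationConfig
from .fitting import FitConfig, fit
from .synthetic import generate_dataset, replicate_config, replicate_seed

logger = logging.getLogger(__name__)

METHODS = ("med_cnn", "sd_based", "reg_based")

#: reduced-cost fit settings used for replicate sweeps on a single CPU;
#: a full-fidelity run would instead use FitConfig() defaults
FAST_FIT = dict(epochs_init=60, epochs=10, learning_rate=5e-3,
                batch_size=128, max_iter=3, patience=5)


@dataclass
class EffectSummary:
    estimates: np.ndarray
    true_value: float
    bias: float
    sd: float
    se: float


@dataclass
class SimulationReport:
    config: SimulationConfig
    reps: int
    threshold: float
    methods: tuple[str, ...]
    nie: dict[str, EffectSummary]
    nde: dict[str, EffectSummary]
    n_failures: int = 0
    seconds_per_replicate: float = float("nan")
    extra: dict = field(default_factory=dict)


def bias_sd(estimates: np.ndarray, true_value: float
            ) -> tuple[float, float, float]:
    """(mean - truth, sample SD, SD/sqrt(m)) over replicate estimates."""
    est = np.asarray(estimates, dtype=float)
    if len(est) < 2:
        raise ValueError("need at least 2 estimates")
    m = len(est)
    sd = float(est.std(ddof=1))
    return float(est.mean() - true_value), sd, sd / np.sqrt(m)


def run_simulation(
    config: SimulationConfig,
    reps: int,
    methods: tuple[str, ...] = ("med_cnn",),
    master_seed: int = 0,
    fit_options: dict | None = None,
) -> SimulationReport:
    """Monte-Carlo evaluation of one study condition.

    ``fit_options`` overrides :class:`FitConfig` fields for the Med-CNN
    fits (the harness default is the fast single-CPU profile
    :data:`FAST_FIT`).  A replicate in which a method fails is recorded and
    skipped, never silently dropped.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    opts = dict(FAST_FIT)
    opts.update(fit_options or {})
    nie_est: dict[str, list[float]] = {m: [] for m in methods}
    nde_est: dict[str, list[float]] = {m: [] for m in methods}
    extra: dict = {"converged": [], "iterations": []}
    failures = 0
    t0 = time.perf_counter()
    for r in range(reps):
        data = generate_dataset(replicate_config(config, master_seed, r))
        fit_seed = int(
            replicate_seed(master_seed, r).generate_state(2)[1] % (2**31)
        )
        for method in methods:
            try:
                if method == "med_cnn":
                    res = fit(data, FitConfig(seed=fit_seed, **opts))
                    nie_est[method].append(res.effects.nie)
                    nde_est[method].append(res.effects.nde)
                    extra["converged"].append(res.converged)
                    extra["iterations"].append(res.iterations_used)
                elif method == "sd_based":
                    b = sd_based_fit(data)
                    nie_est[method].append(b.nie)
                    nde_est[method].append(b.nde)
                else:
                    b = reg_based_fit(data)
                    nie_est[method].append(b.nie)
                    nde_est[method].append(b.nde)
            except Exception:  # noqa: BLE001 - replicate failures are data
                failures += 1
                logger.exception("replicate %d failed for method %s", r, method)
    per_rep = (time.perf_counter() - t0) / reps
    if reps < 3:
        logger.warning("SD from %d replicates; Monte-Carlo SE unreliable", reps)

    def summarize(est: dict[str, list[float]], truth: float
                  ) -> dict[str, EffectSummary]:
        out = {}
        for m, vals in est.items():
            arr = np.asarray(vals)
            bias, sd, se = bias_sd(arr, truth)
            out[m] = EffectSummary(estimates=arr, true_value=truth,
                                   bias=bias, sd=sd, se=se)
        return out

    threshold = opts.get("threshold", FitConfig.threshold)
    return SimulationReport(
        config=config, reps=reps, threshold=threshold, methods=tuple(methods),
        nie=summarize(nie_est, config.true_nie),
        nde=summarize(nde_est, config.true_nde),
        n_failures=failures, seconds_per_replicate=per_rep, extra=extra,
    )


def scenario_sweep(
    kind: str,
    values,
    base_config: SimulationConfig | None = None,
    reps: int = 10,
    methods: tuple[str, ...] = ("med_cnn",),
    seed: int = 0,
    fit_options: dict | None = None,
) -> list[SimulationReport]:
    """One report per sweep value with disjoint seed streams.

    ``kind``: ``beta1_sweep`` varies the exposure-to-mediator effect,
    ``n_sweep`` the sample size, ``threshold_sweep`` the convergence
    criterion (in percent).
    """
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    if kind not in ("beta1_sweep", "threshold_sweep", "n_sweep"):
        raise ValueError(f"unknown sweep kind {kind!r}")
    from .synthetic import make_scenario

    base = base_config or make_scenario("alternative")
    reports = []
    for i, v in enumerate(values):
        cfg = base
        opts = dict(fit_options or {})
        if kind == "beta1_sweep":
            cfg = make_scenario("alternative", beta1_override=float(v),
                                n=base.n, network_sizes=base.network_sizes,
                                feature_map=base.feature_map,
                                interactions=base.interactions)
        elif kind == "n_sweep":
            v = int(v)
            if v < 50:
                raise ValueError("sample size sweep values must be >= 50")
            cfg = make_scenario(base.scenario, n=v,
                                network_sizes=base.network_sizes,
                                feature_map=base.feature_map,
                                interactions=base.interactions,
                                beta1=base.beta1)
        else:
            v = float(v)
            if v <= 0:
                raise ValueError("threshold sweep values must be positive")
            opts["threshold"] = v
        sweep_seed = int(np.random.SeedSequence([seed, 1000 + i])
                         .generate_state(1)[0] % (2**31))
        reports.append(run_simulation(cfg, reps=reps, methods=methods,
                                      master_seed=sweep_seed,
                                      fit_options=opts))
    return reports
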