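"""Natural direct / indirect effect formulas and delta-method SEs.

For a binary exposure contrast (a, a*) under the linear outcome and
mediator regressions, the closed-form effects are

    simplified model (no confounder, no exposure-mediator interaction):
        NIE = alpha2 * beta1 * (a - a*)
        NDE = alpha1 * (a - a*)

    full model (confounder X, interaction theta3):
        NIE = (theta2*beta1 + theta3*beta1*a) * (a - a*)
        NDE = (theta1 + theta3*(beta0 + beta1*a* + beta2*x)) * (a - a*)

and TE = NIE + NDE always.  Standard errors use the first-order delta
method with the two regressions treated as independent (Sobel form), so
the alpha2-beta1 cross-covariance is zero.
"""

from __future__ import annotations

import math

import numpy as np

from .datatypes import EffectEstimates, FullModelParams, MediationParams


def nie_simplified(params: MediationParams, a: float = 1.0, a_star: float = 0.0) -> float:
    """Natural indirect effect alpha2*beta1*(a - a*)."""
    return params.alpha2 * params.beta1 * (a - a_star)


def nde_simplified(params: MediationParams, a: float = 1.0, a_star: float = 0.0) -> float:
    """Natural direct effect alpha1*(a - a*)."""
    return params.alpha1 * (a - a_star)


def nie_full(full: FullModelParams, a: float = 1.0, a_star: float = 0.0) -> float:
    """(theta2*beta1 + theta3*beta1*a)*(a - a*)."""
    return (full.theta2 * full.beta1 + full.theta3 * full.beta1 * a) * (a - a_star)


def nde_full(full: FullModelParams, a: float = 1.0, a_star: float = 0.0,
             x: float = 0.0) -> float:
    """(theta1 + theta3*(beta0 + beta1*a* + beta2*x))*(a - a*)."""
    return (
        full.theta1 + full.theta3 * (full.beta0 + full.beta1 * a_star + full.beta2 * x)
    ) * (a - a_star)


def delta_se(params: MediationParams, a: float = 1.0, a_star: float = 0.0
             ) -> tuple[float, float]:
    """First-order (Sobel) SEs of the simplified NIE and NDE.

    se_NIE = sqrt(beta1^2 Var(alpha2) + alpha2^2 Var(beta1)) |a - a*|
    se_NDE = sqrt(Var(alpha1)) |a - a*|
    """
    if params.cov_outcome is None or params.cov_mediator is None:
        raise ValueError("covariance blocks are required for delta-method SEs")
    var_a2 = float(np.asarray(params.cov_outcome)[2, 2])
    var_a1 = float(np.asarray(params.cov_outcome)[1, 1])
    var_b1 = float(np.asarray(params.cov_mediator)[1, 1])
    scale = abs(a - a_star)
    se_nie = math.sqrt(params.beta1**2 * var_a2 + params.alpha2**2 * var_b1) * scale
    se_nde = math.sqrt(var_a1) * scale
    return se_nie, se_nde


def effect_summary(params: MediationParams, a: float = 1.0, a_star: float = 0.0
                   ) -> EffectEstimates:
    """Assemble NIE, NDE, TE, SEs and proportion mediated at one contrast.

    ``proportion_mediated`` is NIE/TE (signed); it is ``None`` when TE is
    exactly zero rather than a division error.
    """
    nie = nie_simplified(params, a, a_star)
    nde = nde_simplified(params, a, a_star)
    te = nie + nde
    try:
        se_nie, se_nde = delta_se(params, a, a_star)
    except ValueError:
        se_nie = se_nde = None
    prop = nie / te if te != 0 else None
    return EffectEstimates(
        nie=nie, nde=nde, te=te, se_nie=se_nie, se_nde=se_nde,
        proportion_mediated=prop, contrast=(a, a_star),
    )
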