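"""Five-stage, single-sex, post-breeding-pulse projection model.

Stages are the fledgling cohort, three subadult years, and adults
(breeders); floaters are deliberately absent — the model describes the
*potential* growth rate lambda_p of a hypothetical population in which
every adult female holds a territory and breeds at the average rate.

With a post-breeding-pulse census, fertility carries the parent's
survival: in the baseline variant (first fledglings when the parent is
60 months post-fledging) the only fertility term is S_b * f on the adult
class, giving the characteristic equation

    lambda^4 (lambda - S_b) = S_b f S_j S_s^3.

In the early-breeding variant, third-year subadults also reproduce
(first fledglings at parent age 48 months), adding fertility S_s * f on
the subadult-3 class; the characteristic equation reduces to

    lambda^3 (lambda - S_b) = S_j S_s^3 f.

lambda is the unique real root greater than S_b, found by bracketed
root-finding and cross-checkable against the dominant eigenvalue of the
matrix.  Uncertainty in lambda is propagated from the vital-rate SEs by
the delta method with sensitivities from implicit differentiation of the
characteristic polynomial, treating the rates as independent (they come
from separate fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .rates import VitalRates

__all__ = [
    "StageModel",
    "LambdaResult",
    "VARIANTS",
    "build_stage_model",
    "solve_lambda",
    "lambda_se",
    "dominant_eigenvalue",
    "sensitivities",
]

VARIANTS = ("baseline_60mo", "early_breeding_48mo")

STAGE_NAMES = ("fledgling", "subadult1", "subadult2", "subadult3", "adult")

_TOL = 1e-12


@dataclass(frozen=True)
class StageModel:
    matrix: np.ndarray
    rates: VitalRates
    variant: str

    def characteristic(self, lam: float) -> float:
        """g(lambda); the growth rate is the root > S_b."""
        r = self.rates
        rec = r.s_juv * r.s_sub**3 * r.f
        if self.variant == "baseline_60mo":
            return lam**4 * (lam - r.s_breed) - r.s_breed * rec
        return lam**3 * (lam - r.s_breed) - rec


def build_stage_model(
    rates: VitalRates, variant: str = "baseline_60mo"
) -> StageModel:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose {VARIANTS}")
    A = np.zeros((5, 5))
    A[1, 0] = rates.s_juv
    A[2, 1] = rates.s_sub
    A[3, 2] = rates.s_sub
    A[4, 3] = rates.s_sub
    A[4, 4] = rates.s_breed
    A[0, 4] = rates.s_breed * rates.f
    if variant == "early_breeding_48mo":
        A[0, 3] = rates.s_sub * rates.f
    return StageModel(matrix=A, rates=rates, variant=variant)


@dataclass(frozen=True)
class LambdaResult:
    lam: float
    SE: float
    sensitivities: dict[str, float]
    scenario: str
    variant: str

    def elasticities(self, rates: VitalRates) -> dict[str, float]:
        vals = {"s_juv": rates.s_juv, "s_sub": rates.s_sub,
                "s_breed": rates.s_breed, "f": rates.f}
        return {
            k: self.sensitivities[k] * vals[k] / self.lam
            for k in self.sensitivities
        }


def solve_lambda(model: StageModel) -> float:
    """Largest real root of the characteristic equation.

    For f = 0 the matrix is lower triangular and the dominant eigenvalue
    is S_b exactly; otherwise g(S_b) < 0 < g(hi) brackets the root.
    """
    r = model.rates
    if r.f == 0.0:
        return r.s_breed
    lo = r.s_breed
    hi = max(2.0, r.s_breed + r.f + 1.0)
    lam = optimize.brentq(
        model.characteristic, lo, hi, xtol=_TOL, rtol=8.9e-16
    )
    return float(lam)


def dominant_eigenvalue(model: StageModel) -> float:
    """Spectral radius of the projection matrix (cross-check oracle)."""
    ev = np.linalg.eigvals(model.matrix)
    return float(np.max(np.abs(ev)))


def sensitivities(model: StageModel, lam: float | None = None) -> dict[str, float]:
    """d lambda / d theta for theta in {S_j, S_s, S_b, f}.

    Implicit differentiation of g(lambda, theta) = 0:
    d lambda / d theta = -g_theta / g_lambda.
    """
    r = model.rates
    if lam is None:
        lam = solve_lambda(model)
    sj, ss, sb, f = r.s_juv, r.s_sub, r.s_breed, r.f
    if model.variant == "baseline_60mo":
        g_lam = 5 * lam**4 - 4 * sb * lam**3
        g = {
            "s_juv": -sb * f * ss**3,
            "s_sub": -3 * sb * f * sj * ss**2,
            "s_breed": -(lam**4) - f * sj * ss**3,
            "f": -sb * sj * ss**3,
        }
    else:
        g_lam = 4 * lam**3 - 3 * sb * lam**2
        g = {
            "s_juv": -f * ss**3,
            "s_sub": -3 * f * sj * ss**2,
            "s_breed": -(lam**3),
            "f": -sj * ss**3,
        }
    return {k: -v / g_lam for k, v in g.items()}


def lambda_se(model: StageModel) -> LambdaResult:
    """lambda with its delta-method SE under independent vital rates.

    var(lambda) = sum_theta (d lambda / d theta)^2 var(theta) over
    S_j, S_s, S_b and f; floater survival does not enter the model.
    """
    r = model.rates
    lam = solve_lambda(model)
    sens = sensitivities(model, lam)
    ses = {"s_juv": r.se_juv, "s_sub": r.se_sub,
           "s_breed": r.se_breed, "f": r.se_f}
    var = sum(sens[k] ** 2 * ses[k] ** 2 for k in sens)
    return LambdaResult(
        lam=lam,
        SE=float(np.sqrt(var)),
        sensitivities=sens,
        scenario=r.scenario,
        variant=model.variant,
    )
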