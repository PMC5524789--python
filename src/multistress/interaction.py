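"""From fitted log-odds to an antagonism/synergism call.

Pipeline: convert coefficients to survival probabilities at a reference
conspecific density, express each treatment's survival relative to the
control, multiply the single-stressor relatives into a null expectation for
the combined-stressor arm, and compare the combined arm's observed relative
survival (± one bootstrap SE by default) against that null.

Direction convention: survival ABOVE the null means the joint effect
(mortality) is weaker than expected -> antagonistic; below -> synergistic;
null inside the interval -> indistinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, ModelError
from .glm import FitResult

DEFAULT_REFERENCE_DENSITY = 3.0
DEFAULT_BOOTSTRAP_DRAWS = 10_000


def inverse_logit(x: float | np.ndarray) -> float | np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    out = expit(x)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


@dataclass(frozen=True)
class SurvivalPrediction:
    treatment: str
    density: float
    probability: float


@dataclass(frozen=True)
class RelativeSurvival:
    """A treatment's survival as a fraction of the control's."""

    treatment: str
    estimate: float
    se: float
    reference_density: float
    reference_treatment: str = "control"


@dataclass(frozen=True)
class NullExpectation:
    method: str  # "multiplicative" | "additive"
    value: float
    components: tuple[RelativeSurvival, ...]
    se: float | None = None


@dataclass(frozen=True)
class InteractionCall:
    call: str  # "antagonistic" | "synergistic" | "indistinguishable"
    observed: RelativeSurvival
    null: NullExpectation
    interval: tuple[float, float]
    se_multiplier: float = 1.0


def _linear_predictor(
    fit: FitResult, treatment: str, density: float, panel: str | None = None
) -> float:
    coefs = fit.coefficients
    eta = coefs["intercept"]
    if treatment != fit.reference_treatment:
        key = f"treatment[{treatment}]"
        if key not in coefs:
            raise ModelError(f"unknown treatment {treatment!r} in fit")
        eta += coefs[key]
    if "density" in coefs:
        eta += coefs["density"] * density
    if panel is not None and panel != fit.reference_panel:
        key = f"panel[{panel}]"
        if key not in coefs:
            raise ModelError(f"unknown panel {panel!r} in fit")
        eta += coefs[key]
    return eta


def predict_survival(
    fit: FitResult, treatment: str, density: float, panel: str | None = None
) -> SurvivalPrediction:
    """Survival probability for one treatment at a given conspecific density.

    Predictions are at the reference panel unless *panel* is given.
    """
    eta = _linear_predictor(fit, treatment, density, panel)
    return SurvivalPrediction(treatment, density, inverse_logit(eta))


def density_curves(
    fit: FitResult,
    densities: np.ndarray | list[float],
    treatments: list[str] | None = None,
) -> pd.DataFrame:
    """Survival-vs-density grid per treatment (delta-method SEs included)."""
    treatments = treatments or _fit_treatments(fit)
    rows = []
    names = list(fit.vcov.columns)
    V = fit.vcov.to_numpy()
    for t in treatments:
        for d in densities:
            eta = _linear_predictor(fit, t, float(d))
            grad = np.zeros(len(names))
            for i, name in enumerate(names):
                if name == "intercept":
                    grad[i] = 1.0
                elif name == f"treatment[{t}]":
                    grad[i] = 1.0
                elif name == "density":
                    grad[i] = float(d)
            p = inverse_logit(eta)
            se_eta = math.sqrt(max(0.0, grad @ V @ grad))
            rows.append(
                {"treatment": t, "density": float(d), "probability": p,
                 "se": p * (1 - p) * se_eta}
            )
    return pd.DataFrame(rows)


def _fit_treatments(fit: FitResult) -> list[str]:
    labels = [fit.reference_treatment]
    for name in fit.coefficients:
        if name.startswith("treatment[") and ":" not in name:
            labels.append(name[len("treatment["):-1])
    return labels


def _check_converged(fit: FitResult) -> None:
    if not fit.converged:
        raise ModelError("survival fit did not converge; cannot propagate uncertainty")


def relative_survival(
    fit: FitResult,
    treatment: str,
    reference_density: float = DEFAULT_REFERENCE_DENSITY,
    n_boot: int = DEFAULT_BOOTSTRAP_DRAWS,
    seed: int = 0,
) -> RelativeSurvival:
    """Survival relative to control with a parametric-bootstrap SE.

    ``n_boot`` coefficient vectors are drawn from MVN(estimates, vcov); the
    ratio of inverse-logit predictions (treatment vs. control, shared draws)
    is recomputed for each, and its sample standard deviation is the SE.
    For the control itself the shared draws make the ratio identically 1.
    """
    _check_converged(fit)
    point = _ratio_at(fit.coefficients, fit, treatment, reference_density)
    if treatment == fit.reference_treatment:
        return RelativeSurvival(treatment, 1.0, 0.0, reference_density,
                                fit.reference_treatment)

    draws = _coefficient_draws(fit, n_boot, seed)
    ratios = _ratio_at_draws(draws, fit, treatment, reference_density)
    return RelativeSurvival(
        treatment=treatment,
        estimate=point,
        se=float(np.std(ratios, ddof=1)),
        reference_density=reference_density,
        reference_treatment=fit.reference_treatment,
    )


def _coefficient_draws(fit: FitResult, n_boot: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    names = list(fit.vcov.columns)
    mean = np.array([fit.coefficients[c] for c in names])
    draws = rng.multivariate_normal(mean, fit.vcov.to_numpy(), size=n_boot,
                                    method="svd")
    return pd.DataFrame(draws, columns=names)


def _ratio_at(coefs: dict[str, float], fit: FitResult, treatment: str,
              density: float) -> float:
    eta0 = coefs["intercept"] + coefs.get("density", 0.0) * density
    eta1 = eta0
    if treatment != fit.reference_treatment:
        eta1 = eta0 + coefs[f"treatment[{treatment}]"]
    p0 = inverse_logit(eta0)
    if p0 <= 0:
        raise ModelError("control survival prediction is zero; ratio undefined")
    return inverse_logit(eta1) / p0


def _ratio_at_draws(draws: pd.DataFrame, fit: FitResult, treatment: str,
                    density: float) -> np.ndarray:
    eta0 = draws["intercept"].to_numpy()
    if "density" in draws:
        eta0 = eta0 + draws["density"].to_numpy() * density
    eta1 = eta0 + draws[f"treatment[{treatment}]"].to_numpy()
    return expit(eta1) / expit(eta0)


def _validate_components(components: list[RelativeSurvival]) -> float:
    if len(components) < 2:
        raise ConfigurationError("null expectation needs >= 2 stressor components")
    densities = {c.reference_density for c in components}
    if len(densities) != 1:
        raise ConfigurationError(
            f"components computed at mismatched reference densities: {sorted(densities)}"
        )
    for c in components:
        if c.treatment == c.reference_treatment:
            raise ConfigurationError("the control arm is not a stressor component")
    return densities.pop()


def multiplicative_null(
    components: list[RelativeSurvival],
    fit: FitResult | None = None,
    n_boot: int = DEFAULT_BOOTSTRAP_DRAWS,
    seed: int = 0,
) -> NullExpectation:
    """Product of single-stressor relative survivals.

    If *fit* is supplied, a shared-draw bootstrap SE of the product is also
    reported (non-default; the baseline comparison uses the point null).
    """
    density = _validate_components(components)
    value = float(np.prod([c.estimate for c in components]))
    se = None
    if fit is not None:
        _check_converged(fit)
        draws = _coefficient_draws(fit, n_boot, seed)
        prod = np.ones(len(draws))
        for c in components:
            prod *= _ratio_at_draws(draws, fit, c.treatment, density)
        se = float(np.std(prod, ddof=1))
    return NullExpectation("multiplicative", value, tuple(components), se)


def additive_null(components: list[RelativeSurvival]) -> NullExpectation:
    """Survival fractions lost under each stressor summed, floored at zero."""
    _validate_components(components)
    value = max(0.0, 1.0 - sum(1.0 - c.estimate for c in components))
    return NullExpectation("additive", value, tuple(components))


def classify_interaction(
    observed: RelativeSurvival,
    null: NullExpectation,
    se_multiplier: float = 1.0,
) -> InteractionCall:
    """Compare the combined-stressor arm's interval against the null value."""
    if observed.se < 0:
        raise ConfigurationError("observed SE must be >= 0")
    half = se_multiplier * observed.se
    lo, hi = observed.estimate - half, observed.estimate + half
    if lo <= null.value <= hi:
        call = "indistinguishable"
    elif observed.estimate > null.value:
        call = "antagonistic"
    else:
        call = "synergistic"
    return InteractionCall(call, observed, null, (lo, hi), se_multiplier)
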