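"""Bundled demonstration fixture: a published-style logistic survival fit.

The worked example injects a fixed coefficient table (log-odds scale, with
standard errors) straight into the interaction analysis, skipping the
fitting stage entirely, so the conversion chain can be exercised and checked
deterministically.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .glm import FitResult, ModelSpec

#: Log-odds coefficients of the demonstration survival fit.
EXAMPLE_SURVIVAL_COEFFICIENTS: dict[str, float] = {
    "intercept": -0.2,
    "treatment[heat]": -0.18,
    "treatment[salinity]": -0.53,
    "treatment[copper]": -0.45,
    "treatment[delay]": -0.34,
    "treatment[multiple]": -0.70,
    "density": 0.17,
}

#: Matching standard errors.
EXAMPLE_SURVIVAL_SES: dict[str, float] = {
    "intercept": 0.3,
    "treatment[heat]": 0.22,
    "treatment[salinity]": 0.22,
    "treatment[copper]": 0.22,
    "treatment[delay]": 0.22,
    "treatment[multiple]": 0.22,
    "density": 0.06,
}

#: Single-stressor arms entering the multiplicative null, and the combined arm.
EXAMPLE_SINGLE_STRESSORS = ("salinity", "heat", "copper", "delay")
EXAMPLE_COMBINED_STRESSOR = "multiple"


def injected_survival_fit(
    coefficients: dict[str, float] | None = None,
    std_errors: dict[str, float] | None = None,
    reference_treatment: str = "control",
) -> FitResult:
    """Wrap a plain coefficient table as a converged survival FitResult.

    Only marginal standard errors are available for an injected table, so the
    covariance is diagonal (coefficient correlations unknown -> treated as 0).
    """
    coefficients = dict(coefficients or EXAMPLE_SURVIVAL_COEFFICIENTS)
    std_errors = dict(std_errors or EXAMPLE_SURVIVAL_SES)
    if set(coefficients) != set(std_errors):
        raise ValueError("coefficients and std_errors must share keys")
    names = list(coefficients)
    vcov = pd.DataFrame(
        np.diag([std_errors[n] ** 2 for n in names]), index=names, columns=names
    )
    treat_cols = [n for n in names if n.startswith("treatment[")]
    term_columns = {"treatment": treat_cols}
    if "density" in names:
        term_columns["density"] = ["density"]
    z = {n: coefficients[n] / std_errors[n] if std_errors[n] > 0 else math.inf
         for n in names}
    from scipy import stats

    return FitResult(
        spec=ModelSpec("survival", ("treatment", "density")),
        coefficients=coefficients,
        std_errors=std_errors,
        p_values={n: float(2 * stats.norm.sf(abs(v))) for n, v in z.items()},
        vcov=vcov,
        log_likelihood=float("nan"),
        n=0,
        converged=True,
        term_columns=term_columns,
        reference_treatment=reference_treatment,
        reference_panel="",
    )
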