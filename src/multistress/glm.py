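"""Outcome models: GLM fitting, Wald tests, likelihood-ratio tests, pruning.

Three outcome models share one fitting path:

* survival  — binomial errors, logit link;
* size      — Poisson errors, log link;
* log_fecundity — Gaussian errors, identity link on log(fecundity).

Treatment and panel enter as reference-coded categoricals (control and the
lexicographically first panel are the references), density as a continuous
covariate.  The design matrix is built here with explicit column names like
``treatment[heat]`` and ``treatment[heat]:density`` so that Wald tests can
address whole coefficient blocks by term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError, DataError, ModelError

VALID_OUTCOMES = ("survival", "size", "log_fecundity")
VALID_TERMS = ("treatment", "panel", "density")
FAMILY_BY_OUTCOME = {
    "survival": "binomial-logit",
    "size": "poisson-log",
    "log_fecundity": "gaussian-identity",
}
#: |log-odds| beyond this is treated as runaway / separation.
SEPARATION_BOUND = 15.0
CONVERGENCE_TOL = 1e-8
MAX_ITER = 100


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one outcome model."""

    outcome: str
    terms: tuple[str, ...] = ("treatment", "panel", "density")
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.outcome not in VALID_OUTCOMES:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        terms = tuple(self.terms)
        for t in terms:
            if t not in VALID_TERMS:
                raise ConfigurationError(f"unknown model term {t!r}")
        interactions = tuple(tuple(pair) for pair in self.interactions)
        for pair in interactions:
            if len(pair) != 2 or any(t not in terms for t in pair):
                raise ConfigurationError(
                    f"interaction {pair!r} must pair two included main effects"
                )
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "interactions", interactions)

    @property
    def family(self) -> str:
        return FAMILY_BY_OUTCOME[self.outcome]

    def without_interaction(self, pair: tuple[str, str]) -> "ModelSpec":
        if tuple(pair) not in self.interactions:
            raise ConfigurationError(f"interaction {pair!r} not in spec")
        remaining = tuple(p for p in self.interactions if p != tuple(pair))
        return ModelSpec(self.outcome, self.terms, remaining)


@dataclass
class FitResult:
    """Maximum-likelihood fit with covariance and bookkeeping."""

    spec: ModelSpec
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    vcov: pd.DataFrame
    log_likelihood: float
    n: int
    converged: bool
    term_columns: dict[str, list[str]] = field(default_factory=dict)
    reference_treatment: str = ""
    reference_panel: str = ""

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.vcov.columns])


@dataclass(frozen=True)
class WaldTest:
    term: str
    df: int
    chi2: float
    p: float


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class InteractionTest:
    """One entry of the pruning audit trail."""

    interaction: tuple[str, str]
    chi2: float
    df: int
    p: float
    dropped: bool


def _outcome_series(records: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "survival":
        return records["survived"].astype(float)
    if outcome == "size":
        return pd.to_numeric(records["size"], errors="coerce").astype(float)
    # log_fecundity: zero fecundity cannot be logged; treated as missing.
    fec = records["fecundity"].astype(float)
    n_zero = int((fec == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-fecundity records treated as missing for log_fecundity",
            stacklevel=3,
        )
    return np.log(fec.where(fec > 0))


def build_design_matrix(
    records: pd.DataFrame,
    spec: ModelSpec,
    reference_treatment: str,
    reference_panel: str,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Reference-coded design matrix with named columns, plus term->columns map."""
    n = len(records)
    columns: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    term_columns: dict[str, list[str]] = {}

    def categorical_block(term: str, reference: str) -> dict[str, np.ndarray]:
        levels = sorted(set(records[term]))
        if reference not in levels:
            raise DataError(f"reference {term} {reference!r} absent from records")
        block = {}
        for level in levels:
            if level == reference:
                continue
            block[f"{term}[{level}]"] = (records[term] == level).to_numpy(float)
        return block

    main_blocks: dict[str, dict[str, np.ndarray]] = {}
    for term in spec.terms:
        if term == "density":
            main_blocks[term] = {"density": records["density"].to_numpy(float)}
        elif term == "treatment":
            main_blocks[term] = categorical_block("treatment", reference_treatment)
        elif term == "panel":
            main_blocks[term] = categorical_block("panel", reference_panel)
        columns.update(main_blocks[term])
        term_columns[term] = list(main_blocks[term])

    for a, b in spec.interactions:
        name = f"{a}:{b}"
        cols: list[str] = []
        for ca, va in main_blocks[a].items():
            for cb, vb in main_blocks[b].items():
                col = f"{ca}:{cb}"
                columns[col] = va * vb
                cols.append(col)
        term_columns[name] = cols

    return pd.DataFrame(columns, index=records.index), term_columns


def _family(name: str) -> sm.families.Family:
    if name == "binomial-logit":
        return sm.families.Binomial()
    if name == "poisson-log":
        return sm.families.Poisson()
    return sm.families.Gaussian()


def fit_glm(
    records: pd.DataFrame,
    spec: ModelSpec,
    reference_treatment: str | None = None,
    reference_panel: str | None = None,
) -> FitResult:
    """Fit *spec* to *records* by maximum likelihood (IRLS).

    Records with a missing outcome are excluded; ``n`` reflects the rows
    actually used.  Separation / non-convergence is flagged via ``converged``
    (with a warning) rather than raised, so downstream code can decide.
    """
    y_all = _outcome_series(records, spec.outcome)
    mask = y_all.notna()
    used = records.loc[mask]
    y = y_all.loc[mask].to_numpy(float)

    if "treatment" in spec.terms:
        if used["treatment"].nunique() < 2:
            raise DataError("need >= 2 treatment levels with non-missing outcomes")
        lost = set(records["treatment"]) - set(used["treatment"])
        if lost:
            raise DataError(
                f"treatment level(s) {sorted(lost)} have no non-missing outcome"
            )
    if len(used) == 0:
        raise DataError("no records with non-missing outcome")

    if reference_treatment is None:
        levels = sorted(set(used["treatment"])) if "treatment" in spec.terms else []
        reference_treatment = (
            "control" if "control" in levels else (levels[0] if levels else "")
        )
    if reference_panel is None and "panel" in spec.terms:
        reference_panel = sorted(set(used["panel"]))[0]
    reference_panel = reference_panel or ""

    X, term_columns = build_design_matrix(used, spec, reference_treatment, reference_panel)

    model = sm.GLM(y, X, family=_family(spec.family))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation handled below via coef bound
        res = model.fit(maxiter=MAX_ITER, tol=CONVERGENCE_TOL)

    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    vcov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)

    converged = bool(getattr(res, "converged", True))
    if spec.family == "binomial-logit" and np.max(np.abs(params.to_numpy())) > SEPARATION_BOUND:
        converged = False
    if not converged:
        warnings.warn(
            f"{spec.outcome} model did not converge cleanly "
            "(possible separation); estimates returned as-is",
            stacklevel=2,
        )

    if spec.family == "gaussian-identity":
        # Profile (ML) Gaussian log-likelihood so LRTs between nested models
        # are on a common footing; statsmodels' llf uses the REML-style scale.
        resid = y - res.fittedvalues
        n_obs = len(y)
        sigma2 = float(np.sum(resid**2)) / n_obs
        llf = -0.5 * n_obs * (np.log(2 * np.pi * sigma2) + 1.0)
    else:
        llf = float(res.llf)

    z = params / bse
    pvals = 2 * stats.norm.sf(np.abs(z))

    return FitResult(
        spec=spec,
        coefficients=dict(params),
        std_errors=dict(bse),
        p_values=dict(zip(X.columns, pvals)),
        vcov=vcov,
        log_likelihood=llf,
        n=len(used),
        converged=converged,
        term_columns=term_columns,
        reference_treatment=reference_treatment,
        reference_panel=reference_panel,
    )


def wald_test(fit: FitResult, term: str) -> WaldTest:
    """Block Wald chi-square for one model term: b' V^{-1} b."""
    if term not in fit.term_columns:
        raise ModelError(f"term {term!r} not in fitted model {list(fit.term_columns)}")
    cols = fit.term_columns[term]
    b = np.array([fit.coefficients[c] for c in cols])
    V = fit.vcov.loc[cols, cols].to_numpy()
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        raise ModelError(
            f"singular covariance block for term {term!r}; simplify the model"
        )
    if not np.isfinite(chi2) or chi2 < -1e-8:
        raise ModelError(
            f"ill-conditioned covariance block for term {term!r}; simplify the model"
        )
    chi2 = max(chi2, 0.0)
    df = len(cols)
    return WaldTest(term=term, df=df, chi2=chi2, p=float(stats.chi2.sf(chi2, df)))


def lrt(fit_full: FitResult, fit_reduced: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested fits: chi2 = 2 * delta log-likelihood."""
    if fit_full.spec.outcome != fit_reduced.spec.outcome:
        raise ModelError("LRT requires the same outcome in both models")
    if fit_full.n != fit_reduced.n:
        raise ModelError(
            f"LRT requires identical records: n={fit_full.n} vs n={fit_reduced.n}"
        )
    full_cols = set(fit_full.coefficients)
    red_cols = set(fit_reduced.coefficients)
    if not red_cols < full_cols:
        raise ModelError("reduced model is not strictly nested in the full model")
    df = len(full_cols) - len(red_cols)
    if df < 1:
        raise ModelError("LRT degrees of freedom must be >= 1")
    chi2 = max(0.0, 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood))
    return LRTResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def prune_interactions(
    records: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[FitResult, list[InteractionTest]]:
    """Drop non-significant interactions and refit.

    Each interaction is tested by LRT against the full model omitting only
    that interaction; all interactions with p >= *alpha* are then removed
    jointly and the final model refit.  The audit trail records every test.
    """
    if not spec.interactions:
        return fit_glm(records, spec, **fit_kwargs), []

    full_fit = fit_glm(records, spec, **fit_kwargs)
    audit: list[InteractionTest] = []
    to_drop: list[tuple[str, str]] = []
    for pair in spec.interactions:
        reduced_fit = fit_glm(records, spec.without_interaction(pair), **fit_kwargs)
        result = lrt(full_fit, reduced_fit)
        dropped = result.p >= alpha
        audit.append(
            InteractionTest(
                interaction=pair, chi2=result.chi2, df=result.df, p=result.p,
                dropped=dropped,
            )
        )
        if dropped:
            to_drop.append(pair)

    final_spec = spec
    for pair in to_drop:
        final_spec = final_spec.without_interaction(pair)
    final_fit = full_fit if final_spec == spec else fit_glm(records, final_spec, **fit_kwargs)
    return final_fit, audit
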