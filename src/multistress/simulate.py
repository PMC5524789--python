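"""Data-generating process for the transplant experiment.

Survival is binomial on the logit scale with treatment, panel, and
conspecific-density effects; colony size is Poisson on the log scale;
fecundity is lognormal and observed only in designated blocks.

Two causal stories for density are supported:

``exogenous``
    Each plate draws a neighbour-survivor count from a truncated Poisson and
    that count enters every occupant's linear predictor.  Fitting the
    survival model to such data recovers the density coefficient exactly
    (asymptotically), which anchors the parameter-recovery tests.

``emergent``
    Each plate draws a latent quality offset shared by its occupants; density
    is then computed from realised survivors.  This mimics
    microenvironmental variation inducing a survival-density correlation
    without a causal density effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign, generate_design
from .errors import ConfigurationError

#: Default survival coefficients (log-odds scale).
DEFAULT_INTERCEPT = -0.2
DEFAULT_TREATMENT_EFFECTS: dict[str, float] = {
    "control": 0.0,
    "heat": -0.18,
    "salinity": -0.53,
    "copper": -0.45,
    "delay": -0.34,
    "multiple": -0.70,
}
DEFAULT_DENSITY_COEF = 0.17


@dataclass(frozen=True)
class GeneratorParams:
    """True coefficients and noise settings of the simulator.

    ``beta_panel`` maps every panel label to a fixed log-odds offset with the
    first panel as the zero reference.  ``density_rate`` is the mean of the
    (truncated) Poisson neighbour count used in exogenous mode;
    ``plate_effect_sd`` scales the latent plate-quality offset in emergent
    mode.
    """

    beta_intercept: float = DEFAULT_INTERCEPT
    beta_treatment: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS)
    )
    beta_density: float = DEFAULT_DENSITY_COEF
    beta_panel: dict[str, float] = field(default_factory=dict)
    density_rate: float = 3.0
    plate_effect_sd: float = 1.0
    size_log_mean: dict[str, float] = field(default_factory=dict)
    fecundity_mu: dict[str, float] = field(default_factory=dict)
    fecundity_sd: float = 0.5
    fecund_blocks: tuple[int, ...] = (4,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_rate < 0:
            raise ConfigurationError(f"density_rate must be >= 0, got {self.density_rate}")
        if self.plate_effect_sd < 0:
            raise ConfigurationError(
                f"plate_effect_sd must be >= 0, got {self.plate_effect_sd}"
            )
        if self.fecundity_sd <= 0:
            raise ConfigurationError(
                f"fecundity_sd must be > 0, got {self.fecundity_sd}"
            )
        object.__setattr__(self, "fecund_blocks", tuple(self.fecund_blocks))

    @property
    def control(self) -> str:
        for label, beta in self.beta_treatment.items():
            if beta == 0.0:
                return label
        raise ConfigurationError("no control arm (zero treatment effect) in params")


def default_params(
    design: ExperimentDesign | None = None,
    seed: int = 0,
    panel_effect_sd: float = 1.0,
) -> GeneratorParams:
    """Fill a full parameter set for *design* with the default coefficients.

    Panel effects are drawn once as fixed Normal(0, ``panel_effect_sd``)
    constants (first panel pinned at 0) from a seed stream independent of the
    survival draws, so the same truth is reusable across replicate
    simulations.  Size and fecundity means fall back to flat values.
    """
    design = design or ExperimentDesign()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    panels = design.panel_labels()
    offsets = rng.normal(0.0, panel_effect_sd, size=len(panels))
    offsets[0] = 0.0
    treatments = {t: DEFAULT_TREATMENT_EFFECTS.get(t, 0.0) for t in design.treatments}
    treatments[design.control] = 0.0
    return GeneratorParams(
        beta_treatment=treatments,
        beta_panel=dict(zip(panels, offsets)),
        size_log_mean={t: math.log(4.0) for t in design.treatments},
        fecundity_mu={t: math.log(60.0) for t in design.treatments},
        seed=seed,
    )


def _rng_for(params: GeneratorParams, stage: int) -> np.random.Generator:
    # Documented sub-seeding: stage k uses SeedSequence(seed, spawn_key=(k,)).
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(stage,)))


def truncated_poisson_pmf(rate: float, upper: int) -> np.ndarray:
    """Renormalised Poisson pmf on the support {0, ..., upper}."""
    support = np.arange(upper + 1)
    pmf = stats.poisson.pmf(support, rate)
    total = pmf.sum()
    if total <= 0:  # rate far above the truncation point
        out = np.zeros(upper + 1)
        out[-1] = 1.0
        return out
    return pmf / total


def _check_labels(skeleton: pd.DataFrame, params: GeneratorParams) -> None:
    missing_t = set(skeleton["treatment"]) - set(params.beta_treatment)
    if missing_t:
        raise ConfigurationError(f"no treatment coefficient for: {sorted(missing_t)}")
    missing_p = set(skeleton["panel"]) - set(params.beta_panel)
    if missing_p:
        raise ConfigurationError(f"no panel coefficient for: {sorted(missing_p)}")


def simulate_survival(
    skeleton: pd.DataFrame,
    params: GeneratorParams,
    mode: str = "exogenous",
) -> pd.DataFrame:
    """Fill ``survived`` and ``density`` on a design skeleton.

    See the module docstring for the two modes.  Output row order and design
    coordinates are exactly those of *skeleton*; the draw is fully
    reproducible from ``params.seed``.
    """
    if mode not in ("exogenous", "emergent"):
        raise ConfigurationError(f"unknown simulation mode {mode!r}")
    _check_labels(skeleton, params)
    rng = _rng_for(params, stage=0)
    records = skeleton.copy()
    eta = (
        params.beta_intercept
        + records["treatment"].map(params.beta_treatment).to_numpy(float)
        + records["panel"].map(params.beta_panel).to_numpy(float)
    )
    plate_codes, plate_index = pd.factorize(records["plate"], sort=False)
    n_plates = len(plate_index)
    occupancy = np.bincount(plate_codes, minlength=n_plates)

    if mode == "exogenous":
        # One neighbour count per plate, shared by all occupants.
        max_occ = occupancy.max()
        pmf_cache = {
            occ: truncated_poisson_pmf(params.density_rate, occ - 1)
            for occ in np.unique(occupancy)
        }
        u = rng.random(n_plates)
        density_per_plate = np.empty(n_plates, dtype=int)
        for occ in np.unique(occupancy):
            sel = occupancy == occ
            cdf = np.cumsum(pmf_cache[occ])
            density_per_plate[sel] = np.searchsorted(cdf, u[sel], side="right")
        density_per_plate = np.clip(density_per_plate, 0, max_occ - 1)
        d = density_per_plate[plate_codes]
        prob = _expit(eta + params.beta_density * d)
        survived = (rng.random(len(records)) < prob).astype(int)
        records["survived"] = survived
        records["density"] = d
    else:
        quality = rng.normal(0.0, params.plate_effect_sd, size=n_plates)
        prob = _expit(eta + quality[plate_codes])
        survived = (rng.random(len(records)) < prob).astype(int)
        plate_survivors = np.bincount(plate_codes, weights=survived, minlength=n_plates)
        records["survived"] = survived
        records["density"] = (plate_survivors[plate_codes] - survived).astype(int)
    return records


def simulate_size(records: pd.DataFrame, params: GeneratorParams) -> pd.DataFrame:
    """Draw Poisson colony sizes (bifurcation counts) for survivors."""
    missing = set(records["treatment"]) - set(params.size_log_mean)
    if missing:
        raise ConfigurationError(f"no size_log_mean for: {sorted(missing)}")
    rng = _rng_for(params, stage=1)
    out = records.copy()
    mean = np.exp(out["treatment"].map(params.size_log_mean).to_numpy(float))
    draws = rng.poisson(mean)
    alive = out["survived"].to_numpy() == 1
    size = pd.array(draws, dtype="Int64")
    size[~alive] = pd.NA
    out["size"] = size
    return out


def simulate_fecundity(records: pd.DataFrame, params: GeneratorParams) -> pd.DataFrame:
    """Draw lognormal fecundity for survivors in the fecund blocks only."""
    missing = set(records["treatment"]) - set(params.fecundity_mu)
    if missing:
        raise ConfigurationError(f"no fecundity_mu for: {sorted(missing)}")
    rng = _rng_for(params, stage=2)
    out = records.copy()
    mu = out["treatment"].map(params.fecundity_mu).to_numpy(float)
    draws = np.exp(rng.normal(mu, params.fecundity_sd))
    eligible = (out["survived"].to_numpy() == 1) & out["block"].isin(
        params.fecund_blocks
    ).to_numpy()
    fec = np.where(eligible, draws, np.nan)
    out["fecundity"] = fec
    return out


def simulate_experiment(
    design: ExperimentDesign,
    params: GeneratorParams,
    mode: str = "exogenous",
) -> pd.DataFrame:
    """Full simulation: skeleton -> survival/density -> size -> fecundity."""
    skeleton = generate_design(design)
    records = simulate_survival(skeleton, params, mode=mode)
    records = simulate_size(records, params)
    records = simulate_fecundity(records, params)
    return records[
        ["block", "panel", "plate", "treatment", "survived", "size",
         "fecundity", "density"]
    ]


def expected_survival_exogenous(
    params: GeneratorParams,
    treatment: str,
    panel_effect: float,
    occupancy: int,
) -> float:
    """Closed-form marginal survival in exogenous mode.

    Averages the inverse-logit over the truncated Poisson neighbour count by
    direct enumeration; used as an independent oracle in tests.
    """
    pmf = truncated_poisson_pmf(params.density_rate, occupancy - 1)
    d = np.arange(occupancy)
    eta = (
        params.beta_intercept
        + params.beta_treatment[treatment]
        + panel_effect
        + params.beta_density * d
    )
    return float(np.sum(pmf * _expit(eta)))


def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def with_seed(params: GeneratorParams, seed: int) -> GeneratorParams:
    """A copy of *params* with a different master seed."""
    return replace(params, seed=seed)
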