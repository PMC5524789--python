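"""Run configuration: YAML round-trip for design, generator, models, analysis."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import DEFAULT_TREATMENTS, ExperimentDesign
from .errors import ConfigurationError
from .glm import ModelSpec
from .simulate import GeneratorParams, default_params

DEFAULT_MODEL_SPECS = (
    ModelSpec("survival", ("treatment", "panel", "density"),
              (("treatment", "panel"), ("treatment", "density"))),
    ModelSpec("size", ("treatment", "panel", "density"),
              (("treatment", "panel"), ("treatment", "density"))),
    ModelSpec("log_fecundity", ("treatment", "panel", "density"),
              (("treatment", "panel"), ("treatment", "density"))),
)


@dataclass(frozen=True)
class AnalysisSettings:
    reference_density: float = 3.0
    n_boot: int = 10_000
    se_multiplier: float = 1.0
    null_methods: tuple[str, ...] = ("multiplicative",)
    combined_treatment: str = "multiple"

    def __post_init__(self) -> None:
        for m in self.null_methods:
            if m not in ("multiplicative", "additive"):
                raise ConfigurationError(f"unknown null method {m!r}")
        object.__setattr__(self, "null_methods", tuple(self.null_methods))


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a simulate and/or analyze run."""

    seed: int
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    generator: GeneratorParams | None = None
    mode: str = "exogenous"
    panel_effect_sd: float = 1.0
    models: tuple[ModelSpec, ...] = DEFAULT_MODEL_SPECS
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def resolved_generator(self) -> GeneratorParams:
        """The generator params with defaults filled for this design/seed."""
        if self.generator is not None:
            return self.generator
        return default_params(self.design, seed=self.seed,
                              panel_effect_sd=self.panel_effect_sd)


def _design_from_dict(d: dict) -> ExperimentDesign:
    return ExperimentDesign(
        n_blocks=int(d.get("n_blocks", 4)),
        panels_per_block=int(d.get("panels_per_block", 4)),
        plates_per_panel=int(d.get("plates_per_panel", 12)),
        treatments=tuple(d.get("treatments", DEFAULT_TREATMENTS)),
        replicates_per_plate_per_treatment=int(
            d.get("replicates_per_plate_per_treatment", 1)
        ),
    )


def _generator_from_dict(d: dict, design: ExperimentDesign, seed: int,
                         panel_effect_sd: float) -> GeneratorParams:
    base = default_params(design, seed=seed, panel_effect_sd=panel_effect_sd)
    return GeneratorParams(
        beta_intercept=float(d.get("beta_intercept", base.beta_intercept)),
        beta_treatment={str(k): float(v) for k, v in
                        d.get("beta_treatment", base.beta_treatment).items()},
        beta_density=float(d.get("beta_density", base.beta_density)),
        beta_panel={str(k): float(v) for k, v in
                    d.get("beta_panel", base.beta_panel).items()},
        density_rate=float(d.get("density_rate", base.density_rate)),
        plate_effect_sd=float(d.get("plate_effect_sd", base.plate_effect_sd)),
        size_log_mean={str(k): float(v) for k, v in
                       d.get("size_log_mean", base.size_log_mean).items()},
        fecundity_mu={str(k): float(v) for k, v in
                      d.get("fecundity_mu", base.fecundity_mu).items()},
        fecundity_sd=float(d.get("fecundity_sd", base.fecundity_sd)),
        fecund_blocks=tuple(int(b) for b in d.get("fecund_blocks", base.fecund_blocks)),
        seed=int(d.get("seed", seed)),
    )


def _models_from_list(items: list) -> tuple[ModelSpec, ...]:
    specs = []
    for item in items:
        specs.append(
            ModelSpec(
                outcome=item["outcome"],
                terms=tuple(item.get("terms", ("treatment", "panel", "density"))),
                interactions=tuple(
                    tuple(pair) for pair in item.get("interactions", ())
                ),
            )
        )
    return tuple(specs)


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    if "seed" not in raw or raw["seed"] is None:
        raise ConfigurationError(
            "config must set an integer 'seed' (required for reproducibility)"
        )
    seed = int(raw["seed"])
    design = _design_from_dict(raw.get("design", {}))
    panel_effect_sd = float(raw.get("panel_effect_sd", 1.0))
    generator = None
    if "generator" in raw and raw["generator"] is not None:
        generator = _generator_from_dict(raw["generator"], design, seed, panel_effect_sd)
    models = (
        _models_from_list(raw["models"]) if raw.get("models") else DEFAULT_MODEL_SPECS
    )
    a = raw.get("analysis", {}) or {}
    analysis = AnalysisSettings(
        reference_density=float(a.get("reference_density", 3.0)),
        n_boot=int(a.get("n_boot", 10_000)),
        se_multiplier=float(a.get("se_multiplier", 1.0)),
        null_methods=tuple(a.get("null_methods", ("multiplicative",))),
        combined_treatment=str(a.get("combined_treatment", "multiple")),
    )
    mode = str(raw.get("mode", "exogenous"))
    if mode not in ("exogenous", "emergent"):
        raise ConfigurationError(f"unknown simulation mode {mode!r}")
    return RunConfig(
        seed=seed, design=design, generator=generator, mode=mode,
        panel_effect_sd=panel_effect_sd, models=models, analysis=analysis,
    )


def config_to_dict(config: RunConfig) -> dict:
    out: dict = {
        "seed": config.seed,
        "mode": config.mode,
        "panel_effect_sd": config.panel_effect_sd,
        "design": {
            "n_blocks": config.design.n_blocks,
            "panels_per_block": config.design.panels_per_block,
            "plates_per_panel": config.design.plates_per_panel,
            "treatments": list(config.design.treatments),
            "replicates_per_plate_per_treatment":
                config.design.replicates_per_plate_per_treatment,
        },
        "models": [
            {
                "outcome": m.outcome,
                "terms": list(m.terms),
                "interactions": [list(p) for p in m.interactions],
            }
            for m in config.models
        ],
        "analysis": {
            "reference_density": config.analysis.reference_density,
            "n_boot": config.analysis.n_boot,
            "se_multiplier": config.analysis.se_multiplier,
            "null_methods": list(config.analysis.null_methods),
            "combined_treatment": config.analysis.combined_treatment,
        },
    }
    if config.generator is not None:
        g = asdict(config.generator)
        g["fecund_blocks"] = list(config.generator.fecund_blocks)
        out["generator"] = g
    return out


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def roundtrip_equal(a: RunConfig, b: RunConfig) -> bool:
    """Structural equality modulo float representation."""
    da, db = config_to_dict(a), config_to_dict(b)

    def eq(x, y) -> bool:
        if isinstance(x, dict) and isinstance(y, dict):
            return x.keys() == y.keys() and all(eq(x[k], y[k]) for k in x)
        if isinstance(x, (list, tuple)) and isinstance(y, (list, tuple)):
            return len(x) == len(y) and all(eq(i, j) for i, j in zip(x, y))
        if isinstance(x, float) or isinstance(y, float):
            return math.isclose(float(x), float(y), rel_tol=0, abs_tol=0) or x == y
        return x == y

    return eq(da, db)
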