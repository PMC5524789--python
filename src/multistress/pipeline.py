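"""Orchestration: simulate -> fit -> classify -> report.

One master seed drives everything through documented sub-seeding
(``SeedSequence(seed, spawn_key=(stage,))``): the generator uses stages 0-2,
the bootstrap stage 1 of the analysis seed.  Report files:

* ``report.json``        — full-precision machine-readable report
* ``coefficients.csv``   — per-outcome coefficient tables
* ``wald.csv``           — per-outcome Wald tables
* ``density_curves.csv`` — survival-vs-density grid per treatment
* ``report.txt``         — rounded human-readable summary
* ``run.log``            — seed, params, mode, audit trail
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_to_dict, save_config
from .design import generate_design
from .errors import DataError, ModelError
from .glm import FitResult, InteractionTest, fit_glm, prune_interactions, wald_test
from .interaction import (
    InteractionCall,
    additive_null,
    classify_interaction,
    density_curves,
    multiplicative_null,
    relative_survival,
)
from .records_io import write_records
from .simulate import simulate_experiment


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate records per the config; write CSV, config snapshot, and log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.resolved_generator()
    records = simulate_experiment(config.design, params, mode=config.mode)
    records_path = out / "records.csv"
    write_records(records, records_path)
    save_config(config, out / "config.yaml")
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"multistress {__version__}\n")
        fh.write(f"command: simulate\nseed: {config.seed}\nmode: {config.mode}\n")
        fh.write(f"config_hash: {config_hash(config)}\n")
        fh.write(f"records: {len(records)}\n")
        fh.write("generator_params:\n")
        for key, value in asdict(params).items():
            fh.write(f"  {key}: {value}\n")
    return records_path


def analyze_records(records: pd.DataFrame, config: RunConfig) -> dict:
    """Fit all configured outcome models, prune interactions, classify.

    Returns the full report as a JSON-serialisable dict.
    """
    if len(records) == 0:
        raise DataError("no records to analyze")
    if records["survived"].nunique() < 2:
        raise DataError("need at least one survivor and one death overall")

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config),
        },
        "models": {},
    }
    survival_fit: FitResult | None = None
    for spec in config.models:
        section: dict = {"outcome": spec.outcome, "family": spec.family}
        try:
            fit, audit = prune_interactions(records, spec)
        except (DataError, ModelError) as exc:
            section["status"] = "not estimable"
            section["reason"] = str(exc)
            report["models"][spec.outcome] = section
            continue
        section["status"] = "ok"
        if not fit.converged:
            section["warning"] = "model did not converge cleanly (possible separation)"
        section["n"] = fit.n
        section["log_likelihood"] = fit.log_likelihood
        section["reference_treatment"] = fit.reference_treatment
        section["reference_panel"] = fit.reference_panel
        section["coefficients"] = {
            name: {
                "estimate": fit.coefficients[name],
                "se": fit.std_errors[name],
                "p": fit.p_values[name],
            }
            for name in fit.coefficients
        }
        section["wald"] = [
            asdict(wald_test(fit, term)) for term in fit.term_columns
        ]
        section["interaction_pruning"] = [_audit_dict(a) for a in audit]
        report["models"][spec.outcome] = section
        if spec.outcome == "survival":
            survival_fit = fit

    if survival_fit is not None and survival_fit.converged:
        report["interaction_analysis"] = run_interaction_analysis(
            survival_fit, config
        )
        dmax = int(records["density"].max())
        grid = density_curves(survival_fit, np.arange(0, dmax + 1))
        report["density_curves"] = grid.to_dict(orient="records")
    return report


def _audit_dict(a: InteractionTest) -> dict:
    return {"interaction": list(a.interaction), "chi2": a.chi2, "df": a.df,
            "p": a.p, "dropped": a.dropped}


def run_interaction_analysis(fit: FitResult, config: RunConfig) -> dict:
    """Relative survivals, null expectation(s), and the interaction call."""
    settings = config.analysis
    combined = settings.combined_treatment
    treatments = [t for t in _treatment_labels(fit) if t != fit.reference_treatment]
    if combined not in treatments:
        raise DataError(f"combined treatment {combined!r} not in fitted model")
    singles = [t for t in treatments if t != combined]

    relatives = {
        t: relative_survival(
            fit, t,
            reference_density=settings.reference_density,
            n_boot=settings.n_boot, seed=config.seed,
        )
        for t in treatments
    }
    observed = relatives[combined]
    out: dict = {
        "reference_density": settings.reference_density,
        "combined_treatment": combined,
        "single_stressors": singles,
        "relative_survival": {
            t: {"estimate": r.estimate, "se": r.se} for t, r in relatives.items()
        },
        "nulls": {},
    }
    components = [relatives[t] for t in singles]
    for method in settings.null_methods:
        null = (multiplicative_null(components) if method == "multiplicative"
                else additive_null(components))
        call = classify_interaction(observed, null, settings.se_multiplier)
        out["nulls"][method] = {
            "value": null.value,
            "call": call.call,
            "interval": list(call.interval),
            "se_multiplier": settings.se_multiplier,
        }
    return out


def _treatment_labels(fit: FitResult) -> list[str]:
    labels = [fit.reference_treatment]
    labels += [c[len("treatment["):-1] for c in fit.term_columns.get("treatment", [])]
    return labels


def write_report(report: dict, out_dir: str | Path) -> None:
    """Emit report.json plus the CSV and text companions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)

    coef_rows, wald_rows = [], []
    for outcome, section in report.get("models", {}).items():
        if section.get("status") != "ok":
            continue
        for name, c in section["coefficients"].items():
            coef_rows.append({"outcome": outcome, "coefficient": name, **c})
        for w in section["wald"]:
            wald_rows.append({"outcome": outcome, **w})
    pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
    pd.DataFrame(wald_rows).to_csv(out / "wald.csv", index=False)
    if "density_curves" in report:
        pd.DataFrame(report["density_curves"]).to_csv(
            out / "density_curves.csv", index=False
        )
    with open(out / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(format_report_text(report))


def format_report_text(report: dict) -> str:
    """Human-readable summary: coefficients to 2 dp, percentages to integers."""
    lines: list[str] = []
    for outcome, section in report.get("models", {}).items():
        lines.append(f"== {outcome} ({section.get('family', '?')}) ==")
        if section.get("status") != "ok":
            lines.append(f"  not estimable: {section.get('reason', 'unknown')}")
            lines.append("")
            continue
        if "warning" in section:
            lines.append(f"  WARNING: {section['warning']}")
        lines.append(f"  n = {section['n']}")
        for name, c in section["coefficients"].items():
            if name.startswith("panel["):
                continue  # keep the table compact; full set in report.json
            lines.append(
                f"  {name:<24s} {c['estimate']:+.2f}  (SE {c['se']:.2f}, p {c['p']:.3g})"
            )
        for w in section["wald"]:
            lines.append(
                f"  Wald {w['term']:<12s} df={w['df']:<3d} chi2={w['chi2']:.1f} "
                f"p={w['p']:.3g}"
            )
        lines.append("")
    ia = report.get("interaction_analysis")
    if ia:
        lines.append("== interaction analysis ==")
        lines.append(f"  reference density = {ia['reference_density']:g}")
        for t, r in ia["relative_survival"].items():
            lines.append(
                f"  {t:<12s} relative survival {round(100 * r['estimate']):d}% "
                f"± {round(100 * r['se']):d}%"
            )
        for method, n in ia["nulls"].items():
            lines.append(
                f"  {method} null = {round(100 * n['value']):d}%  ->  {n['call']}"
            )
    return "\n".join(lines) + "\n"
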