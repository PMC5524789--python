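import numpy as np
import pandas as pd
import pytest

from multistress import (
    ExperimentDesign,
    GeneratorParams,
    default_params,
    generate_design,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def default_design() -> ExperimentDesign:
    return ExperimentDesign()


@pytest.fixture(scope="session")
def default_truth(default_design) -> GeneratorParams:
    return default_params(default_design, seed=1)


@pytest.fixture(scope="session")
def sim_records(default_design, default_truth) -> pd.DataFrame:
    """One fully simulated experiment at the default design (seed 1)."""
    return simulate_experiment(default_design, default_truth, mode="exogenous")


def flat_design(n_plates: int, treatments=("a", "b"), reps: int = 1) -> ExperimentDesign:
    """Single block/panel design used to get big per-arm samples cheaply."""
    return ExperimentDesign(
        n_blocks=1,
        panels_per_block=1,
        plates_per_panel=n_plates,
        treatments=tuple(treatments),
        replicates_per_plate_per_treatment=reps,
    )


def two_arm_survival_frame(k_a: int, n_a: int, k_b: int, n_b: int) -> pd.DataFrame:
    """Hand-built two-arm records: k survivors of n per arm, density 0."""
    rows = []
    for arm, k, n in (("a", k_a, n_a), ("b", k_b, n_b)):
        for i in range(n):
            rows.append(
                {"block": 1, "panel": "p1", "plate": f"{arm}{i}", "treatment": arm,
                 "survived": int(i < k), "size": pd.NA, "fecundity": np.nan,
                 "density": 0}
            )
    frame = pd.DataFrame(rows)
    frame["size"] = pd.array(frame["size"], dtype="Int64")
    return frame
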