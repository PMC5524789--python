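"""Experimental design: blocks, panels, plates, treatments.

The default design mirrors a transplant experiment in which each of four
temporal blocks deploys four panels, each panel carries twelve plates, and
every plate holds one replicate of each of six treatments (one settler per
replicate).  That yields 192 replicates per treatment and 1152 records in
total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError

#: Canonical treatment labels; the first entry is the control/reference arm.
DEFAULT_TREATMENTS: tuple[str, ...] = (
    "control",
    "delay",
    "salinity",
    "heat",
    "copper",
    "multiple",
)

#: Columns of a design skeleton, in output order.
SKELETON_COLUMNS = ("block", "panel", "plate", "treatment")


@dataclass(frozen=True)
class TreatmentConfig:
    """Physical settings of one treatment arm (metadata only).

    These presets label the arms; treatment effects enter the generator as
    log-odds coefficients, never through these numbers.
    """

    label: str
    larval_delay_h: float
    salinity_psu: float
    temperature_c: float
    copper_ug_per_l: float


#: The six arm presets: control conditions vs. single- and multi-stressor arms.
TREATMENT_PRESETS: dict[str, TreatmentConfig] = {
    "control": TreatmentConfig("control", 0.0, 36.0, 17.5, 0.0),
    "delay": TreatmentConfig("delay", 2.0, 36.0, 17.5, 0.0),
    "salinity": TreatmentConfig("salinity", 0.0, 30.0, 17.5, 0.0),
    "heat": TreatmentConfig("heat", 0.0, 36.0, 22.0, 0.0),
    "copper": TreatmentConfig("copper", 0.0, 36.0, 17.5, 65.0),
    "multiple": TreatmentConfig("multiple", 2.0, 30.0, 22.0, 65.0),
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Dimensions of the blocked, panel-structured transplant design."""

    n_blocks: int = 4
    panels_per_block: int = 4
    plates_per_panel: int = 12
    treatments: tuple[str, ...] = field(default=DEFAULT_TREATMENTS)
    replicates_per_plate_per_treatment: int = 1

    def __post_init__(self) -> None:
        for name in (
            "n_blocks",
            "panels_per_block",
            "plates_per_panel",
            "replicates_per_plate_per_treatment",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise ConfigurationError(
                    f"{name} must be a positive integer, got {value!r}"
                )
        treatments = tuple(self.treatments)
        if len(treatments) < 1:
            raise ConfigurationError("treatments must be non-empty")
        if len(set(treatments)) != len(treatments):
            raise ConfigurationError(f"treatment labels must be unique: {treatments}")
        object.__setattr__(self, "treatments", treatments)

    @property
    def control(self) -> str:
        """The reference arm: always the first treatment label."""
        return self.treatments[0]

    @property
    def n_panels(self) -> int:
        return self.n_blocks * self.panels_per_block

    @property
    def plate_occupancy(self) -> int:
        """Settlers per plate: one replicate set of every treatment."""
        return len(self.treatments) * self.replicates_per_plate_per_treatment

    @property
    def replicates_per_treatment(self) -> int:
        return (
            self.n_blocks
            * self.panels_per_block
            * self.plates_per_panel
            * self.replicates_per_plate_per_treatment
        )

    @property
    def n_records(self) -> int:
        return self.replicates_per_treatment * len(self.treatments)

    def panel_labels(self) -> list[str]:
        """Globally unique panel identifiers in deterministic order."""
        return [
            f"b{b}p{p}"
            for b in range(1, self.n_blocks + 1)
            for p in range(1, self.panels_per_block + 1)
        ]


def generate_design(design: ExperimentDesign) -> pd.DataFrame:
    """Lay out one row per settler with design coordinates but no outcomes.

    Rows are ordered by block, panel, plate, then treatment in the order
    listed in ``design.treatments``.  Plate identifiers are unique across the
    whole experiment so that plate-level draws never collide between panels.
    """
    rows: list[tuple[int, str, str, str]] = []
    for b in range(1, design.n_blocks + 1):
        for p in range(1, design.panels_per_block + 1):
            panel = f"b{b}p{p}"
            for k in range(1, design.plates_per_panel + 1):
                plate = f"{panel}pl{k}"
                for treatment in design.treatments:
                    rows.extend(
                        (b, panel, plate, treatment)
                        for _ in range(design.replicates_per_plate_per_treatment)
                    )
    frame = pd.DataFrame(rows, columns=list(SKELETON_COLUMNS))
    assert len(frame) == design.n_records
    return frame
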