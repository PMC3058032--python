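"""Facility configuration: submission limits and plate chemistry.

All numeric policy lives in configuration, never in code constants: each
facility runs its own chemistry and sets its own acceptance windows for
customer material.  The shipped defaults describe a plausible BigDye-style
10 uL cycle-sequencing reaction and are meant to be overridden via a YAML
config file (see ``seqfab --config``).
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class ValidationLimits(BaseModel):
    """Acceptance windows for customer-supplied material.

    Concentrations in ng/uL (template) and pmol/uL (primer); volumes in uL.
    ``sequencing_types`` maps each allowed type label to its default
    requested read length in bases.
    """

    template_concentration_min: float = 20.0
    template_concentration_max: float = 200.0
    template_volume_min: float = 10.0
    primer_concentration_min: float = 2.0
    primer_concentration_max: float = 20.0
    primer_volume_min: float = 10.0
    sequencing_types: dict[str, int] = Field(
        default_factory=lambda: {"standard": 700, "long": 900}
    )

    @model_validator(mode="after")
    def _bounds_ordered(self) -> "ValidationLimits":
        if self.template_concentration_min > self.template_concentration_max:
            raise ValueError("template concentration: min > max")
        if self.primer_concentration_min > self.primer_concentration_max:
            raise ValueError("primer concentration: min > max")
        if any(v <= 0 for v in self.sequencing_types.values()):
            raise ValueError("default read lengths must be positive")
        return self


class ChemistryConfig(BaseModel):
    """Reaction chemistry and plate-layout policy.

    ``target_template_mass`` is per sequencing type (ng of template wanted
    in the well); variable-volume dosing divides it by the customer's
    stated concentration.  Fixed-mode volumes are used verbatim for every
    well and for control reactions.
    """

    total_reaction_volume: float = 10.0  # uL per well
    mix_volume: float = 4.0  # uL of pre-made reaction mix
    target_template_mass: dict[str, float] = Field(
        default_factory=lambda: {"standard": 100.0, "long": 150.0}
    )
    default_template_mass: float = 100.0  # ng, for unlisted types
    target_primer_amount: float = 5.0  # pmol
    fixed_template_volume: float = 1.0  # uL, FIXED mode
    fixed_primer_volume: float = 1.0  # uL, FIXED mode
    n_reaction_controls: int = 1
    n_instrument_controls: int = 1
    control_placement: str = "tail"  # last wells of the traversal
    traversal: str = "column"  # or "row"
    pipetting_increment: float = 0.1  # uL; robot resolution
    safety_factor: float = 1.5  # head-room on requested customer volumes
    confirmation_increment: float = 0.5  # uL; round-up step on confirmations
    manual_volume_multiplier: float = 1.0  # scales volumes on manual sheets
    run_series: str = "A"

    @model_validator(mode="after")
    def _consistent(self) -> "ChemistryConfig":
        if self.mix_volume >= self.total_reaction_volume:
            raise ValueError("mix volume must be below the reaction volume")
        if (
            self.fixed_template_volume + self.fixed_primer_volume + self.mix_volume
            >= self.total_reaction_volume
        ):
            raise ValueError("fixed volumes plus mix exceed the reaction volume")
        if self.controls_per_plate >= 96:
            raise ValueError("controls must leave room for samples")
        if self.traversal not in ("column", "row"):
            raise ValueError("traversal must be 'column' or 'row'")
        if self.pipetting_increment <= 0 or self.confirmation_increment <= 0:
            raise ValueError("increments must be positive")
        return self

    @property
    def controls_per_plate(self) -> int:
        return self.n_reaction_controls + self.n_instrument_controls

    @property
    def usable_wells(self) -> int:
        return 96 - self.controls_per_plate

    def template_mass_for(self, sequencing_type: str) -> float:
        return self.target_template_mass.get(
            sequencing_type, self.default_template_mass
        )


class FacilityConfig(BaseModel):
    """Top-level config: the two sections a facility tunes."""

    limits: ValidationLimits = Field(default_factory=ValidationLimits)
    chemistry: ChemistryConfig = Field(default_factory=ChemistryConfig)


def load_config(path: str | Path | None) -> FacilityConfig:
    """Load a YAML config file; a missing path yields the defaults."""
    if path is None:
        return FacilityConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return FacilityConfig.model_validate(raw)


def round_half_up(value: float, increment: float) -> float:
    """Round to the nearest multiple of ``increment``, ties away from zero.

    Pipetting volumes are quantised to the robot's resolution; a tiny
    epsilon guards against float representation pushing an exact tie down.
    """
    steps = math.floor(value / increment + 0.5 + 1e-9)
    return round(steps * increment, 6)


def round_up(value: float, increment: float) -> float:
    """Round up to the next multiple of ``increment`` (confirmation volumes)."""
    steps = math.ceil(value / increment - 1e-9)
    return round(steps * increment, 6)
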