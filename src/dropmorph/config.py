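"""Validated configuration models for the synthetic generator and presets."""

from __future__ import annotations

from typing import Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic droplet/organoid mask generator.

    All lengths are in micrometres. ``growth_curve`` maps acquisition day to
    the expected organoid major axis; ``contraction_schedule`` maps day to the
    fractional reduction of the droplet diameter relative to its uncontracted
    (day-0) value and must be non-decreasing in day.
    """

    model_config = ConfigDict(frozen=True)

    droplet_diameter_um: float = Field(gt=0)
    diameter_cv: float = Field(default=0.0, ge=0)
    pixel_size_um: float = Field(default=2.0, gt=0)
    image_shape_px: Tuple[int, int] = (512, 512)
    n_droplets: int = Field(default=10, gt=0)
    branched_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    growth_curve: dict[int, float] = Field(
        default_factory=lambda: {2: 60.0, 3: 85.0, 4: 110.0, 5: 150.0, 6: 170.0}
    )
    contraction_schedule: dict[int, float] = Field(
        default_factory=lambda: {2: 0.0, 3: 0.01, 4: 0.02, 5: 0.04, 6: 0.12}
    )
    branch_count_range: Tuple[int, int] = (2, 3)
    branch_length_range_um: Tuple[float, float] = (45.0, 62.0)
    branch_width_um: float = Field(default=12.0, gt=0)
    spheroid_axis_ratio_range: Tuple[float, float] = (0.62, 0.85)
    organoid_size_jitter: float = Field(default=0.10, ge=0.0, lt=1.0)
    cell_concentration_per_ml: float = Field(default=5000.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if not self.growth_curve:
            raise ValueError("growth_curve must not be empty")
        if not self.contraction_schedule:
            raise ValueError("contraction_schedule must not be empty")
        days = sorted(self.contraction_schedule)
        vals = [self.contraction_schedule[d] for d in days]
        if any(not (0.0 <= v < 1.0) for v in vals):
            raise ValueError("contraction fractions must lie in [0, 1)")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("contraction_schedule must be non-decreasing in day")
        missing = set(days) - set(self.growth_curve)
        if missing:
            raise ValueError(f"growth_curve missing days {sorted(missing)}")
        lo, hi = self.branch_count_range
        if lo < 0 or hi < lo:
            raise ValueError("branch_count_range must be a non-empty interval >= 0")
        lo, hi = self.branch_length_range_um
        if lo <= 0 or hi < lo:
            raise ValueError("branch_length_range_um must be a positive interval")
        lo, hi = self.spheroid_axis_ratio_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("spheroid_axis_ratio_range must lie in (0, 1]")
        # the uncontracted droplet (plus 3 s.d. of diameter spread) must fit
        d_max = self.droplet_diameter_um * (1.0 + 3.0 * self.diameter_cv)
        extent_px = d_max / self.pixel_size_um + 4
        if extent_px > min(self.image_shape_px):
            raise ValueError(
                f"droplet diameter {d_max:.0f} um does not fit in "
                f"{self.image_shape_px} px image at {self.pixel_size_um} um/px"
            )
        return self

    @property
    def days(self) -> list[int]:
        return sorted(self.contraction_schedule)


def small_droplet_config(**overrides) -> SyntheticConfig:
    """Preset mimicking the small-droplet regime (~370 um, 30k cells/ml)."""
    defaults = dict(
        droplet_diameter_um=373.0,
        diameter_cv=21.0 / 373.0,
        image_shape_px=(256, 256),
        cell_concentration_per_ml=30_000.0,
        growth_curve={2: 50.0, 3: 75.0, 4: 100.0, 5: 150.0, 6: 165.0},
        contraction_schedule={2: 0.0, 3: 0.01, 4: 0.02, 5: 0.03, 6: 0.05},
        branched_fraction=0.44,
        organoid_size_jitter=0.08,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def large_droplet_config(**overrides) -> SyntheticConfig:
    """Preset mimicking the large-droplet regime (~750 um, 5k cells/ml)."""
    defaults = dict(
        droplet_diameter_um=756.0,
        diameter_cv=30.0 / 756.0,
        image_shape_px=(512, 512),
        cell_concentration_per_ml=5_000.0,
        growth_curve={2: 60.0, 3: 100.0, 4: 150.0, 5: 266.0, 6: 290.0},
        contraction_schedule={2: 0.0, 3: 0.01, 4: 0.03, 5: 0.05, 6: 0.12},
        branched_fraction=0.59,
        organoid_size_jitter=0.25,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
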