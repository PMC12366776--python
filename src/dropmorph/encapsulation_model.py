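"""Closed-form droplet physics, Poisson occupancy and the bootstrap utility.

Unit constants: 1 nl = 1e6 um^3, 1 ul = 1e3 nl, 1 ml = 1e6 nl, 1 h = 3600 s.
Production rate uses the dispersed-phase (hydrogel) flow only — the
continuous (oil) flow sets droplet spacing, not droplet volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

UM3_PER_NL = 1e6
NL_PER_UL = 1e3
NL_PER_ML = 1e6
S_PER_H = 3600.0

__all__ = [
    "EncapsulationConfig",
    "OccupancyDistribution",
    "EfficiencySummary",
    "droplet_volume_nl",
    "volume_ratio",
    "production_rate_hz",
    "occupancy",
    "organoid_efficiency",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class EncapsulationConfig:
    droplet_diameter_um: float
    cell_concentration_per_ml: float
    dispersed_flow_ul_per_h: float = 1000.0
    continuous_flow_ul_per_h: float = 2000.0

    def __post_init__(self) -> None:
        for name in (
            "droplet_diameter_um",
            "cell_concentration_per_ml",
            "dispersed_flow_ul_per_h",
            "continuous_flow_ul_per_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class OccupancyDistribution:
    """Poisson occupancy split into empty / single / multi-cell droplets."""

    lambda_cells: float
    p_empty: float
    p_single: float
    p_multi: float

    def __post_init__(self) -> None:
        if self.lambda_cells < 0:
            raise ValueError("lambda_cells must be non-negative")
        total = self.p_empty + self.p_single + self.p_multi
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, expected 1")
        for p in (self.p_empty, self.p_single, self.p_multi):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EfficiencySummary:
    percent_with_structure_mean: float
    percent_with_structure_sd: float
    per_experiment_fractions: tuple[float, ...]
    organoids_per_seeded_cell: Optional[float]


def droplet_volume_nl(diameter_um: float) -> float:
    """Volume of a spherical droplet, (pi/6) d^3, in nanolitres."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return (math.pi / 6.0) * diameter_um**3 / UM3_PER_NL


def volume_ratio(d_large_um: float, d_small_um: float) -> float:
    """Fold-difference in volume between two droplet diameters."""
    if d_large_um <= 0 or d_small_um <= 0:
        raise ValueError("diameters must be positive")
    return (d_large_um / d_small_um) ** 3


def production_rate_hz(cfg: EncapsulationConfig) -> float:
    """Droplet production frequency: dispersed-phase flow over droplet volume."""
    flow_nl_per_s = cfg.dispersed_flow_ul_per_h * NL_PER_UL / S_PER_H
    return flow_nl_per_s / droplet_volume_nl(cfg.droplet_diameter_um)


def occupancy(cfg: EncapsulationConfig) -> OccupancyDistribution:
    """Poisson occupancy with mean = concentration x droplet volume."""
    lam = cfg.cell_concentration_per_ml * droplet_volume_nl(cfg.droplet_diameter_um) / NL_PER_ML
    p_empty = math.exp(-lam)
    p_single = lam * p_empty
    return OccupancyDistribution(
        lambda_cells=lam,
        p_empty=p_empty,
        p_single=p_single,
        p_multi=1.0 - p_empty - p_single,
    )


def organoid_efficiency(
    has_structure_by_experiment: Mapping[str, Sequence[bool]],
    mean_cells_per_droplet: Optional[float] = None,
) -> EfficiencySummary:
    """Fraction of droplets containing >= 1 structure, summarised per experiment.

    Returns the mean +/- sample s.d. across experiments (percent) and, when
    ``mean_cells_per_droplet`` is given, the derived organoids-per-seeded-cell
    = fraction / mean occupancy.
    """
    if not has_structure_by_experiment:
        raise ValueError("at least one experiment required")
    fractions = []
    for name, flags in has_structure_by_experiment.items():
        flags = list(flags)
        if not flags:
            raise ValueError(f"experiment {name!r} is empty")
        fractions.append(sum(bool(f) for f in flags) / len(flags))
    arr = np.asarray(fractions)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    per_cell = None
    if mean_cells_per_droplet is not None:
        if mean_cells_per_droplet <= 0:
            raise ValueError("mean_cells_per_droplet must be positive")
        per_cell = float(arr.mean() / mean_cells_per_droplet)
    return EfficiencySummary(
        percent_with_structure_mean=float(arr.mean() * 100.0),
        percent_with_structure_sd=sd * 100.0,
        per_experiment_fractions=tuple(float(f) for f in arr),
        organoids_per_seeded_cell=per_cell,
    )


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap confidence interval of ``statistic``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("bootstrap_ci requires at least one value")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    stats = np.apply_along_axis(statistic, 1, arr[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
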