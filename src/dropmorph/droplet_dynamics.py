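"""Droplet deformation and organoid-droplet spatial relations over time.

Normalisation uses the equivalent-area radius of the droplet: deformed
droplets are non-circular, and the equivalent radius is the stable choice
consistent with diameters derived from segmented area. Population
contraction is the ratio of per-day means (droplets are cross-sectional,
not individually tracked); confidence intervals are seeded percentile
bootstraps over droplets.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from dropmorph.encapsulation_model import bootstrap_ci
from dropmorph.mask_geometry import (
    MaskFrame,
    compactness,
    extract_features,
)

__all__ = [
    "contraction_series",
    "normalized_min_distance",
    "radial_position",
    "droplet_compactness_series",
]


def contraction_series(
    diameters_by_day: Mapping[int, Sequence[float]],
    baseline_day: Optional[int] = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-day population contraction percent with bootstrap CI.

    Contraction = ``100 * (1 - mean(d_day) / mean(d_baseline))``; the CI is a
    percentile bootstrap (``n_boot`` resamples) drawing droplets with
    replacement independently in the baseline and target day. The baseline
    defaults to the earliest observed day.
    """
    if not diameters_by_day:
        raise ValueError("no diameter data")
    days = sorted(diameters_by_day)
    if baseline_day is None:
        baseline_day = days[0]
    if baseline_day not in diameters_by_day:
        raise ValueError(f"baseline day {baseline_day} missing from data")
    base = np.asarray(diameters_by_day[baseline_day], dtype=float)
    if base.size == 0:
        raise ValueError(f"baseline day {baseline_day} has no droplets")
    rng = np.random.default_rng(seed)
    rows = []
    for day in days:
        cur = np.asarray(diameters_by_day[day], dtype=float)
        if cur.size == 0:
            warnings.warn(f"day {day} has no droplets; skipped")
            continue
        est = 100.0 * (1.0 - cur.mean() / base.mean())
        bi = rng.integers(0, base.size, size=(n_boot, base.size))
        ci_idx = rng.integers(0, cur.size, size=(n_boot, cur.size))
        stats = 100.0 * (1.0 - cur[ci_idx].mean(axis=1) / base[bi].mean(axis=1))
        lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
        rows.append(
            {
                "day": day,
                "n": int(cur.size),
                "mean_diameter_um": float(cur.mean()),
                "contraction_percent": float(est),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def _largest_organoid_mask(frame: MaskFrame) -> np.ndarray:
    labels = frame.organoid_labels()
    if not labels:
        raise ValueError(f"frame {frame.droplet_id} day {frame.day}: no organoid labels")
    best, best_area = None, -1
    for label in labels:
        mask = frame.label_image == label
        area = int(mask.sum())
        if area > best_area:
            best, best_area = mask, area
    return best


def _droplet_geometry(frame: MaskFrame):
    droplet = frame.droplet_mask
    if not droplet.any():
        raise ValueError(f"frame {frame.droplet_id} day {frame.day}: no droplet label")
    feats = {f.label: f for f in extract_features(frame)}
    return droplet, feats[1]


def normalized_min_distance(frame: MaskFrame) -> float:
    """Minimal organoid-boundary-to-droplet-boundary distance over the
    droplet's equivalent radius; in [0, 1].

    Uses the exact Euclidean distance transform of the droplet interior.
    Multiple organoid components: the largest is used. Organoid pixels
    outside the droplet are flagged with a warning and ignored.
    """
    droplet, droplet_feat = _droplet_geometry(frame)
    organoid = _largest_organoid_mask(frame)
    outside = organoid & ~droplet
    if outside.any():
        warnings.warn(
            f"frame {frame.droplet_id} day {frame.day}: organoid extends outside "
            "the droplet; distance computed on the interior part"
        )
        organoid = organoid & droplet
        if not organoid.any():
            return 0.0
    edt = ndimage.distance_transform_edt(droplet) * frame.pixel_size_um
    boundary = organoid & ~ndimage.binary_erosion(organoid)
    min_dist = float(edt[boundary].min())
    radius = droplet_feat.equivalent_diameter_um / 2.0
    return float(np.clip(min_dist / radius, 0.0, 1.0))


def radial_position(frame: MaskFrame) -> float:
    """Organoid-centroid offset from the droplet centroid over the droplet's
    equivalent radius; in [0, 1]."""
    _, droplet_feat = _droplet_geometry(frame)
    organoid = _largest_organoid_mask(frame)
    cy, cx = ndimage.center_of_mass(organoid)
    ocy = cy * frame.pixel_size_um
    ocx = cx * frame.pixel_size_um
    dcy, dcx = droplet_feat.centroid_um
    dist = float(np.hypot(ocy - dcy, ocx - dcx))
    radius = droplet_feat.equivalent_diameter_um / 2.0
    return float(np.clip(dist / radius, 0.0, 1.0))


def droplet_compactness_series(frames: Sequence[MaskFrame]) -> pd.DataFrame:
    """Per-day mean droplet compactness (4*pi*A/P^2), sorted by day."""
    values: dict[int, list[float]] = {}
    for frame in frames:
        _, feat = _droplet_geometry(frame)
        values.setdefault(frame.day, []).append(
            compactness(feat.area_um2, feat.perimeter_um)
        )
    rows = [
        {
            "day": day,
            "n": len(vals),
            "mean_compactness": float(np.mean(vals)),
        }
        for day, vals in sorted(values.items())
    ]
    return pd.DataFrame(rows)
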