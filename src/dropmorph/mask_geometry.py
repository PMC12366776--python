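"""Mask I/O and primitive per-component geometry.

Conventions frozen here and relied on everywhere else:

* coordinates are 0-based, row-major; public quantities are in micrometres,
  converted from pixels at extraction time only;
* ``a`` and ``b`` are the FULL major/minor axis lengths of the ellipse with
  matching second central moments;
* perimeter uses the 4-direction Crofton estimator, calibrated so that a
  digital disk of radius >= 50 px has compactness within 0.02 of 1 (naive
  pixel-edge counting would overestimate P by up to ~sqrt(2));
* holes are filled in the droplet label (label 1) before feature extraction
  — interior holes there are segmentation artifacts (or space occupied by
  organoid labels) — but organoid labels (>= 2) are measured as-is, since
  lumens are genuine boundary complexity.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter_crofton, regionprops

DROPLET_LABEL = 1

__all__ = [
    "DROPLET_LABEL",
    "MaskFrame",
    "RegionFeatures",
    "MaskValidationError",
    "read_mask",
    "extract_features",
    "compactness",
    "shape_irregularity_index",
]


class MaskValidationError(ValueError):
    """Raised when a mask file violates the label-image contract."""


@dataclass(frozen=True)
class MaskFrame:
    """One acquisition: a label image plus its calibration and identity.

    Label semantics: 0 background, 1 droplet, >= 2 organoid structures.
    """

    droplet_id: str
    day: int
    label_image: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        img = self.label_image
        if img.ndim != 2:
            raise MaskValidationError("label_image must be 2-D")
        if not np.issubdtype(img.dtype, np.integer):
            raise MaskValidationError("label_image must be integer-valued")
        if img.size and img.min() < 0:
            raise MaskValidationError("labels must be non-negative")
        if self.pixel_size_um <= 0:
            raise MaskValidationError("pixel_size_um must be positive")

    @property
    def droplet_mask(self) -> np.ndarray:
        """Hole-filled boolean mask of the droplet label."""
        return ndimage.binary_fill_holes(self.label_image == DROPLET_LABEL)

    def organoid_labels(self) -> List[int]:
        labels = np.unique(self.label_image)
        return [int(v) for v in labels if v >= 2]


@dataclass(frozen=True)
class RegionFeatures:
    """Primitive geometry of one labelled component (micrometre units)."""

    label: int
    area_um2: float
    perimeter_um: float
    major_axis_um: float
    minor_axis_um: float
    centroid_um: tuple[float, float]
    equivalent_diameter_um: float
    touches_border: bool = False


def read_mask(
    path: str | os.PathLike,
    pixel_size_um: float,
    droplet_id: str,
    day: int,
) -> MaskFrame:
    """Read a single-channel integer label image (TIFF or PNG) into a MaskFrame.

    The droplet label must form a single connected component after hole
    filling; violations raise :class:`MaskValidationError` naming the file.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise MaskValidationError(f"{path}: expected a single-channel 2-D image")
    if not np.issubdtype(img.dtype, np.integer):
        raise MaskValidationError(f"{path}: expected integer labels, got {img.dtype}")
    frame = MaskFrame(
        droplet_id=droplet_id,
        day=day,
        label_image=img.astype(np.int32),
        pixel_size_um=pixel_size_um,
    )
    droplet = frame.droplet_mask
    if droplet.any():
        _, n_comp = ndimage.label(droplet)
        if n_comp != 1:
            raise MaskValidationError(
                f"{path}: droplet label forms {n_comp} components, expected 1"
            )
    return frame


def _region_features(mask: np.ndarray, label: int, px: float) -> RegionFeatures:
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area) * px * px
    perim = float(perimeter_crofton(mask, directions=4)) * px
    cy, cx = props.centroid
    border = bool(
        props.bbox[0] == 0
        or props.bbox[1] == 0
        or props.bbox[2] == mask.shape[0]
        or props.bbox[3] == mask.shape[1]
    )
    return RegionFeatures(
        label=label,
        area_um2=area,
        perimeter_um=perim,
        major_axis_um=float(props.axis_major_length) * px,
        minor_axis_um=float(props.axis_minor_length) * px,
        centroid_um=(cy * px, cx * px),
        equivalent_diameter_um=2.0 * math.sqrt(area / math.pi),
        touches_border=border,
    )


def extract_features(frame: MaskFrame) -> List[RegionFeatures]:
    """Per-label primitive geometry, one record per label >= 1.

    Returns an empty list for an empty mask. Deterministic.
    """
    out: List[RegionFeatures] = []
    for label in (int(v) for v in np.unique(frame.label_image) if v >= 1):
        if label == DROPLET_LABEL:
            mask = frame.droplet_mask
        else:
            mask = frame.label_image == label
        if not mask.any():
            continue
        out.append(_region_features(mask, label, frame.pixel_size_um))
    return out


def compactness(area: float, perimeter: float) -> float:
    """4*pi*A/P**2 — 1 for a mathematical circle, smaller for rougher shapes."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def shape_irregularity_index(area: float, perimeter: float) -> float:
    """Perimeter relative to the perimeter of the equal-area circle.

    Equals ``1/sqrt(compactness)``; 1 for a circle, larger for branched or
    deformed shapes.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return perimeter / (2.0 * math.sqrt(math.pi * area))
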