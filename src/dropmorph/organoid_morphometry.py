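"""Organoid-level morphometry: branch census, classification, population stats.

Branch detection works on the topological skeleton of a single connected
component. Geodesic lengths along the 8-connected skeleton use the
Vossepoel–Smeulders calibrated step weights (0.948 orthogonal, 1.340
diagonal), which keep digital-line length estimates within ~2.5% of the
Euclidean truth; naive unit/sqrt(2) weights overestimate by up to ~8%
depending on orientation. Spurs shorter than ``prune_um`` are removed before
counting. A branch is the skeleton path from the body anchor — the skeleton
node on the plateau of maximal inscribed radius, nearest the plateau
centroid — to an endpoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from dropmorph.mask_geometry import RegionFeatures

# calibrated chain-code step lengths (orthogonal, diagonal), in pixels
W_ORTH = 0.948
W_DIAG = 1.340

__all__ = [
    "BranchCensus",
    "OrganoidMorphology",
    "PopulationStats",
    "branch_census",
    "classify_structure",
    "pdi",
    "branched_fraction",
    "growth_summary",
]


@dataclass(frozen=True)
class BranchCensus:
    """Skeleton branch count and lengths for one component (micrometres)."""

    n_branches: int
    branch_lengths_um: tuple[float, ...]
    skeleton_length_um: float
    min_branch_um: float = 30.0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.branch_lengths_um):
            raise ValueError("branch lengths must be positive")
        if self.n_branches != sum(
            1 for length in self.branch_lengths_um if length >= self.min_branch_um
        ):
            raise ValueError("n_branches inconsistent with qualifying lengths")


@dataclass(frozen=True)
class OrganoidMorphology:
    features: RegionFeatures
    sii: float
    census: BranchCensus
    classification: Literal["spheroid", "branched"]


@dataclass(frozen=True)
class PopulationStats:
    pdi_percent: float
    branched_fraction_mean: float
    branched_fraction_sd: float
    n_structures: int
    per_experiment: tuple[float, ...] = field(default_factory=tuple)


def _skeleton_graph(skeleton: np.ndarray, px: float) -> nx.Graph:
    graph = nx.Graph()
    coords = set(map(tuple, np.argwhere(skeleton)))
    for node in coords:
        graph.add_node(node)
    for r, c in sorted(coords):
        for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)):
            q = (r + dr, c + dc)
            if q in coords:
                w = px * (W_ORTH if dr == 0 or dc == 0 else W_DIAG)
                graph.add_edge((r, c), q, weight=w)
    return graph


def _prune_spurs(graph: nx.Graph, prune_um: float) -> nx.Graph:
    """Iteratively remove endpoint-to-junction spurs shorter than prune_um."""
    changed = True
    while changed:
        changed = False
        for end in sorted(n for n in graph if graph.degree(n) == 1):
            if end not in graph:
                continue
            path = [end]
            length = 0.0
            cur, prev = end, None
            while True:
                nbrs = [n for n in graph.neighbors(cur) if n != prev]
                if graph.degree(cur) >= 3 or not nbrs:
                    break
                nxt = nbrs[0]
                length += graph[cur][nxt]["weight"]
                prev, cur = cur, nxt
                path.append(cur)
                if graph.degree(cur) >= 3:
                    break
            if graph.degree(cur) >= 3 and length < prune_um:
                graph.remove_nodes_from(path[:-1])
                changed = True
    return graph


def branch_census(
    mask: np.ndarray,
    pixel_size_um: float,
    min_branch_um: float = 30.0,
    prune_um: float = 10.0,
) -> BranchCensus:
    """Count skeleton branches of a single connected component.

    Branch length is geodesic along the pruned skeleton, from the nearest
    branch point (or the body anchor when the skeleton has no junction) to
    each endpoint. Only branches >= ``min_branch_um`` contribute to
    ``n_branches``; all retained lengths are reported.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("branch_census requires a non-empty component")
    _, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise ValueError(f"expected a single connected component, got {n_comp}")

    skeleton = skeletonize(mask)
    graph = _prune_spurs(_skeleton_graph(skeleton, pixel_size_um), prune_um)
    skeleton_length = float(
        sum(d["weight"] for _, _, d in graph.edges(data=True))
    )
    ends = sorted(n for n in graph if graph.degree(n) == 1)
    if graph.number_of_nodes() == 0 or not ends:
        return BranchCensus(0, (), skeleton_length, min_branch_um)

    # anchor at the body: the skeleton node on the plateau of maximal
    # inscribed radius, nearest the plateau centroid. Measuring every branch
    # from this single anchor (rather than from the nearest skeleton
    # junction) is robust to tubes that merge near the body, where spurious
    # junction placement would truncate branch lengths.
    edt = ndimage.distance_transform_edt(mask)
    vmax = max(edt[n] for n in graph.nodes)
    plateau = [n for n in graph.nodes if edt[n] >= vmax - 0.5]
    cy = float(np.mean([p[0] for p in plateau]))
    cx = float(np.mean([p[1] for p in plateau]))
    anchor = min(plateau, key=lambda p: ((p[0] - cy) ** 2 + (p[1] - cx) ** 2, p))

    dist = nx.multi_source_dijkstra_path_length(graph, [anchor], weight="weight")
    lengths = tuple(
        sorted((float(dist[e]) for e in ends if e in dist), reverse=True)
    )
    lengths = tuple(length for length in lengths if length > 0)
    n_qual = sum(1 for length in lengths if length >= min_branch_um)
    return BranchCensus(n_qual, lengths, skeleton_length, min_branch_um)


def classify_structure(
    features: RegionFeatures,
    census: BranchCensus,
    a_max_um: float = 60.0,
    axis_ratio: float = 0.5,
    min_branches: int = 2,
    min_branch_um: float = 30.0,
    combine: Literal["or", "and"] = "or",
) -> Literal["spheroid", "branched"]:
    """Spheroid/branched call from moment-ellipse axes and the branch census.

    With the default disjunctive combination a structure is a spheroid iff
    its major axis a < ``a_max_um``, OR its minor axis b > ``axis_ratio * a``,
    OR it has fewer than ``min_branches`` branches of at least
    ``min_branch_um``; everything else is branched. ``combine="and"`` requires
    all three conditions instead.
    """
    a = features.major_axis_um
    b = features.minor_axis_um
    n_qual = sum(1 for length in census.branch_lengths_um if length >= min_branch_um)
    crits = (a < a_max_um, b > axis_ratio * a, n_qual < min_branches)
    is_spheroid = any(crits) if combine == "or" else all(crits)
    return "spheroid" if is_spheroid else "branched"


def pdi(
    projected_areas: Sequence[float],
    formula: Literal["cv", "variance_ratio"] = "cv",
) -> float:
    """Polydispersity of projected areas, in percent.

    Default is the coefficient of variation 100*sd/mean with the population
    (ddof=0) standard deviation; ``variance_ratio`` gives 100*var/mean**2.
    A constant (or single-element) population has PDI 0.
    """
    areas = np.asarray(projected_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("pdi requires at least one area")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    mean = areas.mean()
    if formula == "cv":
        return float(100.0 * areas.std(ddof=0) / mean)
    return float(100.0 * areas.var(ddof=0) / mean**2)


def branched_fraction(
    classifications_by_experiment: Mapping[str, Iterable[str]],
) -> tuple[float, float, tuple[float, ...]]:
    """Mean +/- s.d. (sample, ddof=1) of the per-experiment branched fraction.

    Returns ``(mean_percent, sd_percent, per_experiment_fractions)``; the
    s.d. is 0 for a single experiment.
    """
    if not classifications_by_experiment:
        raise ValueError("at least one experiment group required")
    fractions = []
    for name, calls in classifications_by_experiment.items():
        calls = list(calls)
        if not calls:
            raise ValueError(f"experiment group {name!r} is empty")
        bad = set(calls) - {"spheroid", "branched"}
        if bad:
            raise ValueError(f"experiment group {name!r} has unknown labels {bad}")
        fractions.append(sum(c == "branched" for c in calls) / len(calls))
    arr = np.asarray(fractions)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean() * 100.0), sd * 100.0, tuple(float(f) for f in arr)


def growth_summary(
    major_axes_by_day: Mapping[int, Sequence[float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-day mean +/- s.d. of the major axis, sorted by day.

    Accepts either a mapping day -> axis values or a DataFrame with columns
    ``day`` and ``major_axis_um``. Days with a single structure get s.d. 0
    and ``sd_defined=False``; empty days are dropped with a warning.
    """
    if isinstance(major_axes_by_day, pd.DataFrame):
        grouped = {
            int(day): grp["major_axis_um"].to_numpy()
            for day, grp in major_axes_by_day.groupby("day")
        }
    else:
        grouped = {int(d): np.asarray(v, dtype=float) for d, v in major_axes_by_day.items()}
    rows = []
    for day in sorted(grouped):
        values = np.asarray(grouped[day], dtype=float)
        if values.size == 0:
            warnings.warn(f"day {day} has no structures; dropped from summary")
            continue
        rows.append(
            {
                "day": day,
                "n": int(values.size),
                "major_axis_mean_um": float(values.mean()),
                "major_axis_sd_um": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                "sd_defined": bool(values.size > 1),
            }
        )
    return pd.DataFrame(rows, columns=["day", "n", "major_axis_mean_um", "major_axis_sd_um", "sd_defined"])
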