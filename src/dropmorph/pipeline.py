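"""Config-driven orchestration: dataset in, tidy result tables out.

Outputs are deterministic for a fixed (config, seed): re-running produces
byte-identical tables. Tables are tidy/long (one row per structure per day)
so per-day and per-condition summaries are single group-by operations.
"""

from __future__ import annotations

import json
import os
import platform
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

import dropmorph
from dropmorph.config import SyntheticConfig
from dropmorph.droplet_dynamics import (
    contraction_series,
    normalized_min_distance,
    radial_position,
)
from dropmorph.encapsulation_model import EncapsulationConfig, occupancy
from dropmorph.mask_geometry import (
    MaskFrame,
    compactness,
    extract_features,
    read_mask,
    shape_irregularity_index,
)
from dropmorph.organoid_morphometry import branch_census, classify_structure, pdi
from dropmorph.synthetic_data import generate_organoid_mask

FEATURE_COLUMNS = [
    "droplet_id",
    "day",
    "label",
    "area_um2",
    "perimeter_um",
    "major_axis_um",
    "minor_axis_um",
    "equivalent_diameter_um",
    "compactness",
    "sii",
    "n_branches",
    "branch_lengths_um",
    "classification",
    "touches_border",
]

SUMMARY_COLUMNS = [
    "day",
    "n_structures",
    "major_axis_mean_um",
    "major_axis_sd_um",
    "sii_mean",
    "pdi_percent",
    "branched_fraction_percent",
    "droplet_diameter_mean_um",
    "droplet_compactness_mean",
    "contraction_percent",
    "contraction_ci_low",
    "contraction_ci_high",
    "min_distance_mean",
    "radial_position_mean",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offender."""


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    mode: Literal["synthetic", "masks"] = "synthetic"
    synthetic: Optional[SyntheticConfig] = None
    input_dir: Optional[str] = None
    a_max_um: float = Field(default=60.0, gt=0)
    axis_ratio: float = Field(default=0.5, gt=0)
    min_branch_um: float = Field(default=30.0, gt=0)
    min_branches: int = Field(default=2, ge=1)
    combine: Literal["or", "and"] = "or"
    prune_um: float = Field(default=10.0, ge=0)
    baseline_day: Optional[int] = None
    n_boot: int = Field(default=1000, gt=0)
    ci_level: float = Field(default=0.95, gt=0, lt=1)
    out_dir: str = "dropmorph_out"
    seed: int = 0


def _load_frames(cfg: RunConfig) -> list[MaskFrame]:
    if cfg.mode == "synthetic":
        if cfg.synthetic is None:
            raise PipelineError("stage=config: synthetic mode requires a SyntheticConfig")
        frames = []
        scfg = cfg.synthetic
        for i in range(scfg.n_droplets):
            droplet_id = f"drop{i:04d}"
            for day in scfg.days:
                try:
                    frame, _ = generate_organoid_mask(scfg, droplet_id, day)
                except Exception as exc:
                    raise PipelineError(
                        f"stage=generate: droplet {droplet_id} day {day}: {exc}"
                    ) from exc
                frames.append(frame)
        return frames
    if not cfg.input_dir:
        raise PipelineError("stage=config: masks mode requires input_dir")
    manifest_path = os.path.join(cfg.input_dir, "manifest.csv")
    if not os.path.exists(manifest_path):
        raise PipelineError(f"stage=ingest: manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"droplet_id", "day", "file", "pixel_size_um"}
    missing = required - set(manifest.columns)
    if missing:
        raise PipelineError(f"stage=ingest: manifest missing columns {sorted(missing)}")
    frames = []
    for idx, row in manifest.iterrows():
        try:
            day = int(row["day"])
            px = float(row["pixel_size_um"])
            path = os.path.join(cfg.input_dir, str(row["file"]))
            frames.append(read_mask(path, px, str(row["droplet_id"]), day))
        except Exception as exc:
            raise PipelineError(f"stage=ingest: manifest row {idx}: {exc}") from exc
    return frames


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; write tables to ``cfg.out_dir``.

    Returns a bundle with the feature table, per-day summary, optional
    occupancy report and the paths of everything written.
    """
    frames = _load_frames(cfg)
    os.makedirs(cfg.out_dir, exist_ok=True)

    feature_rows = []
    droplet_diams: dict[int, list[float]] = {}
    droplet_comp: dict[int, list[float]] = {}
    min_dists: dict[int, list[float]] = {}
    radials: dict[int, list[float]] = {}

    for frame in frames:
        try:
            feats = {f.label: f for f in extract_features(frame)}
        except Exception as exc:
            raise PipelineError(
                f"stage=features: droplet {frame.droplet_id} day {frame.day}: {exc}"
            ) from exc
        if 1 in feats:
            droplet_diams.setdefault(frame.day, []).append(
                feats[1].equivalent_diameter_um
            )
            droplet_comp.setdefault(frame.day, []).append(
                compactness(feats[1].area_um2, feats[1].perimeter_um)
            )
            if frame.organoid_labels():
                min_dists.setdefault(frame.day, []).append(
                    normalized_min_distance(frame)
                )
                radials.setdefault(frame.day, []).append(radial_position(frame))
        for label, feat in feats.items():
            if label < 2:
                continue
            mask = frame.label_image == label
            try:
                census = branch_census(
                    mask, frame.pixel_size_um, cfg.min_branch_um, cfg.prune_um
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage=census: droplet {frame.droplet_id} day {frame.day} "
                    f"label {label}: {exc}"
                ) from exc
            call = classify_structure(
                feat,
                census,
                a_max_um=cfg.a_max_um,
                axis_ratio=cfg.axis_ratio,
                min_branches=cfg.min_branches,
                min_branch_um=cfg.min_branch_um,
                combine=cfg.combine,
            )
            feature_rows.append(
                {
                    "droplet_id": frame.droplet_id,
                    "day": frame.day,
                    "label": label,
                    "area_um2": feat.area_um2,
                    "perimeter_um": feat.perimeter_um,
                    "major_axis_um": feat.major_axis_um,
                    "minor_axis_um": feat.minor_axis_um,
                    "equivalent_diameter_um": feat.equivalent_diameter_um,
                    "compactness": compactness(feat.area_um2, feat.perimeter_um),
                    "sii": shape_irregularity_index(feat.area_um2, feat.perimeter_um),
                    "n_branches": census.n_branches,
                    "branch_lengths_um": ";".join(
                        f"{v:.2f}" for v in census.branch_lengths_um
                    ),
                    "classification": call,
                    "touches_border": feat.touches_border,
                }
            )

    features = pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS)

    contraction = contraction_series(
        droplet_diams,
        baseline_day=cfg.baseline_day,
        n_boot=cfg.n_boot,
        level=cfg.ci_level,
        seed=cfg.seed,
    ) if droplet_diams else pd.DataFrame()

    summary_rows = []
    # border-touching structures are censored from PDI and classification stats
    interior = features[~features["touches_border"]]
    for day in sorted(set(features["day"])) if len(features) else []:
        sub = interior[interior["day"] == day]
        con = contraction[contraction["day"] == day] if len(contraction) else pd.DataFrame()
        summary_rows.append(
            {
                "day": day,
                "n_structures": int(len(sub)),
                "major_axis_mean_um": float(sub["major_axis_um"].mean()) if len(sub) else np.nan,
                "major_axis_sd_um": float(sub["major_axis_um"].std(ddof=1)) if len(sub) > 1 else 0.0,
                "sii_mean": float(sub["sii"].mean()) if len(sub) else np.nan,
                "pdi_percent": pdi(sub["area_um2"].to_numpy()) if len(sub) else np.nan,
                "branched_fraction_percent": (
                    100.0 * float((sub["classification"] == "branched").mean())
                    if len(sub)
                    else np.nan
                ),
                "droplet_diameter_mean_um": float(np.mean(droplet_diams.get(day, [np.nan]))),
                "droplet_compactness_mean": float(np.mean(droplet_comp.get(day, [np.nan]))),
                "contraction_percent": float(con["contraction_percent"].iloc[0]) if len(con) else np.nan,
                "contraction_ci_low": float(con["ci_low"].iloc[0]) if len(con) else np.nan,
                "contraction_ci_high": float(con["ci_high"].iloc[0]) if len(con) else np.nan,
                "min_distance_mean": float(np.mean(min_dists.get(day, [np.nan]))),
                "radial_position_mean": float(np.mean(radials.get(day, [np.nan]))),
            }
        )
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)

    occupancy_report = None
    if cfg.mode == "synthetic" and cfg.synthetic is not None:
        scfg = cfg.synthetic
        if scfg.cell_concentration_per_ml > 0:
            dist = occupancy(
                EncapsulationConfig(
                    droplet_diameter_um=scfg.droplet_diameter_um,
                    cell_concentration_per_ml=scfg.cell_concentration_per_ml,
                )
            )
            occupancy_report = {
                "lambda_cells": dist.lambda_cells,
                "p_empty": dist.p_empty,
                "p_single": dist.p_single,
                "p_multi": dist.p_multi,
            }

    features_path = os.path.join(cfg.out_dir, "features.csv")
    summary_path = os.path.join(cfg.out_dir, "summary_by_day.csv")
    report_path = os.path.join(cfg.out_dir, "run_report.json")
    features.to_csv(features_path, index=False, float_format="%.6f")
    summary.to_csv(summary_path, index=False, float_format="%.6f")
    report = {
        "dropmorph_version": dropmorph.__version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "n_frames": len(frames),
        "n_structures": int(len(features)),
        "occupancy": occupancy_report,
    }
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    return {
        "features": features,
        "summary": summary,
        "occupancy": occupancy_report,
        "paths": {
            "features": features_path,
            "summary": summary_path,
            "report": report_path,
        },
    }
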