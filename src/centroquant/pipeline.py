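"""End-to-end pipeline: structured configuration, orchestration, report.

A run is described by one :class:`RunConfig` (YAML-serialisable, flat
key/value with a few nested tuples); every parameter defaults to the
convention documented in its stage module, and all randomness derives
from the single master seed, so identical config + seed ⇒ identical
outputs.  The :class:`RunReport` written as ``report.json`` is a summary:
every number in it is recomputable from the per-stage CSVs persisted next
to it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .coloc import proximity_fraction
from .detect import (
    assign_centrosome,
    call_detectable,
    cells_from_field,
    cells_from_segmentation,
    classify_zone,
    detect_spots,
    estimate_wound_edge,
    pair_centrioles,
    segment_nuclei,
    spots_to_dataframe,
)
from .errors import CentroquantError, PipelineError
from .intensity import aggregate_by_image, net_integrated_density, records_to_dataframe
from .orient import orientation_pipeline
from .stacks import project_z_sd, write_stack
from .synth import generate_field, preset_config, render_stack

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Full configuration of one analysis run.

    ``mode='coords'`` analyses the generator's ground-truth coordinate
    tables directly (or user-supplied CSVs); ``mode='render'`` renders
    the field to an image stack and runs the full imaging chain
    (projection, segmentation, spot detection) before the statistics.
    """

    # input / simulation
    preset: str = "control"            # control | depleted | uniform
    mode: str = "coords"               # coords | render
    n_cells: int = 200
    kappa: Optional[float] = None      # overrides the preset when set
    mu_deg: float = 0.0
    spots_per_cell: int = 20
    centrosome_spot_fraction: float = 0.3
    seed: int = 0
    cells_csv: Optional[str] = None    # external coordinate tables bypass
    spots_csv: Optional[str] = None    # the generator entirely

    # channel map
    nuclei_channel: str = "dapi"
    centrosome_channel: str = "centrosome"
    fish_channel: str = "fish"

    # stage parameters (paper-derived conventions as defaults)
    sector_halfwidth_deg: float = 75.0
    rose_bin_deg: float = 15.0
    coloc_radius_um: float = 2.0
    pairing_radius_um: float = 1.0
    assign_max_dist_um: float = 15.0
    d_outer_um: Optional[float] = None  # None → 1.5 × median nucleus diameter
    detect_sigma_um: tuple = (0.7, 0.3, 0.3)
    threshold_k: float = 5.0
    roi_diameter_um: float = 2.0
    background_strategy: str = "offset-roi"
    agg_min_cells: int = 5
    agg_max_cells: int = 20

    out_dir: Optional[str] = None
    write_images: bool = False

    # ------------------------------------------------------------------
    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["detect_sigma_um"] = list(self.detect_sigma_um)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "detect_sigma_um" in data:
            data["detect_sigma_um"] = tuple(data["detect_sigma_um"])
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Check every invariant; returns a list of problems (empty = valid).

    Never raises — callers decide whether problems are fatal.
    """
    problems: list[str] = []
    if config.preset not in ("control", "depleted", "uniform"):
        problems.append(f"preset: unknown preset {config.preset!r}")
    if config.mode not in ("coords", "render"):
        problems.append(f"mode: must be 'coords' or 'render', got {config.mode!r}")
    if config.n_cells < 0:
        problems.append("n_cells: must be >= 0")
    if config.kappa is not None and config.kappa < 0:
        problems.append("kappa: von Mises concentration must be >= 0")
    if not 0.0 <= config.centrosome_spot_fraction <= 1.0:
        problems.append("centrosome_spot_fraction: must be in [0, 1]")
    if config.spots_per_cell < 0:
        problems.append("spots_per_cell: must be >= 0")
    if not 0.0 < config.sector_halfwidth_deg <= 180.0:
        problems.append("sector_halfwidth_deg: must be in (0, 180]")
    if config.rose_bin_deg <= 0 or abs(
        360.0 / config.rose_bin_deg - round(360.0 / config.rose_bin_deg)
    ) > 1e-9:
        problems.append("rose_bin_deg: must divide 360 evenly")
    for name in ("coloc_radius_um", "pairing_radius_um", "assign_max_dist_um",
                 "roi_diameter_um", "threshold_k"):
        if getattr(config, name) <= 0:
            problems.append(f"{name}: must be > 0")
    if config.d_outer_um is not None and config.d_outer_um <= 0:
        problems.append("d_outer_um: must be > 0 when set")
    if any(s <= 0 for s in config.detect_sigma_um):
        problems.append("detect_sigma_um: all scales must be > 0")
    if config.background_strategy not in ("offset-roi", "annulus"):
        problems.append("background_strategy: must be 'offset-roi' or 'annulus'")
    if config.agg_min_cells < 1 or config.agg_max_cells < config.agg_min_cells:
        problems.append("agg_min_cells/agg_max_cells: need 1 <= min <= max")
    if (config.cells_csv is None) != (config.spots_csv is None) and (
        config.spots_per_cell > 0
    ):
        problems.append("cells_csv/spots_csv: supply both tables or neither")
    return problems


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    version: str
    seed: int
    counts: dict
    orientation: Optional[dict] = None
    detectable_pct_outer: Optional[float] = None
    intensity: Optional[dict] = None
    coloc: Optional[dict] = None

    def to_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True))
        return path


def _json_safe(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and (optionally) persist all outputs.

    Stage order: simulate → [render → project → detect] → orient /
    intensity / coloc.  Any stage failure is re-raised as
    :class:`PipelineError` naming the stage.  Identical config + seed
    yields an identical report and identical output files.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    counts: dict = {}
    synth_kwargs = dict(
        n_cells=config.n_cells,
        mu_deg=config.mu_deg,
        spots_per_cell=config.spots_per_cell,
        centrosome_spot_fraction=config.centrosome_spot_fraction,
        coloc_radius_um=config.coloc_radius_um,
        seed=config.seed,
    )
    if config.kappa is not None:
        synth_kwargs["kappa"] = config.kappa

    # ---- simulate (or load external tables) --------------------------
    try:
        if config.cells_csv is not None:
            from .detect import cells_from_table

            cells = cells_from_table(pd.read_csv(config.cells_csv))
            spots = (pd.read_csv(config.spots_csv)
                     if config.spots_csv else pd.DataFrame(
                         columns=["spot_id", "cell_id", "channel",
                                  "z_um", "y_um", "x_um"]))
            field = None
            scfg = None
        else:
            scfg = preset_config(config.preset, **synth_kwargs)
            field = generate_field(scfg)
            cells = cells_from_field(field)
            spots = field.spots
            if out:
                field.write_csv(out)
    except CentroquantError as exc:
        raise PipelineError("simulate", str(exc)) from exc
    counts["cells_in"] = len(cells)
    counts["spots_in"] = len(spots)

    detectable_pct = None
    intensity_summary = None

    # ---- imaging chain (render mode) ---------------------------------
    if config.mode == "render" and field is not None:
        try:
            stack = render_stack(field)
            origin = np.array(stack.origin_um)
            if out and config.write_images:
                write_stack(out / "stack.ome.tif", stack)

            nuc_proj = project_z_sd(stack, config.nuclei_channel)
            vz, vy, vx = stack.voxel_um
            labels, seg_table = segment_nuclei(nuc_proj, (vy, vx))
            # segmentation coordinates are in the stack frame; shift back
            # to the field frame for comparison with ground truth
            seg_table = seg_table.copy()
            seg_table["centroid_y_um"] += origin[1]
            seg_table["centroid_x_um"] += origin[2]
            cells = cells_from_segmentation(seg_table)

            raw_spots = detect_spots(stack, config.centrosome_channel,
                                     sigma_um=config.detect_sigma_um,
                                     threshold_k=config.threshold_k)
            raw_spots.coords_um = raw_spots.coords_um + origin
            centrosomes = pair_centrioles(raw_spots, config.pairing_radius_um)
            cells = assign_centrosome(cells, centrosomes,
                                      config.assign_max_dist_um)
            diam = cells["equiv_diameter_um"].to_numpy(float)
            inset = 0.5 * float(np.nanmedian(diam)) if np.isfinite(diam).any() else 0.0
            wound = estimate_wound_edge(
                cells[["nucleus_y_um", "nucleus_x_um"]].to_numpy(float),
                edge_inset_um=inset,
            )
            cells = classify_zone(cells, wound, config.d_outer_um)
            cells, detectable_pct = call_detectable(cells, centrosomes,
                                                    config.threshold_k)
            counts["nuclei_segmented"] = len(cells)
            counts["centrosomes_detected"] = len(centrosomes)

            if config.spots_per_cell > 0:
                fish = detect_spots(stack, config.fish_channel,
                                    sigma_um=config.detect_sigma_um,
                                    threshold_k=config.threshold_k)
                fish.coords_um = fish.coords_um + origin
                fish_df = spots_to_dataframe(fish)
                # assign each smFISH spot to the nearest nucleus centroid
                from scipy.spatial import cKDTree

                tree = cKDTree(cells[["nucleus_y_um",
                                      "nucleus_x_um"]].to_numpy(float))
                _, idx = tree.query(fish.coords_um[:, 1:3])
                fish_df["cell_id"] = cells["cell_id"].to_numpy()[idx]
                spots = fish_df
                counts["fish_spots_detected"] = len(fish_df)
            else:
                spots = pd.DataFrame(columns=spots.columns)

            # intensity quantification on the summed marker projection
            marker_proj = stack.channel(config.centrosome_channel).sum(axis=0)
            records = []
            for row in cells.itertuples(index=False):
                if not np.isfinite(row.centrosome_y_um):
                    continue
                records.append(net_integrated_density(
                    marker_proj,
                    (row.centrosome_y_um - origin[1],
                     row.centrosome_x_um - origin[2]),
                    (vy, vx),
                    diameter_um=config.roi_diameter_um,
                    strategy=config.background_strategy,
                    cell_id=row.cell_id,
                    marker=config.centrosome_channel,
                    image_id=f"seed{config.seed}",
                ))
            if records:
                rec_df = records_to_dataframe(records)
                agg = aggregate_by_image(records, config.agg_min_cells,
                                         config.agg_max_cells)
                intensity_summary = {
                    "n_measured": int((~rec_df["flagged"]).sum()),
                    "n_flagged": int(rec_df["flagged"].sum()),
                    "mean_net": float(
                        rec_df.loc[~rec_df["flagged"], "net"].mean()),
                    "per_image": agg.to_dict(orient="records"),
                }
                if out:
                    rec_df.to_csv(out / "intensity.csv", index=False)
                    agg.to_csv(out / "intensity_by_image.csv", index=False)
        except CentroquantError as exc:
            raise PipelineError("detect", str(exc)) from exc

    counts["cells_outer"] = int((cells["zone"] == "outer").sum())
    counts["cells_inner"] = int((cells["zone"] == "inner").sum())
    counts["cells_with_centrosome"] = int(cells["centrosome_y_um"].notna().sum())
    if out:
        cells.to_csv(out / "cells_detected.csv", index=False)
        if len(spots):
            spots.to_csv(out / "spots_detected.csv", index=False)

    # ---- orientation --------------------------------------------------
    try:
        result, angle_table = orientation_pipeline(
            cells, condition=config.preset,
            sector_halfwidth_deg=config.sector_halfwidth_deg)
    except CentroquantError as exc:
        raise PipelineError("orient", str(exc)) from exc
    if out:
        angle_table.to_csv(out / "orientation.csv", index=False)
        (out / "orientation_summary.json").write_text(
            json.dumps(result.summary_dict(), indent=2, sort_keys=True,
                       default=_json_safe))

    # ---- colocalization ----------------------------------------------
    coloc_summary = None
    if len(spots):
        try:
            records, excluded = proximity_fraction(
                spots, cells, config.coloc_radius_um)
        except CentroquantError as exc:
            raise PipelineError("coloc", str(exc)) from exc
        props = [r.proportion for r in records]
        coloc_summary = {
            "n_cells": len(records),
            "mean_proportion": float(np.mean(props)) if props else None,
            "excluded": excluded,
        }
        if out:
            pd.DataFrame({
                "condition": config.preset,
                "cell_id": [r.cell_id for r in records],
                "n_spots": [r.n_spots for r in records],
                "n_near": [r.n_near for r in records],
                "proportion": props,
            }).to_csv(out / "coloc.csv", index=False)

    report = RunReport(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()},
        version=_version,
        seed=config.seed,
        counts=counts,
        orientation=json.loads(json.dumps(result.summary_dict(),
                                          default=_json_safe)),
        detectable_pct_outer=detectable_pct,
        intensity=intensity_summary,
        coloc=coloc_summary,
    )
    if out:
        report.to_json(out / "report.json")
    return report
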