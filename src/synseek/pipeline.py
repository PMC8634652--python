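"""End-to-end orchestration: preprocess -> segment -> detect -> shortlist
-> schedule -> quantify.

These functions are the library behind the command-line interface.  A run
is fully determined by its inputs and parameters; exports are plain CSV /
JSON so an acquisition plan can be handed to microscope-control software
and the ROI table reviewed elsewhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import NormalizationParams, preprocess_plane
from .quant import AreaStats, ImagingPlan, QuantReport, density_and_folds, imaging_time, measure_areas
from .roi import (
    AlignmentTransform,
    Box,
    CandidateROI,
    ROISeries,
    TargetArea,
    bind_series,
    continuity_filter,
    detect_overlaps,
    full_frame_target_area,
    make_fov_boxes,
    merge_fov_boxes,
    rasterize_target_area,
    reject_interior,
)
from .segment import BinaryMask, ThresholdParams, binarize_channel, dilate_mask
from .stack import SectionStack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Everything the detection stages need beyond the images themselves.

    fov_um is the super-resolution field of view (33 um by default, a
    typical SIM tile at 100x); match_radius defaults to the dilation
    radius plus two pixels; interior_margin is the both-channel depth (px)
    beyond which an overlap counts as a large-structure interior.
    """

    normalization: NormalizationParams = NormalizationParams()
    threshold: ThresholdParams = ThresholdParams()
    fov_um: float = 33.0
    match_radius: float = 3.0
    interior_margin: float = 5.0
    n_neighbors: int = 1  # sections bound on each side of a series anchor
    neighbor_span: int = 1  # sections examined by the continuity filter
    minutes_per_tile: float = 3.0


@dataclass
class DetectionResult:
    """All artefacts of a detection run, in memory."""

    candidates: list[CandidateROI]
    shortlisted: list[CandidateROI]
    series: list[ROISeries]
    merged_boxes: dict[int, list[Box]]  # per section, the acquisition cover
    plan_tiles: pd.DataFrame  # one row per scheduled SIM tile
    raw_masks: dict[str, list[BinaryMask]]  # undilated, per channel role
    dilated_masks: dict[str, list[BinaryMask]]
    counts: dict[str, int]
    params: DetectionParams


def segment_stack(
    stack: SectionStack, params: DetectionParams
) -> tuple[dict[str, list[BinaryMask]], dict[str, list[BinaryMask]]]:
    """Preprocess and binarize every channel of every section.

    Returns (raw, dilated) masks keyed by channel role.
    """
    raw: dict[str, list[BinaryMask]] = {role: [] for role in stack.channels}
    dilated: dict[str, list[BinaryMask]] = {role: [] for role in stack.channels}
    for z in range(stack.n_sections):
        for role in stack.channels:
            plane = preprocess_plane(stack.plane(z, role), params.normalization)
            mask = binarize_channel(plane, params.threshold, section=z, channel=role)
            raw[role].append(mask)
            dilated[role].append(dilate_mask(mask))
    return raw, dilated


def run_detect(
    stack: SectionStack,
    target_areas: Sequence[TargetArea] | None = None,
    transforms: Sequence[AlignmentTransform] | None = None,
    params: DetectionParams = DetectionParams(),
) -> DetectionResult:
    """Detect, shortlist and schedule putative synapse ROIs on a stack."""
    if transforms is None:
        # Pre-aligned stack: local pixels map to global um by the pixel size.
        transforms = [
            AlignmentTransform.scaling(stack.pixel_size_um) for _ in range(stack.n_sections)
        ]
    if len(transforms) != stack.n_sections:
        raise ValueError("one alignment transform per section required")
    if target_areas is None:
        target_areas = [full_frame_target_area("all", stack.shape, transforms[0])]

    fov_px = max(1, int(round(params.fov_um / stack.pixel_size_um)))
    h, w = stack.shape
    if fov_px > min(h, w):
        raise ValueError(
            f"FOV of {fov_px} px exceeds the {h}x{w} px section; "
            "reduce fov_um or use a larger stack"
        )

    raw, dil = segment_stack(stack, params)

    candidates: list[CandidateROI] = []
    next_id = 0
    n_interior = 0
    for z in range(stack.n_sections):
        axon_m, dend_m = dil["axon"][z], dil["dendrite"][z]
        for area in target_areas:
            if not area.covers_section(z):
                continue
            region = rasterize_target_area(area, stack.shape, transforms[z])
            components = detect_overlaps(axon_m, dend_m, region)
            boxes = make_fov_boxes(components, fov_px, stack.shape)
            for comp, box in zip(components, boxes):
                cand = CandidateROI(
                    id=next_id,
                    section=z,
                    pixels=comp,
                    centroid=(float(comp[:, 1].mean()), float(comp[:, 0].mean())),
                    fov_box=box,
                    target_area=area.name,
                )
                cand.interior_of_large_structure = reject_interior(
                    cand, axon_m, dend_m, params.interior_margin
                )
                if cand.interior_of_large_structure:
                    n_interior += 1
                next_id += 1
                candidates.append(cand)

    # Continuity is judged on the undilated masks: dilation absorbs the
    # survey's localization error during overlap detection, but evidence
    # that a structure reappears in a neighbouring section should not be
    # inflated by it (a dilated noise speck covers 9 pixels).
    surface = [c for c in candidates if not c.interior_of_large_structure]
    kept = continuity_filter(
        surface,
        raw["axon"],
        raw["dendrite"],
        transforms,
        match_radius=params.match_radius,
        neighbor_span=params.neighbor_span,
    )
    n_continuity_rejected = len(surface) - len(kept)

    series = [
        bind_series(c, params.n_neighbors, stack.n_sections, transforms, stack.shape)
        for c in kept
    ]

    # Acquisition cover: merge the shortlisted FOV boxes per section, then
    # bind each merged tile to its neighbouring sections like an ROI series.
    merged: dict[int, list[Box]] = {}
    plan_rows = []
    tile_id = 0
    for z in range(stack.n_sections):
        sect = [c for c in kept if c.section == z]
        if not sect:
            continue
        pixels = np.vstack([c.pixels for c in sect])
        boxes = [c.fov_box for c in sect]
        cover = merge_fov_boxes(boxes, pixels, fov_px, stack.shape)
        merged[z] = cover
        for box in cover:
            anchor = CandidateROI(
                id=-1, section=z, pixels=pixels, centroid=box.center, fov_box=box
            )
            bound = bind_series(anchor, params.n_neighbors, stack.n_sections, transforms, stack.shape)
            for nz, nbox in bound.entries:
                gx, gy = transforms[nz].to_global(nbox.center)
                plan_rows.append(
                    {
                        "tile_id": tile_id,
                        "anchor_section": z,
                        "section": nz,
                        "x0": nbox.x0, "y0": nbox.y0, "x1": nbox.x1, "y1": nbox.y1,
                        "global_x_um": gx, "global_y_um": gy,
                    }
                )
                tile_id += 1
    plan_tiles = pd.DataFrame(
        plan_rows,
        columns=["tile_id", "anchor_section", "section",
                 "x0", "y0", "x1", "y1", "global_x_um", "global_y_um"],
    )

    counts = {
        "detected": len(candidates),
        "interior_rejected": n_interior,
        "continuity_rejected": n_continuity_rejected,
        "shortlisted": len(kept),
        "scheduled_tiles": len(plan_tiles),
    }
    assert counts["shortlisted"] == (
        counts["detected"] - counts["interior_rejected"] - counts["continuity_rejected"]
    )
    logger.info("detection counts: %s", counts)
    return DetectionResult(
        candidates=candidates,
        shortlisted=kept,
        series=series,
        merged_boxes=merged,
        plan_tiles=plan_tiles,
        raw_masks=raw,
        dilated_masks=dil,
        counts=counts,
        params=params,
    )


def roi_table(result: DetectionResult, transforms: Sequence[AlignmentTransform]) -> pd.DataFrame:
    """Flat ROI table: one row per detected candidate, with flags."""
    series_of = {s.anchor.id: i for i, s in enumerate(result.series)}
    rows = []
    for c in result.candidates:
        gx, gy = transforms[c.section].to_global(c.centroid)
        rows.append(
            {
                "id": c.id,
                "section": c.section,
                "local_x_px": c.centroid[0],
                "local_y_px": c.centroid[1],
                "global_x_um": gx,
                "global_y_um": gy,
                "box_x0": c.fov_box.x0, "box_y0": c.fov_box.y0,
                "box_x1": c.fov_box.x1, "box_y1": c.fov_box.y1,
                "target_area": c.target_area,
                "interior_of_large_structure": c.interior_of_large_structure,
                "has_continuity": bool(c.has_continuity),
                "shortlisted": c.shortlisted,
                "series_id": series_of.get(c.id, -1),
                "n_overlap_px": len(c.pixels),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "section", "local_x_px", "local_y_px", "global_x_um", "global_y_um",
                 "box_x0", "box_y0", "box_x1", "box_y1", "target_area",
                 "interior_of_large_structure", "has_continuity", "shortlisted",
                 "series_id", "n_overlap_px"],
    )


def export_detection(
    result: DetectionResult,
    transforms: Sequence[AlignmentTransform],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the ROI table, acquisition plan, counts and a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = roi_table(result, transforms)
    paths = {
        "rois_csv": out_dir / "rois.csv",
        "rois_json": out_dir / "rois.json",
        "plan_csv": out_dir / "acquisition_plan.csv",
        "counts": out_dir / "counts.json",
        "manifest": out_dir / "manifest.json",
    }
    table.to_csv(paths["rois_csv"], index=False)
    paths["rois_json"].write_text(table.to_json(orient="records", indent=1))
    result.plan_tiles.to_csv(paths["plan_csv"], index=False)
    paths["counts"].write_text(json.dumps(result.counts, indent=1, sort_keys=True))
    params_dict = dataclasses.asdict(result.params)
    manifest = {
        "synseek_version": __version__,
        "seed": seed,
        "params": params_dict,
        "params_sha256": hashlib.sha256(
            json.dumps(params_dict, sort_keys=True).encode()
        ).hexdigest(),
        "counts": result.counts,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths


def run_quant(
    result: DetectionResult,
    stack: SectionStack,
    target_areas: Sequence[TargetArea],
    transforms: Sequence[AlignmentTransform],
    confirmations: dict[int, bool] | None = None,
) -> tuple[QuantReport | dict[str, AreaStats], ImagingPlan, ImagingPlan]:
    """Quantify structure areas, confirmed synapse counts and imaging cost.

    ``confirmations`` maps shortlisted candidate ids to the verdict of
    visual review (True = confirmed synapse); omitted ids count as
    unconfirmed, unknown ids are rejected.  With two or more target areas
    the report carries fold ratios; with one, the bare per-area stats are
    returned.  Also returns the full-grid and targeted imaging plans.
    """
    known = {c.id for c in result.shortlisted}
    confirmations = dict(confirmations or {})
    unknown = set(confirmations) - known
    if unknown:
        raise ValueError(f"confirmation refers to unknown/unshortlisted ROI ids: {sorted(unknown)}")

    areas: dict[str, AreaStats] = {}
    for area in target_areas:
        stats = measure_areas(
            result.raw_masks["dendrite"],
            result.raw_masks["axon"],
            area,
            transforms,
            stack.pixel_size_um,
        )
        stats.synapse_count = sum(
            1
            for c in result.shortlisted
            if c.target_area == area.name and confirmations.get(c.id, False)
        )
        areas[area.name] = stats

    h, w = stack.shape
    full = imaging_time(
        width_um=w * stack.pixel_size_um,
        height_um=h * stack.pixel_size_um,
        fov_um=result.params.fov_um,
        minutes_per_tile=result.params.minutes_per_tile,
        n_sections=stack.n_sections,
    )
    targeted = imaging_time(
        width_um=w * stack.pixel_size_um,
        height_um=h * stack.pixel_size_um,
        fov_um=result.params.fov_um,
        minutes_per_tile=result.params.minutes_per_tile,
        n_sections=stack.n_sections,
        targeted_tiles=len(result.plan_tiles),
    )
    if len(areas) >= 2:
        report = density_and_folds(areas, stack.pixel_size_um)
    else:
        report = QuantReport(areas=areas, pixel_size_um=stack.pixel_size_um)
    return report, full, targeted
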