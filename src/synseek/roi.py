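"""Overlap-site detection, FOV scheduling and cross-section shortlisting.

Putative synapses are the places where presynaptic axon foreground and
postsynaptic dendrite foreground overlap inside a named target area (a
cortical layer outline).  Each overlap connected component becomes a
candidate with a super-resolution field-of-view (FOV) box centred on it.
Candidates are then pruned by two structural rules:

* interior rejection — an overlap sitting deep inside large foreground of
  *both* channels is a crossing through thick structures, not a contact
  at their surfaces, and is discarded;
* continuity — neurites are continuous processes, so both the axon and
  the dendrite signal must reappear at the same global coordinate (within
  a small radius) in at least one neighbouring section; isolated
  single-section blobs are staining noise.

Survivors are bound into ROI series (the same slide coordinate on 1-2
preceding and following sections, 3-5 images per series) and the
per-section FOV boxes are merged into a minimal-overlap cover — the
acquisition plan handed to the super-resolution microscope.

Coordinate conventions: pixel-centred, 0-based; boxes are half-open
``[x0, x1) x [y0, y1)``.  Global coordinates are micrometres in the slide
frame, reached through each section's affine alignment transform.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon, box as shapely_box

from .segment import BinaryMask

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class Box:
    """Half-open pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1 - 1) / 2.0, (self.y0 + self.y1 - 1) / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class TargetArea:
    """Named polygonal detection region (e.g. cortical layer L4 or L5).

    The polygon lives in global (slide) coordinates, micrometres; the
    section range restricts which sections are searched.
    """

    name: str
    polygon: Polygon
    section_range: tuple[int, int] | None = None  # inclusive; None = all

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"target area {self.name!r}: polygon must be simple and nonempty")
        if self.polygon.area <= 0:
            raise ValueError(f"target area {self.name!r}: polygon area must be nonzero")

    def covers_section(self, z: int) -> bool:
        if self.section_range is None:
            return True
        lo, hi = self.section_range
        return lo <= z <= hi


@dataclass(frozen=True)
class AlignmentTransform:
    """Invertible planar affine mapping section-local pixels to global
    micrometre slide coordinates: ``(gx, gy) = A @ (x, y) + b``.

    Coefficients are ``(a, b, c, d, e, f)`` for
    ``gx = a*x + b*y + c``, ``gy = d*x + e*y + f``.
    """

    coefficients: tuple[float, float, float, float, float, float] = (1, 0, 0, 0, 1, 0)

    def __post_init__(self) -> None:
        a, b, _, d, e, _ = self.coefficients
        if abs(a * e - b * d) < 1e-12:
            raise ValueError("singular alignment transform")

    @classmethod
    def identity(cls) -> "AlignmentTransform":
        return cls()

    @classmethod
    def scaling(cls, s: float) -> "AlignmentTransform":
        return cls((s, 0, 0, 0, s, 0))

    def to_global(self, point: tuple[float, float]) -> tuple[float, float]:
        a, b, c, d, e, f = self.coefficients
        x, y = point
        return (a * x + b * y + c, d * x + e * y + f)

    def to_local(self, point: tuple[float, float]) -> tuple[float, float]:
        a, b, c, d, e, f = self.coefficients
        gx, gy = point
        det = a * e - b * d
        x = (e * (gx - c) - b * (gy - f)) / det
        y = (-d * (gx - c) + a * (gy - f)) / det
        return (x, y)


def to_global(point: tuple[float, float], transform: AlignmentTransform) -> tuple[float, float]:
    """Map a section-local pixel point to global slide coordinates (um)."""
    return transform.to_global(point)


def to_local(point: tuple[float, float], transform: AlignmentTransform) -> tuple[float, float]:
    """Inverse of :func:`to_global`; round-trips to < 1e-6 px."""
    return transform.to_local(point)


@dataclass
class CandidateROI:
    """One axon-dendrite overlap site on one section."""

    id: int
    section: int
    pixels: np.ndarray  # (n, 2) array of (y, x) overlap pixel coordinates
    centroid: tuple[float, float]  # (x, y), pixel units
    fov_box: Box
    target_area: str = ""
    interior_of_large_structure: bool = False
    has_continuity: bool | None = None  # None until the filter has run

    @property
    def shortlisted(self) -> bool:
        return not self.interior_of_large_structure and bool(self.has_continuity)


@dataclass
class ROISeries:
    """A shortlisted candidate bound to the same slide coordinate on its
    neighbouring sections (3-5 entries)."""

    anchor: CandidateROI
    entries: list[tuple[int, Box]]  # (section, box in that section's local frame)

    @property
    def length(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Detection


def rasterize_target_area(
    area: TargetArea,
    shape: tuple[int, int],
    transform: AlignmentTransform,
) -> np.ndarray:
    """Boolean pixel mask of the target-area polygon in one section's frame.

    A pixel belongs to the area when its centre, mapped to global
    coordinates, falls inside the polygon.
    """
    h, w = shape
    minx, miny, maxx, maxy = area.polygon.bounds
    # Map the polygon bounds into local pixel space to limit the test region.
    corners = [(minx, miny), (minx, maxy), (maxx, miny), (maxx, maxy)]
    local = np.array([transform.to_local(c) for c in corners])
    x_lo = max(0, int(math.floor(local[:, 0].min())))
    x_hi = min(w, int(math.ceil(local[:, 0].max())) + 1)
    y_lo = max(0, int(math.floor(local[:, 1].min())))
    y_hi = min(h, int(math.ceil(local[:, 1].max())) + 1)
    mask = np.zeros(shape, dtype=bool)
    if x_lo >= x_hi or y_lo >= y_hi:
        return mask
    xs, ys = np.meshgrid(np.arange(x_lo, x_hi), np.arange(y_lo, y_hi))
    a, b, c, d, e, f = transform.coefficients
    gx = a * xs + b * ys + c
    gy = d * xs + e * ys + f
    from shapely import contains_xy

    inside = contains_xy(area.polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    mask[y_lo:y_hi, x_lo:x_hi] = inside
    return mask


def detect_overlaps(
    axon_mask: BinaryMask,
    dendrite_mask: BinaryMask,
    target_area_mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Connected components (8-connectivity) of axon AND dendrite foreground.

    Masks are expected dilated.  Returns a list of (n, 2) arrays of (y, x)
    pixel coordinates, ordered by first (topmost, then leftmost) pixel.
    """
    if axon_mask.pixels.shape != dendrite_mask.pixels.shape:
        raise ValueError("axon and dendrite masks have mismatched shapes")
    overlap = axon_mask.pixels & dendrite_mask.pixels
    if target_area_mask is not None:
        if target_area_mask.shape != overlap.shape:
            raise ValueError("target-area mask shape mismatch")
        overlap &= target_area_mask
    labels, n = ndimage.label(overlap, structure=np.ones((3, 3), dtype=bool))
    components = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        components.append(np.column_stack([ys, xs]))
    components.sort(key=lambda c: (int(c[:, 0].min()), int(c[c[:, 0] == c[:, 0].min(), 1].min())))
    return components


def make_fov_boxes(
    components: Sequence[np.ndarray],
    fov_size: int,
    image_shape: tuple[int, int],
) -> list[Box]:
    """One FOV-sized box per component, centred at its centroid (rounded).

    Boxes are clamped to the image bounds by shifting the centre — never
    shrunk — so every exported box has exactly the FOV dimensions.
    """
    if fov_size <= 0:
        raise ValueError("fov_size must be positive")
    h, w = image_shape
    if fov_size > h or fov_size > w:
        raise ValueError(f"FOV {fov_size} exceeds image bounds {image_shape}")
    boxes = []
    for comp in components:
        cy = int(round(float(comp[:, 0].mean())))
        cx = int(round(float(comp[:, 1].mean())))
        x0 = min(max(cx - fov_size // 2, 0), w - fov_size)
        y0 = min(max(cy - fov_size // 2, 0), h - fov_size)
        boxes.append(Box(x0=x0, y0=y0, x1=x0 + fov_size, y1=y0 + fov_size))
    return boxes


def merge_fov_boxes(
    boxes: Sequence[Box],
    overlap_pixels: np.ndarray,
    fov_size: int,
    image_shape: tuple[int, int],
) -> list[Box]:
    """Greedy minimal-overlap cover of the overlap pixels by FOV boxes.

    Repeatedly places the box position covering the most still-uncovered
    pixels, breaking ties toward the topmost then leftmost position, until
    every pixel is covered.  Candidate positions are the canonical anchors
    whose top and left edges coincide with pixel coordinates (clamped to
    the image); any box can be shifted onto such an anchor without losing
    coverage, so the greedy optimum over all positions is preserved.

    Returns at most ``len(boxes)`` boxes and guarantees complete coverage;
    a pixel no FOV-sized box inside the image can reach raises an error.
    """
    overlap_pixels = np.asarray(overlap_pixels)
    if overlap_pixels.size == 0:
        return []
    if overlap_pixels.ndim != 2 or overlap_pixels.shape[1] != 2:
        raise ValueError("overlap_pixels must be an (n, 2) array of (y, x)")
    h, w = image_shape
    ys = overlap_pixels[:, 0].astype(int)
    xs = overlap_pixels[:, 1].astype(int)
    if ys.min() < 0 or xs.min() < 0 or ys.max() >= h or xs.max() >= w:
        raise ValueError("overlap pixel outside image: cannot be covered")
    if boxes:
        covered_by_input = np.zeros(len(ys), dtype=bool)
        for b in boxes:
            covered_by_input |= (ys >= b.y0) & (ys < b.y1) & (xs >= b.x0) & (xs < b.x1)
        if not covered_by_input.all():
            raise ValueError("precondition violated: overlap pixel not covered by any input box")

    # Canonical candidate anchors: top/left edges at pixel coords, clamped.
    cand_y = np.unique(np.clip(ys, 0, h - fov_size))
    cand_x = np.unique(np.clip(xs, 0, w - fov_size))
    uncovered = np.ones(len(ys), dtype=bool)
    result: list[Box] = []
    while uncovered.any():
        uy, ux = ys[uncovered], xs[uncovered]
        # Coverage count for every candidate (y0, x0) pair, vectorized.
        in_y = (uy[None, :] >= cand_y[:, None]) & (uy[None, :] < cand_y[:, None] + fov_size)
        in_x = (ux[None, :] >= cand_x[:, None]) & (ux[None, :] < cand_x[:, None] + fov_size)
        counts = in_y.astype(np.int32) @ in_x.astype(np.int32).T  # (n_cy, n_cx)
        best = np.unravel_index(int(np.argmax(counts)), counts.shape)
        # argmax returns the first maximum in row-major order: topmost, then leftmost.
        y0, x0 = int(cand_y[best[0]]), int(cand_x[best[1]])
        result.append(Box(x0=x0, y0=y0, x1=x0 + fov_size, y1=y0 + fov_size))
        uncovered &= ~((ys >= y0) & (ys < y0 + fov_size) & (xs >= x0) & (xs < x0 + fov_size))
    return result


# ---------------------------------------------------------------------------
# Shortlisting


def reject_interior(
    candidate: CandidateROI,
    axon_mask: BinaryMask,
    dendrite_mask: BinaryMask,
    interior_margin: float = 5.0,
) -> bool:
    """Flag a candidate sitting deep inside large structures of both channels.

    True iff every overlap pixel lies at Euclidean distance greater than
    ``interior_margin`` from the background of *both* masks.  Such overlaps
    are thick-structure crossings rather than surface contacts.
    """
    if interior_margin < 0:
        raise ValueError("interior_margin must be >= 0")
    if interior_margin == 0:
        return False
    dist_a = ndimage.distance_transform_edt(axon_mask.pixels)
    dist_d = ndimage.distance_transform_edt(dendrite_mask.pixels)
    ys, xs = candidate.pixels[:, 0], candidate.pixels[:, 1]
    return bool(
        np.all(dist_a[ys, xs] > interior_margin) and np.all(dist_d[ys, xs] > interior_margin)
    )


def _foreground_near(
    mask: np.ndarray, center_xy: tuple[float, float], radius: float
) -> bool:
    """Any foreground pixel within ``radius`` (px) of a local-frame point?"""
    h, w = mask.shape
    cx, cy = center_xy
    x_lo = max(0, int(math.floor(cx - radius)))
    x_hi = min(w, int(math.ceil(cx + radius)) + 1)
    y_lo = max(0, int(math.floor(cy - radius)))
    y_hi = min(h, int(math.ceil(cy + radius)) + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return False
    window = mask[y_lo:y_hi, x_lo:x_hi]
    if not window.any():
        return False
    yy, xx = np.nonzero(window)
    d2 = (yy + y_lo - cy) ** 2 + (xx + x_lo - cx) ** 2
    return bool(np.any(d2 <= radius**2))


def continuity_filter(
    candidates: Sequence[CandidateROI],
    axon_masks: Sequence[BinaryMask],
    dendrite_masks: Sequence[BinaryMask],
    transforms: Sequence[AlignmentTransform],
    match_radius: float = 5.0,
    neighbor_span: int = 1,
) -> list[CandidateROI]:
    """Keep candidates whose axon AND dendrite signal reappears nearby in a
    neighbouring section.

    The candidate's centroid is mapped through its section's alignment
    transform to global coordinates and back into each neighbour's local
    frame; the neighbour must contain foreground of both structural
    channels within ``match_radius`` pixels.  End sections use their single
    neighbour.  A single-section stack keeps nothing (logged warning).

    Returns the kept candidates; every input candidate has its
    ``has_continuity`` flag set as a side effect.
    """
    if match_radius < 0:
        raise ValueError("match_radius must be >= 0")
    if neighbor_span not in (1, 2):
        raise ValueError("neighbor_span must be 1 or 2")
    n_sections = len(axon_masks)
    if n_sections != len(dendrite_masks) or n_sections != len(transforms):
        raise ValueError("masks and transforms must cover the same sections")
    if n_sections < 2:
        logger.warning("continuity filter on a single-section stack removes all candidates")
        for cand in candidates:
            cand.has_continuity = False
        return []
    kept = []
    for cand in candidates:
        z = cand.section
        global_pt = transforms[z].to_global(cand.centroid)
        found = False
        for dz in range(1, neighbor_span + 1):
            for nb in (z - dz, z + dz):
                if nb < 0 or nb >= n_sections:
                    continue
                local_pt = transforms[nb].to_local(global_pt)
                if _foreground_near(
                    axon_masks[nb].pixels, local_pt, match_radius
                ) and _foreground_near(dendrite_masks[nb].pixels, local_pt, match_radius):
                    found = True
                    break
            if found:
                break
        cand.has_continuity = found
        if found:
            kept.append(cand)
    return kept


def bind_series(
    candidate: CandidateROI,
    n_neighbors: int,
    n_sections: int,
    transforms: Sequence[AlignmentTransform],
    image_shape: tuple[int, int],
) -> ROISeries:
    """Bind a shortlisted candidate to the same slide coordinate on its
    preceding and following sections.

    ``n_neighbors`` is 1 or 2, giving series of length 3 or 5 on interior
    sections; the series truncates at stack ends.  The anchor's FOV-box
    centre is mapped through global coordinates into each neighbour's
    local frame and a box of the same size is placed there (clamped to
    image bounds).
    """
    if n_neighbors not in (1, 2):
        raise ValueError("n_neighbors must be 1 or 2")
    z = candidate.section
    fov_w = candidate.fov_box.width
    fov_h = candidate.fov_box.height
    h, w = image_shape
    global_center = transforms[z].to_global(candidate.fov_box.center)
    entries: list[tuple[int, Box]] = []
    for nz in range(z - n_neighbors, z + n_neighbors + 1):
        if nz < 0 or nz >= n_sections:
            continue
        cx, cy = transforms[nz].to_local(global_center)
        x0 = min(max(int(round(cx)) - fov_w // 2, 0), w - fov_w)
        y0 = min(max(int(round(cy)) - fov_h // 2, 0), h - fov_h)
        entries.append((nz, Box(x0=x0, y0=y0, x1=x0 + fov_w, y1=y0 + fov_h)))
    return ROISeries(anchor=candidate, entries=entries)


# ---------------------------------------------------------------------------
# File interfaces


def save_target_areas(areas: Sequence[TargetArea], path: str | Path) -> None:
    """Write target areas as a GeoJSON-style FeatureCollection (global um)."""
    features = []
    for area in areas:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "name": area.name,
                    "section_range": list(area.section_range) if area.section_range else None,
                },
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [list(map(list, area.polygon.exterior.coords))],
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def load_target_areas(path: str | Path) -> list[TargetArea]:
    data = json.loads(Path(path).read_text())
    areas = []
    for feat in data["features"]:
        rng = feat["properties"].get("section_range")
        areas.append(
            TargetArea(
                name=feat["properties"]["name"],
                polygon=Polygon(feat["geometry"]["coordinates"][0]),
                section_range=tuple(rng) if rng else None,
            )
        )
    return areas


def save_transforms(transforms: Sequence[AlignmentTransform], path: str | Path) -> None:
    """Per-section 6-coefficient affine transforms as a JSON sidecar."""
    Path(path).write_text(
        json.dumps([list(t.coefficients) for t in transforms], indent=0)
    )


def load_transforms(path: str | Path) -> list[AlignmentTransform]:
    return [AlignmentTransform(tuple(c)) for c in json.loads(Path(path).read_text())]


def full_frame_target_area(
    name: str,
    image_shape: tuple[int, int],
    transform: AlignmentTransform,
) -> TargetArea:
    """Target area covering an entire section frame (mapped to global um)."""
    h, w = image_shape
    corners = [(-0.5, -0.5), (w - 0.5, -0.5), (w - 0.5, h - 0.5), (-0.5, h - 0.5)]
    return TargetArea(name=name, polygon=Polygon([transform.to_global(c) for c in corners]))
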