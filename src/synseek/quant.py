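"""Layer-wise synapse quantification, imaging-time arithmetic and
resolution utilities.

Given confirmed synapse locations and the binarized (undilated) channel
masks, this module measures per-target-area structure areas (dendrite,
axon and their intersection, summed over sections), synapse counts and
densities per 100 um^2 of each structure class, and the pairwise fold
ratios between areas (e.g. L5 : L4).  It also computes the acquisition
cost of a full-grid survey versus the targeted plan, the full width at
half maximum of bead intensity profiles, and bilinear line profiles for
figure-style channel inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .roi import TargetArea, rasterize_target_area


@dataclass
class AreaStats:
    """Per-target-area structure measurements (um^2) and synapse counts."""

    name: str
    dendrite_area: float = 0.0
    axon_area: float = 0.0
    intersection_area: float = 0.0
    synapse_count: int = 0

    def density_per_100um2(self, denominator: str = "dendrite") -> float | None:
        """Synapses per 100 um^2 of the chosen structure class.

        Returns None (undefined, not infinity) when the area is zero.
        """
        area = {
            "dendrite": self.dendrite_area,
            "axon": self.axon_area,
            "intersection": self.intersection_area,
        }[denominator]
        if area == 0:
            return None
        return self.synapse_count / area * 100.0


@dataclass
class QuantReport:
    """Per-layer areas, counts, densities and fold ratios."""

    areas: dict[str, AreaStats]
    pixel_size_um: float
    folds: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stats in self.areas.values():
            rows.append(
                {
                    "target_area": stats.name,
                    "dendrite_area_um2": stats.dendrite_area,
                    "axon_area_um2": stats.axon_area,
                    "intersection_area_um2": stats.intersection_area,
                    "synapse_count": stats.synapse_count,
                    "density_per_100um2_dendrite": stats.density_per_100um2("dendrite"),
                    "density_per_100um2_axon": stats.density_per_100um2("axon"),
                    "density_per_100um2_intersection": stats.density_per_100um2("intersection"),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ImagingPlan:
    """Acquisition cost of a full-grid survey vs the targeted plan."""

    mode: str  # "full-grid" or "targeted"
    n_tiles: int
    n_sections: int
    minutes_per_tile: float
    total_hours: float
    percent_saved: int | None = None  # vs full grid; None for the full plan


# ---------------------------------------------------------------------------
# Areas and densities


def measure_areas(
    dendrite_masks,
    axon_masks,
    target_area: TargetArea,
    transforms,
    pixel_size_um: float,
    project_z: bool = False,
) -> AreaStats:
    """Foreground areas within one target area.

    Masks must be the *undilated* binarized channels (dilation exists only
    to protect detection recall and would inflate areas).  Area is
    foreground pixel count times pixel_size^2, and the intersection is the
    per-section conjunction of the two channel masks.  By default areas
    are summed over sections; with ``project_z`` the masks are OR-projected
    along z first and each pixel counts once (requires identical alignment
    across the projected sections to be meaningful).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    px_area = pixel_size_um**2
    stats = AreaStats(name=target_area.name)
    any_area_pixels = False
    proj_d = proj_a = None
    for z, (dmask, amask) in enumerate(zip(dendrite_masks, axon_masks)):
        if not target_area.covers_section(z):
            continue
        region = rasterize_target_area(target_area, dmask.pixels.shape, transforms[z])
        if region.any():
            any_area_pixels = True
        d_in, a_in = dmask.pixels & region, amask.pixels & region
        if project_z:
            proj_d = d_in if proj_d is None else (proj_d | d_in)
            proj_a = a_in if proj_a is None else (proj_a | a_in)
        else:
            stats.dendrite_area += float(d_in.sum()) * px_area
            stats.axon_area += float(a_in.sum()) * px_area
            stats.intersection_area += float((d_in & a_in).sum()) * px_area
    if not any_area_pixels:
        raise ValueError(f"target area {target_area.name!r} rasterizes to zero pixels")
    if project_z and proj_d is not None:
        stats.dendrite_area = float(proj_d.sum()) * px_area
        stats.axon_area = float(proj_a.sum()) * px_area
        stats.intersection_area = float((proj_d & proj_a).sum()) * px_area
    return stats


def density_and_folds(
    areas: dict[str, AreaStats],
    pixel_size_um: float,
    numerator: str | None = None,
    denominator: str | None = None,
) -> QuantReport:
    """Complete a report with densities and pairwise fold ratios.

    Fold ratios are reported for every ordered pair of target areas (or
    only ``numerator`` : ``denominator`` when given) for the synapse count
    and each structure-class area.  Zero denominators give None
    (undefined), never infinity.  No rounding happens here; presentation
    rounding lives in :func:`format_report`.
    """
    if len(areas) < 2:
        raise ValueError("fold ratios need at least two target areas")
    report = QuantReport(areas=areas, pixel_size_um=pixel_size_um)
    names = list(areas)
    pairs = (
        [(numerator, denominator)]
        if numerator is not None and denominator is not None
        else [(a, b) for a in names for b in names if a != b]
    )
    for num, den in pairs:
        a, b = areas[num], areas[den]
        report.folds[f"{num}:{den}"] = {
            "count": _ratio(a.synapse_count, b.synapse_count),
            "dendrite_area": _ratio(a.dendrite_area, b.dendrite_area),
            "axon_area": _ratio(a.axon_area, b.axon_area),
            "intersection_area": _ratio(a.intersection_area, b.intersection_area),
        }
    return report


def _ratio(a: float, b: float) -> float | None:
    return None if b == 0 else a / b


def format_report(report: QuantReport) -> str:
    """Human-readable table with presentation rounding: fold ratios to one
    decimal, count folds truncated to whole multiples."""
    lines = [report.to_frame().to_string(index=False), ""]
    for pair, folds in report.folds.items():
        parts = []
        for key, val in folds.items():
            if val is None:
                parts.append(f"{key}=undefined")
            elif key == "count":
                parts.append(f"{key}={int(val)}x")
            else:
                parts.append(f"{key}={val:.1f}x")
        lines.append(f"fold {pair}: " + ", ".join(parts))
    return "\n".join(lines)


def extrapolate_density(
    density_per_100um2: float,
    areal_expansion_factor: float = 1.6,
    reference_density_per_100um2: float = 50.0,
) -> tuple[float, float]:
    """Scale a per-dendrite-area synapse density to whole-neuropil terms.

    The measured density (synapses per 10 x 10 um^2 of postsynaptic
    neuron area) is multiplied by the areal expansion factor relating
    dendrite+soma area to total unmyelinated-process area, then expressed
    as a percentage of a reference total synapse density for the same
    neuropil.  Returns (extrapolated density, percent of reference).
    """
    extrapolated = density_per_100um2 * areal_expansion_factor
    percent = extrapolated / reference_density_per_100um2 * 100.0
    return extrapolated, percent


# ---------------------------------------------------------------------------
# Imaging time


def imaging_time(
    width_um: float,
    height_um: float,
    fov_um: float,
    minutes_per_tile: float,
    n_sections: int,
    targeted_tiles: int | None = None,
) -> ImagingPlan:
    """Acquisition plan arithmetic.

    Full-grid mode tiles the target extent with ceil(width/fov) x
    ceil(height/fov) tiles on each of ``n_sections`` sections.  When
    ``targeted_tiles`` is given, the targeted plan images only those tiles
    and the percent saved versus the full grid is reported, rounded to the
    nearest integer.
    """
    if fov_um <= 0:
        raise ValueError("fov_um must be positive")
    if width_um <= 0 or height_um <= 0 or minutes_per_tile <= 0 or n_sections <= 0:
        raise ValueError("plan inputs must be positive")
    tiles_per_section = math.ceil(width_um / fov_um) * math.ceil(height_um / fov_um)
    full_tiles = tiles_per_section * n_sections
    full_hours = full_tiles * minutes_per_tile / 60.0
    if targeted_tiles is None:
        return ImagingPlan(
            mode="full-grid",
            n_tiles=full_tiles,
            n_sections=n_sections,
            minutes_per_tile=minutes_per_tile,
            total_hours=full_hours,
        )
    hours = targeted_tiles * minutes_per_tile / 60.0
    saved = round((1.0 - targeted_tiles / full_tiles) * 100.0)
    return ImagingPlan(
        mode="targeted",
        n_tiles=targeted_tiles,
        n_sections=n_sections,
        minutes_per_tile=minutes_per_tile,
        total_hours=hours,
        percent_saved=int(saved),
    )


# ---------------------------------------------------------------------------
# Resolution and profiles


def fwhm(profile: np.ndarray, sample_spacing: float = 1.0) -> float:
    """Full width at half maximum of a unimodal 1-D intensity profile.

    The half level is baseline + (max - baseline) / 2 with the baseline
    taken as the profile minimum; crossings on each side of the peak are
    located by linear interpolation.  Scaling the profile by a constant
    leaves the width unchanged.  Returns the width in the units of
    ``sample_spacing``.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1 or profile.size < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    baseline = profile.min()
    peak = profile.max()
    if peak == baseline:
        raise ValueError("flat profile has no defined width")
    half = baseline + (peak - baseline) / 2.0
    i_peak = int(np.argmax(profile))

    def cross(idx_range) -> float:
        prev = None
        for i in idx_range:
            if prev is not None and (profile[prev] - half) * (profile[i] - half) <= 0:
                lo, hi = (prev, i) if profile[prev] <= profile[i] else (i, prev)
                # linear interpolation between the bracketing samples
                f = (half - profile[prev]) / (profile[i] - profile[prev])
                return prev + f * (i - prev)
            prev = i
        raise ValueError("profile does not fall to half maximum on both sides of the peak")

    left = cross(range(i_peak, -1, -1))
    right = cross(range(i_peak, profile.size))
    return abs(right - left) * sample_spacing


def line_profile(
    planes: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
) -> pd.DataFrame:
    """Bilinear-sampled intensities along a segment, one column per channel.

    ``planes`` is (n_channels, h, w); ``start`` / ``end`` are (x, y) pixel
    coordinates inside the image.  Samples are taken at unit-pixel spacing
    along the segment: ceil(length) + 1 samples including both endpoints.
    """
    planes = np.asarray(planes, dtype=np.float64)
    if planes.ndim == 2:
        planes = planes[None]
    h, w = planes.shape[1:]
    for (x, y) in (start, end):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"endpoint ({x}, {y}) outside image")
    length = math.hypot(end[0] - start[0], end[1] - start[1])
    if length == 0:
        raise ValueError("zero-length line")
    n = math.ceil(length) + 1
    ts = np.linspace(0.0, 1.0, n)
    xs = start[0] + ts * (end[0] - start[0])
    ys = start[1] + ts * (end[1] - start[1])
    data = {"distance_px": ts * length}
    for c in range(planes.shape[0]):
        data[f"channel_{c}"] = ndimage.map_coordinates(
            planes[c], np.vstack([ys, xs]), order=1, mode="nearest"
        )
    return pd.DataFrame(data)
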