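"""Synthetic serial-section phantoms with known ground truth.

The generator emulates the specimen geometry the pipeline is built for:
a resin-embedded cortical volume cut into 90 nm serial sections and
surveyed at low magnification in three fluorescence channels.  Dendrites
and axons are rendered as capsule tubes (cylinder with hemispherical
caps) with Gaussian cross-sectional intensity whose full width at half
maximum equals the tube diameter.  True synapses are axon-dendrite
contacts (tube surfaces touching, gap 0) carrying a sub-diffraction
synaptic-marker punctum; near-misses are bypassing tube pairs separated
by a 0.1-0.3 um gap and carry no punctum — at survey resolution both
look like overlaps, which is exactly the ambiguity the targeted
re-imaging stage exists to adjudicate.

Nuisance signals mirror real mosaics: a per-tile multiplicative
brightness factor (what the normalization step must cancel), a smooth
planar background gradient, Poisson shot noise and Gaussian read noise.
All randomness flows from one seeded generator, so a fixed seed and
config reproduce the stack byte for byte.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stack import CHANNEL_ROLES, SectionStack, read_stack, write_stack

_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise: counts ~ Poisson(img * poisson_scale) / poisson_scale
    + N(0, gaussian_sd)."""

    gaussian_sd: float = 2.0
    poisson_scale: float = 1.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and noise of a synthetic serial-section stack.

    Distances are micrometres.  ``n_synapses`` true contacts (gap 0, with
    punctum) and ``n_near_misses`` bypasses (gap 0.1-0.3, no punctum) are
    hosted on dendrites round-robin; each event consumes one axon, so
    ``n_axons`` must be at least the event total.  The default lateral
    pixel size of 0.31 um stands in for 20x survey sampling.
    """

    volume_size_um: tuple[float, float, float] = (50.0, 50.0, 3.15)
    section_thickness_um: float = 0.09
    pixel_size_um: float = 0.31
    n_dendrites: int = 10
    n_axons: int = 48
    neurite_radius_um: tuple[float, float] = (0.25, 0.6)
    n_synapses: int = 24
    n_near_misses: int = 24
    near_miss_gap_um: tuple[float, float] = (0.1, 0.3)
    tile_grid: tuple[int, int] = (4, 4)
    tile_brightness_cv: float = 0.1
    background_level: float = 20.0
    background_gradient_amplitude: float = 10.0
    signal_amplitude: float = 100.0
    punctum_fwhm_um: float = 0.3
    noise: NoiseModel = NoiseModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_size_um):
            raise ValueError("volume extents must all be positive")
        if self.section_thickness_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("section thickness and pixel size must be positive")
        for name in ("n_dendrites", "n_axons", "n_synapses", "n_near_misses"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.tile_brightness_cv < 1:
            raise ValueError("tile_brightness_cv must be in [0, 1)")
        n_events = self.n_synapses + self.n_near_misses
        if n_events > self.n_axons:
            raise ValueError("each contact/bypass event needs its own axon: raise n_axons")
        if n_events > 0 and self.n_dendrites == 0:
            raise ValueError("events need at least one dendrite to host them")

    @property
    def n_sections(self) -> int:
        return int(math.ceil(self.volume_size_um[2] / self.section_thickness_um - 1e-9))

    @property
    def plane_shape(self) -> tuple[int, int]:
        w = int(math.ceil(self.volume_size_um[0] / self.pixel_size_um - 1e-9))
        h = int(math.ceil(self.volume_size_um[1] / self.pixel_size_um - 1e-9))
        return h, w


@dataclass
class Neurite:
    """A tube: centerline polyline (n, 3) in um, radius, channel role."""

    id: int
    channel: str  # "dendrite" or "axon"
    radius_um: float
    points: np.ndarray


@dataclass
class GroundTruth:
    """Known synapse/bypass sites and the neurites that form them.

    ``synapses`` has one row per event: id, x/y/z (um), section index,
    axon and dendrite ids, gap (0 for true synapses) and the
    is_true_synapse flag.
    """

    synapses: pd.DataFrame
    neurites: list[Neurite]


# ---------------------------------------------------------------------------
# Geometry


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _spanning_line(
    rng: np.random.Generator, cfg: PhantomConfig, z_band: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """A nearly in-plane line through the volume: (anchor point, unit dir).

    ``z_band`` restricts the anchor depth (used for event-hosting dendrites
    so contacts can sit clear of the first and last sections).
    """
    X, Y, Z = cfg.volume_size_um
    z_band = z_band or (0.25 * Z, 0.75 * Z)
    anchor = np.array(
        [
            rng.uniform(0.15 * X, 0.85 * X),
            rng.uniform(0.15 * Y, 0.85 * Y),
            rng.uniform(*z_band),
        ]
    )
    phi = rng.uniform(0, 2 * math.pi)
    dz = rng.uniform(-0.03, 0.03)  # gentle axial drift, tubes stay in the slab
    direction = _unit(np.array([math.cos(phi), math.sin(phi), dz]))
    return anchor, direction


def _clip_segment(anchor: np.ndarray, direction: np.ndarray, half_length: float,
                  cfg: PhantomConfig) -> np.ndarray:
    """Segment of the given half-length around anchor, clipped to the volume."""
    X, Y, Z = cfg.volume_size_um
    lo, hi = -half_length, half_length
    for axis, extent in enumerate((X, Y, Z)):
        d = direction[axis]
        if abs(d) < 1e-12:
            continue
        t0 = (0.0 - anchor[axis]) / d
        t1 = (extent - anchor[axis]) / d
        t0, t1 = min(t0, t1), max(t0, t1)
        lo, hi = max(lo, t0), min(hi, t1)
    lo, hi = min(lo, 0.0), max(hi, 0.0)
    return np.array([anchor + lo * direction, anchor + hi * direction])


def _sample_radius(rng: np.random.Generator, cfg: PhantomConfig) -> float:
    lo, hi = cfg.neurite_radius_um
    return float(rng.uniform(lo, hi))


def _build_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> GroundTruth:
    X, Y, Z = cfg.volume_size_um
    neurites: list[Neurite] = []
    dendrites: list[tuple[np.ndarray, np.ndarray, float]] = []  # anchor, dir, radius

    z_lo_evt = 3.0 * cfg.section_thickness_um
    z_hi_evt = Z - z_lo_evt
    dend_band = (
        max(0.25 * Z, z_lo_evt + 0.05 * Z),
        min(0.75 * Z, z_hi_evt - 0.05 * Z),
    )
    if dend_band[0] >= dend_band[1]:  # very thin slab: fall back to mid-depth
        dend_band = (0.4 * Z, 0.6 * Z)
    for i in range(cfg.n_dendrites):
        anchor, direction = _spanning_line(rng, cfg, dend_band)
        radius = _sample_radius(rng, cfg)
        seg = _clip_segment(anchor, direction, 0.75 * max(X, Y), cfg)
        neurites.append(Neurite(id=i, channel="dendrite", radius_um=radius, points=seg))
        dendrites.append((anchor, direction, radius))

    n_events = cfg.n_synapses + cfg.n_near_misses
    rows = []
    placed: list[np.ndarray] = []
    axon_id_base = cfg.n_dendrites
    margin_xy = 4.0
    z_lo, z_hi = z_lo_evt, z_hi_evt
    for e in range(n_events):
        is_true = e < cfg.n_synapses
        d_idx = e % cfg.n_dendrites
        d_anchor, d_dir, d_radius = dendrites[d_idx]
        a_radius = _sample_radius(rng, cfg)
        gap = 0.0 if is_true else float(rng.uniform(*cfg.near_miss_gap_um))

        # Find a point on the dendrite axis, interior and clear of earlier
        # events.  The feasible parameter range along the axis is the
        # intersection of one interval per bounding constraint; only the
        # separation from earlier events needs rejection sampling.
        center = None
        for d_try in range(cfg.n_dendrites):
            d_anchor, d_dir, d_radius = dendrites[(d_idx + d_try) % cfg.n_dendrites]
            lo, hi = -np.inf, np.inf
            bounds = (
                (0, margin_xy, X - margin_xy),
                (1, margin_xy, Y - margin_xy),
                (2, z_lo, z_hi),
            )
            for axis, b_lo, b_hi in bounds:
                d = d_dir[axis]
                if abs(d) < 1e-12:
                    if not (b_lo < d_anchor[axis] < b_hi):
                        lo, hi = 1.0, 0.0
                        break
                    continue
                t0 = (b_lo - d_anchor[axis]) / d
                t1 = (b_hi - d_anchor[axis]) / d
                lo, hi = max(lo, min(t0, t1)), min(hi, max(t0, t1))
            if lo >= hi:
                continue
            for _ in range(200):
                cand = d_anchor + rng.uniform(lo, hi) * d_dir
                if placed and min(np.linalg.norm(cand - p) for p in placed) < 3.0:
                    continue
                center = cand
                break
            if center is not None:
                d_idx = (d_idx + d_try) % cfg.n_dendrites
                break
        if center is None:
            raise RuntimeError(
                "could not place all contact events with 3 um separation; "
                "reduce event counts or enlarge the volume"
            )
        placed.append(center)

        # Horizontal normal perpendicular to the dendrite axis; the axon axis
        # is perpendicular to it too, so the centerline clearance is exactly
        # r_d + r_a + gap at this point.
        n_vec = _unit(np.cross(d_dir, np.array([0.0, 0.0, 1.0])))
        if rng.random() < 0.5:
            n_vec = -n_vec
        w_vec = _unit(np.cross(d_dir, n_vec))
        theta = rng.uniform(0.35, 1.2) * (1 if rng.random() < 0.5 else -1)
        a_dir = _unit(math.cos(theta) * d_dir + math.sin(theta) * w_vec)
        offset = d_radius + a_radius + gap
        a_anchor = center + offset * n_vec
        a_seg = _clip_segment(a_anchor, a_dir, 5.0, cfg)
        aid = axon_id_base + e
        neurites.append(Neurite(id=aid, channel="axon", radius_um=a_radius, points=a_seg))

        site = center + d_radius * n_vec  # on the dendrite surface
        section = int(site[2] / cfg.section_thickness_um)
        rows.append(
            {
                "id": e,
                "x_um": float(site[0]),
                "y_um": float(site[1]),
                "z_um": float(site[2]),
                "section": min(section, cfg.n_sections - 1),
                "axon_id": aid,
                "dendrite_id": d_idx,
                "gap_um": gap,
                "is_true_synapse": is_true,
            }
        )

    # Free axons beyond the event-hosting ones.
    for i in range(cfg.n_axons - n_events):
        anchor, direction = _spanning_line(rng, cfg)
        seg = _clip_segment(anchor, direction, 0.75 * max(X, Y), cfg)
        neurites.append(
            Neurite(
                id=axon_id_base + n_events + i,
                channel="axon",
                radius_um=_sample_radius(rng, cfg),
                points=seg,
            )
        )

    columns = [
        "id", "x_um", "y_um", "z_um", "section",
        "axon_id", "dendrite_id", "gap_um", "is_true_synapse",
    ]
    synapses = pd.DataFrame(rows, columns=columns)
    return GroundTruth(synapses=synapses, neurites=neurites)


# ---------------------------------------------------------------------------
# Rendering


def _render_tube(plane: np.ndarray, seg: np.ndarray, radius: float, amp: float,
                 z_mid: float, cfg: PhantomConfig) -> None:
    """Add one capsule's Gaussian cross-section intensity to a section plane."""
    sigma = radius / _FWHM_FACTOR * 2.0  # FWHM of the cross-section = 2 * radius
    reach = radius + 3.0 * sigma
    p0, p1 = seg
    # Quick axial rejection: the capsule cannot touch this section.
    if max(p0[2], p1[2]) + reach < z_mid or min(p0[2], p1[2]) - reach > z_mid:
        return
    h, w = plane.shape
    px = cfg.pixel_size_um
    x_lo = max(0, int((min(p0[0], p1[0]) - reach) / px))
    x_hi = min(w, int((max(p0[0], p1[0]) + reach) / px) + 1)
    y_lo = max(0, int((min(p0[1], p1[1]) - reach) / px))
    y_hi = min(h, int((max(p0[1], p1[1]) + reach) / px) + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs = (np.arange(x_lo, x_hi) + 0.5) * px
    ys = (np.arange(y_lo, y_hi) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx, gy, np.full_like(gx, z_mid)], axis=-1)
    d_vec = p1 - p0
    seg_len2 = float(d_vec @ d_vec)
    if seg_len2 == 0:
        closest = p0
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d_vec) / seg_len2, 0.0, 1.0)
        closest = p0 + t[..., None] * d_vec
        dist = np.linalg.norm(pts - closest, axis=-1)
    plane[y_lo:y_hi, x_lo:x_hi] += amp * np.exp(-(dist**2) / (2.0 * sigma**2))


def _render_punctum(plane: np.ndarray, site: np.ndarray, amp: float, z_mid: float,
                    cfg: PhantomConfig) -> None:
    sigma = cfg.punctum_fwhm_um / _FWHM_FACTOR
    axial = math.exp(-((z_mid - site[2]) ** 2) / (2.0 * sigma**2))
    if axial < 1e-3:
        return
    h, w = plane.shape
    px = cfg.pixel_size_um
    reach = 4.0 * sigma
    x_lo = max(0, int((site[0] - reach) / px))
    x_hi = min(w, int((site[0] + reach) / px) + 1)
    y_lo = max(0, int((site[1] - reach) / px))
    y_hi = min(h, int((site[1] + reach) / px) + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs = (np.arange(x_lo, x_hi) + 0.5) * px
    ys = (np.arange(y_lo, y_hi) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    r2 = (gx - site[0]) ** 2 + (gy - site[1]) ** 2
    plane[y_lo:y_hi, x_lo:x_hi] += amp * axial * np.exp(-r2 / (2.0 * sigma**2))


def _tile_factors(rng: np.random.Generator, cfg: PhantomConfig) -> np.ndarray:
    rows, cols = cfg.tile_grid
    factors = rng.normal(1.0, cfg.tile_brightness_cv, size=(rows, cols))
    return np.clip(factors, 0.2, None)


def _tile_factor_map(factors: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = factors.shape
    h, w = shape
    row_idx = np.minimum((np.arange(h) * rows) // h, rows - 1)
    col_idx = np.minimum((np.arange(w) * cols) // w, cols - 1)
    return factors[np.ix_(row_idx, col_idx)]


def generate_phantom(config: PhantomConfig) -> tuple[SectionStack, GroundTruth]:
    """Render a serial-section stack and its ground truth.

    Returns a stack of ``ceil(z_extent / section_thickness)`` sections with
    three channel planes each (dendrite, axon, synaptic marker); sections
    are sampled at their mid-plane z.  Synaptic-marker puncta appear at
    true synapses only.
    """
    rng = np.random.default_rng(config.seed)
    truth = _build_geometry(config, rng)
    n_sections = config.n_sections
    h, w = config.plane_shape
    planes = np.zeros((n_sections, 3, h, w), dtype=np.float64)

    gradient_phi = rng.uniform(0, 2 * math.pi)
    xs = np.linspace(0.0, 1.0, w)
    ys = np.linspace(0.0, 1.0, h)
    gx, gy = np.meshgrid(xs, ys)
    gradient = config.background_gradient_amplitude * (
        gx * math.cos(gradient_phi) + gy * math.sin(gradient_phi)
    )
    gradient -= gradient.min()

    chan_of = {role: i for i, role in enumerate(CHANNEL_ROLES)}
    true_sites = truth.synapses[truth.synapses["is_true_synapse"]]
    for z in range(n_sections):
        z_mid = (z + 0.5) * config.section_thickness_um
        for neurite in truth.neurites:
            _render_tube(
                planes[z, chan_of[neurite.channel]],
                neurite.points,
                neurite.radius_um,
                config.signal_amplitude,
                z_mid,
                config,
            )
        for _, row in true_sites.iterrows():
            site = np.array([row["x_um"], row["y_um"], row["z_um"]])
            _render_punctum(planes[z, chan_of["marker"]], site,
                            config.signal_amplitude, z_mid, config)

    # Nuisance signals: background, per-tile brightness, shot + read noise.
    for z in range(n_sections):
        factor_map = _tile_factor_map(_tile_factors(rng, config), (h, w))
        for c in range(3):
            img = (planes[z, c] + config.background_level + gradient) * factor_map
            img = rng.poisson(np.maximum(img, 0.0) * config.noise.poisson_scale)
            img = img / config.noise.poisson_scale
            img = img + rng.normal(0.0, config.noise.gaussian_sd, size=img.shape)
            planes[z, c] = img

    stack = SectionStack(
        planes=planes.astype(np.float32),
        pixel_size_um=config.pixel_size_um,
        section_thickness_um=config.section_thickness_um,
        channels=CHANNEL_ROLES,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# I/O


def write_phantom(stack: SectionStack, truth: GroundTruth, config: PhantomConfig,
                  directory: str | Path) -> None:
    """Write per-section TIFFs, ground-truth CSVs and a config sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(stack, directory)
    truth.synapses.to_csv(directory / "synapses.csv", index=False)
    vertex_rows = []
    for n in truth.neurites:
        for k, (x, y, z) in enumerate(n.points):
            vertex_rows.append(
                {"neurite_id": n.id, "channel": n.channel, "radius_um": n.radius_um,
                 "vertex": k, "x_um": x, "y_um": y, "z_um": z}
            )
    pd.DataFrame(vertex_rows).to_csv(directory / "neurites.csv", index=False)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["noise"] = dataclasses.asdict(config.noise)
    (directory / "phantom_config.yaml").write_text(
        yaml.safe_dump(_plainify(cfg_dict), sort_keys=True)
    )


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_phantom(directory: str | Path) -> tuple[SectionStack, GroundTruth, PhantomConfig]:
    """Read back a phantom written by :func:`write_phantom`."""
    directory = Path(directory)
    stack = read_stack(directory)
    synapses = pd.read_csv(directory / "synapses.csv")
    neurites = []
    nv = pd.read_csv(directory / "neurites.csv")
    for nid, grp in nv.groupby("neurite_id", sort=True):
        grp = grp.sort_values("vertex")
        neurites.append(
            Neurite(
                id=int(nid),
                channel=str(grp["channel"].iloc[0]),
                radius_um=float(grp["radius_um"].iloc[0]),
                points=grp[["x_um", "y_um", "z_um"]].to_numpy(),
            )
        )
    cfg_dict = yaml.safe_load((directory / "phantom_config.yaml").read_text())
    cfg_dict["noise"] = NoiseModel(**cfg_dict["noise"])
    for key in ("volume_size_um", "neurite_radius_um", "near_miss_gap_um",
                "tile_grid"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = PhantomConfig(**cfg_dict)
    return stack, GroundTruth(synapses=synapses, neurites=neurites), config
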