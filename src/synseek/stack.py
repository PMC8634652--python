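"""Serial-section image stacks and their on-disk layout.

A :class:`SectionStack` holds an ordered series of aligned ultrathin
sections.  Each section carries one plane per fluorescence channel; the
three canonical channel roles are ``dendrite`` (postsynaptic structure),
``axon`` (presynaptic structure) and ``marker`` (synaptic-vesicle
immunostain).  Axial resolution equals the physical section thickness, so
the stack is anisotropic: lateral pixel size is set by the survey
objective while the z step is the ultramicrotome feed.

On disk a stack is a directory of per-section multi-channel TIFFs named
``section_0000.tif`` .. plus a ``stack.yaml`` sidecar recording pixel
size, section thickness and the channel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

CHANNEL_ROLES = ("dendrite", "axon", "marker")


@dataclass
class SectionStack:
    """Aligned serial sections with per-section channel planes.

    Parameters
    ----------
    planes
        Array of shape ``(n_sections, n_channels, height, width)``.
    pixel_size_um
        Lateral pixel size in micrometres.
    section_thickness_um
        Physical section thickness in micrometres (the axial step).
    channels
        Channel role names in plane order.
    """

    planes: np.ndarray
    pixel_size_um: float
    section_thickness_um: float
    channels: tuple[str, ...] = CHANNEL_ROLES

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 4:
            raise ValueError(
                f"planes must be (sections, channels, y, x); got shape {self.planes.shape}"
            )
        if self.planes.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.planes.shape[1]} planes per section but {len(self.channels)} channel names"
            )
        if self.pixel_size_um <= 0 or self.section_thickness_um <= 0:
            raise ValueError("pixel size and section thickness must be positive")

    @property
    def n_sections(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each plane in pixels."""
        return self.planes.shape[2], self.planes.shape[3]

    def channel_index(self, role: str) -> int:
        try:
            return self.channels.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}; have {self.channels}") from None

    def plane(self, section: int, role: str) -> np.ndarray:
        return self.planes[section, self.channel_index(role)]


def write_stack(stack: SectionStack, directory: str | Path) -> list[Path]:
    """Write one multi-channel TIFF per section plus a metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for z in range(stack.n_sections):
        path = directory / f"section_{z:04d}.tif"
        tifffile.imwrite(path, stack.planes[z], photometric="minisblack")
        paths.append(path)
    meta = {
        "pixel_size_um": float(stack.pixel_size_um),
        "section_thickness_um": float(stack.section_thickness_um),
        "channels": list(stack.channels),
        "n_sections": stack.n_sections,
    }
    meta_path = directory / "stack.yaml"
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    paths.append(meta_path)
    return paths


def read_stack(directory: str | Path) -> SectionStack:
    """Read a stack written by :func:`write_stack`."""
    directory = Path(directory)
    meta_path = directory / "stack.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"no stack.yaml in {directory}")
    meta = yaml.safe_load(meta_path.read_text())
    section_paths = sorted(directory.glob("section_*.tif"))
    if len(section_paths) != meta["n_sections"]:
        raise ValueError(
            f"metadata promises {meta['n_sections']} sections, found {len(section_paths)} TIFFs"
        )
    planes = np.stack([tifffile.imread(p) for p in section_paths])
    return SectionStack(
        planes=planes,
        pixel_size_um=meta["pixel_size_um"],
        section_thickness_um=meta["section_thickness_um"],
        channels=tuple(meta["channels"]),
    )
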