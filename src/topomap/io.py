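"""Core data containers, TIFF stack I/O and pipeline configuration.

Physical convention used throughout the package: voxel indices are 0-based
``(z, y, x)`` and the physical position of a voxel center is
``index * spacing`` with spacing in nanometres, so the first voxel center
sits at the origin.  All distances produced downstream are Euclidean
distances between such physical positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .classify import ClassMap

#: Default acquisition geometry of a reconstructed 3D-SIM stack:
#: 125 nm axial step, 39.5 nm lateral pixel (the 79 nm raw pixel halved
#: during reconstruction to meet Nyquist sampling).
DEFAULT_SPACING_NM: tuple[float, float, float] = (125.0, 39.5, 39.5)

#: Heat-map palette for the seven compaction classes plus the out-of-mask
#: label 0 (black).  Class 1 (interchromatin compartment, near-background
#: DAPI) is blue, classes 2-3 purple / deep red (decondensed chromatin),
#: class 4 dark orange (intermediate), classes 5-7 orange / yellow / white
#: (increasingly compact chromatin).
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),        # 0: outside nuclear mask
    (0, 0, 255),      # 1: blue
    (160, 32, 240),   # 2: purple
    (139, 0, 0),      # 3: deep red
    (255, 100, 0),    # 4: dark orange
    (255, 165, 0),    # 5: orange
    (255, 255, 0),    # 6: yellow
    (255, 255, 255),  # 7: white
)


def reconstruction_pixel_nm(raw_pixel_nm: float) -> float:
    """Lateral pixel size after SIM reconstruction.

    Reconstruction doubles the lateral pixel number, halving the pixel
    size (e.g. a 79 nm camera pixel becomes 39.5 nm).
    """
    if raw_pixel_nm <= 0:
        raise ConfigurationError("raw pixel size must be positive")
    return raw_pixel_nm / 2.0


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ConfigurationError("spacing must be (dz, dy, dx) in nm")
    if any(s <= 0 for s in spacing):
        raise ConfigurationError(f"spacing components must be > 0, got {spacing}")
    return spacing


@dataclass
class ImageStack:
    """A single-channel 3D fluorescence stack with physical voxel spacing.

    Parameters
    ----------
    voxels:
        3D array of non-negative intensities, axis order ``(z, y, x)``.
    spacing:
        Voxel spacing ``(dz, dy, dx)`` in nanometres.
    channel_name:
        Free-text channel label (e.g. ``"dapi"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ConfigurationError("stack must be 3D")
        if self.voxels.size == 0:
            raise ConfigurationError("stack must be non-empty")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.isfinite(
            self.voxels
        ).all():
            raise ConfigurationError("stack contains non-finite intensities")
        if (self.voxels < 0).any():
            raise ConfigurationError("stack intensities must be non-negative")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in cubic micrometres."""
        dz, dy, dx = self.spacing
        return dz * dy * dx * 1e-9  # nm^3 -> um^3


@dataclass
class NucleusMask:
    """Boolean nuclear mask matching the shape of the stack it masks."""

    member: np.ndarray
    flagged: bool = False  # set when the mask fraction fell below the floor

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.ndim != 3:
            raise ConfigurationError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.member.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())

    @property
    def fraction(self) -> float:
        return float(self.member.mean())


@dataclass
class PipelineConfig:
    """All tunable parameters of the mapping pipeline.

    Defaults follow the acquisition geometry and filter settings described
    in the package documentation (``docs/methods.md``).
    """

    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM
    n_classes: int = 7
    potts_beta: float = 0.5
    mask_sigma_nm: float = 200.0
    min_mask_fraction: float = 0.005
    rescale_dapi: bool = False
    k_sd: float = 4.0
    min_voxels: int = 4
    relative_floor: float = 0.25
    pairing_max_dist_nm: float = 500.0
    max_iter: int = 50
    tol: float = 1e-3
    use_pi: bool = True
    channel_index: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.spacing = _validate_spacing(self.spacing)
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.pairing_max_dist_nm <= 0:
            raise ConfigurationError("pairing_max_dist_nm must be > 0")
        if self.min_voxels < 1:
            raise ConfigurationError("min_voxels must be >= 1")
        if self.potts_beta < 0:
            raise ConfigurationError("potts_beta must be >= 0")
        if self.mask_sigma_nm < 0:
            raise ConfigurationError("mask_sigma_nm must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "spacing" in data:
            data["spacing"] = tuple(data["spacing"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["spacing"] = list(self.spacing)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_stack(
    path: str | Path,
    channel_name: str = "",
    spacing: Sequence[float] = DEFAULT_SPACING_NM,
    channel_index: int | None = None,
) -> ImageStack:
    """Read a 3D TIFF / OME-TIFF stack.

    A 4D file is treated as multi-channel; the channel axis is taken to be
    the shortest axis and ``channel_index`` selects the channel.  Integer
    intensities are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 4:
        if channel_index is None:
            raise ConfigurationError(
                "multi-channel stack requires a channel_index"
            )
        caxis = int(np.argmin(arr.shape))
        arr = np.take(arr, channel_index, axis=caxis)
    if arr.ndim != 3:
        raise ConfigurationError("stack must be 3D")
    return ImageStack(arr, _validate_spacing(spacing), channel_name)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack to TIFF, preserving dtype bit-exactly."""
    tifffile.imwrite(Path(path), stack.voxels)


def write_mask(mask: NucleusMask, path: str | Path) -> None:
    """Write a mask as an 8-bit TIFF (0 outside, 255 inside)."""
    tifffile.imwrite(Path(path), mask.member.astype(np.uint8) * 255)


def export_heatmap(
    class_map: "ClassMap",
    path: str | Path,
    palette: Sequence[tuple[int, int, int]] = DEFAULT_PALETTE,
) -> None:
    """Write an RGB TIFF heat map of a compaction class map.

    Label ``c`` maps to ``palette[c]``; label 0 (outside the nuclear mask)
    maps to the first palette entry, black by default.
    """
    labels = np.asarray(class_map.labels)
    k = int(class_map.n_classes)
    if len(palette) < k + 1:
        raise ConfigurationError(
            f"palette needs >= {k + 1} colors, got {len(palette)}"
        )
    if labels.min() < 0 or labels.max() > k:
        raise ConfigurationError(
            f"class labels must lie in 0..{k}, found {labels.max()}"
        )
    lut = np.asarray(palette[: k + 1], dtype=np.uint8)
    rgb = lut[labels]
    tifffile.imwrite(Path(path), rgb, photometric="rgb")
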