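"""Synthetic 3D nucleus phantoms with known chromatin layering and spots.

The generator emulates the structure the mapping pipeline assumes: an
ellipsoidal DAPI-stained nucleus containing chromatin domain clusters
(CDCs) organized as radial compaction layers — a decondensed outer shell
(class 2) grading into a compact core (class 7), embedded in the
interchromatin compartment (class 1) — plus diffraction-limited FISH
spots placed with a configurable preference over the compaction classes,
paired across the two signal channels, and unpaired background speckles
that exercise the cross-channel pairing filter.

Construction of the true class map: CDC spheres are placed inside the
nuclear ellipsoid; the depth of every CDC voxel below the CDC surface is
measured with an anisotropy-aware Euclidean distance transform and
converted to a class by the per-class shell thickness (depth within the
first shell -> class 2, ..., deeper than five shells -> class 7).

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config, with draws in a fixed order (CDC placement, channel-1
spot classes and voxels, channel-2 offsets, speckles per channel, DAPI
noise, channel noise), so a fixed config and seed reproduce the stacks
and truth bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import ClassMap
from .errors import ConfigurationError, EmptyMaskError, PhantomError
from .io import DEFAULT_SPACING_NM, ImageStack, NucleusMask
from .spots import Spot, SpotSet
from .topography import ClassProfile


@dataclass
class PhantomConfig:
    """Parameters of a synthetic nucleus.

    Defaults reproduce the acquisition geometry of a reconstructed 3D-SIM
    stack (125 x 39.5 x 39.5 nm voxels) and a flat nucleus of ~4 um axial
    diameter.  Class mean intensities are free parameters (arbitrary
    fluorescence units, strictly ascending); the ~50 nm shell thickness
    sets the radial layering scale of the CDCs.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM
    semi_axes_nm: tuple[float, float, float] = (2000.0, 1100.0, 1100.0)
    n_cdcs: int = 20
    cdc_radius_nm: tuple[float, float] = (500.0, 700.0)
    # peripheral chromatin layer lining the nuclear envelope
    # (lamina-associated heterochromatin); 0 disables
    rim_nm: float = 200.0
    shell_nm: float = 80.0
    # class means sit well above the detector background (~0): even the
    # interchromatin compartment carries clear DAPI signal in real nuclei
    mu: tuple[float, ...] = (40.0, 55.0, 70.0, 85.0, 100.0, 115.0, 130.0)
    noise_sd: float = 4.5
    psf_sigma_nm: tuple[float, float] = (125.0, 50.0)  # (axial, lateral)
    spots_per_channel: int = 12
    # sampling preference over classes 1..7 for channel-1 spot centers;
    # None = uniform over all in-mask voxels (i.e. proportional to the
    # DAPI class fractions)
    spot_class_probs: tuple[float, ...] | None = (0.0, 0.6, 0.3, 0.1, 0.0, 0.0, 0.0)
    spot_amplitude: float = 150.0
    spot_sigma_nm: tuple[float, float] = (110.0, 55.0)  # (axial, lateral)
    pair_offset_nm: tuple[float, float] = (100.0, 300.0)
    speckles_per_channel: float = 2.0  # Poisson mean of background speckles
    speckle_min_dist_nm: float = 800.0
    channel_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mu) < 2 or not all(
            b > a for a, b in zip(self.mu, self.mu[1:])
        ):
            raise ConfigurationError("class means mu must be strictly ascending")
        if self.shell_nm <= 0:
            raise ConfigurationError("shell thickness must be > 0")
        if self.spot_class_probs is not None:
            p = np.asarray(self.spot_class_probs, dtype=float)
            if len(p) != len(self.mu):
                raise ConfigurationError("spot_class_probs must have K entries")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError("spot_class_probs must sum to 1")
        extent = (np.array(self.shape) - 1) * np.array(self.spacing)
        if (np.array(self.semi_axes_nm) > extent / 2).any():
            raise ConfigurationError("nucleus does not fit the grid")

    @property
    def n_classes(self) -> int:
        return len(self.mu)


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: class map, mask and spot table.

    ``spot_table`` columns: ``channel``, center coordinates ``cz/cy/cx``
    (nm, snapped to the voxel center), voxel indices ``z/y/x``,
    ``class_label`` (true class at the center voxel) and
    ``is_background`` flagging unpaired speckles.
    """

    class_map: ClassMap
    mask: NucleusMask
    spot_table: pd.DataFrame
    config: PhantomConfig


class PhantomResult(NamedTuple):
    dapi: ImageStack
    ch1: ImageStack
    ch2: ImageStack
    truth: PhantomTruth


def _physical_grids(shape, spacing):
    z = np.arange(shape[0]) * spacing[0]
    y = np.arange(shape[1]) * spacing[1]
    x = np.arange(shape[2]) * spacing[2]
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def _true_class_map(cfg: PhantomConfig, rng: np.random.Generator):
    zz, yy, xx = _physical_grids(cfg.shape, cfg.spacing)
    center = (np.array(cfg.shape) - 1) * np.array(cfg.spacing) / 2.0
    az, ay, ax = cfg.semi_axes_nm
    ell = (
        ((zz - center[0]) / az) ** 2
        + ((yy - center[1]) / ay) ** 2
        + ((xx - center[2]) / ax) ** 2
    )
    nucleus = ell <= 1.0

    # CDC centers drawn from the nuclear interior (scaled radius <= 0.75
    # keeps most of each sphere inside the nucleus); overlap is allowed,
    # as CDCs are clusters of touching ~1-Mb domains.
    cand = np.argwhere(ell <= 0.75**2)
    if cand.shape[0] == 0:
        raise PhantomError("nucleus interior too small for CDC placement")
    picks = cand[rng.integers(0, cand.shape[0], size=cfg.n_cdcs)]
    radii = rng.uniform(*cfg.cdc_radius_nm, size=cfg.n_cdcs)

    cdc = np.zeros(cfg.shape, dtype=bool)
    sp = np.array(cfg.spacing)
    for (iz, iy, ix), r in zip(picks, radii):
        c = np.array([iz, iy, ix]) * sp
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        cdc |= d2 <= r * r
    cdc &= nucleus
    if cfg.rim_nm > 0:
        # lamina-associated chromatin lining the nuclear envelope
        border_depth = ndimage.distance_transform_edt(
            nucleus, sampling=cfg.spacing
        )
        cdc |= nucleus & (border_depth <= cfg.rim_nm)

    labels = np.zeros(cfg.shape, dtype=np.int16)
    labels[nucleus] = 1
    if cdc.any():
        depth = ndimage.distance_transform_edt(cdc, sampling=cfg.spacing)
        cls = np.minimum(
            cfg.n_classes, 1 + np.ceil(depth[cdc] / cfg.shell_nm)
        ).astype(np.int16)
        labels[cdc] = cls
    return labels, nucleus


def _sample_spot_voxels(
    cfg: PhantomConfig,
    labels: np.ndarray,
    nucleus: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Channel-1 spot voxels drawn per the configured class preference."""
    n = cfg.spots_per_channel
    if cfg.spot_class_probs is None:
        pool = np.argwhere(nucleus)
        return pool[rng.integers(0, pool.shape[0], size=n)]
    classes = rng.choice(
        np.arange(1, cfg.n_classes + 1), size=n, p=cfg.spot_class_probs
    )
    out = np.zeros((n, 3), dtype=int)
    pools: dict[int, np.ndarray] = {}
    for i, c in enumerate(classes):
        if c not in pools:
            pools[c] = np.argwhere(nucleus & (labels == c))
        pool = pools[c]
        if pool.shape[0] == 0:
            raise PhantomError(f"requested spot class {c} has no voxels")
        out[i] = pool[rng.integers(0, pool.shape[0])]
    return out


def _paired_voxels(
    cfg: PhantomConfig,
    anchors: np.ndarray,
    nucleus: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Channel-2 spot voxels: each within pair_offset_nm of a channel-1 spot."""
    sp = np.array(cfg.spacing)
    shape = np.array(cfg.shape)
    out = np.zeros_like(anchors)
    for i, a in enumerate(anchors):
        base = a * sp
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            length = rng.uniform(*cfg.pair_offset_nm)
            idx = np.rint((base + direction * length) / sp).astype(int)
            if (idx >= 0).all() and (idx < shape).all() and nucleus[tuple(idx)]:
                out[i] = idx
                break
        else:
            raise PhantomError("could not place a paired spot inside the mask")
    return out


def _speckle_voxels(
    cfg: PhantomConfig,
    nucleus: np.ndarray,
    avoid_nm: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unpaired background speckles, kept far from the other channel.

    Every speckle center is at least ``speckle_min_dist_nm`` from all
    positions in ``avoid_nm`` (the other channel's true spots and
    speckles), so the 500-nm pairing filter removes it by construction.
    """
    n = rng.poisson(cfg.speckles_per_channel)
    sp = np.array(cfg.spacing)
    pool = np.argwhere(nucleus)
    out = []
    for _ in range(n):
        for _ in range(500):
            idx = pool[rng.integers(0, pool.shape[0])]
            pos = idx * sp
            if avoid_nm.size == 0 or np.min(
                np.linalg.norm(avoid_nm - pos, axis=1)
            ) >= cfg.speckle_min_dist_nm:
                out.append(idx)
                break
        # silently drop a speckle that cannot be placed far enough away
    return np.array(out, dtype=int).reshape(-1, 3)


def _render_channel(
    cfg: PhantomConfig, centers_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Additive anisotropic Gaussian foci plus clipped sensor noise."""
    img = np.zeros(cfg.shape, dtype=float)
    sp = np.array(cfg.spacing)
    sig = np.array(
        [cfg.spot_sigma_nm[0], cfg.spot_sigma_nm[1], cfg.spot_sigma_nm[1]]
    )
    half = np.ceil(4 * sig / sp).astype(int)
    for idx in centers_idx:
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, cfg.shape)
        zz = (np.arange(lo[0], hi[0]) - idx[0]) * sp[0]
        yy = (np.arange(lo[1], hi[1]) - idx[1]) * sp[1]
        xx = (np.arange(lo[2], hi[2]) - idx[2]) * sp[2]
        g = np.exp(
            -(
                (zz[:, None, None] / sig[0]) ** 2
                + (yy[None, :, None] / sig[1]) ** 2
                + (xx[None, None, :] / sig[2]) ** 2
            )
            / 2.0
        )
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += cfg.spot_amplitude * g
    if cfg.channel_noise_sd > 0:
        img += rng.normal(0.0, cfg.channel_noise_sd, size=cfg.shape)
    return np.clip(img, 0.0, None)


def generate_phantom(config: PhantomConfig) -> PhantomResult:
    """Generate one synthetic nucleus: DAPI, two signal channels and truth."""
    rng = np.random.default_rng(config.seed)
    labels, nucleus = _true_class_map(config, rng)

    vox1 = _sample_spot_voxels(config, labels, nucleus, rng)
    vox2 = _paired_voxels(config, vox1, nucleus, rng)
    sp = np.array(config.spacing)
    true2_nm = vox2 * sp
    true1_nm = vox1 * sp
    spk1 = _speckle_voxels(
        config, nucleus, true2_nm, rng
    )  # ch1 speckles: far from every ch2 position
    avoid_for_2 = np.vstack([true1_nm, spk1 * sp]) if spk1.size else true1_nm
    spk2 = _speckle_voxels(config, nucleus, avoid_for_2, rng)

    rows = []
    for idx in vox1:
        rows.append(("ch1", *(idx * sp), *idx, labels[tuple(idx)], False))
    for idx in vox2:
        rows.append(("ch2", *(idx * sp), *idx, labels[tuple(idx)], False))
    for idx in spk1:
        rows.append(("ch1", *(idx * sp), *idx, labels[tuple(idx)], True))
    for idx in spk2:
        rows.append(("ch2", *(idx * sp), *idx, labels[tuple(idx)], True))
    table = pd.DataFrame(
        rows,
        columns=[
            "channel", "cz_nm", "cy_nm", "cx_nm", "z", "y", "x",
            "class_label", "is_background",
        ],
    )

    mu = np.asarray(config.mu)
    dapi = np.zeros(config.shape, dtype=float)
    dapi[nucleus] = mu[labels[nucleus] - 1]
    if config.noise_sd > 0:
        dapi += rng.normal(0.0, config.noise_sd, size=config.shape)
    if any(s > 0 for s in config.psf_sigma_nm):
        sig = [
            config.psf_sigma_nm[0] / config.spacing[0],
            config.psf_sigma_nm[1] / config.spacing[1],
            config.psf_sigma_nm[1] / config.spacing[2],
        ]
        dapi = ndimage.gaussian_filter(dapi, sigma=sig)
    dapi = np.clip(dapi, 0.0, None)

    ch1 = _render_channel(config, np.vstack([vox1, spk1]), rng)
    ch2 = _render_channel(config, np.vstack([vox2, spk2]), rng)

    truth = PhantomTruth(
        ClassMap(labels, config.n_classes),
        NucleusMask(nucleus),
        table,
        config,
    )
    return PhantomResult(
        ImageStack(dapi, config.spacing, "dapi"),
        ImageStack(ch1, config.spacing, "ch1"),
        ImageStack(ch2, config.spacing, "ch2"),
        truth,
    )


def truth_class_fractions(truth: PhantomTruth) -> ClassProfile:
    """Per-class fraction of in-mask voxels of the true class map."""
    member = truth.mask.member
    if not member.any():
        raise EmptyMaskError("phantom mask is empty")
    k = truth.class_map.n_classes
    counts = np.bincount(truth.class_map.labels[member], minlength=k + 1)[1:]
    return ClassProfile(counts / counts.sum(), source="truth")


def spots_from_truth(
    truth: PhantomTruth, channel: str, include_background: bool = False
) -> SpotSet:
    """Single-voxel spot set at the true centers of one channel.

    Useful for testing the class-mapping statistics without the spot
    segmentation stage in the loop.
    """
    sub = truth.spot_table[truth.spot_table.channel == channel]
    if not include_background:
        sub = sub[~sub.is_background]
    out = SpotSet(channel)
    for _, row in sub.iterrows():
        out.spots.append(
            Spot(
                channel,
                np.array([[row.z, row.y, row.x]]),
                np.array([1.0]),
                truth.config.spacing,
            )
        )
    return out


def write_phantom(result: PhantomResult, out_dir: str | Path) -> None:
    """Write dapi/ch1/ch2 stacks, the true class map and the spot table."""
    from .io import write_stack  # local import to avoid cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(result.dapi, out / "dapi.tif")
    write_stack(result.ch1, out / "ch1.tif")
    write_stack(result.ch2, out / "ch2.tif")
    import tifffile

    tifffile.imwrite(out / "truth_classes.tif", result.truth.class_map.labels)
    result.truth.spot_table.to_csv(out / "truth_spots.csv", index=False)
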