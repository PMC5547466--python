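"""Mapping of FISH signals onto compaction classes and spatial statistics.

Covers the per-nucleus quantities of the mapping workflow: relative class
distributions of DAPI and FISH voxels, percentage-point enrichment /
depletion profiles, nearest-neighbor voxel class frequencies, minimal
class-to-class distances (anisotropy-aware), centroid distance analyses
and two small genomic bookkeeping helpers.

All distances are physical (nanometres), computed from 0-based voxel
indices multiplied by the voxel spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import EmptyMaskError, EmptyProfileError
from .io import NucleusMask

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .classify import ClassMap
    from .spots import SpotSet

log = logging.getLogger(__name__)


@dataclass
class ClassProfile:
    """Relative distribution of voxels (or signal) over the K classes."""

    fractions: np.ndarray
    source: str = ""
    nucleus_id: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if (self.fractions < -1e-12).any():
            raise ValueError("profile fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("profile fractions must sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.fractions)


@dataclass
class EnrichmentProfile:
    """Percentage-point deviation of a signal profile from the DAPI profile.

    ``points[k] = 100 * (signal_k - dapi_k)``; positive values mean
    relative enrichment of the signal in class ``k + 1``, negative values
    depletion.  Entries sum to zero.
    """

    points: np.ndarray
    channel: str = ""
    nucleus_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if abs(self.points.sum()) > 1e-9:
            raise ValueError("enrichment points must sum to 0")

    @property
    def n_classes(self) -> int:
        return len(self.points)


@dataclass
class NeighborMatrix:
    """Row-normalized class frequencies of neighbor voxels.

    ``matrix[k - 1, j - 1]`` is the frequency with which a neighbor of a
    class-``k`` voxel carries class ``j``.  Rows of classes absent from
    the map are NaN.
    """

    matrix: np.ndarray
    mode: str = "adjacent"

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MinDistTable:
    """Mean/SD minimal distances from one source class to every class.

    ``mean_nm[j - 1]`` averages, over all source-class voxels, the
    distance to the nearest voxel of class ``j``; NaN where class ``j`` is
    absent from the map.
    """

    source_class: int
    mean_nm: np.ndarray
    sd_nm: np.ndarray
    n_source_voxels: int


def spot_class_distribution(
    spots: "SpotSet",
    class_map: "ClassMap",
    weighting: str = "intensity",
) -> ClassProfile:
    """Relative distribution of segmented signal over compaction classes.

    Each spot voxel contributes its fluorescence intensity (default) or a
    unit count to the class at its location; the profile is normalized to
    sum to 1.  Voxels mapping to label 0 (outside the nuclear mask) are
    excluded with a logged warning.
    """
    if weighting not in ("intensity", "count"):
        raise ValueError("weighting must be 'intensity' or 'count'")
    if not spots.spots:
        raise EmptyProfileError("no spots: signal profile undefined")
    k = class_map.n_classes
    tally = np.zeros(k, dtype=float)
    n_outside = 0
    for spot in spots.spots:
        idx = spot.indices
        labels = class_map.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        w = spot.intensities if weighting == "intensity" else np.ones(len(idx))
        inside = labels > 0
        n_outside += int(np.count_nonzero(~inside))
        np.add.at(tally, labels[inside] - 1, w[inside])
    if n_outside:
        log.warning("%d spot voxels outside the nuclear mask excluded", n_outside)
    total = tally.sum()
    if total <= 0:
        raise EmptyProfileError("all spot voxels fell outside the mask")
    return ClassProfile(
        tally / total, source=spots.channel, nucleus_id=spots.nucleus_id
    )


def enrichment_profile(
    signal: ClassProfile, dapi: ClassProfile
) -> EnrichmentProfile:
    """Percentage-point enrichment of a signal profile over the DAPI one."""
    if signal.n_classes != dapi.n_classes:
        raise ValueError("profiles have different numbers of classes")
    return EnrichmentProfile(
        100.0 * (signal.fractions - dapi.fractions),
        channel=signal.source,
        nucleus_id=signal.nucleus_id,
    )


def _adjacent_tally(labels: np.ndarray, member: np.ndarray, k: int) -> np.ndarray:
    counts = np.zeros((k, k), dtype=float)
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(0, -1)
        b[axis] = slice(1, None)
        la, lb = labels[tuple(a)], labels[tuple(b)]
        both = member[tuple(a)] & member[tuple(b)]
        pair = np.stack([la[both], lb[both]]) - 1
        np.add.at(counts, (pair[0], pair[1]), 1.0)
        np.add.at(counts, (pair[1], pair[0]), 1.0)  # both directions
    return counts


def neighbor_class_matrix(
    class_map: "ClassMap",
    mask: NucleusMask,
    mode: str = "adjacent",
) -> NeighborMatrix:
    """Class frequencies of neighbor voxels for every compaction class.

    ``mode="adjacent"`` (default) tallies the classes of the 6-connected
    in-mask neighbors of every in-mask voxel.  ``mode="nearest"`` instead
    records, for every voxel, the class of the nearest in-mask voxel of a
    *different* class (anisotropy-aware Euclidean distance).
    """
    member = mask.member
    if not member.any():
        raise EmptyMaskError("nuclear mask is empty")
    labels = class_map.labels
    k = class_map.n_classes
    if mode == "adjacent":
        counts = _adjacent_tally(labels, member, k)
    elif mode == "nearest":
        counts = np.zeros((k, k), dtype=float)
        for src in range(1, k + 1):
            sel = member & (labels == src)
            if not sel.any():
                continue
            other = member & (labels != src) & (labels > 0)
            if not other.any():
                continue
            _, idx = ndimage.distance_transform_edt(
                ~other, return_indices=True
            )
            nn_lab = labels[idx[0], idx[1], idx[2]]
            vals = nn_lab[sel]
            counts[src - 1] = np.bincount(vals, minlength=k + 1)[1:]
    else:
        raise ValueError("mode must be 'adjacent' or 'nearest'")
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(rowsum > 0, counts / rowsum, np.nan)
    return NeighborMatrix(matrix, mode=mode)


def min_class_distances(
    class_map: "ClassMap",
    source_class: int,
    spacing: Sequence[float],
) -> MinDistTable:
    """Mean minimal distance from source-class voxels to every class.

    For each target class ``j`` the anisotropy-aware Euclidean distance
    transform of the class-``j`` voxel set is evaluated at all voxels of
    ``source_class`` and averaged.  Absent target classes yield NaN
    (undefined, not zero).  The entry for ``j == source_class`` is 0 by
    construction (each voxel is its own nearest same-class voxel).
    """
    labels = class_map.labels
    k = class_map.n_classes
    src = labels == source_class
    if not src.any():
        raise ValueError(f"source class {source_class} absent from map")
    spacing = tuple(float(s) for s in spacing)
    mean = np.full(k, np.nan)
    sd = np.full(k, np.nan)
    for j in range(1, k + 1):
        target = labels == j
        if not target.any():
            continue
        dist = ndimage.distance_transform_edt(~target, sampling=spacing)
        vals = dist[src]
        mean[j - 1] = vals.mean()
        sd[j - 1] = vals.std(ddof=0)
    return MinDistTable(source_class, mean, sd, int(src.sum()))


def nn_centroid_distances(set_a: "SpotSet", set_b: "SpotSet") -> np.ndarray:
    """For each spot of ``set_a``, distance (nm) to nearest ``set_b`` centroid."""
    if not set_a.spots:
        raise ValueError("set_a is empty")
    if not set_b.spots:
        raise ValueError("set_b is empty")
    ca = np.array([s.centroid_nm for s in set_a.spots])
    cb = np.array([s.centroid_nm for s in set_b.spots])
    return cdist(ca, cb).min(axis=1)


def replicate_pair_distances(
    spots: "SpotSet", cutoff_nm: float = 500.0
) -> np.ndarray:
    """Same-channel mutual-nearest-neighbor centroid distances below a cutoff.

    Pairs of hybridization signals closer than ``cutoff_nm`` (default
    500 nm) are taken to be replicated loci (sister chromatids); each spot
    contributes to at most one pair via mutual-nearest-neighbor matching.
    """
    n = len(spots.spots)
    if n < 2:
        log.warning("replicate pairing needs >= 2 spots, returning empty list")
        return np.array([])
    c = np.array([s.centroid_nm for s in spots.spots])
    d = cdist(c, c)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    out = []
    for i in range(n):
        j = nn[i]
        if j > i and nn[j] == i and d[i, j] < cutoff_nm:
            out.append(d[i, j])
    return np.array(out)


def expected_site_count(copy_numbers: Sequence[int]) -> int:
    """Maximal number of distinct hybridization sites for a probe set.

    Sum of per-locus genomic copy numbers: a diploid autosomal locus
    contributes 2, so a pool of six such loci can label up to 12 distinct
    segments per nucleus and a pool of two up to 4.
    """
    copies = list(copy_numbers)
    if any(c < 0 for c in copies):
        raise ValueError("copy numbers must be non-negative")
    return int(sum(copies))


def extended_fiber_length(
    kilobases: float,
    repeat_bp: float = 200.0,
    nm_per_nucleosome: float = 10.0,
) -> float:
    """Length (nm) of a genomic segment as a fully extended 10-nm fiber.

    One nucleosome bead of ``nm_per_nucleosome`` per ``repeat_bp`` of
    sequence: 10 kb at a 200-bp repeat spans ~500 nm, which anchors the
    0.5-um cross-channel pairing threshold used to reject background.
    """
    if kilobases <= 0 or repeat_bp <= 0 or nm_per_nucleosome <= 0:
        raise ValueError("all inputs must be positive")
    return 1000.0 * kilobases / repeat_bp * nm_per_nucleosome
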