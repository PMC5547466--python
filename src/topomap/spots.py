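"""FISH signal segmentation and the cross-channel pairing filter.

Signals are segmented per channel inside the nuclear mask with a
threshold of the form ``max(mean + k_sd * SD, relative_floor * max)``
(both statistics over in-mask voxels), grouped by 26-connectivity, and
filtered by a minimum voxel count.  Centroids are geometric gravity
centers (unweighted means of member voxel positions) in nanometres.

Because single-copy FISH signals sit at the volumetric resolution limit
(~0.005 um^3), isolated background fluorophores are indistinguishable
from true signals by size or intensity.  The pairing filter therefore
rejects, symmetrically in both channels, any spot whose centroid lies
farther than 0.5 um from every centroid of the differently labeled
channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import EmptyMaskError
from .io import ImageStack, NucleusMask

log = logging.getLogger(__name__)


@dataclass
class Spot:
    """One segmented 3D focus."""

    channel: str
    indices: np.ndarray       # (n, 3) voxel indices (z, y, x)
    intensities: np.ndarray   # (n,) matching fluorescence values
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=int))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, dtype=float))
        if self.indices.shape[0] != self.intensities.shape[0]:
            raise ValueError("indices and intensities lengths differ")

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    @property
    def centroid_nm(self) -> np.ndarray:
        """Geometric gravity center (z, y, x) in nm."""
        return self.indices.mean(axis=0) * np.asarray(self.spacing)

    @property
    def volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return self.n_voxels * dz * dy * dx * 1e-9


@dataclass
class SpotSet:
    """All segmented spots of one channel in one nucleus."""

    channel: str
    spots: list[Spot] = field(default_factory=list)
    nucleus_id: str = ""

    def __len__(self) -> int:
        return len(self.spots)

    def centroids_nm(self) -> np.ndarray:
        if not self.spots:
            return np.zeros((0, 3))
        return np.array([s.centroid_nm for s in self.spots])


def segment_spots(
    channel: ImageStack,
    mask: NucleusMask,
    k_sd: float = 4.0,
    min_voxels: int = 4,
    relative_floor: float = 0.25,
) -> SpotSet:
    """Segment FISH signals of one channel inside the nuclear mask.

    Threshold ``T = max(mean + k_sd * SD, relative_floor * max)`` over
    in-mask intensities; voxels above ``T`` are grouped by
    26-connectivity and components smaller than ``min_voxels`` are
    discarded.  A threshold above the channel maximum yields an empty set
    with a logged warning rather than an error.
    """
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    member = mask.member
    if not member.any():
        raise EmptyMaskError("nuclear mask is empty")
    vals = channel.voxels[member].astype(float)
    thr = max(vals.mean() + k_sd * vals.std(), relative_floor * vals.max())
    fg = member & (channel.voxels > thr)
    out = SpotSet(channel.channel_name)
    if not fg.any():
        log.warning(
            "channel %r: threshold %.3g above all in-mask intensities",
            channel.channel_name, thr,
        )
        return out
    lab, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    objects = ndimage.find_objects(lab)
    for i, sl in enumerate(objects, start=1):
        sel = lab[sl] == i
        if sel.sum() < min_voxels:
            continue
        zyx = np.argwhere(sel) + np.array([s.start for s in sl])
        out.spots.append(
            Spot(
                channel.channel_name,
                zyx,
                channel.voxels[zyx[:, 0], zyx[:, 1], zyx[:, 2]].astype(float),
                channel.spacing,
            )
        )
    return out


def pair_filter(
    set_a: SpotSet,
    set_b: SpotSet,
    max_dist_nm: float = 500.0,
) -> tuple[SpotSet, SpotSet, list[SpotSet]]:
    """Reject spots without a nearby partner in the other channel.

    A spot of either set is retained iff the Euclidean distance from its
    centroid to the nearest centroid of the other set is at most
    ``max_dist_nm`` (default 500 nm, the extended-fiber span of ~10 kb);
    everything else is attributed to background.  The filter is symmetric
    in its arguments and idempotent.

    Returns ``(kept_a, kept_b, [discarded_a, discarded_b])``.
    """
    if max_dist_nm <= 0:
        raise ValueError("max_dist_nm must be > 0")

    def split(src: SpotSet, other: SpotSet) -> tuple[SpotSet, SpotSet]:
        kept = SpotSet(src.channel, [], src.nucleus_id)
        lost = SpotSet(src.channel, [], src.nucleus_id)
        if not src.spots:
            return kept, lost
        if not other.spots:
            lost.spots = list(src.spots)
            return kept, lost
        d = cdist(src.centroids_nm(), other.centroids_nm()).min(axis=1)
        for spot, di in zip(src.spots, d):
            (kept if di <= max_dist_nm else lost).spots.append(spot)
        return kept, lost

    kept_a, lost_a = split(set_a, set_b)
    kept_b, lost_b = split(set_b, set_a)
    return kept_a, kept_b, [lost_a, lost_b]
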