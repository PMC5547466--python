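"""Voxel-wise chromatin compaction classification of DAPI intensities.

In-mask DAPI intensities are modeled as a K-component Gaussian mixture with
one shared variance (``equal intensity variance``), optionally coupled to a
Potts spatial prior over the 6-connected voxel lattice — a hidden Markov
random field.  The per-voxel labeling energy is

    E(c) = (x - mu_c)^2 / (2 sigma^2) + log sigma - log pi_c
           + beta * #{6-neighbors in mask with label != c}

Labels are optimized by iterated conditional modes (ICM) alternating with
re-estimation of (mu, sigma^2, pi); ``beta = 0`` reduces the procedure to a
hard-assignment (classification) EM fit of the plain equal-variance
mixture, which is exposed separately as :func:`classify_gmm`.

Class 1 always carries the lowest mean intensity (interchromatin
compartment, at or near background DAPI levels) and class K the highest
(most compact chromatin); components are relabeled after fitting so that
the means ascend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .errors import DegenerateFitError, EmptyMaskError
from .io import ImageStack, NucleusMask
from .topography import ClassProfile

log = logging.getLogger(__name__)

_AXES = ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1))


@dataclass
class MixtureParams:
    """Fitted parameters of the equal-variance Gaussian mixture / HMRF."""

    n_classes: int
    mu: np.ndarray          # ascending class means, intensity units
    sigma2: float           # shared intensity variance
    pi: np.ndarray          # mixture weights, sum to 1
    beta: float             # Potts interaction strength (0 = no spatial prior)
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if len(self.mu) != self.n_classes or len(self.pi) != self.n_classes:
            raise ValueError("mu and pi must have length n_classes")
        if not np.all(np.diff(self.mu) > 0):
            raise ValueError("class means must be strictly ascending")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class ClassMap:
    """Per-voxel compaction labels: 0 outside the mask, 1..K inside."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("class map must be 3D")
        if self.labels.min() < 0 or self.labels.max() > self.n_classes:
            raise ValueError(f"labels must lie in 0..{self.n_classes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


def _shifted(a: np.ndarray, axis: int, step: int, fill=0) -> np.ndarray:
    """Array shifted by one voxel along ``axis``; vacated border filled."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        src[axis] = slice(0, -1)
        dst[axis] = slice(1, None)
    else:
        src[axis] = slice(1, None)
        dst[axis] = slice(0, -1)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _neighbor_class_counts(
    labels: np.ndarray, member: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class counts of in-mask 6-neighbors sharing that class.

    Returns ``(same, n_nb)`` where ``same[k]`` counts neighbors with label
    ``k + 1`` and ``n_nb`` counts all in-mask neighbors.
    """
    same = np.zeros((n_classes,) + labels.shape, dtype=np.int16)
    n_nb = np.zeros(labels.shape, dtype=np.int16)
    for axis, step in _AXES:
        nb_lab = _shifted(labels, axis, step)
        nb_in = _shifted(member, axis, step, fill=False)
        n_nb += nb_in
        for k in range(n_classes):
            same[k] += nb_in & (nb_lab == k + 1)
    return same, n_nb


def _data_cost(
    voxels: np.ndarray, params: MixtureParams, use_pi: bool
) -> np.ndarray:
    """Per-class Gaussian data cost grid, shape ``(K,) + voxels.shape``."""
    s2 = params.sigma2
    cost = (voxels[None, ...] - params.mu[:, None, None, None]) ** 2 / (2.0 * s2)
    cost += 0.5 * np.log(s2)
    if use_pi:
        cost -= np.log(np.maximum(params.pi, 1e-300))[:, None, None, None]
    return cost


def labeling_energy(
    labels: np.ndarray,
    voxels: np.ndarray,
    member: np.ndarray,
    params: MixtureParams,
    use_pi: bool = True,
) -> float:
    """Total posterior energy of a labeling at fixed parameters.

    Sum of the per-voxel Gaussian data terms over in-mask voxels plus
    ``beta`` times the number of disagreeing in-mask 6-neighbor pairs
    (each unordered pair counted once).
    """
    x = voxels[member].astype(float)
    lab = labels[member] - 1
    s2 = params.sigma2
    data = np.sum((x - params.mu[lab]) ** 2) / (2.0 * s2)
    data += 0.5 * np.log(s2) * lab.size
    if use_pi:
        data -= np.sum(np.log(np.maximum(params.pi, 1e-300))[lab])
    pairs = 0
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(0, -1)
        b[axis] = slice(1, None)
        both = member[tuple(a)] & member[tuple(b)]
        pairs += int(np.sum((labels[tuple(a)] != labels[tuple(b)]) & both))
    return float(data + params.beta * pairs)


def icm_sweep(
    labels: np.ndarray,
    voxels: np.ndarray,
    member: np.ndarray,
    params: MixtureParams,
    use_pi: bool = True,
    parity: np.ndarray | None = None,
) -> np.ndarray:
    """One full ICM sweep at fixed parameters; returns the new label grid.

    The lattice is swept in checkerboard order (the two parity classes of
    ``z + y + x`` are independent sets under 6-connectivity), which makes
    the vectorized update exact ICM: the total energy is non-increasing.
    Energy ties are broken toward the lower class index.
    """
    if parity is None:
        parity = _parity(labels.shape)
    labels = labels.copy()
    cost_data = _data_cost(voxels, params, use_pi)
    for p in (0, 1):
        same, n_nb = _neighbor_class_counts(labels, member, params.n_classes)
        cost = cost_data + params.beta * (n_nb[None, ...] - same)
        best = np.argmin(cost, axis=0).astype(labels.dtype) + 1
        sel = member & (parity == p)
        labels[sel] = best[sel]
    return labels


def _parity(shape: tuple[int, int, int]) -> np.ndarray:
    zi, yi, xi = np.indices(shape, sparse=True)
    return ((zi + yi + xi) % 2).astype(np.int8)


def _kmeans_centers(values: np.ndarray, n_classes: int, seed: int) -> np.ndarray:
    """Seeded k-means on intensities; centers sorted ascending."""
    km = KMeans(n_clusters=n_classes, n_init=4, random_state=seed)
    km.fit(values.reshape(-1, 1))
    return np.sort(km.cluster_centers_.ravel())


def _histogram_peak_centers(values: np.ndarray, n_classes: int) -> np.ndarray | None:
    """Class centers from smoothed-histogram modes, gap-filled up to K.

    Intensity classes of strongly unbalanced size (a dominant
    interchromatin background class) defeat SSE-based initializers such
    as k-means, which split the heavy mode and merge sparse ones;
    histogram peaks recover mode centers regardless of their mass.  A
    sparse class riding on the tail of a heavy one appears only as a
    shoulder, not a local maximum, so when fewer than K peaks are found
    the widest gaps between adjacent centers are bisected until K
    centers exist.
    """
    hist, edges = np.histogram(values, bins=256)
    sm = ndimage.gaussian_filter1d(hist.astype(float), sigma=2.0)
    mids = (edges[:-1] + edges[1:]) / 2.0
    interior = np.arange(1, 255)
    is_peak = (sm[interior] >= sm[interior - 1]) & (sm[interior] > sm[interior + 1])
    peaks = interior[is_peak]
    if peaks.size < 2:
        return None
    if peaks.size > n_classes:
        peaks = peaks[np.argsort(sm[peaks])[::-1][: n_classes]]
    centers = sorted(mids[peaks])
    while len(centers) < n_classes:
        gaps = np.diff(centers)
        i = int(np.argmax(gaps))
        centers.insert(i + 1, (centers[i] + centers[i + 1]) / 2.0)
    return np.asarray(centers)


def _init_candidates(
    values: np.ndarray, n_classes: int, seed: int
) -> list[np.ndarray]:
    """Candidate initial class means for the multi-start fit."""
    cands = [_kmeans_centers(values, n_classes, seed)]
    lo, hi = np.percentile(values, [0.5, 99.5])
    if hi > lo:
        cands.append(np.linspace(lo, hi, n_classes))
    peaks = _histogram_peak_centers(values, n_classes)
    if peaks is not None and np.unique(peaks).size == n_classes:
        cands.append(peaks)
    return cands


def _estimate(
    values: np.ndarray,
    lab0: np.ndarray,
    n_classes: int,
    mu_prev: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """(mu, sigma2, pi) from a hard labeling (labels 0-based).

    Empty classes keep their previous mean and receive a small floor
    weight so they can be repopulated in later sweeps.  The shared
    variance is the pooled within-class variance, floored to stay
    positive for degenerate (noise-free) data.
    """
    counts = np.bincount(lab0, minlength=n_classes).astype(float)
    mu = np.zeros(n_classes)
    for k in range(n_classes):
        if counts[k] > 0:
            mu[k] = values[lab0 == k].mean()
        elif mu_prev is not None:
            mu[k] = mu_prev[k]
    sigma2 = float(np.sum((values - mu[lab0]) ** 2) / values.size)
    vrange = float(values.max() - values.min())
    sigma2 = max(sigma2, 1e-10 * vrange**2, 1e-30)
    pi = np.maximum(counts, 0.5) / np.maximum(counts, 0.5).sum()
    return mu, sigma2, pi


def _sort_components(
    mu: np.ndarray, pi: np.ndarray, labels: np.ndarray, member: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Keep components ordered by ascending mean, remapping labels."""
    order = np.argsort(mu, kind="stable")
    if np.array_equal(order, np.arange(len(mu))):
        return mu, pi, labels
    remap = np.zeros(len(mu) + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, len(mu) + 1)
    labels = np.where(member, remap[labels], 0)
    return mu[order], pi[order], labels


def _soft_em(
    values: np.ndarray,
    mu0: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Soft EM for the shared-variance Gaussian mixture from given means.

    Returns ``(mu, sigma2, pi, loglik)`` at convergence.  Used to refine
    every restart and to select among restarts by the incomplete-data
    likelihood: hard (classification) assignments truncate the tails of
    overlapping components and systematically understate the fit of the
    correct solution, so model selection must use the proper EM optimum.
    """
    k = len(mu0)
    mu = mu0.astype(float).copy()
    sigma2 = max(float(np.var(values)) / k, 1e-12)
    pi = np.full(k, 1.0 / k)
    ll_old = -np.inf
    ll = ll_old
    for _ in range(max_iter):
        logp = (
            -((values[:, None] - mu[None, :]) ** 2) / (2.0 * sigma2)
            + np.log(np.maximum(pi, 1e-300))[None, :]
            - 0.5 * np.log(2.0 * np.pi * sigma2)
        )
        m = logp.max(axis=1)
        lse = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        mu = (resp * values[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        sigma2 = float(
            (resp * (values[:, None] - mu[None, :]) ** 2).sum() / values.size
        )
        vrange = float(values.max() - values.min())
        sigma2 = max(sigma2, 1e-10 * vrange**2, 1e-30)
        pi = nk / values.size
        if ll - ll_old < tol * abs(ll):
            break
        ll_old = ll
    return mu, sigma2, pi, ll


def _run_cem(
    mu: np.ndarray,
    sigma2: float,
    pi: np.ndarray,
    values: np.ndarray,
    voxels: np.ndarray,
    member: np.ndarray,
    parity: np.ndarray,
    n_classes: int,
    beta: float,
    max_iter: int,
    tol: float,
    use_pi: bool,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool, int]:
    """ICM / re-estimation loop from given mixture parameters."""
    params0 = MixtureParams(n_classes, _ascending(mu), sigma2, pi, beta)
    cost = _data_cost(values[None, None, :], params0, use_pi)
    lab0 = np.argmin(cost[:, 0, 0, :], axis=0)
    labels = np.zeros(voxels.shape, dtype=np.int16)
    labels[member] = lab0 + 1

    n_in = values.size
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        params = MixtureParams(n_classes, _ascending(mu), sigma2, pi, beta)
        new_labels = icm_sweep(labels, voxels, member, params, use_pi, parity)
        changed = np.count_nonzero(new_labels[member] != labels[member]) / n_in
        labels = new_labels
        mu, sigma2, pi = _estimate(values, labels[member] - 1, n_classes, mu)
        mu, pi, labels = _sort_components(mu, pi, labels, member)
        if changed < tol:
            converged = True
            break
    return labels, mu, sigma2, pi, converged, it


def _ascending(mu: np.ndarray) -> np.ndarray:
    """Nudge exact ties apart so the means are strictly ascending."""
    mu = mu.copy()
    for k in range(1, len(mu)):
        if mu[k] <= mu[k - 1]:
            mu[k] = np.nextafter(mu[k - 1], np.inf)
    return mu


def classify_hmrf(
    dapi: ImageStack,
    mask: NucleusMask,
    n_classes: int = 7,
    beta: float = 0.5,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-3,
    use_pi: bool = True,
) -> tuple[ClassMap, MixtureParams]:
    """Hidden-Markov-random-field classification of in-mask DAPI voxels.

    Two stages.  (1) Model fit: the shared-variance mixture is fitted by
    soft EM from several initializations (seeded k-means centers, evenly
    spaced intensities, gap-filled histogram peaks) and the solution with
    the highest incomplete-data log-likelihood is kept.  Multiple
    restarts are needed because a dominant interchromatin class traps
    SSE-based initializers in mode-splitting local optima; selection
    uses the pure mixture likelihood because the Potts term rewards
    merging thin layered classes and must not arbitrate between basins.
    (2) Labeling: starting from the MAP assignment under the selected
    parameters, checkerboard ICM sweeps alternate with re-estimation of
    (mu, sigma^2, pi) until the fraction of changed labels drops below
    ``tol`` or ``max_iter`` sweeps are reached (the result is then
    flagged as non-converged).  Deterministic for fixed ``seed`` and
    input.
    """
    if dapi.shape != mask.shape:
        raise ValueError("stack and mask shapes differ")
    member = mask.member
    if not member.any():
        raise EmptyMaskError("nuclear mask is empty")
    values = dapi.voxels[member].astype(float)
    if np.unique(values).size < n_classes:
        raise DegenerateFitError(
            f"need >= {n_classes} distinct in-mask intensities"
        )

    voxels = dapi.voxels.astype(float)
    parity = _parity(dapi.shape)

    best = None
    best_ll = -np.inf
    for mu0 in _init_candidates(values, n_classes, seed):
        mu, sigma2, pi, ll = _soft_em(values, mu0)
        if ll > best_ll + 1e-9:
            best_ll = ll
            best = (mu, sigma2, pi)
    mu, sigma2, pi = best  # type: ignore[misc]
    order = np.argsort(mu, kind="stable")
    mu, pi = mu[order], pi[order]

    labels, mu, sigma2, pi, converged, it = _run_cem(
        mu, sigma2, pi, values, voxels, member, parity, n_classes, beta,
        max_iter, tol, use_pi,
    )
    params = MixtureParams(
        n_classes, _ascending(mu), sigma2, pi, beta,
        converged=converged, n_iter=it,
    )
    if not params.converged:
        log.warning("HMRF did not converge within %d sweeps", max_iter)
    return ClassMap(labels, n_classes), params


def classify_gmm(
    dapi: ImageStack,
    mask: NucleusMask,
    n_classes: int = 7,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-3,
    use_pi: bool = True,
) -> tuple[ClassMap, MixtureParams]:
    """Equal-variance Gaussian mixture classification (no spatial prior).

    Hard-assignment (classification) EM: each voxel is assigned its MAP
    component at every step.  Identical to :func:`classify_hmrf` with
    ``beta = 0``, which makes the mixture fit the exact spatial-model
    oracle for the Potts-free limit.
    """
    return classify_hmrf(
        dapi, mask, n_classes=n_classes, beta=0.0, seed=seed,
        max_iter=max_iter, tol=tol, use_pi=use_pi,
    )


def decision_boundary(params: MixtureParams, k: int) -> float:
    """Intensity at which classes ``k`` and ``k+1`` (1-based) are equi-cost.

    For equal weights the boundary is the midpoint of the two means; the
    weight term shifts it by ``sigma^2 log(pi_k / pi_{k+1}) / (mu_{k+1} -
    mu_k)``.
    """
    mu1, mu2 = params.mu[k - 1], params.mu[k]
    pi1, pi2 = params.pi[k - 1], params.pi[k]
    return float((mu1 + mu2) / 2.0 + params.sigma2 * np.log(pi1 / pi2) / (mu2 - mu1))


def class_fractions(class_map: ClassMap, mask: NucleusMask) -> ClassProfile:
    """Fraction of in-mask voxels per compaction class (sums to 1)."""
    member = mask.member
    if not member.any():
        raise EmptyMaskError("nuclear mask is empty")
    lab = class_map.labels[member]
    counts = np.bincount(lab, minlength=class_map.n_classes + 1)[1:]
    total = counts.sum()
    if total == 0:
        raise EmptyMaskError("no labeled voxels inside the mask")
    return ClassProfile(counts / total, source="dapi")
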