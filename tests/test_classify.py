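"""Chromatin compaction classification: mixture fit, ICM, invariants."""

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

import topomap as tm
from topomap.classify import (
    MixtureParams,
    _parity,
    decision_boundary,
    icm_sweep,
    labeling_energy,
)


@pytest.fixture(scope="module")
def two_level_stack():
    rng = np.random.default_rng(0)
    v = np.concatenate([rng.normal(100, 5, 2000), rng.normal(200, 5, 2000)])
    rng.shuffle(v)
    stack = tm.ImageStack(
        np.clip(v.reshape(10, 20, 20), 0, None), (100.0, 100.0, 100.0)
    )
    return stack, tm.NucleusMask(np.ones((10, 20, 20), bool))


def test_two_component_boundary_near_midpoint(two_level_stack):
    """Half N(100,5), half N(200,5): the decision boundary sits at
    150 +- 2 and all low voxels get class 1."""
    stack, mask = two_level_stack
    cmap, params = tm.classify_gmm(stack, mask, n_classes=2, seed=0)
    assert decision_boundary(params, 1) == pytest.approx(150.0, abs=2.0)
    assert np.all(cmap.labels[stack.voxels < 150.0 - 2.0] == 1)
    assert np.all(cmap.labels[stack.voxels > 150.0 + 2.0] == 2)


def test_boundary_agrees_with_sklearn_tied_mixture(two_level_stack):
    """Independent soft-EM oracle: sklearn tied-covariance mixture finds
    the same means and boundary."""
    stack, mask = two_level_stack
    _, params = tm.classify_gmm(stack, mask, n_classes=2, seed=0)
    gm = GaussianMixture(
        2, covariance_type="tied", random_state=0, n_init=3
    ).fit(stack.voxels.reshape(-1, 1))
    mu = np.sort(gm.means_.ravel())
    np.testing.assert_allclose(params.mu, mu, atol=1.0)
    s2 = float(np.ravel(gm.covariances_)[0])
    sk_boundary = (mu[0] + mu[1]) / 2 + s2 * np.log(
        gm.weights_[np.argsort(gm.means_.ravel())][0]
        / gm.weights_[np.argsort(gm.means_.ravel())][1]
    ) / (mu[1] - mu[0])
    assert decision_boundary(params, 1) == pytest.approx(sk_boundary, abs=2.0)


def test_uniform_image_is_degenerate():
    stack = tm.ImageStack(np.full((6, 6, 6), 9.0), (100.0, 100.0, 100.0))
    mask = tm.NucleusMask(np.ones((6, 6, 6), bool))
    with pytest.raises(tm.DegenerateFitError):
        tm.classify_gmm(stack, mask, n_classes=2)


def test_noise_free_phantom_classified_exactly():
    """With sigma=0 and no blur the seven exact levels are recovered
    voxel for voxel."""
    cfg = tm.PhantomConfig(
        seed=7, noise_sd=0.0, psf_sigma_nm=(0.0, 0.0), channel_noise_sd=0.0
    )
    r = tm.generate_phantom(cfg)
    cmap, _ = tm.classify_hmrf(r.dapi, r.truth.mask, 7, beta=0.5, seed=0)
    member = r.truth.mask.member
    np.testing.assert_array_equal(
        cmap.labels[member], r.truth.class_map.labels[member]
    )


def test_beta_zero_equals_plain_mixture(small_phantom):
    """The Potts-free HMRF is voxelwise identical to the mixture MAP."""
    mask = small_phantom.truth.mask
    a, pa = tm.classify_hmrf(small_phantom.dapi, mask, 7, beta=0.0, seed=0)
    b, pb = tm.classify_gmm(small_phantom.dapi, mask, 7, seed=0)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_allclose(pa.mu, pb.mu)


def _count_singletons(labels, n_classes):
    from scipy import ndimage

    n = 0
    for k in range(1, n_classes + 1):
        lab, cnt = ndimage.label(labels == k)
        if cnt:
            n += int(np.sum(np.bincount(lab.ravel())[1:] == 1))
    return n


def test_potts_prior_suppresses_salt_and_pepper():
    """On a corrupted two-level image, beta=1 leaves strictly fewer
    isolated single-voxel labels than beta=0."""
    rng = np.random.default_rng(1)
    shape = (24, 32, 32)
    base = np.where(
        np.arange(shape[2])[None, None, :] < 16, 100.0, 200.0
    ) * np.ones(shape)
    flip = rng.random(shape) < 0.05
    base[flip] = 300.0 - base[flip]
    base += rng.normal(0, 35, shape)
    stack = tm.ImageStack(np.clip(base, 0, None), (100.0, 100.0, 100.0))
    mask = tm.NucleusMask(np.ones(shape, bool))
    cm0, _ = tm.classify_hmrf(stack, mask, 2, beta=0.0, seed=0)
    cm1, _ = tm.classify_hmrf(stack, mask, 2, beta=1.0, seed=0)
    assert _count_singletons(cm1.labels, 2) < _count_singletons(cm0.labels, 2)


def test_noisy_shell_phantom_recovery(recovery_phantom):
    """Noise at 0.3x the class gap: >= 90% voxelwise truth agreement."""
    mask = recovery_phantom.truth.mask
    cmap, params = tm.classify_hmrf(
        recovery_phantom.dapi, mask, 7, beta=0.5, seed=0
    )
    member = mask.member
    agreement = np.mean(
        cmap.labels[member] == recovery_phantom.truth.class_map.labels[member]
    )
    assert agreement >= 0.90
    assert params.converged


def test_class_means_ascend_and_match_data(recovery_phantom):
    mask = recovery_phantom.truth.mask
    cmap, params = tm.classify_hmrf(
        recovery_phantom.dapi, mask, 7, beta=0.5, seed=0
    )
    assert np.all(np.diff(params.mu) > 0)
    member = mask.member
    observed = [
        recovery_phantom.dapi.voxels[member][cmap.labels[member] == k].mean()
        for k in range(1, 8)
        if np.any(cmap.labels[member] == k)
    ]
    assert np.all(np.diff(observed) >= 0)


def test_icm_energy_monotone_at_fixed_params(small_phantom):
    """Total posterior energy never increases across ICM sweeps."""
    mask = small_phantom.truth.mask
    voxels = small_phantom.dapi.voxels.astype(float)
    rng = np.random.default_rng(3)
    labels = np.zeros(voxels.shape, dtype=np.int16)
    labels[mask.member] = rng.integers(1, 8, size=mask.n_voxels)
    params = MixtureParams(
        7, np.array([40.0, 55, 70, 85, 100, 115, 130.0]), 25.0,
        np.full(7, 1 / 7), beta=0.7,
    )
    parity = _parity(voxels.shape)
    energies = [labeling_energy(labels, voxels, mask.member, params)]
    for _ in range(5):
        labels = icm_sweep(labels, voxels, mask.member, params, True, parity)
        energies.append(labeling_energy(labels, voxels, mask.member, params))
    assert np.all(np.diff(energies) <= 1e-9)


def test_classification_is_deterministic(small_phantom):
    mask = small_phantom.truth.mask
    a, _ = tm.classify_hmrf(small_phantom.dapi, mask, 7, beta=0.5, seed=4)
    b, _ = tm.classify_hmrf(small_phantom.dapi, mask, 7, beta=0.5, seed=4)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_labels_zero_outside_mask(small_phantom):
    mask = small_phantom.truth.mask
    cmap, _ = tm.classify_hmrf(small_phantom.dapi, mask, 7, seed=0)
    assert np.all(cmap.labels[~mask.member] == 0)
    assert np.all(cmap.labels[mask.member] >= 1)


def test_class_fractions_equal_counts():
    labels = np.zeros((2, 2, 2), np.int16)
    labels[0] = 1
    labels[1] = 2
    cmap = tm.ClassMap(labels, 7)
    mask = tm.NucleusMask(np.ones((2, 2, 2), bool))
    prof = tm.class_fractions(cmap, mask)
    np.testing.assert_allclose(prof.fractions, [0.5, 0.5, 0, 0, 0, 0, 0])


def test_class_fractions_sum_to_one(default_phantom):
    prof = tm.class_fractions(
        default_phantom.truth.class_map, default_phantom.truth.mask
    )
    assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-12)


def test_class_fractions_empty_mask():
    cmap = tm.ClassMap(np.zeros((2, 2, 2), np.int16), 7)
    with pytest.raises(tm.EmptyMaskError):
        tm.class_fractions(cmap, tm.NucleusMask(np.zeros((2, 2, 2), bool)))
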