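"""Shared phantom fixtures.

Phantoms are generated once per session; tests must not mutate them.
Layered-truth fixtures use 50 nm axial sampling so that one voxel step
never spans more than one ~80 nm compaction shell — at the acquisition
default of 125 nm an axial step crosses two class boundaries and the
voxel-level truth is not recoverable by any classifier.
"""

import pytest

import topomap as tm


@pytest.fixture(scope="session")
def default_phantom() -> tm.PhantomResult:
    """One phantom at the default acquisition geometry (125 nm axial)."""
    return tm.generate_phantom(tm.PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_phantom() -> tm.PhantomResult:
    """Noise-only phantom with axially resolvable shells for
    classification ground-truth recovery."""
    cfg = tm.PhantomConfig(
        seed=1,
        shape=(64, 64, 64),
        spacing=(50.0, 39.5, 39.5),
        semi_axes_nm=(1400.0, 1100.0, 1100.0),
        n_cdcs=6,
        cdc_radius_nm=(400.0, 550.0),
        psf_sigma_nm=(0.0, 0.0),
    )
    return tm.generate_phantom(cfg)


@pytest.fixture(scope="session")
def single_cdc_phantom() -> tm.PhantomResult:
    """Clean single-CDC phantom: exact radial layering, no rim/noise."""
    cfg = tm.PhantomConfig(
        seed=5,
        shape=(64, 64, 64),
        spacing=(50.0, 39.5, 39.5),
        semi_axes_nm=(1400.0, 1100.0, 1100.0),
        n_cdcs=1,
        cdc_radius_nm=(620.0, 620.0),
        rim_nm=0.0,
        noise_sd=0.0,
        psf_sigma_nm=(0.0, 0.0),
        channel_noise_sd=0.0,
        spot_class_probs=None,
    )
    return tm.generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_phantom_config() -> tm.PhantomConfig:
    """Fast sub-32^3 phantom for pipeline and oracle-equivalence tests."""
    return tm.PhantomConfig(
        seed=11,
        shape=(24, 32, 32),
        spacing=(50.0, 39.5, 39.5),
        semi_axes_nm=(500.0, 550.0, 550.0),
        n_cdcs=3,
        cdc_radius_nm=(300.0, 430.0),
        rim_nm=100.0,
        spots_per_channel=4,
        speckles_per_channel=1.0,
        psf_sigma_nm=(0.0, 0.0),
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config) -> tm.PhantomResult:
    return tm.generate_phantom(small_phantom_config)
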