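import numpy as np
import pytest

from octvario import LayerBoundaries, SyntheticParams

#: small synthetic geometry for fast tests; keeps the anisotropic
#: A-scan/B-scan pitch ratio of the full acquisition field
TINY_GRID = (64, 32, 96)


def make_params(**overrides) -> SyntheticParams:
    base = dict(
        grid=TINY_GRID,
        spacing_x_mm=6.7 / TINY_GRID[0],
        spacing_y_mm=6.7 / TINY_GRID[1],
    )
    base.update(overrides)
    return SyntheticParams(**base)


def make_volume_params(grid=(48, 24, 64), **overrides) -> SyntheticParams:
    """Params with a layer stack scaled to fit a small axial extent."""
    nz = grid[2]
    nsr = 0.3 * nz
    base = dict(
        grid=grid,
        spacing_x_mm=6.7 / grid[0],
        spacing_y_mm=6.7 / grid[1],
        base_depth_ilm=0.15 * nz,
        nsr_thickness_mean=nsr,
        nsr_thickness_sd=0.02 * nz,
        rpedc_thickness_mean=0.08 * nz,
        rpedc_thickness_sd=0.01 * nz,
        pit_depth=0.3 * nsr,
        drusen_amp_range=(0.15 * nsr, 0.4 * nsr),
    )
    base.update(overrides)
    return SyntheticParams(**base)


def constant_case(ilm=10.0, rpe=14.0, bm=15.0, shape=(8, 6), n_axial=32,
                  label="UNKNOWN") -> LayerBoundaries:
    """Case with spatially constant boundary depths."""
    return LayerBoundaries(
        b_ilm=np.full(shape, ilm),
        b_rpe=np.full(shape, rpe),
        b_bm=np.full(shape, bm),
        n_axial=n_axial,
        spacing_x_mm=0.1,
        spacing_y_mm=0.1,
        fovea_xy=(shape[0] // 2, shape[1] // 2),
        label=label,
    )


@pytest.fixture
def tiny_params() -> SyntheticParams:
    return make_params()


@pytest.fixture
def quiet_params() -> SyntheticParams:
    """Noise-free generator: deterministic surfaces, single drusen draw."""
    return make_params(
        surface_noise_sd=0.0,
        nsr_thickness_sd=0.0,
        rpedc_thickness_sd=0.0,
        speckle_cv=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
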