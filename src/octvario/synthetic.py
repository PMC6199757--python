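"""Synthetic SD-OCT boundary surfaces and reflectance volumes.

The generator emulates the morphology the texture method assumes:

* a smooth inner limiting membrane with a Gaussian foveal pit (the
  neurosensory retina thins toward the fovea while the RPE stays flat),
* smooth baseline thickness fields for the neurosensory retina (NSR) and
  the RPE-drusen complex (RPEDC),
* for AMD eyes, drusen as localized Gaussian elevations of the RPE
  border: the border is lifted toward the ILM while Bruch's membrane
  stays put, so the RPEDC thickens focally — total retinal thickness
  (BM - ILM) is untouched by drusen, matching the weak discriminative
  power of the total-retina map,
* optionally a layered reflectance volume with piecewise-constant
  compartment intensities (RPEDC band brightest) under multiplicative
  gamma speckle of a given coefficient of variation.

Smooth surface variation is realized as white noise blurred with a
Gaussian kernel and rescaled to the requested standard deviation, so
thickness maps carry spatial correlation at a controllable length scale
(``noise_corr_mm``) — the regime variogram descriptors are designed for.

The default grid is 200 x 50 x 128 voxels over a 6.7 mm x 6.7 mm field,
a scaled-down version of the 1000 x 512 x 100 acquisition geometry that
keeps the anisotropic A-scan/B-scan pitch ratio; full-size generation is
a parameter change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .types import LABEL_AMD, LABEL_CONTROL, LayerBoundaries, OctVolume

logger = logging.getLogger(__name__)

#: compartment mean intensities (arbitrary reflectance units);
#: vitreous < below-BM < NSR < RPEDC so the RPEDC band is brightest
INTENSITY_VITREOUS = 20.0
INTENSITY_NSR = 90.0
INTENSITY_RPEDC = 160.0
INTENSITY_BELOW_BM = 50.0


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults give a realistic scaled-down cohort.

    All depths/thicknesses are in voxels, lateral lengths in mm.
    """

    grid: tuple[int, int, int] = (200, 50, 128)  # (n_ascan, n_bscan, n_axial)
    spacing_x_mm: float = 6.7 / 200
    spacing_y_mm: float = 6.7 / 50
    base_depth_ilm: float = 30.0
    nsr_thickness_mean: float = 40.0
    nsr_thickness_sd: float = 1.5
    rpedc_thickness_mean: float = 8.0
    rpedc_thickness_sd: float = 1.0
    pit_depth: float = 15.0
    pit_sigma_mm: float = 0.35
    drusen_count_mean: float = 8.0
    drusen_amp_range: tuple[float, float] = (5.0, 20.0)
    drusen_sigma_range_mm: tuple[float, float] = (0.08, 0.25)
    surface_noise_sd: float = 1.0
    noise_corr_mm: float = 0.2
    speckle_cv: float = 0.2
    seed: int = 0

    def validate(self) -> "SyntheticParams":
        nx, ny, nz = self.grid
        if min(nx, ny, nz) < 4:
            raise ValidationError("grid dimensions must all be >= 4")
        if self.nsr_thickness_mean <= 0 or self.rpedc_thickness_mean <= 0:
            raise ValidationError("thickness means must be positive")
        lo, hi = self.drusen_amp_range
        if not (0 <= lo <= hi):
            raise ValidationError("drusen_amp_range must satisfy 0 <= min <= max")
        if hi >= self.nsr_thickness_mean:
            raise ValidationError(
                "max drusen amplitude must stay below the mean NSR thickness "
                "(drusen must not invert boundary order)"
            )
        if self.pit_depth >= self.nsr_thickness_mean:
            raise ValidationError("pit depth must stay below the mean NSR thickness")
        slo, shi = self.drusen_sigma_range_mm
        if not (0 < slo <= shi):
            raise ValidationError("drusen_sigma_range_mm must be positive and ordered")
        total = self.base_depth_ilm + self.nsr_thickness_mean + self.rpedc_thickness_mean
        if total >= nz:
            raise ValidationError(
                f"mean layer stack ({total} voxels) does not fit the axial extent {nz}"
            )
        return self


def _smooth_field(rng: np.random.Generator, shape, sd: float,
                  corr_mm: float, spacing: tuple[float, float]) -> np.ndarray:
    """Zero-mean smooth random field with target pointwise sd."""
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    sig = (max(corr_mm / spacing[0], 1e-9), max(corr_mm / spacing[1], 1e-9))
    f = gaussian_filter(white, sigma=sig, mode="nearest")
    s = f.std()
    if s < 1e-12:
        return np.zeros(shape)
    return f * (sd / s)


def gen_case(params: SyntheticParams, label: str,
             rng: np.random.Generator | int | None = None) -> LayerBoundaries:
    """One synthetic labeled eye.

    Construction: ILM = base plane + foveal pit + smooth noise; the NSR
    thickness field subtracts the pit again so the RPE border is flat on
    average; RPEDC thickness rides on the RPE border.  For AMD eyes
    K ~ Poisson(drusen_count_mean) bumps (K >= 1 enforced) with uniform
    amplitude/width and uniform integer lateral centers are SUBTRACTED
    from the RPE border depth.  Amplitudes are clipped where they would
    cross the ILM; clips are counted and logged.
    """
    params.validate()
    if label not in (LABEL_AMD, LABEL_CONTROL):
        raise ValidationError(f"label must be AMD or CONTROL, got {label!r}")
    rng = np.random.default_rng(params.seed if rng is None else rng)
    nx, ny, nz = params.grid
    sp = (params.spacing_x_mm, params.spacing_y_mm)
    fovea = (nx // 2, ny // 2)

    x_mm = (np.arange(nx)[:, None] - fovea[0]) * sp[0]
    y_mm = (np.arange(ny)[None, :] - fovea[1]) * sp[1]
    r2 = x_mm**2 + y_mm**2
    pit = params.pit_depth * np.exp(-r2 / (2.0 * params.pit_sigma_mm**2))

    e_ilm = _smooth_field(rng, (nx, ny), params.surface_noise_sd, params.noise_corr_mm, sp)
    e_nsr = _smooth_field(rng, (nx, ny), params.nsr_thickness_sd, params.noise_corr_mm, sp)
    e_rpedc = _smooth_field(rng, (nx, ny), params.rpedc_thickness_sd, params.noise_corr_mm, sp)

    b_ilm = params.base_depth_ilm + pit + e_ilm
    b_rpe = b_ilm + (params.nsr_thickness_mean - pit + e_nsr)
    b_bm = b_rpe + (params.rpedc_thickness_mean + e_rpedc)

    if label == LABEL_AMD:
        k = int(rng.poisson(params.drusen_count_mean))
        k = max(k, 1)
        bumps = np.zeros((nx, ny))
        for _ in range(k):
            cx = int(rng.integers(0, nx))
            cy = int(rng.integers(0, ny))
            amp = float(rng.uniform(*params.drusen_amp_range))
            sig = float(rng.uniform(*params.drusen_sigma_range_mm))
            d2 = ((np.arange(nx)[:, None] - cx) * sp[0]) ** 2 + (
                (np.arange(ny)[None, :] - cy) * sp[1]
            ) ** 2
            bumps += amp * np.exp(-d2 / (2.0 * sig**2))
        b_rpe = b_rpe - bumps
        n_clip = int(np.count_nonzero(b_rpe < b_ilm))
        if n_clip:
            logger.info("clipped %d drusen pixel(s) at the ILM", n_clip)
            b_rpe = np.maximum(b_rpe, b_ilm)

    # keep depths inside the axial range
    for arr in (b_ilm, b_rpe, b_bm):
        np.clip(arr, 0.0, nz - 1e-6, out=arr)
    b_rpe = np.clip(b_rpe, b_ilm, b_bm)

    case = LayerBoundaries(
        b_ilm=b_ilm, b_rpe=b_rpe, b_bm=b_bm, n_axial=nz,
        spacing_x_mm=sp[0], spacing_y_mm=sp[1], fovea_xy=fovea,
        case_id="synthetic", label=label,
    )
    return case.validate()


def gen_volume(case: LayerBoundaries, params: SyntheticParams,
               rng: np.random.Generator | int | None = None) -> OctVolume:
    """Layered reflectance volume consistent with a boundary case.

    Piecewise-constant compartment means (vitreous < NSR < RPEDC band >
    below-BM, RPEDC brightest) multiplied by gamma-distributed speckle of
    unit mean and coefficient of variation ``speckle_cv``; cv = 0 yields
    the exact compartment means.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    nx, ny = case.n_ascan, case.n_bscan
    nz = case.n_axial
    z = np.arange(nz)[None, :, None]
    ilm = case.b_ilm[:, None, :]
    rpe = case.b_rpe[:, None, :]
    bm = case.b_bm[:, None, :]
    mean = np.where(
        z < ilm, INTENSITY_VITREOUS,
        np.where(z < rpe, INTENSITY_NSR,
                 np.where(z < bm, INTENSITY_RPEDC, INTENSITY_BELOW_BM)),
    ).astype(float)
    if params.speckle_cv > 0:
        shape_k = 1.0 / params.speckle_cv**2
        noise = rng.gamma(shape_k, 1.0 / shape_k, size=(nx, nz, ny))
        mean = mean * noise
    vol = OctVolume(
        reflectance=mean,
        spacing_x_mm=case.spacing_x_mm,
        spacing_y_mm=case.spacing_y_mm,
        fovea_xy=case.fovea_xy,
        case_id=case.case_id,
        label=case.label,
    )
    return vol.validate(case)


def gen_cohort(params: SyntheticParams, n_amd: int, n_control: int,
               seed: int | None = None) -> list[LayerBoundaries]:
    """Reproducible labeled cohort: AMD cases first, then controls.

    Per-case RNG streams are spawned deterministically from the cohort
    seed, so the cohort is identical across runs and platforms for a
    fixed seed.
    """
    if n_amd < 0 or n_control < 0:
        raise ValidationError("cohort counts must be nonnegative")
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_amd + n_control)
    cohort: list[LayerBoundaries] = []
    for i in range(n_amd):
        c = gen_case(params, LABEL_AMD, np.random.default_rng(children[i]))
        cohort.append(replace(c, case_id=f"amd_{i:03d}"))
    for i in range(n_control):
        c = gen_case(params, LABEL_CONTROL, np.random.default_rng(children[n_amd + i]))
        cohort.append(replace(c, case_id=f"ctl_{i:03d}"))
    return cohort
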