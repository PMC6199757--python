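"""En-face reflectance projection along the RPE border.

At each lateral position (x, y) the projection value is the mean
reflectance over the axial window centred on the RPE border,
``z in [round(b_rpe) - d, round(b_rpe) + d]``, intersected with the
volume's axial range.  Averaging over +/- d voxels makes the projection
more robust to speckle; d = 0 samples the border voxel itself.

Fractional boundary depths are rounded half-to-even before windowing
(the projection indexes voxels, it does not interpolate).  Where the
window is clipped by the top or bottom of the volume the mean shrinks to
the in-range voxels, keeping the map dense; with ``strict=True`` such
pixels are masked instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .types import OctVolume


@dataclass
class EnFaceMap:
    """Masked en-face mean-reflectance grid with its axial half-window d."""

    values: np.ndarray
    mask: np.ndarray
    d: int
    spacing_x_mm: float
    spacing_y_mm: float
    fovea_xy: tuple[float, float]
    case_id: str = ""
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    def validate(self) -> "EnFaceMap":
        if self.d < 0:
            raise ValidationError("d must be >= 0")
        v = self.values[self.mask]
        if v.size and (not np.all(np.isfinite(v)) or v.min() < 0):
            raise ValidationError("en-face map has invalid values under the mask")
        return self


def reconstruct_enface(volume: OctVolume, b_rpe: np.ndarray, d: int,
                       strict: bool = False) -> EnFaceMap:
    """Mean reflectance in the +/- d voxel window around the RPE border.

    Parameters
    ----------
    volume
        Reflectance indexed (x, z, y).
    b_rpe
        RPE border depth grid, shape (n_ascan, n_bscan); non-finite
        entries are masked out.
    d
        Axial half-window in voxels (integer >= 0, < n_axial).
    strict
        Mask pixels whose window is clipped at the volume edge instead of
        shrinking the mean.
    """
    d = int(d)
    if d < 0:
        raise ValidationError("d must be >= 0")
    refl = volume.reflectance
    nx, nz, ny = refl.shape
    if d >= nz:
        raise ValidationError(f"d={d} must be smaller than the axial extent {nz}")
    b = np.asarray(b_rpe, dtype=float)
    if b.shape != (nx, ny):
        raise ValidationError(
            f"boundary shape {b.shape} does not match volume lateral grid {(nx, ny)}"
        )
    finite = np.isfinite(b)
    zc = np.zeros(b.shape, dtype=np.int64)
    zc[finite] = np.rint(b[finite]).astype(np.int64)  # half-to-even

    total = np.zeros((nx, ny))
    count = np.zeros((nx, ny), dtype=np.int64)
    for off in range(-d, d + 1):
        z = zc + off
        ok = finite & (z >= 0) & (z < nz)
        zi = np.clip(z, 0, nz - 1)
        sampled = np.take_along_axis(refl, zi[:, None, :], axis=1)[:, 0, :]
        total += np.where(ok, sampled, 0.0)
        count += ok
    mask = finite & (count > 0)
    if strict:
        mask &= count == (2 * d + 1)
    values = np.zeros((nx, ny))
    nonzero = count > 0
    values[nonzero] = total[nonzero] / count[nonzero]
    return EnFaceMap(
        values=values,
        mask=mask,
        d=d,
        spacing_x_mm=volume.spacing_x_mm,
        spacing_y_mm=volume.spacing_y_mm,
        fovea_xy=volume.fovea_xy,
        case_id=volume.case_id,
        label=volume.label,
    )
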