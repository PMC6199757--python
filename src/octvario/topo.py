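"""Topographic thickness maps and the fovea-centered region of interest.

Three maps are derived from the boundary surfaces by counting the voxels
between two borders, i.e. plain subtraction on the depth grids:

* TR    (total retina)      = BM  - ILM
* NSR   (neurosensory)      = RPE - ILM
* RPEDC (RPE + drusen)      = BM  - RPE

so that TR = NSR + RPEDC holds exactly at every pixel.  Thickness stays
in voxel units; a micrometre conversion is display-only and never feeds
feature extraction.  Maps are kept on the native (possibly anisotropic)
lateral grid — no resampling to a square raster.

The region of interest is a disc of a given physical radius (mm) around
the fovea marking, which becomes an ellipse in pixel indices when the
A-scan and B-scan spacings differ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .types import LayerBoundaries

LAYER_TR = "TR"
LAYER_NSR = "NSR"
LAYER_RPEDC = "RPEDC"


@dataclass
class ThicknessMap:
    """Masked 2-D thickness grid for one retinal compartment."""

    values: np.ndarray
    mask: np.ndarray
    layer: str
    spacing_x_mm: float
    spacing_y_mm: float
    fovea_xy: tuple[float, float]
    case_id: str = ""
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    def validate(self) -> "ThicknessMap":
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")
        v = self.values[self.mask]
        if v.size and (not np.all(np.isfinite(v)) or v.min() < 0):
            raise ValidationError(f"{self.layer} map has invalid values under the mask")
        return self


def compute_thickness_maps(case: LayerBoundaries) -> tuple[ThicknessMap, ThicknessMap, ThicknessMap]:
    """(TR, NSR, RPEDC) thickness maps from a validated boundary case.

    Subtraction is exact; a negative thickness means a boundary-order
    violation leaked through and raises.
    """
    nsr = case.b_rpe - case.b_ilm
    rpedc = case.b_bm - case.b_rpe
    # summing the two sub-layers keeps TR = NSR + RPEDC bit-exact even on
    # fractional boundaries (equal to BM - ILM up to rounding)
    tr = nsr + rpedc
    for name, arr in ((LAYER_TR, tr), (LAYER_NSR, nsr), (LAYER_RPEDC, rpedc)):
        n_neg = int(np.count_nonzero(arr < 0))
        if n_neg:
            raise ValidationError(
                f"negative {name} thickness at {n_neg} pixel(s): boundary order violated"
            )
    mask = np.ones(tr.shape, dtype=bool)
    common = dict(
        spacing_x_mm=case.spacing_x_mm,
        spacing_y_mm=case.spacing_y_mm,
        fovea_xy=case.fovea_xy,
        case_id=case.case_id,
        label=case.label,
    )
    return (
        ThicknessMap(tr, mask, LAYER_TR, **common),
        ThicknessMap(nsr, mask.copy(), LAYER_NSR, **common),
        ThicknessMap(rpedc, mask.copy(), LAYER_RPEDC, **common),
    )


def apply_roi(m, radius_mm: float):
    """Mask pixels outside a physical disc of ``radius_mm`` around the fovea.

    Works on any map carrying values/mask/spacing/fovea fields
    (thickness or en-face).  Values are untouched; only the mask shrinks.
    Idempotent.  Raises if fewer than 2 pixels survive.
    """
    if radius_mm <= 0:
        raise ValidationError("roi radius must be positive")
    nx, ny = m.values.shape
    fx, fy = m.fovea_xy
    x = (np.arange(nx)[:, None] - fx) * m.spacing_x_mm
    y = (np.arange(ny)[None, :] - fy) * m.spacing_y_mm
    inside = x * x + y * y <= radius_mm * radius_mm
    mask = m.mask & inside
    if int(mask.sum()) < 2:
        raise ValidationError(
            f"ROI radius {radius_mm} mm leaves {int(mask.sum())} pixel(s)"
        )
    return replace(m, mask=mask)
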