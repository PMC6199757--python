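"""Core in-memory containers for segmented SD-OCT cases.

A case is described by three expert-reviewed boundary surfaces over the
lateral (A-scan x, B-scan y) grid: the inner limiting membrane (ILM), the
RPE border, and Bruch's membrane (BM).  Axial depth increases with the
voxel index, so at every lateral position ILM <= RPE <= BM.  Depths are
stored as floats: thickness-by-subtraction is exact on integer voxel
indices and remains well defined for sub-voxel expert boundaries.

Axis convention used by every module: x = A-scan (column axis of maps),
z = axial depth, y = B-scan; a reflectance volume is indexed (x, z, y).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

LABEL_AMD = "AMD"
LABEL_CONTROL = "CONTROL"
LABEL_UNKNOWN = "UNKNOWN"
VALID_LABELS = (LABEL_AMD, LABEL_CONTROL, LABEL_UNKNOWN)


@dataclass
class LayerBoundaries:
    """Three boundary surfaces of one eye on the (A-scan, B-scan) grid.

    Parameters
    ----------
    b_ilm, b_rpe, b_bm
        Axial depth grids of shape ``(n_ascan, n_bscan)`` in voxel units
        (fractional allowed).
    n_axial
        Axial extent of the source volume in voxels.
    spacing_x_mm, spacing_y_mm
        Lateral sampling pitch per A-scan / per B-scan.
    fovea_xy
        Lateral pixel coordinates of the manually marked fovea center.
    """

    b_ilm: np.ndarray
    b_rpe: np.ndarray
    b_bm: np.ndarray
    n_axial: int
    spacing_x_mm: float
    spacing_y_mm: float
    fovea_xy: tuple[float, float]
    case_id: str = ""
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        self.b_ilm = np.asarray(self.b_ilm, dtype=float)
        self.b_rpe = np.asarray(self.b_rpe, dtype=float)
        self.b_bm = np.asarray(self.b_bm, dtype=float)
        self.fovea_xy = (float(self.fovea_xy[0]), float(self.fovea_xy[1]))
        self.n_axial = int(self.n_axial)

    @property
    def n_ascan(self) -> int:
        return self.b_ilm.shape[0]

    @property
    def n_bscan(self) -> int:
        return self.b_ilm.shape[1]

    def order_violations(self) -> int:
        """Number of lateral positions where ILM <= RPE <= BM fails."""
        bad = (self.b_rpe < self.b_ilm) | (self.b_bm < self.b_rpe)
        return int(np.count_nonzero(bad))

    def validate(self) -> "LayerBoundaries":
        """Check all structural invariants; raise ValidationError on failure."""
        if self.b_ilm.ndim != 2:
            raise ValidationError("boundary grids must be 2-D")
        if not (self.b_ilm.shape == self.b_rpe.shape == self.b_bm.shape):
            raise ValidationError(
                f"boundary grids disagree in shape: "
                f"{self.b_ilm.shape}, {self.b_rpe.shape}, {self.b_bm.shape}"
            )
        for name, g in (("ilm", self.b_ilm), ("rpe", self.b_rpe), ("bm", self.b_bm)):
            if not np.all(np.isfinite(g)):
                raise ValidationError(f"non-finite depths in boundary '{name}'")
            if g.min() < 0 or g.max() >= self.n_axial:
                raise ValidationError(
                    f"boundary '{name}' has depths outside [0, {self.n_axial})"
                )
        n_bad = self.order_violations()
        if n_bad:
            raise ValidationError(
                f"boundary order ILM <= RPE <= BM violated at {n_bad} pixel(s)"
            )
        fx, fy = self.fovea_xy
        if not (0 <= fx < self.n_ascan and 0 <= fy < self.n_bscan):
            raise ValidationError(f"fovea_xy {self.fovea_xy} lies outside the grid")
        if self.label not in VALID_LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        return self

    def repaired(self) -> tuple["LayerBoundaries", int]:
        """Clamp b_rpe into [b_ilm, b_bm]; return (new case, #pixels changed)."""
        rpe = np.clip(self.b_rpe, self.b_ilm, self.b_bm)
        n_fixed = int(np.count_nonzero(rpe != self.b_rpe))
        return replace(self, b_rpe=rpe), n_fixed


@dataclass
class OctVolume:
    """Reflectance volume paired with a :class:`LayerBoundaries`.

    ``reflectance`` is indexed ``(x: A-scan, z: axial, y: B-scan)`` — the
    native acquisition layout (e.g. 1000 x 512 x 100 voxels over a
    6.7 mm x 6.7 mm field).
    """

    reflectance: np.ndarray
    spacing_x_mm: float
    spacing_y_mm: float
    fovea_xy: tuple[float, float]
    case_id: str = ""
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)

    @property
    def n_ascan(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_axial(self) -> int:
        return self.reflectance.shape[1]

    @property
    def n_bscan(self) -> int:
        return self.reflectance.shape[2]

    def validate(self, case: LayerBoundaries | None = None) -> "OctVolume":
        if self.reflectance.ndim != 3:
            raise ValidationError("reflectance must be 3-D (x, z, y)")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValidationError("reflectance contains non-finite values")
        if self.reflectance.min() < 0:
            raise ValidationError("reflectance contains negative intensities")
        if case is not None:
            expect = (case.n_ascan, case.n_axial, case.n_bscan)
            if self.reflectance.shape != expect:
                raise ValidationError(
                    f"volume shape {self.reflectance.shape} does not match "
                    f"boundaries {expect}"
                )
        return self
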