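"""Fixed-length feature vectors for the eight map x function arrangements.

Each arrangement pairs one 2-D representation of the eye (TR, NSR or
RPEDC thickness map, or the RPE en-face projection) with one estimator
(semivariogram or semimadogram).  The curve values are concatenated
direction-major (0, 45, 90, 135 degrees), lag-ascending within each
direction — with the default geometry that is 4 x 15 = 60 features.
Concatenation (rather than pooling directions) preserves anisotropy.

No normalization happens here: standardization is a classifier-fold
concern, so it cannot leak test-set statistics into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enface import reconstruct_enface
from .errors import ConfigError, ValidationError
from .geostats import SEMIMADOGRAM, SEMIVARIOGRAM, GeostatConfig, GeostatCurve, empirical_curve
from .topo import apply_roi, compute_thickness_maps
from .types import LayerBoundaries, OctVolume

#: arrangement id -> (map key, geostatistical function)
ARRANGEMENTS: dict[str, tuple[str, str]] = {
    "TR-SV": ("TR", SEMIVARIOGRAM),
    "TR-SM": ("TR", SEMIMADOGRAM),
    "NSR-SV": ("NSR", SEMIVARIOGRAM),
    "NSR-SM": ("NSR", SEMIMADOGRAM),
    "RPEDC-SV": ("RPEDC", SEMIVARIOGRAM),
    "RPEDC-SM": ("RPEDC", SEMIMADOGRAM),
    "ENFACE-SV": ("ENFACE", SEMIVARIOGRAM),
    "ENFACE-SM": ("ENFACE", SEMIMADOGRAM),
}

THICKNESS_ARRANGEMENTS = tuple(a for a, (m, _) in ARRANGEMENTS.items() if m != "ENFACE")


@dataclass
class FeatureVector:
    """One case's descriptor under one arrangement."""

    arrangement: str
    values: np.ndarray
    case_id: str = ""
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def build_feature_vector(curve: GeostatCurve, arrangement: str,
                         case_id: str = "", label: str = "UNKNOWN") -> FeatureVector:
    """Flatten a curve direction-major into an arrangement's feature vector."""
    if arrangement not in ARRANGEMENTS:
        raise ConfigError(f"unknown arrangement {arrangement!r}")
    _, func = ARRANGEMENTS[arrangement]
    if curve.config.function != func:
        raise ValidationError(
            f"arrangement {arrangement} expects {func}, curve holds "
            f"{curve.config.function}"
        )
    return FeatureVector(arrangement, curve.flatten(), case_id, label)


def extract_all(case: LayerBoundaries, volume: OctVolume | None = None,
                config: GeostatConfig | None = None,
                roi_radius_mm: float | None = None, d: int | None = None,
                arrangements: tuple[str, ...] | None = None,
                strict: bool = False) -> list[FeatureVector]:
    """All requested feature vectors for one case.

    Parameters
    ----------
    roi_radius_mm
        Physical radius of the fovea-centered region of interest; ``None``
        keeps the full scan field (no silent default radius is assumed).
    d
        Axial half-window for the en-face projection; required if any
        ENFACE arrangement is requested.
    arrangements
        Defaults to all eight when a volume is given, else the six
        thickness arrangements.
    """
    if config is None:
        config = GeostatConfig()
    if arrangements is None:
        arrangements = tuple(ARRANGEMENTS) if volume is not None else THICKNESS_ARRANGEMENTS
    for a in arrangements:
        if a not in ARRANGEMENTS:
            raise ConfigError(f"unknown arrangement {a!r}")
    need_enface = [a for a in arrangements if ARRANGEMENTS[a][0] == "ENFACE"]
    if need_enface and volume is None:
        raise ValidationError(
            f"arrangements {need_enface} (ENFACE) require a reflectance volume"
        )
    if need_enface and d is None:
        raise ConfigError("ENFACE arrangements require the axial half-window d")

    tr, nsr, rpedc = compute_thickness_maps(case)
    maps = {"TR": tr, "NSR": nsr, "RPEDC": rpedc}
    if need_enface:
        maps["ENFACE"] = reconstruct_enface(volume, case.b_rpe, d)
    if roi_radius_mm is not None:
        maps = {k: apply_roi(m, roi_radius_mm) for k, m in maps.items()}

    from dataclasses import replace as _replace

    out: list[FeatureVector] = []
    curve_cache: dict[tuple[str, str], GeostatCurve] = {}
    for a in arrangements:
        map_key, func = ARRANGEMENTS[a]
        key = (map_key, func)
        if key not in curve_cache:
            cfg = _replace(config, function=func)
            curve_cache[key] = empirical_curve(maps[map_key], cfg, strict=strict)
        out.append(build_feature_vector(curve_cache[key], a, case.case_id, case.label))
    return out
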