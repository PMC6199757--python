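"""Directional empirical semivariogram and semimadogram on masked 2-D grids.

For a grid of values DN and a set of unordered pixel pairs (i, j) whose
separation vector falls in a (direction, lag) cell, the two estimators are

    semivariogram   gamma(h) = 1 / (2 N(h)) * sum (DN_i - DN_j)^2
    semimadogram    m(h)     = 1 / (2 N(h)) * sum |DN_i - DN_j|

where N(h) is the number of admitted pairs.  A pair is admitted into the
cell for direction theta and lag h when its separation vector v satisfies
all of:

* distance:   max(1, h - lag_tolerance) <= |v| <= h + lag_tolerance
  (closed interval, Euclidean; the lower clamp at 1 excludes the
  zero-offset self pair),
* angle:      the acute angle between v and the direction axis, taken
  modulo 180 degrees, is at most ``angular_tolerance_deg`` (a half-angle),
* bandwidth:  the perpendicular distance of v from the direction axis is
  at most ``bandwidth_px``.

Directions are measured counterclockwise with x = the map column axis
(A-scan axis) and y = the row axis.  Both estimators are symmetric in the
pair, so separation vectors are canonicalized to the half-plane
``dx > 0 or (dx == 0 and dy > 0)`` and each unordered pair is counted
exactly once; direction theta and theta + 180 are therefore identical.

With unit lag spacing and lag_tolerance = 3 the distance annuli of
adjacent lags overlap; values at neighboring lags are correlated by
construction.  This mirrors the estimator the feature extraction relies
on and is intentional.

The fast path (:func:`empirical_curve`) precomputes the admissible set of
integer offsets once per (direction, lag) and accumulates shifted-grid
differences under the joint validity mask — mathematically identical to
enumerating pixel pairs.  :func:`brute_force_curve` is the independent
O(P^2) pair-enumeration reference used as a test oracle.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

SEMIVARIOGRAM = "SEMIVARIOGRAM"
SEMIMADOGRAM = "SEMIMADOGRAM"
UNITS_PIXEL = "PIXEL"
UNITS_PHYSICAL = "PHYSICAL"

#: slack on closed-interval geometric comparisons so that e.g. an offset at
#: exactly |v| = lag + tolerance is admitted despite floating-point noise
_GEOM_EPS = 1e-9


@dataclass(frozen=True)
class GeostatConfig:
    """Pair-selection geometry for directional variography.

    Defaults follow the standard image-texture setup: lags 1..15 pixels
    with tolerance +/-3, directions 0/45/90/135 degrees with a 10 degree
    half-angle, and a maximum bandwidth of 3 pixels.
    """

    lags: tuple[int, ...] = tuple(range(1, 16))
    lag_tolerance: float = 3.0
    directions_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    angular_tolerance_deg: float = 10.0
    bandwidth_px: float = 3.0
    function: str = SEMIVARIOGRAM
    units: str = UNITS_PIXEL

    def __post_init__(self) -> None:
        lags = tuple(int(h) for h in self.lags)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "directions_deg", tuple(float(t) for t in self.directions_deg))
        if not lags or any(h < 1 for h in lags):
            raise ConfigError("lags must be positive integers >= 1")
        if any(b <= a for a, b in zip(lags, lags[1:])):
            raise ConfigError("lags must be strictly increasing")
        if self.lag_tolerance < 0:
            raise ConfigError("lag_tolerance must be nonnegative")
        if not (0 <= self.angular_tolerance_deg < 90):
            raise ConfigError("angular_tolerance_deg must lie in [0, 90)")
        if self.bandwidth_px < 0:
            raise ConfigError("bandwidth_px must be nonnegative")
        if self.function not in (SEMIVARIOGRAM, SEMIMADOGRAM):
            raise ConfigError(f"unknown function {self.function!r}")
        if self.units not in (UNITS_PIXEL, UNITS_PHYSICAL):
            raise ConfigError(f"unknown units {self.units!r}")

    @property
    def n_features(self) -> int:
        return len(self.directions_deg) * len(self.lags)

    def check_grid(self, shape: tuple[int, int]) -> None:
        """Reject geometry that cannot fit the grid at all."""
        reach = max(self.lags) + self.lag_tolerance
        if reach > max(shape):
            raise ConfigError(
                f"max lag + tolerance ({reach}) exceeds the grid's larger "
                f"dimension ({max(shape)})"
            )

    def to_dict(self) -> dict:
        return {
            "lags": list(self.lags),
            "lag_tolerance": self.lag_tolerance,
            "directions_deg": list(self.directions_deg),
            "angular_tolerance_deg": self.angular_tolerance_deg,
            "bandwidth_px": self.bandwidth_px,
            "function": self.function,
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeostatConfig":
        return cls(
            lags=tuple(d["lags"]),
            lag_tolerance=d["lag_tolerance"],
            directions_deg=tuple(d["directions_deg"]),
            angular_tolerance_deg=d["angular_tolerance_deg"],
            bandwidth_px=d["bandwidth_px"],
            function=d["function"],
            units=d["units"],
        )


@dataclass
class GeostatCurve:
    """Per-(direction, lag) estimator values with pair counts.

    ``values`` and ``pair_counts`` have shape (n_directions, n_lags) in
    the order declared by the config.  Cells with no admissible pairs
    carry value 0 and are flagged in ``empty``.
    """

    values: np.ndarray
    pair_counts: np.ndarray
    config: GeostatConfig
    empty: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=np.int64)
        if self.empty is None:
            self.empty = self.pair_counts == 0
        else:
            self.empty = np.asarray(self.empty, dtype=bool)

    def flatten(self) -> np.ndarray:
        """Direction-major, lag-ascending flattening (feature-vector order)."""
        return self.values.reshape(-1).copy()


def _extract(map_or_values, mask):
    """Accept a map object (values/mask/spacing attrs) or a bare array."""
    if hasattr(map_or_values, "values") and hasattr(map_or_values, "mask"):
        m = map_or_values
        return (
            np.asarray(m.values, dtype=float),
            np.asarray(m.mask, dtype=bool),
            (float(getattr(m, "spacing_x_mm", 1.0)), float(getattr(m, "spacing_y_mm", 1.0))),
        )
    values = np.asarray(map_or_values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return values, np.asarray(mask, dtype=bool), (1.0, 1.0)


def _pair_admissible(ox: float, oy: float, theta_deg: float, lag: float,
                     lag_tol: float, ang_tol: float, bandwidth: float,
                     min_step: float) -> bool:
    """Distance/angle/bandwidth test for one separation vector (ox, oy)."""
    r = math.hypot(ox, oy)
    lo = max(min_step, lag - lag_tol)
    if not (lo - _GEOM_EPS <= r <= lag + lag_tol + _GEOM_EPS):
        return False
    th = math.radians(theta_deg)
    # acute angular distance to the direction axis, modulo 180 degrees
    ang = math.degrees(math.atan2(oy, ox)) % 180.0
    d = abs(ang - theta_deg % 180.0)
    d = min(d, 180.0 - d)
    if d > ang_tol + _GEOM_EPS:
        return False
    perp = abs(ox * math.sin(th) - oy * math.cos(th))
    return perp <= bandwidth + _GEOM_EPS


def admissible_offsets(config: GeostatConfig, direction_deg: float, lag: int,
                       spacing: tuple[float, float] = (1.0, 1.0)) -> list[tuple[int, int]]:
    """Integer lateral offsets (dx, dy) admitted for one (direction, lag) cell.

    Offsets are canonicalized to the half-plane ``dx > 0 or (dx == 0 and
    dy > 0)`` so each unordered pair of pixels is generated exactly once.
    In PIXEL units the spacing argument is ignored; in PHYSICAL units
    distances and angles are evaluated on (dx * spacing_x, dy * spacing_y)
    and lags/bandwidth are interpreted in mm.
    """
    if direction_deg not in config.directions_deg:
        raise ConfigError(f"direction {direction_deg} not declared in config")
    if lag not in config.lags:
        raise ConfigError(f"lag {lag} not declared in config")
    if config.units == UNITS_PIXEL:
        sx = sy = 1.0
        min_step = 1.0
    else:
        sx, sy = spacing
        min_step = min(sx, sy)
    hi = lag + config.lag_tolerance
    nx_max = int(math.floor(hi / sx + _GEOM_EPS))
    ny_max = int(math.floor(hi / sy + _GEOM_EPS))
    out: list[tuple[int, int]] = []
    for dx in range(0, nx_max + 1):
        dy_start = 1 if dx == 0 else -ny_max
        for dy in range(dy_start, ny_max + 1):
            if dx == 0 and dy == 0:
                continue
            if _pair_admissible(dx * sx, dy * sy, direction_deg, lag,
                                config.lag_tolerance, config.angular_tolerance_deg,
                                config.bandwidth_px, min_step):
                out.append((dx, dy))
    return out


def _shifted_pairs(values, mask, dx, dy):
    """Paired (a, b) value arrays for offset (dx, dy), both endpoints valid."""
    nx, ny = values.shape
    if dx >= nx or abs(dy) >= ny:
        return None
    if dy >= 0:
        a = values[: nx - dx, : ny - dy]
        b = values[dx:, dy:]
        ma = mask[: nx - dx, : ny - dy]
        mb = mask[dx:, dy:]
    else:
        a = values[: nx - dx, -dy:]
        b = values[dx:, : ny + dy]
        ma = mask[: nx - dx, -dy:]
        mb = mask[dx:, : ny + dy]
    both = ma & mb
    return a[both], b[both]


def empirical_curve(map_or_values, config: GeostatConfig, mask=None,
                    strict: bool = False) -> GeostatCurve:
    """Directional empirical curve via the shifted-grid fast path.

    Parameters
    ----------
    map_or_values
        A ThicknessMap/EnFaceMap-like object, or a bare 2-D array (then
        ``mask`` may be given separately).
    strict
        If True, any (direction, lag) cell with zero admissible pairs
        raises instead of being zero-filled and flagged.
    """
    values, msk, spacing = _extract(map_or_values, mask)
    if values.shape != msk.shape:
        raise ValidationError("values and mask shapes differ")
    if int(msk.sum()) < 2:
        raise ValidationError("need at least 2 valid pixels")
    config.check_grid(values.shape)

    n_dir, n_lag = len(config.directions_deg), len(config.lags)
    out = np.zeros((n_dir, n_lag))
    counts = np.zeros((n_dir, n_lag), dtype=np.int64)
    sq = config.function == SEMIVARIOGRAM
    for di, theta in enumerate(config.directions_deg):
        for li, lag in enumerate(config.lags):
            acc = 0.0
            n = 0
            for dx, dy in admissible_offsets(config, theta, lag, spacing):
                pair = _shifted_pairs(values, msk, dx, dy)
                if pair is None:
                    continue
                a, b = pair
                if a.size == 0:
                    continue
                d = a - b
                acc += float(np.square(d).sum()) if sq else float(np.abs(d).sum())
                n += a.size
            counts[di, li] = n
            if n > 0:
                out[di, li] = acc / (2.0 * n)
    if counts.sum() == 0:
        raise ValidationError("pair-selection geometry admits no pairs on this grid")
    empty = counts == 0
    if empty.any():
        cells = [
            (config.directions_deg[i], config.lags[j])
            for i, j in zip(*np.nonzero(empty))
        ]
        if strict:
            raise ValidationError(f"empty (direction, lag) cells: {cells}")
        warnings.warn(f"zero-filled empty (direction, lag) cells: {cells}", stacklevel=2)
        logger.warning("empty (direction, lag) cells zero-filled: %s", cells)
    return GeostatCurve(out, counts, config, empty)


def brute_force_curve(map_or_values, config: GeostatConfig, mask=None) -> GeostatCurve:
    """Reference estimator by direct enumeration of all valid pixel pairs.

    O(P^2) in the number of valid pixels; intended for small grids
    (<= ~40 x 40) as an independent oracle for :func:`empirical_curve`.
    Applies the distance/angle/bandwidth tests per pair.
    """
    values, msk, spacing = _extract(map_or_values, mask)
    if int(msk.sum()) < 2:
        raise ValidationError("need at least 2 valid pixels")
    config.check_grid(values.shape)
    if config.units == UNITS_PIXEL:
        sx = sy = 1.0
        min_step = 1.0
    else:
        sx, sy = spacing
        min_step = min(sx, sy)

    xs, ys = np.nonzero(msk)
    vals = values[xs, ys]
    p = xs.size
    ii, jj = np.triu_indices(p, k=1)
    dx = (xs[jj] - xs[ii]).astype(float)
    dy = (ys[jj] - ys[ii]).astype(float)
    # canonicalize each unordered pair's separation to the half-plane
    flip = (dx < 0) | ((dx == 0) & (dy < 0))
    dx[flip] *= -1
    dy[flip] *= -1
    ox, oy = dx * sx, dy * sy
    r = np.hypot(ox, oy)
    ang = np.degrees(np.arctan2(oy, ox)) % 180.0
    diffs = vals[jj] - vals[ii]

    n_dir, n_lag = len(config.directions_deg), len(config.lags)
    out = np.zeros((n_dir, n_lag))
    counts = np.zeros((n_dir, n_lag), dtype=np.int64)
    sq = config.function == SEMIVARIOGRAM
    for di, theta in enumerate(config.directions_deg):
        th = math.radians(theta)
        d = np.abs(ang - theta % 180.0)
        d = np.minimum(d, 180.0 - d)
        in_sector = d <= config.angular_tolerance_deg + _GEOM_EPS
        perp = np.abs(ox * math.sin(th) - oy * math.cos(th))
        in_band = perp <= config.bandwidth_px + _GEOM_EPS
        for li, lag in enumerate(config.lags):
            lo = max(min_step, lag - config.lag_tolerance)
            sel = (
                (r >= lo - _GEOM_EPS)
                & (r <= lag + config.lag_tolerance + _GEOM_EPS)
                & in_sector
                & in_band
            )
            n = int(sel.sum())
            counts[di, li] = n
            if n:
                dd = diffs[sel]
                s = float(np.square(dd).sum()) if sq else float(np.abs(dd).sum())
                out[di, li] = s / (2.0 * n)
    if counts.sum() == 0:
        raise ValidationError("pair-selection geometry admits no pairs on this grid")
    return GeostatCurve(out, counts, config)
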