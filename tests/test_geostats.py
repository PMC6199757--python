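"""Directional semivariogram/semimadogram estimation on masked grids."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octvario import (
    ConfigError,
    GeostatConfig,
    SEMIMADOGRAM,
    SEMIVARIOGRAM,
    ValidationError,
    admissible_offsets,
    brute_force_curve,
    empirical_curve,
)

ZERO_TOL = dict(lag_tolerance=0, angular_tolerance_deg=0, bandwidth_px=0)


def column_gradient_3x3():
    """values[x, y] = x: constant down each column, step 1 across columns."""
    return np.tile(np.arange(3.0)[:, None], (1, 3))


class TestAdmissibleOffsets:
    @pytest.mark.parametrize(
        "direction,lag,expected",
        [(0.0, 1, {(1, 0)}), (90.0, 2, {(0, 2)})],
    )
    def test_axis_aligned_zero_tolerance(self, direction, lag, expected):
        cfg = GeostatConfig(lags=(1, 2), directions_deg=(0.0, 90.0), **ZERO_TOL)
        assert set(admissible_offsets(cfg, direction, lag)) == expected

    def test_direction_plus_180_identical(self):
        cfg = GeostatConfig(directions_deg=(0.0, 45.0, 180.0, 225.0))
        for theta in (0.0, 45.0):
            a = set(admissible_offsets(cfg, theta, 5))
            b = set(admissible_offsets(cfg, theta + 180.0, 5))
            assert a == b

    def test_matches_independent_enumeration(self):
        """Every default (direction, lag) cell against a from-scratch predicate."""
        cfg = GeostatConfig()
        for theta in cfg.directions_deg:
            u = np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta))])
            for lag in cfg.lags:
                hi = lag + cfg.lag_tolerance
                lo = max(1.0, lag - cfg.lag_tolerance)
                expected = set()
                r = int(math.ceil(hi)) + 1
                for dx in range(-r, r + 1):
                    for dy in range(-r, r + 1):
                        if not (dx > 0 or (dx == 0 and dy > 0)):
                            continue
                        v = np.array([dx, dy], dtype=float)
                        dist = np.linalg.norm(v)
                        if not (lo - 1e-9 <= dist <= hi + 1e-9):
                            continue
                        cosang = abs(float(v @ u)) / dist
                        ang = math.degrees(math.acos(min(1.0, cosang)))
                        if ang > cfg.angular_tolerance_deg + 1e-9:
                            continue
                        perp = dist * math.sin(math.radians(ang))
                        if perp > cfg.bandwidth_px + 1e-6:
                            continue
                        expected.add((dx, dy))
                assert set(admissible_offsets(cfg, theta, lag)) == expected, (theta, lag)

    def test_physical_units_use_mm_spacing(self):
        cfg = GeostatConfig(lags=(1,), directions_deg=(0.0,), units="PHYSICAL",
                            **ZERO_TOL)
        offsets = admissible_offsets(cfg, 0.0, 1, spacing=(0.5, 1.0))
        assert offsets == [(2, 0)]  # 2 pixels * 0.5 mm = 1 mm lag

    def test_undeclared_direction_rejected(self):
        cfg = GeostatConfig()
        with pytest.raises(ConfigError):
            admissible_offsets(cfg, 30.0, 1)


class TestEmpiricalCurve:
    @pytest.mark.parametrize("function", [SEMIVARIOGRAM, SEMIMADOGRAM])
    def test_worked_3x3_column_gradient(self, function):
        """6 pairs of |diff| = 1 along x: value = 6 / (2*6) = 0.5 exactly."""
        cfg = GeostatConfig(lags=(1,), directions_deg=(0.0,), function=function,
                            **ZERO_TOL)
        curve = empirical_curve(column_gradient_3x3(), cfg)
        assert curve.pair_counts[0, 0] == 6
        assert curve.values[0, 0] == 0.5

    @pytest.mark.parametrize("function", [SEMIVARIOGRAM, SEMIMADOGRAM])
    def test_constant_map_zero_with_positive_counts(self, function):
        cfg = GeostatConfig(lags=tuple(range(1, 6)), function=function)
        curve = empirical_curve(np.full((20, 20), 7.3), cfg)
        assert np.all(curve.values == 0)
        assert np.all(curve.pair_counts > 0)
        assert not curve.empty.any()

    def test_scaling_and_shift_identities(self, rng):
        v = rng.normal(size=(18, 18))
        for function, power in ((SEMIVARIOGRAM, 2), (SEMIMADOGRAM, 1)):
            cfg = GeostatConfig(lags=tuple(range(1, 6)), function=function)
            base = empirical_curve(v, cfg)
            for c in (-2.5, 3.0):
                scaled = empirical_curve(c * v, cfg)
                assert np.allclose(scaled.values, abs(c) ** power * base.values)
            shifted = empirical_curve(v + 11.0, cfg)
            assert np.allclose(shifted.values, base.values)

    @pytest.mark.parametrize("function", [SEMIVARIOGRAM, SEMIMADOGRAM])
    def test_matches_brute_force_on_random_masked_grids(self, function, rng):
        cfg = GeostatConfig(lags=tuple(range(1, 9)), function=function)
        for _ in range(10):
            v = rng.normal(size=(16, 16))
            mask = rng.random((16, 16)) > 0.25
            fast = empirical_curve(v, cfg, mask=mask)
            slow = brute_force_curve(v, cfg, mask=mask)
            assert np.array_equal(fast.pair_counts, slow.pair_counts)
            np.testing.assert_allclose(fast.values, slow.values, rtol=0, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mask_monotonicity(self, seed):
        """Shrinking the mask never increases any pair count."""
        r = np.random.default_rng(seed)
        v = r.normal(size=(14, 14))
        mask = r.random((14, 14)) > 0.2
        smaller = mask & (r.random((14, 14)) > 0.3)
        if smaller.sum() < 2:
            return
        cfg = GeostatConfig(lags=tuple(range(1, 6)))
        big = empirical_curve(v, cfg, mask=mask)
        small = empirical_curve(v, cfg, mask=smaller)
        assert np.all(small.pair_counts <= big.pair_counts)

    def test_empty_cells_zero_filled_and_flagged(self, rng):
        # a single-row grid admits no pairs in the 90-degree sector
        v = rng.normal(size=(20, 1))
        cfg = GeostatConfig(lags=(1, 2), directions_deg=(0.0, 90.0), **ZERO_TOL)
        with pytest.warns(UserWarning, match="empty"):
            curve = empirical_curve(v, cfg)
        assert np.all(curve.empty[1])          # 90 degrees: no pairs
        assert np.all(curve.values[1] == 0)
        assert np.all(curve.pair_counts[0] > 0)  # 0 degrees fine

    def test_strict_mode_errors_on_empty_cells(self, rng):
        v = rng.normal(size=(20, 1))
        cfg = GeostatConfig(lags=(1,), directions_deg=(0.0, 90.0), **ZERO_TOL)
        with pytest.raises(ValidationError, match="empty"):
            empirical_curve(v, cfg, strict=True)

    def test_geometry_admitting_no_pairs_errors(self):
        v = np.zeros((8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = mask[5, 3] = True  # no pair at lag 1 along x
        cfg = GeostatConfig(lags=(1,), directions_deg=(0.0,), **ZERO_TOL)
        with pytest.raises(ValidationError):
            empirical_curve(v, cfg, mask=mask)

    def test_fewer_than_two_valid_pixels_errors(self):
        v = np.zeros((8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValidationError, match="2 valid"):
            empirical_curve(v, GeostatConfig(lags=(1,)), mask=mask)

    def test_reach_exceeding_grid_rejected(self):
        with pytest.raises(ConfigError):
            empirical_curve(np.zeros((6, 6)), GeostatConfig())  # 15+3 > 6


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lags=()),
            dict(lags=(0, 1)),
            dict(lags=(2, 2)),
            dict(lags=(3, 1)),
            dict(lag_tolerance=-1),
            dict(angular_tolerance_deg=90),
            dict(bandwidth_px=-0.5),
            dict(function="MADOGRAM"),
            dict(units="FURLONG"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GeostatConfig(**kwargs)
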