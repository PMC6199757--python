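"""Case/feature/report persistence across the three dialects."""

import json

import numpy as np
import pytest
import scipy.io

from octvario import (
    FeatureVector,
    FormatError,
    ValidationError,
    gen_case,
    gen_volume,
    load_case,
    load_features,
    load_report,
    repeated_kfold_evaluate,
    save_case,
    save_features,
    save_report,
)

from conftest import constant_case, make_params, make_volume_params


def small_case():
    rng = np.random.default_rng(0)
    ilm = rng.uniform(5, 8, size=(4, 3))
    case = constant_case(shape=(4, 3))
    case.b_ilm = ilm
    case.b_rpe = ilm + 2.5
    case.b_bm = ilm + 3.25
    case.case_id = "case_x"
    case.label = "AMD"
    return case.validate()


class TestCaseRoundTrips:
    @pytest.mark.parametrize("dialect,suffix", [("NPZ", ".npz"), ("MAT", ".mat"), ("CSV", "")])
    def test_round_trip_identity(self, tmp_path, dialect, suffix):
        case = small_case()
        path = tmp_path / f"case{suffix}"
        save_case(case, path, dialect=dialect)
        back, vol = load_case(path, dialect=dialect)
        assert vol is None
        for attr in ("b_ilm", "b_rpe", "b_bm"):
            np.testing.assert_array_equal(getattr(back, attr), getattr(case, attr))
        assert back.n_axial == case.n_axial
        assert back.fovea_xy == case.fovea_xy
        assert back.spacing_x_mm == case.spacing_x_mm
        assert (back.case_id, back.label) == (case.case_id, case.label)

    @pytest.mark.parametrize("dialect,suffix", [("NPZ", ".npz"), ("MAT", ".mat")])
    def test_volume_round_trip(self, tmp_path, dialect, suffix):
        params = make_volume_params(grid=(8, 6, 16))
        case = gen_case(params, "CONTROL", np.random.default_rng(1))
        vol = gen_volume(case, params, np.random.default_rng(2))
        path = tmp_path / f"case{suffix}"
        save_case(case, path, dialect=dialect, volume=vol)
        _, back = load_case(path, dialect=dialect, with_volume=True)
        np.testing.assert_array_equal(back.reflectance, vol.reflectance)

    def test_csv_dialect_refuses_volumes(self, tmp_path):
        params = make_volume_params(grid=(8, 6, 16))
        case = gen_case(params, "CONTROL", np.random.default_rng(1))
        vol = gen_volume(case, params, np.random.default_rng(2))
        with pytest.raises(ValidationError):
            save_case(case, tmp_path / "case", dialect="CSV", volume=vol)

    def test_missing_bm_key_named_in_error(self, tmp_path):
        path = tmp_path / "broken.mat"
        scipy.io.savemat(str(path), {"ilm": np.zeros((2, 2)), "rpe": np.zeros((2, 2))})
        with pytest.raises(FormatError, match="'bm'"):
            load_case(path)

    def test_missing_csv_boundary_file_named(self, tmp_path):
        case = small_case()
        save_case(case, tmp_path / "c", dialect="CSV")
        (tmp_path / "c.rpe.csv").unlink()
        with pytest.raises(FormatError, match="rpe"):
            load_case(tmp_path / "c", dialect="CSV")

    def test_order_violation_reported_with_count(self, tmp_path):
        case = small_case()
        case.b_rpe[0, 0] = case.b_ilm[0, 0] - 1.0
        case.b_rpe[1, 2] = case.b_ilm[1, 2] - 0.5
        save_case(case, tmp_path / "bad", dialect="CSV")
        with pytest.raises(ValidationError, match="2 pixel"):
            load_case(tmp_path / "bad", dialect="CSV")

    def test_repair_flag_clamps_and_loads(self, tmp_path):
        case = small_case()
        case.b_rpe[0, 0] = case.b_ilm[0, 0] - 1.0
        save_case(case, tmp_path / "bad.npz")
        fixed, _ = load_case(tmp_path / "bad.npz", repair=True)
        assert fixed.order_violations() == 0
        assert fixed.b_rpe[0, 0] == fixed.b_ilm[0, 0]

    def test_nonexistent_file(self, tmp_path):
        with pytest.raises(FormatError):
            load_case(tmp_path / "nope.npz")


class TestFeatureTables:
    def _vectors(self, n=2, length=60):
        rng = np.random.default_rng(3)
        return [
            FeatureVector("RPEDC-SV", rng.uniform(size=length), f"c{i}", "AMD")
            for i in range(n)
        ]

    def test_column_layout(self, tmp_path):
        path = tmp_path / "f.csv"
        save_features(self._vectors(2, 60), path)
        header = path.read_text().splitlines()[0].split(",")
        assert len(header) == 63  # 3 metadata + 60 features
        assert header[:3] == ["arrangement", "case_id", "label"]
        assert len(path.read_text().splitlines()) == 3

    def test_round_trip_precision(self, tmp_path):
        table = self._vectors(4, 30)
        save_features(table, tmp_path / "f.csv")
        back = load_features(tmp_path / "f.csv")
        assert len(back) == 4
        for a, b in zip(table, back):
            assert (a.arrangement, a.case_id, a.label) == (b.arrangement, b.case_id, b.label)
            np.testing.assert_allclose(a.values, b.values, rtol=0, atol=1e-12)

    def test_empty_collection(self, tmp_path):
        save_features([], tmp_path / "f.csv")
        assert load_features(tmp_path / "f.csv") == []

    def test_ragged_vectors_rejected(self, tmp_path):
        table = self._vectors(2, 10)
        table[1].values = table[1].values[:5]
        with pytest.raises(ValidationError, match="ragged"):
            save_features(table, tmp_path / "f.csv")

    def test_mixed_arrangements_rejected(self, tmp_path):
        table = self._vectors(2, 10)
        table[1].arrangement = "TR-SV"
        with pytest.raises(ValidationError, match="mixed"):
            save_features(table, tmp_path / "f.csv")


class TestReports:
    def _report(self):
        rng = np.random.default_rng(0)
        table = [
            FeatureVector("RPEDC-SV", rng.normal(loc=3 * (i < 10), size=6),
                          f"c{i}", "AMD" if i < 10 else "CONTROL")
            for i in range(20)
        ]
        return repeated_kfold_evaluate(table, k=5, repetitions=2, seed=1)

    def test_round_trip_and_internal_consistency(self, tmp_path):
        report = self._report()
        path = tmp_path / "report.json"
        save_report(report, path)
        raw = json.loads(path.read_text())
        assert len(raw["repetitions"]) == 2
        assert set(raw["aggregates"]) == {"mean", "std", "max_accuracy", "max_kappa"}
        assert len(raw["aggregates"]["mean"]) == 5
        back = load_report(path)
        # aggregates recomputed from serialized repetitions match stored ones
        for row, vals in back.aggregates().items():
            for metric, v in vals.items():
                assert abs(v - raw["aggregates"][row][metric]) < 1e-9
        # re-serialization is semantically identical
        assert back.to_dict() == raw

    def test_unwritable_path_raises(self, tmp_path):
        with pytest.raises(OSError):
            save_report(self._report(), tmp_path / "no_dir" / "r.json")
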