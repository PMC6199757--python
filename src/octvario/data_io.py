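"""Reading and writing cases, feature tables and evaluation reports.

Boundary surfaces circulate in three dialects:

* ``MAT``  — MATLAB files (v5 via scipy.io, v7.3/HDF5 via h5py on read)
  with 2-D arrays ``ilm``, ``rpe``, ``bm``, plus ``fovea_xy``,
  ``spacing_mm`` ([sx, sy]) and ``n_axial``; an optional ``reflectance``
  array holds a paired volume.  The public AREDS2 boundary release ships
  as MAT files, hence this dialect.
* ``NPZ``  — the same keys in a NumPy archive (the native round-trip
  format of this package).
* ``CSV``  — a dependency-light triplet ``<stem>.ilm.csv`` /
  ``<stem>.rpe.csv`` / ``<stem>.bm.csv`` of depth grids plus
  ``<stem>.meta.json`` for the scalar geometry; no volume support.

Feature tables are plain CSV (``arrangement, case_id, label,
f_001..f_NNN``); evaluation reports are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .errors import FormatError, ValidationError
from .features import FeatureVector
from .types import LABEL_UNKNOWN, LayerBoundaries, OctVolume

logger = logging.getLogger(__name__)

DIALECT_MAT = "MAT"
DIALECT_NPZ = "NPZ"
DIALECT_CSV = "CSV"

_REQUIRED_KEYS = ("ilm", "rpe", "bm", "fovea_xy", "spacing_mm", "n_axial")


def infer_dialect(path: str | Path) -> str:
    s = str(path)
    if s.endswith(".mat"):
        return DIALECT_MAT
    if s.endswith(".npz"):
        return DIALECT_NPZ
    return DIALECT_CSV


def _case_payload(case: LayerBoundaries, volume: OctVolume | None) -> dict:
    payload = {
        "ilm": case.b_ilm,
        "rpe": case.b_rpe,
        "bm": case.b_bm,
        "fovea_xy": np.asarray(case.fovea_xy, dtype=float),
        "spacing_mm": np.asarray([case.spacing_x_mm, case.spacing_y_mm], dtype=float),
        "n_axial": np.asarray(case.n_axial),
        "case_id": case.case_id,
        "label": case.label,
    }
    if volume is not None:
        payload["reflectance"] = volume.reflectance
    return payload


def save_case(case: LayerBoundaries, path: str | Path, dialect: str | None = None,
              volume: OctVolume | None = None) -> Path:
    """Persist a case (and optionally its volume) in the given dialect."""
    path = Path(path)
    if dialect is None:
        dialect = infer_dialect(path)
    payload = _case_payload(case, volume)
    if dialect == DIALECT_NPZ:
        np.savez(path, **payload)
    elif dialect == DIALECT_MAT:
        scipy.io.savemat(str(path), payload)
    elif dialect == DIALECT_CSV:
        if volume is not None:
            raise ValidationError("the CSV dialect does not carry reflectance volumes")
        stem = _csv_stem(path)
        for key, arr in (("ilm", case.b_ilm), ("rpe", case.b_rpe), ("bm", case.b_bm)):
            np.savetxt(f"{stem}.{key}.csv", arr, delimiter=",", fmt="%.17g")
        meta = {
            "n_axial": case.n_axial,
            "spacing_x_mm": case.spacing_x_mm,
            "spacing_y_mm": case.spacing_y_mm,
            "fovea_xy": list(case.fovea_xy),
            "case_id": case.case_id,
            "label": case.label,
        }
        with open(f"{stem}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return path


def _csv_stem(path: Path) -> str:
    s = str(path)
    for suf in (".meta.json", ".ilm.csv", ".rpe.csv", ".bm.csv", ".csv"):
        if s.endswith(suf):
            return s[: -len(suf)]
    return s


def _to_scalar_str(v) -> str:
    if isinstance(v, np.ndarray):
        v = v.ravel()
        return "".join(str(x) for x in v) if v.dtype.kind in "US" else str(v[0])
    return str(v)


def _read_mat(path: Path) -> dict:
    try:
        raw = scipy.io.loadmat(str(path))
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        # MAT v7.3 is HDF5; datasets come back transposed vs MATLAB order
        import h5py

        out = {}
        with h5py.File(path, "r") as fh:
            for k in fh.keys():
                ds = fh[k]
                arr = np.asarray(ds)
                if arr.dtype.kind == "u" and k in ("case_id", "label"):
                    out[k] = "".join(chr(c) for c in arr.ravel())
                else:
                    out[k] = arr.T if arr.ndim >= 2 else arr
        return out


def load_case(path: str | Path, dialect: str | None = None, repair: bool = False,
              with_volume: bool = False) -> tuple[LayerBoundaries, OctVolume | None]:
    """Load and validate a case; returns (boundaries, volume-or-None).

    Boundary-order violations raise a :class:`ValidationError` reporting
    the offending pixel count, unless ``repair=True`` clamps the RPE
    border into [ILM, BM] (repairs are counted and logged).
    """
    path = Path(path)
    if dialect is None:
        dialect = infer_dialect(path)

    if dialect == DIALECT_NPZ:
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        with np.load(path, allow_pickle=False) as z:
            data = {k: z[k] for k in z.files}
    elif dialect == DIALECT_MAT:
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        data = _read_mat(path)
    elif dialect == DIALECT_CSV:
        stem = _csv_stem(path)
        meta_path = Path(f"{stem}.meta.json")
        if not meta_path.exists():
            raise FormatError(f"missing key file: {meta_path}")
        with open(meta_path) as fh:
            meta = json.load(fh)
        data = {}
        for key in ("ilm", "rpe", "bm"):
            p = Path(f"{stem}.{key}.csv")
            if not p.exists():
                raise FormatError(f"missing boundary file for key '{key}': {p}")
            data[key] = np.loadtxt(p, delimiter=",", ndmin=2)
        for k in ("n_axial", "fovea_xy"):
            if k not in meta:
                raise FormatError(f"meta file lacks key '{k}'")
        data["n_axial"] = np.asarray(meta["n_axial"])
        data["fovea_xy"] = np.asarray(meta["fovea_xy"], dtype=float)
        data["spacing_mm"] = np.asarray(
            [meta.get("spacing_x_mm", 1.0), meta.get("spacing_y_mm", 1.0)]
        )
        data["case_id"] = meta.get("case_id", stem)
        data["label"] = meta.get("label", LABEL_UNKNOWN)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    for key in _REQUIRED_KEYS:
        if key not in data:
            raise FormatError(f"{dialect} file {path} lacks required key '{key}'")

    fovea = np.asarray(data["fovea_xy"], dtype=float).ravel()
    spacing = np.asarray(data["spacing_mm"], dtype=float).ravel()
    case = LayerBoundaries(
        b_ilm=np.atleast_2d(np.asarray(data["ilm"], dtype=float)),
        b_rpe=np.atleast_2d(np.asarray(data["rpe"], dtype=float)),
        b_bm=np.atleast_2d(np.asarray(data["bm"], dtype=float)),
        n_axial=int(np.asarray(data["n_axial"]).ravel()[0]),
        spacing_x_mm=float(spacing[0]),
        spacing_y_mm=float(spacing[1]),
        fovea_xy=(fovea[0], fovea[1]),
        case_id=_to_scalar_str(data.get("case_id", path.stem)),
        label=_to_scalar_str(data.get("label", LABEL_UNKNOWN)),
    )
    if repair and case.order_violations():
        case, n_fixed = case.repaired()
        logger.warning("repaired boundary order at %d pixel(s) in %s", n_fixed, path)
    case.validate()

    vol = None
    if with_volume:
        if "reflectance" not in data:
            raise FormatError(f"{dialect} file {path} lacks required key 'reflectance'")
        vol = OctVolume(
            reflectance=np.asarray(data["reflectance"], dtype=float),
            spacing_x_mm=case.spacing_x_mm,
            spacing_y_mm=case.spacing_y_mm,
            fovea_xy=case.fovea_xy,
            case_id=case.case_id,
            label=case.label,
        ).validate(case)
    return case, vol


# ---------------------------------------------------------------- features


def save_features(table: list[FeatureVector], path: str | Path) -> Path:
    """Write feature vectors as CSV: arrangement, case_id, label, f_001..f_NNN."""
    path = Path(path)
    meta_cols = ["arrangement", "case_id", "label"]
    if not table:
        pd.DataFrame(columns=meta_cols).to_csv(path, index=False)
        return path
    n = len(table[0].values)
    arr_id = table[0].arrangement
    for fv in table:
        if len(fv.values) != n:
            raise ValidationError("ragged feature vectors: lengths differ")
        if fv.arrangement != arr_id:
            raise ValidationError("mixed arrangements in one feature table")
    width = max(3, len(str(n)))
    cols = [f"f_{i + 1:0{width}d}" for i in range(n)]
    rows = [
        [fv.arrangement, fv.case_id, fv.label, *np.asarray(fv.values, dtype=float)]
        for fv in table
    ]
    pd.DataFrame(rows, columns=meta_cols + cols).to_csv(path, index=False)
    return path


def load_features(path: str | Path) -> list[FeatureVector]:
    """Inverse of :func:`save_features`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in ("arrangement", "case_id", "label"):
        if col not in df.columns:
            raise FormatError(f"feature table {path} lacks column '{col}'")
    fcols = [c for c in df.columns if c.startswith("f_")]
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureVector(
                arrangement=str(row["arrangement"]),
                values=row[fcols].to_numpy(dtype=float),
                case_id=str(row["case_id"]),
                label=str(row["label"]),
            )
        )
    return out


# ----------------------------------------------------------------- reports


def save_report(report, path: str | Path) -> Path:
    """Serialize an EvalReport to JSON (stable key order)."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return path


def load_report(path: str | Path):
    """Load an EvalReport written by :func:`save_report`."""
    from .classify import EvalReport

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        return EvalReport.from_dict(json.load(fh))
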