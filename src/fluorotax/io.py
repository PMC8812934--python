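"""Readers and writers for the tabular artifacts of the workflow.

Everything is plain text: pigment tables and casts are CSV (as exported
from the instrument vendor software and the HPLC post-processing),
reference databases are CSV with a versioned header comment, calibration
models are YAML, and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel
from .chemotax import EXTRA_PIGMENTS, PIGMENTS, PigmentSample
from .conversion import ReferenceDatabase
from .profiles import CAST_COLS, BinnedProfile, MexCast

__all__ = [
    "read_pigment_table",
    "read_cast",
    "write_reference_db",
    "read_reference_db",
    "write_calibration",
    "read_calibration",
    "write_profile",
    "write_report",
]

PIGMENT_META_COLS = ("cruise", "station", "depth_m", "area", "season")
REFDB_FORMAT_VERSION = "fluorotax-refdb-1"


def read_pigment_table(path: str | Path) -> tuple[list[PigmentSample], pd.DataFrame]:
    """Load a pigment CSV (µg/L) into validated samples.

    Required columns: the 13 pigments (11 markers + Neo, Lut) and the
    sampling metadata.  Rows with negative concentrations are skipped and
    reported; returns (samples, error table).
    """
    df = pd.read_csv(path)
    required = list(PIGMENTS) + list(EXTRA_PIGMENTS) + list(PIGMENT_META_COLS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pigment table is missing columns: {missing}")
    samples, errors = [], []
    for i, row in df.iterrows():
        try:
            conc = {p: float(row[p]) for p in PIGMENTS + EXTRA_PIGMENTS}
            samples.append(PigmentSample(
                concentrations=conc, cruise=str(row["cruise"]),
                station=str(row["station"]), depth_m=float(row["depth_m"]),
                area=str(row["area"]), season=str(row["season"])))
        except ValueError as exc:
            errors.append({"row": i, "error": str(exc)})
    return samples, pd.DataFrame(errors, columns=["row", "error"])


def read_cast(path: str | Path, station: str = "") -> MexCast:
    """Load a 10 Hz cast CSV; rows are time-sorted, duplicate times dropped."""
    df = pd.read_csv(path)
    missing = [c for c in CAST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cast file is missing columns: {missing}")
    if df.empty:
        raise ValueError("empty cast file")
    df = df.sort_values("time_s", kind="stable")
    dup = df["time_s"].duplicated()
    if dup.any():
        df = df[~dup]
    return MexCast(df.reset_index(drop=True),
                   station=station or Path(path).stem)


def write_reference_db(db: ReferenceDatabase, path: str | Path) -> None:
    path = Path(path)
    frame = db.to_frame()
    with path.open("w") as fh:
        fh.write(f"# {REFDB_FORMAT_VERSION} provenance={db.provenance}\n")
        frame.to_csv(fh, index=False)


def read_reference_db(path: str | Path) -> ReferenceDatabase:
    path = Path(path)
    provenance = ""
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            provenance = first.split("provenance=", 1)[-1].strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return ReferenceDatabase.from_frame(df, provenance=provenance)


def write_calibration(model: CalibrationModel, path: str | Path) -> None:
    payload = {
        "channel": int(model.channel),
        "slope": float(model.slope),
        "slope_se": float(model.slope_se),
        "r2": float(model.r2),
        "n": int(model.n),
        "outlier_indices": ([] if model.outlier_flags is None else
                            [int(i) for i in np.flatnonzero(model.outlier_flags)]),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_calibration(path: str | Path) -> CalibrationModel:
    payload = yaml.safe_load(Path(path).read_text())
    flags = None
    if payload.get("outlier_indices") is not None and payload.get("n"):
        flags = np.zeros(int(payload["n"]), dtype=bool)
        flags[np.asarray(payload["outlier_indices"], dtype=int)] = True
    return CalibrationModel(channel=int(payload["channel"]),
                            slope=float(payload["slope"]),
                            slope_se=float(payload["slope_se"]),
                            r2=float(payload["r2"]), n=int(payload["n"]),
                            outlier_flags=flags)


def write_profile(profile: BinnedProfile, path: str | Path) -> None:
    profile.data.to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    raise TypeError(f"not JSON serializable: {type(obj)}")
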