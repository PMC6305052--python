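"""Dataset JSON and feature-table CSV input/output.

Trace dialect (one file per dataset)::

    {"records": [{"id": "r0", "fhr": [140, 141, ...], "label": 0}, ...]}

``fhr`` holds integer bpm values with 0 marking signal loss.  Malformed
records are collected into an error report rather than aborting the whole
load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ctgkit.simulate import FEATURE_COLUMNS, FeatureVector, FHRRecord

log = logging.getLogger("ctgkit")


@dataclass
class LoadReport:
    n_loaded: int = 0
    errors: list = field(default_factory=list)  # (record_id_or_index, message)


def write_dataset_json(records: list[FHRRecord], path) -> None:
    payload = {
        "records": [
            {
                "id": r.record_id,
                "fhr": [int(round(v)) for v in r.values],
                "label": int(r.label),
            }
            for r in records
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_dataset_json(
    path, expected_length: int | None = 2400
) -> tuple[list[FHRRecord], LoadReport]:
    """Load and validate a dataset; bad records go to the error report."""
    with open(path) as fh:
        payload = json.load(fh)
    report = LoadReport()
    records: list[FHRRecord] = []
    raw = payload.get("records")
    if raw is None:
        raise ValueError("dataset JSON must contain a 'records' list")
    for i, entry in enumerate(raw):
        rid = entry.get("id", f"#{i}")
        try:
            values = np.asarray(entry["fhr"], dtype=float)
            if expected_length is not None and len(values) != expected_length:
                raise ValueError(
                    f"expected {expected_length} values, got {len(values)}"
                )
            rec = FHRRecord(record_id=str(rid), values=values,
                            label=int(entry["label"]))
            records.append(rec)
        except (KeyError, TypeError, ValueError) as exc:
            report.errors.append((str(rid), str(exc)))
    report.n_loaded = len(records)
    if not records:
        log.warning("no valid records loaded from %s", path)
    return records, report


def write_feature_csv(features: list[FeatureVector], path) -> None:
    df = pd.DataFrame([fv.as_row() for fv in features], columns=FEATURE_COLUMNS)
    df.to_csv(path, index=False)


def read_feature_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and in-memory labels (disk result code minus 1)."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns: {missing}")
    X = df[FEATURE_COLUMNS[:-1]].to_numpy(dtype=float)
    y = df["Result"].to_numpy(dtype=int) - 1
    return X, y
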