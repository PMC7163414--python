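"""Readers and writers for the on-disk session and cohort formats.

Formats are deliberately plain text:

- patient case: one JSON document per case; cohort manifest CSV
  (``case_id,diagnosis,prediction_time``)
- gaze stream: CSV with header ``timestamp_ms,x_px,y_px,valid``
- layout stream: JSON Lines, one snapshot per line:
  ``{"timestamp_ms": ..., "elements": [{"item_id", "x0", "y0", "x1", "y1"}]}``
- manual selections: CSV ``case_id,item_id``
- dwell tables: CSV ``case_id,item_id,dwell_ms``
- labels: CSV ``case_id,item_id,label,source``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from gazerel.gaze import Element, GazeStream, LayoutSnapshot, LayoutStream
from gazerel.simulate import PatientCase, RelevanceModel


def write_case(case: PatientCase, path: Path) -> None:
    doc = {
        "case_id": case.case_id,
        "diagnosis": case.diagnosis,
        "demographics": case.demographics,
        "admission_time_h": case.admission_time_h,
        "prediction_time_h": case.prediction_time_h,
        "series": {k: [[t, v] for t, v in pts] for k, pts in sorted(case.series.items())},
    }
    path.write_text(json.dumps(doc, sort_keys=True, indent=None) + "\n")


def read_case(path: Path) -> PatientCase:
    doc = json.loads(path.read_text())
    return PatientCase(
        case_id=doc["case_id"],
        diagnosis=doc["diagnosis"],
        demographics={k: float(v) for k, v in doc["demographics"].items()},
        series={k: [(float(t), float(v)) for t, v in pts] for k, pts in doc["series"].items()},
        admission_time_h=float(doc["admission_time_h"]),
        prediction_time_h=float(doc["prediction_time_h"]),
    )


def write_cohort_manifest(cases: Iterable[PatientCase], path: Path) -> None:
    rows = [
        {"case_id": c.case_id, "diagnosis": c.diagnosis, "prediction_time": c.prediction_time_h}
        for c in cases
    ]
    pd.DataFrame(rows, columns=["case_id", "diagnosis", "prediction_time"]).to_csv(
        path, index=False
    )


def write_relevance_model(model: RelevanceModel, path: Path) -> None:
    doc = {
        "normal_range": list(model.normal_range),
        "intercepts": model.intercepts,
        "coefficients": {k: list(v) for k, v in model.coefficients.items()},
    }
    path.write_text(json.dumps(doc, sort_keys=True) + "\n")


def read_relevance_model(path: Path) -> RelevanceModel:
    doc = json.loads(path.read_text())
    return RelevanceModel(
        intercepts={k: float(v) for k, v in doc["intercepts"].items()},
        coefficients={k: tuple(float(x) for x in v) for k, v in doc["coefficients"].items()},
        normal_range=tuple(doc["normal_range"]),
    )


def write_gaze_csv(stream: GazeStream, path: Path) -> None:
    df = pd.DataFrame(
        {
            "timestamp_ms": stream.timestamps_ms,
            "x_px": stream.x,
            "y_px": stream.y,
            "valid": stream.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_gaze_csv(path: Path) -> GazeStream:
    df = pd.read_csv(path)
    return GazeStream(
        df["timestamp_ms"].to_numpy(float),
        df["x_px"].to_numpy(float),
        df["y_px"].to_numpy(float),
        df["valid"].to_numpy(int).astype(bool),
    )


def write_layout_jsonl(stream: LayoutStream, path: Path) -> None:
    with path.open("w") as fh:
        for snap in stream.snapshots:
            doc = {
                "timestamp_ms": snap.timestamp_ms,
                "elements": [
                    {"item_id": e.item_id, "x0": e.x0, "y0": e.y0, "x1": e.x1, "y1": e.y1}
                    for e in snap.elements
                ],
            }
            fh.write(json.dumps(doc) + "\n")


def read_layout_jsonl(path: Path) -> LayoutStream:
    snaps = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        doc = json.loads(line)
        snaps.append(
            LayoutSnapshot(
                timestamp_ms=float(doc["timestamp_ms"]),
                elements=[
                    Element(e["item_id"], float(e["x0"]), float(e["y0"]),
                            float(e["x1"]), float(e["y1"]))
                    for e in doc["elements"]
                ],
            )
        )
    return LayoutStream(snapshots=snaps)


def write_selections_csv(selections: Mapping[str, set[str] | None], path: Path) -> None:
    """One row per (session, selected item); sessions with a missing
    selection record are omitted entirely (distinct from zero selections,
    which contribute no rows but are listed in the session index)."""
    rows = []
    for sid in sorted(selections):
        sel = selections[sid]
        if sel is None:
            continue
        for item in sorted(sel):
            rows.append({"case_id": sid, "item_id": item})
    pd.DataFrame(rows, columns=["case_id", "item_id"]).to_csv(path, index=False)


def write_dwell_csv(dwells: Mapping[str, Mapping[str, float]], path: Path) -> None:
    rows = [
        {"case_id": sid, "item_id": item, "dwell_ms": ms}
        for sid in sorted(dwells)
        for item, ms in sorted(dwells[sid].items())
    ]
    pd.DataFrame(rows, columns=["case_id", "item_id", "dwell_ms"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_labels_csv(rows: Iterable[dict], path: Path) -> None:
    pd.DataFrame(list(rows), columns=["case_id", "item_id", "label", "source"]).to_csv(
        path, index=False
    )


def read_labels_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix_csv(df: pd.DataFrame, path: Path) -> None:
    """Matrix CSV: empty field is the missing marker."""
    df.to_csv(path, index_label="case_id", float_format="%.10g", na_rep="")


def read_matrix_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="case_id")
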