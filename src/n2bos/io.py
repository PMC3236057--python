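"""Reading and writing the long-format visit tables and report TSVs.

The visit-table schema is one row per (patient, visit, variable):

    patient_id  sex  age_years  height_cm  months_post_tx  variable  value

Missing measurements are simply absent rows.  Writers prepend a ``#``
comment line recording the seed and a configuration hash so every emitted
table is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import PatientTimeline, VARIABLES

__all__ = ["read_visit_table", "write_visit_table", "write_truth_table", "config_hash"]

_COLUMNS = ["patient_id", "sex", "age_years", "height_cm", "months_post_tx", "variable", "value"]


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serialisable configuration view."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def timelines_to_frame(timelines: Iterable[PatientTimeline]) -> pd.DataFrame:
    rows = []
    for tl in timelines:
        for months, visit in tl.visits.iterrows():
            for var in tl.visits.columns:
                if pd.isna(visit[var]):
                    continue
                rows.append(
                    (tl.patient_id, tl.sex, tl.age_years, tl.height_cm,
                     float(months), var, float(visit[var]))
                )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_visit_table(
    timelines: Iterable[PatientTimeline], path: str | Path, header_meta: dict | None = None
) -> None:
    path = Path(path)
    df = timelines_to_frame(timelines)
    meta = dict(header_meta or {})
    comment = "# n2bos visit table " + " ".join(f"{k}={v}" for k, v in meta.items())
    with path.open("w") as fh:
        fh.write(comment.rstrip() + "\n")
        # full repr precision: the written table round-trips exactly
        df.to_csv(fh, sep="\t", index=False)


def read_visit_table(path: str | Path) -> list[PatientTimeline]:
    """Parse a long-format visit table into per-patient timelines.

    Rows may arrive in any order (they are sorted chronologically); a
    duplicate (patient, month, variable) triple is a validation error that
    names the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["patient_id", "months_post_tx", "variable"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate measurement for patient_id={first['patient_id']!r}, "
            f"months_post_tx={first['months_post_tx']}, variable={first['variable']!r}"
        )
    bad = df[~(df["value"] > 0)]
    if len(bad):
        first = bad.iloc[0]
        raise ValidationError(
            f"{path}: non-positive value in column 'value' for "
            f"patient_id={first['patient_id']!r}, months_post_tx={first['months_post_tx']}"
        )

    timelines = []
    for pid, group in df.groupby("patient_id", sort=True):
        demo = group.iloc[0]
        wide = (
            group.pivot(index="months_post_tx", columns="variable", values="value")
            .sort_index()
        )
        # keep the canonical column order; tolerate extra variables
        cols = [v for v in VARIABLES if v in wide.columns] + [
            c for c in wide.columns if c not in VARIABLES
        ]
        wide = wide[cols]
        wide.index.name = "months_post_tx"
        timelines.append(
            PatientTimeline(
                patient_id=str(pid),
                sex=str(demo["sex"]),
                age_years=float(demo["age_years"]),
                height_cm=float(demo["height_cm"]),
                visits=wide,
            )
        )
    return timelines


def write_truth_table(truth: pd.DataFrame, path: str | Path, header_meta: dict | None = None) -> None:
    path = Path(path)
    meta = dict(header_meta or {})
    comment = "# n2bos truth sidecar " + " ".join(f"{k}={v}" for k, v in meta.items())
    with path.open("w") as fh:
        fh.write(comment.rstrip() + "\n")
        truth.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_report_tsv(
    df: pd.DataFrame, path: str | Path, header_meta: dict | None = None
) -> None:
    path = Path(path)
    meta = dict(header_meta or {})
    comment = "# n2bos report " + " ".join(f"{k}={v}" for k, v in meta.items())
    with path.open("w") as fh:
        fh.write(comment.rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
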