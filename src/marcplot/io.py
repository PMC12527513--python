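"""Reading and writing effect-size tables and response sheets.

The effect-size table is UTF-8 delimited text with a header. Required
columns: ``study_id``, ``smd``, and exactly one of ``se``, ``variance``
or ``weight``; optional: ``n_students``, ``n_clusters_t``,
``n_clusters_c``, ``cluster_size``. Floats are written with shortest
round-trip repr and read back with pandas' round-trip parser, so
``read_effect_table(write_effect_table(d))`` reproduces ``d`` exactly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import pandas as pd

from .meta import MetaDataset, StudyEffect

__all__ = ["read_effect_table", "write_effect_table", "read_response_sheets"]

_UNCERTAINTY_COLUMNS = ("se", "variance", "weight")
_OPTIONAL_INT_COLUMNS = ("n_students", "n_clusters_t", "n_clusters_c", "cluster_size")


def read_effect_table(path) -> MetaDataset:
    """Parse a delimited effect-size table into a :class:`MetaDataset`.

    Errors carry 1-based data row numbers and, for duplicates, the
    offending ``study_id``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "study_id" not in df.columns or "smd" not in df.columns:
        missing = {"study_id", "smd"} - set(df.columns)
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    present = [c for c in _UNCERTAINTY_COLUMNS if c in df.columns]
    if len(present) != 1:
        raise ValueError(
            f"{path}: need exactly one of {_UNCERTAINTY_COLUMNS}, found {present}"
        )
    ucol = present[0]
    studies = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        sid = row["study_id"]
        if pd.isna(sid) or str(sid) == "":
            raise ValueError(f"{path}: row {i}: empty study_id")
        sid = str(sid)
        if sid in seen:
            raise ValueError(f"{path}: row {i}: duplicate study_id {sid!r}")
        seen.add(sid)
        numeric = {}
        for col in ("smd", ucol):
            v = row[col]
            try:
                if pd.isna(v):
                    raise ValueError
                numeric[col] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {i}: non-numeric {col}={v!r}"
                ) from None
        meta = {}
        for col in _OPTIONAL_INT_COLUMNS:
            if col in row and not pd.isna(row[col]):
                meta[col] = int(row[col])
        try:
            studies.append(
                StudyEffect.from_uncertainty(
                    sid, numeric["smd"], **{ucol: numeric[ucol]}, **meta
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return MetaDataset(studies)


def write_effect_table(dataset: MetaDataset, path) -> Path:
    """Write a dataset as a delimited table (header always emitted)."""
    path = Path(path)
    rows = []
    for s in dataset:
        rows.append(
            {
                "study_id": s.study_id,
                "smd": repr(s.smd),
                "se": repr(s.se),
                "n_students": "" if s.n_students is None else s.n_students,
                "n_clusters_t": "" if s.n_clusters_t is None else s.n_clusters_t,
                "n_clusters_c": "" if s.n_clusters_c is None else s.n_clusters_c,
                "cluster_size": "" if s.cluster_size is None else s.cluster_size,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_response_sheets(path):
    """Parse a long-format response CSV into :class:`ResponseSheet`s.

    Expected columns: ``participant_id``, ``viz``, ``k``, ``Q1``..``Q8``,
    ``duration_s``, ``attention_pass``, ``total_duration_s`` — one row
    per participant-condition (4 rows per participant).
    """
    from .experiment import ALL_QUESTIONS, ConditionResponse, ResponseSheet

    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"participant_id", "viz", "k", "duration_s", "attention_pass",
                "total_duration_s", *ALL_QUESTIONS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    sheets = []
    for pid, grp in df.groupby("participant_id", sort=True):
        conds = tuple(
            ConditionResponse(
                viz=str(row["viz"]),
                k=int(row["k"]),
                answers={q: row[q] for q in ALL_QUESTIONS},
                duration_s=float(row["duration_s"]),
            )
            for _, row in grp.iterrows()
        )
        sheets.append(
            ResponseSheet(
                participant_id=str(pid),
                conditions=conds,
                attention_pass=bool(grp["attention_pass"].iloc[0]),
                total_duration_s=float(grp["total_duration_s"].iloc[0]),
            )
        )
    return sheets
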