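"""Readers and writers for the tabular formats around the pipeline.

Fluency CSV (long): columns ``participant_id, position, response`` with
1-based positions.  Fluency CSV (wide): ``participant_id, responses`` with
';'-separated responses, one participant per row; the reader sniffs the
format from the header.  Trait CSV: ``participant_id`` plus one numeric
column per trait.  Feature CSV: ``participant_id`` plus the 17 canonical
feature columns, missing values written as empty cells.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import DataError
from .walks import FEATURE_NAMES, FluencyList

__all__ = [
    "read_fluency_csv",
    "write_fluency_csv",
    "read_trait_csv",
    "write_trait_csv",
    "read_feature_csv",
    "write_feature_csv",
]


def read_fluency_csv(path) -> list:
    """Read fluency lists (long or wide format) into ``FluencyList`` objects,
    ordered by first appearance of each participant."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise DataError(f"cannot read fluency file {path}: {exc}") from exc
    cols = set(frame.columns)
    lists = []
    if {"participant_id", "position", "response"} <= cols:
        try:
            frame["position"] = frame["position"].astype(int)
        except ValueError as exc:
            raise DataError(f"{path}: non-integer position") from exc
        for pid, group in frame.groupby("participant_id", sort=False):
            ordered = group.sort_values("position", kind="stable")
            lists.append(FluencyList(pid, list(ordered["response"])))
    elif {"participant_id", "responses"} <= cols:
        for _, row in frame.iterrows():
            lists.append(FluencyList(
                row["participant_id"],
                [r for r in str(row["responses"]).split(";")]))
    else:
        raise DataError(
            f"{path}: expected columns (participant_id, position, response) "
            f"or (participant_id, responses); found {sorted(cols)}")
    ids = [fl.participant_id for fl in lists]
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicate participant ids")
    return lists


def write_fluency_csv(lists: Sequence[FluencyList], path) -> None:
    """Write fluency lists in the long format."""
    rows = [(fl.participant_id, pos, resp)
            for fl in lists
            for pos, resp in enumerate(fl.raw_responses, start=1)]
    frame = pd.DataFrame(rows, columns=["participant_id", "position",
                                        "response"])
    frame.to_csv(path, index=False)


def read_trait_csv(path) -> pd.DataFrame:
    """Trait table: participant_id index, one numeric column per trait."""
    path = Path(path)
    frame = pd.read_csv(path)
    if "participant_id" not in frame.columns:
        raise DataError(f"{path}: missing participant_id column")
    frame = frame.set_index(frame["participant_id"].astype(str)).drop(
        columns="participant_id")
    if frame.index.has_duplicates:
        raise DataError(f"{path}: duplicate participant ids")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise DataError(f"{path}: non-numeric trait column {col!r}")
    return frame


def write_trait_csv(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index=True, index_label="participant_id")


def read_feature_csv(path) -> pd.DataFrame:
    """Feature table with the canonical 17-column header."""
    path = Path(path)
    frame = pd.read_csv(path)
    if "participant_id" not in frame.columns:
        raise DataError(f"{path}: missing participant_id column")
    frame = frame.set_index(frame["participant_id"].astype(str)).drop(
        columns="participant_id")
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing feature columns {missing}")
    return frame[list(FEATURE_NAMES)]


def write_feature_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True, index_label="participant_id")
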