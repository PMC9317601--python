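"""Readers and writers for the package's CSV/TSV dialects.

Pose scores travel as long-form CSV (ligand_id, frame_ns, monomer,
score_type, pose, value), labels as (ligand_id, active), pocket volumes
as (frame_ns, monomer, variant, volume); UTF-8, "." decimal separator.
Packaged reference tables are loaded through importlib.resources.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import DataError, PoseScoreTable
from .trajectory import VolumeTable

_POSE_COLUMNS = ["ligand_id", "frame_ns", "monomer", "score_type",
                 "pose", "value"]


def _read_strict_csv(path, columns, dtypes) -> pd.DataFrame:
    """RFC-4180-ish reader that rejects ragged rows with line numbers."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty file") from None
        missing = set(columns) - set(header)
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise DataError(
                    f"{path}:{lineno}: ragged row "
                    f"({len(row)} fields, expected {len(header)})")
            rows.append(row)
    df = pd.DataFrame(rows, columns=header)[columns]
    for col, dtype in dtypes.items():
        try:
            df[col] = df[col].astype(dtype)
        except ValueError as exc:
            raise DataError(f"{path}: bad value in column {col}: {exc}") \
                from exc
    return df


def read_pose_scores(path, variant: str = "RAW",
                     pose_budget: int = 10) -> PoseScoreTable:
    df = _read_strict_csv(path, _POSE_COLUMNS,
                          {"frame_ns": int, "pose": int, "value": float})
    df["score_type"] = df["score_type"].str.upper()
    df["monomer"] = df["monomer"].str.upper()
    return PoseScoreTable(df=df, variant=variant, pose_budget=pose_budget)


def write_pose_scores(table: PoseScoreTable, path) -> None:
    table.df[_POSE_COLUMNS].to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    df = _read_strict_csv(path, ["ligand_id", "active"], {"active": int})
    if not df["active"].isin((0, 1)).all():
        raise DataError(f"{path}: active column must be 0/1")
    return df


def write_labels(labels: pd.DataFrame, path) -> None:
    labels[["ligand_id", "active"]].to_csv(path, index=False)


def read_volumes(path) -> VolumeTable:
    df = _read_strict_csv(path, ["frame_ns", "monomer", "variant", "volume"],
                          {"frame_ns": int, "volume": float})
    df["variant"] = df["variant"].str.upper().replace(
        {"OPT": "OPTIMIZED"})
    return VolumeTable(df=df)


def write_volumes(volumes: VolumeTable, path) -> None:
    volumes.df.to_csv(path, index=False)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n", encoding="utf-8")


REFERENCE_TABLES = ("frames_raw", "frames_opt", "term_frequency_raw",
                    "term_frequency_opt", "segment_summary",
                    "multiframe_summary", "metrics_comparison")


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a packaged reference TSV by short name."""
    if name not in REFERENCE_TABLES:
        raise DataError(f"unknown reference table {name!r}; "
                        f"known: {REFERENCE_TABLES}")
    ref = resources.files("efoscreen.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def load_frame_table(variant: str = "RAW") -> pd.DataFrame:
    """Per-frame reference results with typed columns.

    Returns frame_ns (int), ef1 (float, NaN for discarded frames),
    equation (str or None) and accepted (bool).
    """
    name = "frames_raw" if variant.upper() == "RAW" else "frames_opt"
    df = load_reference_table(name)
    df["frame_ns"] = df["frame_ns"].astype(int)
    accepted = ~df["ef1"].str.lower().eq("nd")
    df["accepted"] = accepted
    df["ef1"] = np.where(accepted, df["ef1"], np.nan).astype(float)
    df.loc[~accepted, "equation"] = None
    return df
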