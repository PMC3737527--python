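"""Genomic interval utilities (0-based, half-open coordinates).

Interval sets are plain :class:`pandas.DataFrame` objects with columns
``chrom``, ``start``, ``end`` and optionally ``id``.  All operations treat
coordinates as BED-style 0-based half-open, so abutting intervals do not
overlap.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "id"]


class IntervalParseError(ValueError):
    """Malformed interval input (e.g. start >= end)."""


def make_intervals(chrom, start, end, ids=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
        }
    )
    if ids is not None:
        df["id"] = list(ids)
    _check(df)
    return df


def _check(df: pd.DataFrame, context: str = "") -> None:
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        row = df.loc[bad[0]]
        raise IntervalParseError(
            f"interval start >= end at {context}row {bad[0]}: "
            f"{row['chrom']}:{row['start']}-{row['end']}"
        )
    if "id" in df.columns and df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise IntervalParseError(f"duplicate interval id {dup!r}")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file; a 4th column, when present, becomes ``id``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise IntervalParseError(f"{path}: BED requires >= 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if df.shape[1] >= 4:
        out["id"] = df.iloc[:, 3].astype(str)
    _check(out, context=f"{path}: ")
    return out


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def centers(df: pd.DataFrame) -> np.ndarray:
    """Interval centers: floor((start + end) / 2)."""
    return (df["start"].to_numpy() + df["end"].to_numpy()) // 2


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals per chromosome; output sorted genomically."""
    pieces = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        # new run wherever the start exceeds the running max end so far
        new_run = np.ones(len(sub), dtype=bool)
        new_run[1:] = starts[1:] >= run_end[:-1]
        group = np.cumsum(new_run) - 1
        merged_start = pd.Series(starts).groupby(group).min().to_numpy()
        merged_end = pd.Series(run_end).groupby(group).max().to_numpy()
        pieces.append(
            pd.DataFrame({"chrom": chrom, "start": merged_start, "end": merged_end})
        )
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["chrom", "start"], ignore_index=True)


def overlaps_any(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Boolean vector: query i overlaps >= 1 bp with some subject interval."""
    result = np.zeros(len(queries), dtype=bool)
    if subjects.empty or queries.empty:
        return result
    merged = merge_intervals(subjects)
    for chrom, sub in merged.groupby("chrom", sort=False):
        mask = (queries["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        q_start = queries.loc[mask, "start"].to_numpy()
        q_end = queries.loc[mask, "end"].to_numpy()
        # merged intervals are disjoint and sorted, so ends are increasing
        idx = np.searchsorted(s, q_end, side="left")
        hit = np.zeros(len(q_start), dtype=bool)
        nz = idx > 0
        hit[nz] = e[idx[nz] - 1] > q_start[nz]
        result[mask] = hit
    return result
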