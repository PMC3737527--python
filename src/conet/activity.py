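"""Enhancer region construction and the binary accessibility matrix.

Enhancer regions are built from P300-style peak sets: overlapping peaks are
merged and each merged region is replaced by a fixed-length interval centred
at its centre.  The activity matrix sets an entry to 1 when the enhancer
interval overlaps (>= 1 bp, half-open) any DHS peak of a cell type.  Cell
types are optionally reduced to cluster representatives via average-linkage
hierarchical clustering under Russell–Rao dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from conet.intervals import merge_intervals, overlaps_any

__all__ = [
    "build_enhancer_regions",
    "build_activity_matrix",
    "select_representative_tissues",
    "TissueClustering",
    "read_activity_matrix",
    "write_activity_matrix",
    "read_peak_directory",
]


@dataclass
class TissueClustering:
    cluster_of: dict  # cell type -> cluster id
    representative_of: dict  # cluster id -> cell type

    @property
    def representatives(self) -> list:
        return [self.representative_of[c] for c in sorted(self.representative_of)]


def build_enhancer_regions(peak_sets, region_length: int = 500) -> pd.DataFrame:
    """Union peak sets, merge overlaps, emit fixed-length centred regions.

    Each merged region becomes an interval of ``region_length`` centred at
    ``floor((start + end) / 2)``; negative coordinates are clipped to 0.
    Output is sorted genomically with ids assigned in that order.
    """
    if region_length % 2 != 0:
        raise ValueError("region_length must be even")
    pooled = pd.concat(list(peak_sets), ignore_index=True)[["chrom", "start", "end"]]
    merged = merge_intervals(pooled)
    center = (merged["start"].to_numpy() + merged["end"].to_numpy()) // 2
    half = region_length // 2
    start = np.maximum(center - half, 0)
    end = center + half
    out = pd.DataFrame({"chrom": merged["chrom"], "start": start, "end": end})
    out = out.sort_values(["chrom", "start"], ignore_index=True)
    out["id"] = [f"enh{i:06d}" for i in range(len(out))]
    return out


def build_activity_matrix(enhancers: pd.DataFrame, dhs_peak_sets: dict) -> pd.DataFrame:
    """Binary enhancer-by-cell-type matrix from per-cell-type DHS peaks.

    Entry is 1 iff the enhancer overlaps any peak of that cell type by at
    least 1 bp.  Peaks on chromosomes absent from the enhancer set are
    ignored with a warning; an empty peak set yields an all-zero column.
    """
    if enhancers.empty:
        raise ValueError("enhancer set is empty")
    if not dhs_peak_sets:
        raise ValueError("need at least one cell type")
    known = set(enhancers["chrom"])
    columns = {}
    for ct in dhs_peak_sets:
        peaks = dhs_peak_sets[ct]
        if peaks.empty:
            warnings.warn(f"cell type {ct!r}: empty peak set, all-zero column")
            columns[ct] = np.zeros(len(enhancers), dtype=np.int8)
            continue
        unknown = set(peaks["chrom"]) - known
        if unknown:
            warnings.warn(
                f"cell type {ct!r}: ignoring peaks on unknown chromosomes "
                f"{sorted(unknown)}"
            )
            peaks = peaks[peaks["chrom"].isin(known)]
        columns[ct] = overlaps_any(enhancers, peaks).astype(np.int8)
    index = (
        pd.Index(enhancers["id"], name="enhancer_id")
        if "id" in enhancers.columns
        else pd.RangeIndex(len(enhancers))
    )
    return pd.DataFrame(columns, index=index)


def _russellrao_distances(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed Russell–Rao dissimilarity between cell-type columns."""
    x = matrix.to_numpy().T.astype(bool)
    return pdist(x, metric="russellrao")


def select_representative_tissues(
    matrix: pd.DataFrame, inconsistency_cutoff: float = 1.0
):
    """Cluster cell types and reduce the matrix to cluster representatives.

    Average-linkage hierarchical clustering on Russell–Rao dissimilarity of
    cell-type columns, cut by the inconsistency criterion.  In clusters of
    size >= 3 the representative is the member with the lowest mean distance
    to the other members; in clusters of size 2 it is the member with the
    greatest mean distance to all other cell types; singletons represent
    themselves.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    cts = list(matrix.columns)
    dist = _russellrao_distances(matrix)
    if inconsistency_cutoff <= 0:
        # limit of an arbitrarily strict cut: every tissue its own cluster
        labels = np.arange(1, len(cts) + 1)
    elif np.allclose(dist, 0):
        labels = np.ones(len(cts), dtype=int)
    else:
        Z = linkage(dist, method="average")
        labels = fcluster(Z, t=inconsistency_cutoff, criterion="inconsistent")
    D = squareform(dist)
    cluster_of = {ct: int(lab) for ct, lab in zip(cts, labels)}
    representative_of = {}
    for lab in sorted(set(labels)):
        members = [i for i, l in enumerate(labels) if l == lab]
        if len(members) == 1:
            rep = members[0]
        elif len(members) == 2:
            # the member more distant from everything else in the sample
            others = [i for i in range(len(cts)) if i not in members]
            if others:
                rep = max(members, key=lambda i: (D[i, others].mean(), -i))
            else:
                rep = members[0]
        else:
            rep = min(
                members,
                key=lambda i: (D[i, [j for j in members if j != i]].mean(), i),
            )
        representative_of[int(lab)] = cts[rep]
    clustering = TissueClustering(cluster_of, representative_of)
    reps = [ct for ct in cts if ct in set(representative_of.values())]
    return clustering, matrix[reps]


# ---------------------------------------------------------------------------
# I/O helpers


def write_activity_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_activity_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~df.isin([0, 1]).all()
    if bad.any():
        raise ValueError(f"{path}: non-binary entries in columns {list(df.columns[bad])}")
    return df.astype(np.int8)


def read_peak_directory(directory) -> dict:
    """Read ``<celltype>.bed`` files from a directory into a peak-set map."""
    from conet.intervals import read_bed

    directory = Path(directory)
    peak_sets = {}
    for path in sorted(directory.glob("*.bed")):
        peak_sets[path.stem] = read_bed(path)
    if not peak_sets:
        raise FileNotFoundError(f"no .bed files in {directory}")
    return peak_sets
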