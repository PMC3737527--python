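"""Enhancer co-activity networks: degrees, assortativity, clusters.

Degrees use a dual-threshold rule: an enhancer counts as degree 0 only if it
has no partner even at the relaxed FDR; enhancers with relaxed-only partners
are indeterminate and excluded from degree binning.  Clusters are connected
components of the MI-thresholded graph, filtered by a motif-sharing
criterion, each with an accessibility- and footprint-matched background
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from conet.coactivity import pairwise_mi
from conet.intervals import centers as interval_centers
from conet.motifs import collapse_to_cluster_representatives
from conet.stats import fisher_exact_2x2

__all__ = [
    "EnhancerNetwork",
    "EnhancerCluster",
    "DEGREE_BINS",
    "build_network",
    "strength_by_degree",
    "assortativity_test",
    "extract_clusters",
    "matched_background_cluster",
]

DEGREE_BINS = ((0, 0), (1, 4), (5, 8), (9, np.inf))


@dataclass
class EnhancerNetwork:
    nodes: list
    edges_strict: pd.DataFrame  # id_a, id_b, mi
    edges_relaxed: pd.DataFrame
    degree_strict: dict = field(default_factory=dict)
    degree_relaxed: dict = field(default_factory=dict)

    def degree_bin(self, node) -> str | None:
        """Degree-bin label, or None for indeterminate nodes.

        Degree 0 requires no partner even at the relaxed FDR; nodes with
        relaxed partners but no strict partner are indeterminate.
        """
        ds = self.degree_strict.get(node, 0)
        dr = self.degree_relaxed.get(node, 0)
        if ds == 0:
            return "0" if dr == 0 else None
        for lo, hi in DEGREE_BINS[1:]:
            if lo <= ds <= hi:
                return f"{lo}-{hi}" if np.isfinite(hi) else f">={lo}"
        return None


def _degree_counts(edges: pd.DataFrame) -> dict:
    deg: dict = {}
    for a, b in zip(edges["id_a"], edges["id_b"]):
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return deg


def build_network(
    called_strict: pd.DataFrame, called_relaxed: pd.DataFrame, nodes=None
) -> EnhancerNetwork:
    """Assemble the co-activity network from strict and relaxed pair calls."""
    strict_keys = set(zip(called_strict["id_a"], called_strict["id_b"]))
    relaxed_keys = set(zip(called_relaxed["id_a"], called_relaxed["id_b"]))
    if not strict_keys <= relaxed_keys:
        raise ValueError("strict call set is not a subset of the relaxed set")
    if nodes is None:
        nodes = sorted(
            set(called_relaxed["id_a"]) | set(called_relaxed["id_b"])
        )
    net = EnhancerNetwork(
        nodes=list(nodes),
        edges_strict=called_strict[["id_a", "id_b", "mi"]].copy(),
        edges_relaxed=called_relaxed[["id_a", "id_b", "mi"]].copy(),
    )
    net.degree_strict = _degree_counts(net.edges_strict)
    net.degree_relaxed = _degree_counts(net.edges_relaxed)
    return net


def strength_by_degree(
    network: EnhancerNetwork, labels: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Fraction of strong enhancers per degree bin, plus a Fisher contrast.

    Only non-ambiguous strong/weak labels are counted.  The returned p-value
    compares strong/weak counts in the degree-0 bin against all other bins
    pooled (two-sided Fisher exact).
    """
    rows: dict[str, list[int]] = {}
    for node in network.nodes:
        lab = labels.get(node)
        if lab not in ("strong", "weak"):
            continue
        b = network.degree_bin(node)
        if b is None:
            continue
        rows.setdefault(b, [0, 0])
        rows[b][0 if lab == "strong" else 1] += 1
    if not rows:
        raise ValueError("no labeled enhancers in any degree bin")
    table = pd.DataFrame(
        [
            {"bin": b, "n_strong": s, "n_weak": w,
             "strong_fraction": s / (s + w) if s + w else np.nan}
            for b, (s, w) in rows.items()
        ]
    ).set_index("bin")
    if "0" in table.index and len(table) > 1:
        s0, w0 = int(table.loc["0", "n_strong"]), int(table.loc["0", "n_weak"])
        rest = table.drop(index="0")
        sr, wr = int(rest["n_strong"].sum()), int(rest["n_weak"].sum())
        _, p = fisher_exact_2x2([[s0, w0], [sr, wr]])
    else:
        p = np.nan
    return table, p


def assortativity_test(
    network: EnhancerNetwork, labels: pd.Series, rng: np.random.Generator,
    kind: str = "strong",
) -> tuple[float, float]:
    """Like-with-like excess among edge endpoint labels (Fisher exact).

    Each edge with two non-ambiguous endpoints contributes one row of a 2x2
    table crossing the first endpoint's label with the second's; endpoint
    orientation is randomized per edge so the table is exchangeable.  An
    odds ratio > 1 indicates assortative wiring.  ``kind`` selects which
    label is treated as "success" (symmetric for the odds ratio; kept for
    reporting).
    """
    edges = network.edges_strict
    first, second = [], []
    for a, b in zip(edges["id_a"], edges["id_b"]):
        la, lb = labels.get(a), labels.get(b)
        if la not in ("strong", "weak") or lb not in ("strong", "weak"):
            continue
        if rng.integers(0, 2):
            la, lb = lb, la
        first.append(la)
        second.append(lb)
    if not first:
        raise ValueError("no edges with both endpoints labeled")
    first_a = np.array(first)
    second_a = np.array(second)
    pos = "strong" if kind == "strong" else "weak"
    n11 = int(np.sum((first_a == pos) & (second_a == pos)))
    n10 = int(np.sum((first_a == pos) & (second_a != pos)))
    n01 = int(np.sum((first_a != pos) & (second_a == pos)))
    n00 = int(np.sum((first_a != pos) & (second_a != pos)))
    odds, p = fisher_exact_2x2([[n11, n10], [n01, n00]])
    return odds, p


@dataclass
class EnhancerCluster:
    members: list
    intra_distances: np.ndarray  # sorted pairwise centre distances (same chrom)
    shared_motifs: list


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _intra_distances(members, enhancers: pd.DataFrame) -> np.ndarray:
    sub = enhancers[enhancers["id"].isin(members)]
    cent = interval_centers(sub)
    chrom = sub["chrom"].to_numpy()
    out = []
    for i in range(len(sub)):
        for j in range(i + 1, len(sub)):
            if chrom[i] == chrom[j]:
                out.append(abs(int(cent[i]) - int(cent[j])))
    return np.array(sorted(out), dtype=np.int64)


def extract_clusters(
    edges: pd.DataFrame,
    enhancers: pd.DataFrame,
    motifs: pd.DataFrame,
    min_mi: float = 0.0,
    min_size: int = 2,
    min_shared_fraction: float = 0.0,
    motif_clustering: pd.Series | None = None,
) -> list[EnhancerCluster]:
    """Connected components of the MI-thresholded graph with motif filter.

    A component of at least ``min_size`` members is kept when some motif
    (after collapsing motifs to similarity-cluster representatives, if a
    clustering is given) is present in at least ``min_shared_fraction`` of
    its members; the qualifying motifs are recorded.
    """
    strong = edges[edges["mi"] >= min_mi]
    nodes = sorted(set(strong["id_a"]) | set(strong["id_b"]))
    uf = _UnionFind(nodes)
    for a, b in zip(strong["id_a"], strong["id_b"]):
        uf.union(a, b)
    comps: dict = {}
    for node in nodes:
        comps.setdefault(uf.find(node), []).append(node)
    M = motifs
    if motif_clustering is not None:
        M = collapse_to_cluster_representatives(motifs, motif_clustering)
    clusters = []
    for members in comps.values():
        if len(members) < min_size:
            continue
        present = M.loc[[m for m in members if m in M.index]]
        if len(present):
            frac = present.to_numpy().mean(axis=0)
            qualifying = [c for c, f in zip(M.columns, frac)
                          if f >= min_shared_fraction]
        else:
            qualifying = []
        if min_shared_fraction > 0 and not qualifying:
            continue
        clusters.append(
            EnhancerCluster(
                members=sorted(members),
                intra_distances=_intra_distances(members, enhancers),
                shared_motifs=qualifying,
            )
        )
    clusters.sort(key=lambda c: (-len(c.members), c.members[0]))
    return clusters


def matched_background_cluster(
    cluster: EnhancerCluster,
    pool: list,
    enhancers: pd.DataFrame,
    activity: pd.DataFrame,
    rng: np.random.Generator,
    mi_ceiling: float = 0.01,
    tolerance: float = 0.2,
    max_tries: int = 200,
) -> EnhancerCluster:
    """Sample an uncorrelated cluster mirroring size and genomic footprint.

    Members come from ``pool``; the sorted intra-cluster distance multiset
    must match the foreground's within ``tolerance`` relative error per
    sorted-distance quantile, and every member pair must have MI below
    ``mi_ceiling``.  The placement translates the foreground footprint to a
    random anchor and snaps each position to the nearest pool enhancer.
    """
    k = len(cluster.members)
    enh = enhancers.set_index("id")
    pool = [p for p in pool if p in enh.index]
    if len(pool) < k:
        raise ValueError("pool smaller than cluster size")
    pool_df = enh.loc[pool]
    states = activity.loc[pool].to_numpy().astype(np.int8)

    fg = enh.loc[cluster.members]
    fg_cent = (fg["start"].to_numpy() + fg["end"].to_numpy()) // 2
    anchor_chrom = fg["chrom"].mode().iat[0]
    on_anchor = fg["chrom"].to_numpy() == anchor_chrom
    rel = np.sort(fg_cent[on_anchor] - fg_cent[on_anchor].min())
    span = int(rel.max()) if len(rel) else 0

    by_chrom = {}
    for chrom, sub in pool_df.groupby("chrom"):
        cent = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        order = np.argsort(cent)
        by_chrom[chrom] = (cent[order], np.array(sub.index)[order])

    target = np.array(sorted(cluster.intra_distances))
    chroms = list(by_chrom)
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        cent, ids_sorted = by_chrom[chrom]
        if len(cent) < k or cent.max() - cent.min() < span:
            continue
        base = int(rng.integers(cent.min(), max(cent.min() + 1, cent.max() - span)))
        want = base + rel if len(rel) == k else base + np.sort(
            rng.integers(0, max(span, 1) + 1, size=k)
        )
        idx = np.clip(np.searchsorted(cent, want), 0, len(cent) - 1)
        # snap to nearest of the two neighbours, keeping members distinct
        chosen: list[int] = []
        used: set = set()
        for w, i in zip(want, idx):
            best, best_d = None, None
            for j in (i - 1, i, i + 1):
                if 0 <= j < len(cent) and j not in used:
                    d = abs(int(cent[j]) - int(w))
                    if best_d is None or d < best_d:
                        best, best_d = j, d
            if best is None:
                break
            chosen.append(best)
            used.add(best)
        if len(chosen) < k:
            continue
        members = list(ids_sorted[np.array(sorted(chosen))])
        got = _intra_distances(members, enhancers)
        if len(got) != len(target):
            continue
        if len(target):
            with np.errstate(divide="ignore", invalid="ignore"):
                relerr = np.abs(got - target) / np.maximum(target, 1)
            if np.any(relerr > tolerance):
                continue
        rows = [pool.index(m) for m in members]
        ii, jj = np.triu_indices(k, 1)
        mis = pairwise_mi(states, np.array(rows)[ii], np.array(rows)[jj])
        if np.any(mis >= mi_ceiling):
            continue
        return EnhancerCluster(members=members, intra_distances=got,
                               shared_motifs=[])
    raise ValueError(
        f"no background placement found for cluster of size {k} "
        f"after {max_tries} tries"
    )
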