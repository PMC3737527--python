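"""Motif co-occurrence in correlated enhancer pairs.

A motif occurring in fraction ``p`` of all enhancers is expected, under
independence, to co-occur in ``p**2`` of enhancer pairs; the co-occurrence
score is the ratio of the observed co-occurrence frequency to ``p**2``.
Significance is a 1-df chi-squared goodness-of-fit on co-occurrence counts,
BH-corrected across motifs.  Foreground-specific motifs survive a three-step
filter: BH significance in the foreground, an empirical-FDR comparison of
foreground vs background p-values, and removal of motifs that are also
BH-significant in the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from conet.stats import bh_adjust, fisher_exact_2x2

__all__ = [
    "cooccurrence_table",
    "select_foreground_specific_motifs",
    "pair_motif_jaccard",
    "pair_jaccard_many",
    "cluster_motifs",
    "collapse_to_cluster_representatives",
    "pair_classification_cv",
    "cme_preference",
]


def _pair_index_arrays(pairs: pd.DataFrame, motifs: pd.DataFrame):
    pos = {eid: i for i, eid in enumerate(motifs.index)}
    try:
        ia = np.array([pos[e] for e in pairs["id_a"]], dtype=np.int64)
        ib = np.array([pos[e] for e in pairs["id_b"]], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"enhancer {exc.args[0]!r} missing from motif matrix")
    return ia, ib


def cooccurrence_table(pairs: pd.DataFrame, motifs: pd.DataFrame) -> pd.DataFrame:
    """Per-motif co-occurrence score and chi-squared significance.

    ``p_occurrence`` is computed over all enhancers in the motif matrix (not
    only those appearing in pairs).  The chi-squared statistic is a 1-df
    two-cell goodness-of-fit of the observed co-occurrence count against the
    ``n p**2`` expectation; motifs with zero expected count get NaN p.
    """
    if pairs.empty:
        raise ValueError("pair set is empty")
    ia, ib = _pair_index_arrays(pairs, motifs)
    M = motifs.to_numpy().astype(np.int8)
    n_pairs = len(ia)
    p_occ = M.mean(axis=0)
    co_count = (M[ia] & M[ib]).sum(axis=0).astype(np.float64)
    observed = co_count / n_pairs
    expected = p_occ**2
    with np.errstate(divide="ignore", invalid="ignore"):
        score = observed / expected
    e = expected * n_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (co_count - e) ** 2 / e + (co_count - e) ** 2 / (n_pairs - e)
    pvals = np.where(
        (e > 0) & (e < n_pairs), sps.chi2.sf(chi2, df=1), np.nan
    )
    return pd.DataFrame(
        {
            "motif": motifs.columns,
            "p_occurrence": p_occ,
            "expected_freq": expected,
            "observed_freq": observed,
            "score": score,
            "p_value": pvals,
            "q_value": bh_adjust(pvals),
        }
    ).set_index("motif")


def select_foreground_specific_motifs(
    fg_results: pd.DataFrame,
    bg_results: pd.DataFrame,
    fdr_bh: float = 0.05,
    fdr_empirical: float = 0.05,
) -> list:
    """Three-step foreground-specific motif filter.

    1. keep motifs BH-significant in the foreground at ``fdr_bh``;
    2. keep those whose foreground p-value passes an empirical-FDR filter
       that uses the background p-values as the null: the threshold is the
       largest t with #{bg p <= t} / #{fg p <= t} <= ``fdr_empirical``;
    3. drop motifs that are also BH-significant in the background.
    """
    if fg_results.empty or bg_results.empty:
        raise ValueError("empty result sets")
    if set(fg_results.index) != set(bg_results.index):
        raise ValueError("foreground and background motif universes differ")
    bg = bg_results.loc[fg_results.index]

    step1 = fg_results.index[fg_results["q_value"] <= fdr_bh]

    fg_p = fg_results["p_value"].to_numpy()
    bg_p = bg["p_value"].to_numpy()
    fg_ok = fg_p[~np.isnan(fg_p)]
    bg_ok = bg_p[~np.isnan(bg_p)]
    candidates = np.unique(fg_ok)
    fg_sorted = np.sort(fg_ok)
    bg_sorted = np.sort(bg_ok)
    n_fg_le = np.searchsorted(fg_sorted, candidates, side="right")
    n_bg_le = np.searchsorted(bg_sorted, candidates, side="right")
    ratio = n_bg_le / np.maximum(1, n_fg_le)
    passing = candidates[ratio <= fdr_empirical]
    t_star = passing.max() if len(passing) else -np.inf
    step2 = [m for m in step1 if fg_results.loc[m, "p_value"] <= t_star]

    bg_sig = set(bg.index[bg["q_value"] <= fdr_bh])
    return [m for m in step2 if m not in bg_sig]


def pair_motif_jaccard(id_a, id_b, motifs: pd.DataFrame, motif_subset=None) -> float:
    """Jaccard index of two enhancers' motif sets (0 when both are empty)."""
    cols = list(motifs.columns) if motif_subset is None else list(motif_subset)
    a = motifs.loc[id_a, cols].to_numpy().astype(bool)
    b = motifs.loc[id_b, cols].to_numpy().astype(bool)
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return float(np.sum(a & b) / union)


def pair_jaccard_many(pairs: pd.DataFrame, motifs: pd.DataFrame,
                      motif_subset=None) -> np.ndarray:
    """Vectorized motif-set Jaccard for a table of pairs."""
    sub = motifs if motif_subset is None else motifs[list(motif_subset)]
    ia, ib = _pair_index_arrays(pairs, sub)
    M = sub.to_numpy().astype(bool)
    inter = (M[ia] & M[ib]).sum(axis=1).astype(np.float64)
    union = (M[ia] | M[ib]).sum(axis=1).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = inter / union
    return np.where(union > 0, j, 0.0)


def cluster_motifs(similarity: pd.DataFrame, max_cophenetic: float) -> pd.Series:
    """Cluster motifs from their similarity profiles.

    Each motif is represented by its row of pairwise similarities; rows are
    hierarchically clustered (Euclidean distance, complete linkage) and the
    tree is cut at cophenetic distance ``max_cophenetic``.
    """
    if similarity.shape[0] != similarity.shape[1]:
        raise ValueError("similarity matrix must be square")
    X = similarity.to_numpy(dtype=np.float64)
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=max_cophenetic, criterion="distance")
    return pd.Series(labels, index=similarity.index, name="cluster")


def collapse_to_cluster_representatives(
    motifs: pd.DataFrame, clustering: pd.Series
) -> pd.DataFrame:
    """Keep one motif column per similarity cluster (first in column order)."""
    seen = set()
    keep = []
    for m in motifs.columns:
        c = clustering.get(m, None)
        if c is None or c not in seen:
            keep.append(m)
            if c is not None:
                seen.add(c)
    return motifs[keep]


def pair_classification_cv(
    features: np.ndarray,
    labels: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV accuracy of a linear margin classifier.

    Features are per-pair binary motif co-presence indicators; any
    deterministic-given-seed linear margin classifier satisfies the
    contract — a linear SVM is used.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if k_folds > len(labels):
        raise ValueError("k_folds exceeds sample count")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(features, labels):
        clf = LinearSVC(dual="auto", random_state=seed, max_iter=5000)
        clf.fit(features[train], labels[train])
        accs.append(float(np.mean(clf.predict(features[test]) == labels[test])))
    return float(np.mean(accs))


def cme_preference(
    interactions: pd.DataFrame,
    motif_to_tf: dict,
    significant_motifs,
    all_motifs,
) -> pd.DataFrame:
    """Per-CME preference for TFs of significant motifs (Fisher exact).

    ``interactions`` has columns ``tf_id`` and ``cme_id``.  For each CME the
    2x2 table crosses motif significance with whether the motif's TF
    interacts with the CME; two-sided Fisher p-values are BH-corrected.
    ``interaction_frequency`` is the fraction of significant motifs whose TF
    interacts with the CME.
    """
    significant = set(significant_motifs)
    universe = list(all_motifs)
    if not significant <= set(universe):
        raise ValueError("significant_motifs must be a subset of all_motifs")
    other = [m for m in universe if m not in significant]
    sig = sorted(significant)
    records = []
    by_cme = interactions.groupby("cme_id")["tf_id"].agg(set)
    for cme, tfs in by_cme.items():
        hit_sig = sum(1 for m in sig if motif_to_tf.get(m) in tfs)
        hit_other = sum(1 for m in other if motif_to_tf.get(m) in tfs)
        table = [
            [hit_sig, len(sig) - hit_sig],
            [hit_other, len(other) - hit_other],
        ]
        flagged = hit_sig + hit_other == 0 or not other or not sig
        if flagged:
            odds, p = np.nan, 1.0
        else:
            odds, p = fisher_exact_2x2(table)
        records.append(
            {
                "cme_id": cme,
                "p_value": p,
                "interaction_frequency": hit_sig / len(sig) if sig else np.nan,
                "odds_ratio": odds,
                "flagged": flagged,
            }
        )
    out = pd.DataFrame(records).set_index("cme_id")
    out["q_value"] = bh_adjust(out["p_value"])
    return out
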