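"""Target-gene analyses: nearest genes, co-expression, shared function.

Enhancers map to the gene with the nearest TSS (absolute distance from the
enhancer centre, same chromosome, ties broken by gene id).  Contrasts
compare foreground (correlated) vs background pairs or clusters on target
co-expression (Spearman), annotation-term sharing (Fisher), cluster-level
term enrichment (hypergeometric, BH), and tissue-class concordance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from conet.intervals import centers as interval_centers
from conet.stats import (
    bh_adjust,
    fisher_exact_2x2,
    hypergeom_upper_tail,
    rank_sum_test,
    spearman,
)

__all__ = [
    "nearest_gene",
    "expression_correlation_contrast",
    "jaccard_expression_regression",
    "term_sharing_contrast",
    "cluster_expression_contrast",
    "cluster_term_enrichment",
    "concordance_rank",
]


def nearest_gene(enhancers: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Map each enhancer to the gene with the nearest TSS on its chromosome.

    Ties break lexicographically on gene id; enhancers on chromosomes
    without genes are left unmapped with a warning.
    """
    if genes.empty:
        raise ValueError("gene set is empty")
    cent = interval_centers(enhancers)
    out = {}
    gene_by_chrom = {
        chrom: sub.sort_values(["tss", "gene_id"], kind="stable")
        for chrom, sub in genes.groupby("chrom")
    }
    unmapped = 0
    for eid, chrom, c in zip(enhancers["id"], enhancers["chrom"], cent):
        sub = gene_by_chrom.get(chrom)
        if sub is None:
            unmapped += 1
            continue
        tss = sub["tss"].to_numpy()
        d = np.abs(tss - c)
        best = d.min()
        cand = sub.loc[sub.index[d == best], "gene_id"]
        out[eid] = sorted(cand)[0]
    if unmapped:
        warnings.warn(f"{unmapped} enhancers on gene-free chromosomes left unmapped")
    return pd.Series(out, name="gene_id").rename_axis("enhancer_id")


def _pair_gene_correlations(pairs: pd.DataFrame, target_map: pd.Series,
                            expression: pd.DataFrame):
    """Spearman correlation of target-gene expression for each pair.

    Pairs whose enhancers share one target gene, map to no gene, or have a
    constant expression vector are excluded; the exclusion count is returned.
    """
    cors, excluded = [], 0
    for a, b in zip(pairs["id_a"], pairs["id_b"]):
        ga, gb = target_map.get(a), target_map.get(b)
        if ga is None or gb is None or ga == gb:
            excluded += 1
            continue
        if ga not in expression.index or gb not in expression.index:
            excluded += 1
            continue
        r = spearman(expression.loc[ga].to_numpy(), expression.loc[gb].to_numpy())
        if np.isnan(r):
            excluded += 1
            continue
        cors.append(r)
    return np.array(cors), excluded


def expression_correlation_contrast(
    fg_pairs: pd.DataFrame,
    bg_pairs: pd.DataFrame,
    target_map: pd.Series,
    expression: pd.DataFrame,
) -> dict:
    """Median target-gene expression correlation, foreground vs background."""
    fg, fg_excl = _pair_gene_correlations(fg_pairs, target_map, expression)
    bg, bg_excl = _pair_gene_correlations(bg_pairs, target_map, expression)
    if len(fg) < 2 or len(bg) < 2:
        raise ValueError("need >= 2 usable pairs on each side")
    _, p = rank_sum_test(fg, bg)
    return {
        "fg_median": float(np.median(fg)),
        "bg_median": float(np.median(bg)),
        "p_value": p,
        "n_fg": len(fg),
        "n_bg": len(bg),
        "n_excluded": fg_excl + bg_excl,
    }


def jaccard_expression_regression(
    pairs: pd.DataFrame,
    jaccard: np.ndarray,
    target_map: pd.Series,
    expression: pd.DataFrame,
) -> dict:
    """OLS of pair expression correlation on pair motif Jaccard."""
    ok_r, ok_j = [], []
    for (a, b), j in zip(zip(pairs["id_a"], pairs["id_b"]), jaccard):
        ga, gb = target_map.get(a), target_map.get(b)
        if ga is None or gb is None or ga == gb:
            continue
        if ga not in expression.index or gb not in expression.index:
            continue
        r = spearman(expression.loc[ga].to_numpy(), expression.loc[gb].to_numpy())
        if np.isnan(r):
            continue
        ok_r.append(r)
        ok_j.append(float(j))
    x = np.array(ok_j)
    y = np.array(ok_r)
    if len(x) < 3 or np.ptp(x) == 0:
        raise ValueError("zero variance in Jaccard values")
    res = sps.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "p_value": float(res.pvalue), "n": len(x)}


def _term_membership(annotations: pd.DataFrame, max_term_size: int) -> dict:
    sizes = annotations.groupby("term_id")["gene_id"].nunique()
    keep = set(sizes.index[sizes <= max_term_size])
    terms: dict = {}
    for term, gene in zip(annotations["term_id"], annotations["gene_id"]):
        if term in keep:
            terms.setdefault(gene, set()).add(term)
    return terms


def term_sharing_contrast(
    fg_pairs: pd.DataFrame,
    bg_pairs: pd.DataFrame,
    target_map: pd.Series,
    annotations: pd.DataFrame,
    max_term_size: int = 200,
) -> dict:
    """Fraction of pairs whose distinct target genes share a term."""
    terms_of = _term_membership(annotations, max_term_size)

    def _count(pairs):
        share = total = 0
        for a, b in zip(pairs["id_a"], pairs["id_b"]):
            ga, gb = target_map.get(a), target_map.get(b)
            if ga is None or gb is None or ga == gb:
                continue
            total += 1
            if terms_of.get(ga, set()) & terms_of.get(gb, set()):
                share += 1
        return share, total

    fg_share, fg_total = _count(fg_pairs)
    bg_share, bg_total = _count(bg_pairs)
    if fg_total == 0 or bg_total == 0:
        raise ValueError("no eligible pairs with distinct targets")
    odds, p = fisher_exact_2x2(
        [[fg_share, fg_total - fg_share], [bg_share, bg_total - bg_share]]
    )
    return {
        "fg_fraction": fg_share / fg_total,
        "bg_fraction": bg_share / bg_total,
        "odds_ratio": odds,
        "p_value": p,
    }


def _cluster_mean_correlation(members, target_map, expression):
    genes = sorted({target_map.get(m) for m in members} - {None})
    genes = [g for g in genes if g in expression.index]
    if len(genes) < 2:
        return None
    cors = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = spearman(
                expression.loc[genes[i]].to_numpy(),
                expression.loc[genes[j]].to_numpy(),
            )
            if not np.isnan(r):
                cors.append(r)
    return float(np.mean(cors)) if cors else None


def cluster_expression_contrast(
    clusters, background_clusters, target_map: pd.Series, expression: pd.DataFrame
) -> dict:
    """Mean pairwise target co-expression, clusters vs matched backgrounds."""
    fg, bg, excluded = [], [], 0
    for c in clusters:
        m = _cluster_mean_correlation(c.members, target_map, expression)
        if m is None:
            excluded += 1
        else:
            fg.append(m)
    for c in background_clusters:
        m = _cluster_mean_correlation(c.members, target_map, expression)
        if m is None:
            excluded += 1
        else:
            bg.append(m)
    if not fg or not bg:
        raise ValueError("no clusters with >= 2 distinct target genes")
    _, p = rank_sum_test(fg, bg)
    return {
        "fg_means": fg,
        "bg_means": bg,
        "p_value": p,
        "n_excluded": excluded,
    }


def cluster_term_enrichment(
    cluster_genes,
    universe,
    annotations: pd.DataFrame,
    fdr: float = 0.01,
    max_term_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric term enrichment for a gene cluster, BH-filtered."""
    universe = set(universe)
    cluster_genes = set(cluster_genes)
    if not universe:
        raise ValueError("empty gene universe")
    if not cluster_genes <= universe:
        raise ValueError("cluster genes must lie within the universe")
    ann = annotations[annotations["gene_id"].isin(universe)]
    rows = []
    for term, sub in ann.groupby("term_id"):
        term_genes = set(sub["gene_id"])
        if max_term_size is not None and len(term_genes) > max_term_size:
            continue
        overlap = len(term_genes & cluster_genes)
        p = hypergeom_upper_tail(
            overlap, len(universe), len(term_genes), len(cluster_genes)
        )
        rows.append({"term_id": term, "overlap": overlap,
                     "term_size": len(term_genes), "p_value": p})
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "overlap", "term_size", "p_value", "q_value"]
        ).set_index("term_id")
    out = pd.DataFrame(rows).set_index("term_id")
    out["q_value"] = bh_adjust(out["p_value"])
    return out[out["q_value"] <= fdr].sort_values("p_value")


def _class_accessibility_fraction(activity: pd.DataFrame, members,
                                  class_members: dict) -> dict:
    """Fraction of the given enhancers accessible in >= 1 cell type per class."""
    sub = activity.loc[[m for m in members if m in activity.index]]
    out = {}
    for cid, cts in class_members.items():
        cols = [c for c in cts if c in sub.columns]
        if not cols:
            out[cid] = 0.0
            continue
        out[cid] = float((sub[cols].to_numpy().max(axis=1) > 0).mean()) if len(sub) else 0.0
    return out


def concordance_rank(
    clusters,
    activity: pd.DataFrame,
    class_of_cell_type: pd.Series,
    matched_class_of_cluster: dict,
    background_clusters=None,
) -> dict:
    """Rank of the matched tissue class by accessibility fold enrichment.

    For each cluster and class, fold enrichment is the fraction of cluster
    enhancers accessible in >= 1 cell type of the class divided by the same
    fraction over all enhancers; classes are ranked by descending enrichment
    with average ranks for ties.  Classes with zero global accessibility are
    excluded with a warning.
    """
    class_members: dict = {}
    for ct, cid in class_of_cell_type.items():
        class_members.setdefault(cid, []).append(ct)
    global_frac = _class_accessibility_fraction(
        activity, list(activity.index), class_members
    )
    dropped = [cid for cid, f in global_frac.items() if f == 0]
    if dropped:
        warnings.warn(f"classes with zero global accessibility excluded: {dropped}")
        class_members = {c: m for c, m in class_members.items() if c not in dropped}

    def _ranks(cluster_list):
        ranks = []
        for i, cluster in enumerate(cluster_list):
            matched = matched_class_of_cluster.get(i)
            if matched is None or matched not in class_members:
                continue
            frac = _class_accessibility_fraction(
                activity, cluster.members, class_members
            )
            cids = sorted(class_members)
            enrich = np.array([frac[c] / global_frac[c] for c in cids])
            # descending enrichment, average ranks on ties
            rank = sps.rankdata(-enrich, method="average")
            ranks.append(float(rank[cids.index(matched)]))
        return ranks

    fg_ranks = _ranks(clusters)
    result = {
        "ranks": fg_ranks,
        "median_rank": float(np.median(fg_ranks)) if fg_ranks else np.nan,
        "n_classes": len(class_members),
    }
    if background_clusters is not None:
        bg_ranks = _ranks(background_clusters)
        result["bg_ranks"] = bg_ranks
        result["bg_median_rank"] = (
            float(np.median(bg_ranks)) if bg_ranks else np.nan
        )
        k = min(len(fg_ranks), len(bg_ranks))
        if k >= 1:
            diff = np.array(fg_ranks[:k]) - np.array(bg_ranks[:k])
            if np.any(diff != 0):
                res = sps.wilcoxon(diff)
                result["paired_p"] = float(res.pvalue)
            else:
                result["paired_p"] = 1.0
    return result
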