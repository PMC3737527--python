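"""Spatial-proximity tests against accessibility-matched backgrounds.

Correlated enhancer pairs are compared with uncorrelated pairs matched per
distance bin on average pair-mean accessibility, asking whether they
coincide with contact pairs (Hi-C-like input) more often than expected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from conet.intervals import make_intervals, overlaps_any
from conet.stats import fisher_exact_2x2

__all__ = [
    "pair_mean_accessibility",
    "dhs_matched_background",
    "map_contacts_to_enhancers",
    "contact_enrichment",
]


def pair_mean_accessibility(pairs: pd.DataFrame, activity: pd.DataFrame) -> np.ndarray:
    """Mean accessibility over both members and all cell types, per pair."""
    a = activity.loc[pairs["id_a"]].to_numpy(dtype=np.float64)
    b = activity.loc[pairs["id_b"]].to_numpy(dtype=np.float64)
    return (a.mean(axis=1) + b.mean(axis=1)) / 2.0


def dhs_matched_background(
    fg_pairs: pd.DataFrame,
    candidate_pairs: pd.DataFrame,
    activity: pd.DataFrame,
    rng: np.random.Generator,
    tolerance: float = 0.02,
    relative: bool = True,
    max_tries: int = 2000,
) -> pd.DataFrame:
    """Sample accessibility-matched uncorrelated pairs, per distance bin.

    Matches the foreground pair count exactly per bin and requires the
    average pair-mean accessibility of the sample to be within ``tolerance``
    (relative by default) of the foreground's.  A random sample is refined
    by greedy swaps that shrink the accessibility gap; raises with the
    achieved gap if the tolerance is unattainable.
    """
    cand_acc_all = pair_mean_accessibility(candidate_pairs, activity)
    picks = []
    for b, fg_bin in fg_pairs.groupby("bin"):
        want = len(fg_bin)
        cand = candidate_pairs[candidate_pairs["bin"] == b]
        if len(cand) <= want:
            raise ValueError(f"bin {b}: {len(cand)} candidates for {want} slots")
        target = float(pair_mean_accessibility(fg_bin, activity).mean())
        acc = cand_acc_all[candidate_pairs["bin"].to_numpy() == b]
        sel = rng.choice(len(cand), size=want, replace=False)
        selected = np.zeros(len(cand), dtype=bool)
        selected[sel] = True

        def gap(mean):
            return abs(mean - target) / (abs(target) if relative and target else 1.0)

        # best-improvement local search: swap one selected pair for the
        # unselected candidate that brings the sample mean closest to target
        total = float(acc[selected].sum())
        tries = 0
        while gap(total / want) > tolerance and tries < max_tries:
            tries += 1
            need = target * want - total  # signed correction to the sum
            if need > 0:
                out_i = np.flatnonzero(selected)[np.argmin(acc[selected])]
            else:
                out_i = np.flatnonzero(selected)[np.argmax(acc[selected])]
            pool = np.flatnonzero(~selected)
            ideal = acc[out_i] + need
            in_i = pool[np.argmin(np.abs(acc[pool] - ideal))]
            new_total = total - acc[out_i] + acc[in_i]
            if abs(new_total / want - target) >= abs(total / want - target):
                break
            selected[out_i] = False
            selected[in_i] = True
            total = new_total
        mean = total / want
        if gap(mean) > tolerance:
            raise ValueError(
                f"bin {b}: accessibility match unattainable, achieved gap "
                f"{gap(mean):.4f} > tolerance {tolerance}"
            )
        picks.append(cand.iloc[np.flatnonzero(selected)])
    return pd.concat(picks, ignore_index=True)


def map_contacts_to_enhancers(
    contacts: pd.DataFrame, enhancers: pd.DataFrame
) -> set:
    """Set of unordered enhancer-id pairs whose intervals overlap (>= 1 bp)
    the two anchors of some contact."""
    hits = set()
    if contacts.empty:
        return hits
    anchors_a = make_intervals(contacts["chrom_a"], contacts["start_a"],
                               contacts["end_a"])
    anchors_b = make_intervals(contacts["chrom_b"], contacts["start_b"],
                               contacts["end_b"])
    ids = enhancers["id"].to_numpy()

    def anchor_hits(anchors):
        per_contact: list[list] = [[] for _ in range(len(anchors))]
        for k in range(len(anchors)):
            one = anchors.iloc[[k]]
            ov = overlaps_any(enhancers, one)
            per_contact[k] = list(ids[ov])
        return per_contact

    hits_a = anchor_hits(anchors_a)
    hits_b = anchor_hits(anchors_b)
    for ea_list, eb_list in zip(hits_a, hits_b):
        for ea in ea_list:
            for eb in eb_list:
                if ea != eb:
                    hits.add((min(ea, eb), max(ea, eb)))
    return hits


def contact_enrichment(
    fg_pairs: pd.DataFrame,
    bg_pairs: pd.DataFrame,
    contacts: pd.DataFrame,
    enhancers: pd.DataFrame,
    top_fraction: float = 1.0,
) -> dict:
    """Fisher test of contact coincidence, foreground vs background pairs.

    ``top_fraction`` < 1 first restricts contacts to the ``ceil(f * n)``
    highest-confidence rows.
    """
    used = contacts
    if top_fraction < 1.0:
        n_keep = int(np.ceil(top_fraction * len(contacts)))
        used = contacts.sort_values("confidence", ascending=False).head(n_keep)
    contact_keys = map_contacts_to_enhancers(used, enhancers)
    if not contact_keys:
        return {"odds_ratio": np.nan, "p_value": 1.0, "flagged": True,
                "fg_in_contact": 0, "bg_in_contact": 0}

    def count(pairs):
        keys = zip(pairs["id_a"], pairs["id_b"])
        return sum(1 for a, b in keys if (min(a, b), max(a, b)) in contact_keys)

    fg_in = count(fg_pairs)
    bg_in = count(bg_pairs)
    odds, p = fisher_exact_2x2(
        [[fg_in, len(fg_pairs) - fg_in], [bg_in, len(bg_pairs) - bg_in]]
    )
    return {
        "odds_ratio": odds,
        "p_value": p,
        "flagged": False,
        "fg_in_contact": fg_in,
        "bg_in_contact": bg_in,
        "n_contacts_used": len(used),
    }
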