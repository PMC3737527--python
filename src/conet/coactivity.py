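"""Pairwise co-activity scoring against an autocorrelation-preserving null.

Enhancer pairs are scored by the plug-in mutual information (bits) of their
binary accessibility vectors.  For each pair, a synthetic partner is drawn
from per-cell-type conditional accessibility probabilities estimated from
random genomic segments at the pair's distance bin, preserving both the
marginal accessibility and the along-genome autocorrelation.  Significant
pairs are called per distance bin with a monotonized empirical FDR, then
optionally reduced to a matching by greedy transitive pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from conet.intervals import centers as interval_centers

__all__ = [
    "DEFAULT_BIN_EDGES",
    "AutocorrelationModel",
    "SignificancePolicy",
    "mutual_information",
    "binary_entropy",
    "pairwise_mi",
    "estimate_autocorrelation",
    "synthesize_partner",
    "synthesize_partners",
    "enumerate_pairs",
    "call_significant",
    "prune_transitive",
    "matched_uncorrelated_background",
]

# Six geometric bins spanning 20 kb - 12.5 Mb, preceded by a closed
# (0, 20 kb] bin; distances beyond the last edge fall in an open far bin.
DEFAULT_BIN_EDGES = (20_000, 72_000, 260_000, 950_000, 3_500_000, 12_500_000)


def binary_entropy(x: np.ndarray) -> float:
    """Plug-in entropy (bits) of a binary vector."""
    x = np.asarray(x)
    p = float(np.mean(x))
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            h -= q * np.log2(q)
    return h


def mutual_information(x, y) -> float:
    """Plug-in mutual information (bits) between two binary vectors.

    Computes ``sum p(x,y) log2(p(x,y) / (p(x) p(y)))`` over the four joint
    cells, with ``0 log 0 = 0``.  Symmetric; bounded by ``min(H(x), H(y))``.
    """
    x = np.asarray(x).astype(np.int64)
    y = np.asarray(y).astype(np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("vectors must have length >= 2")
    n11 = int(np.sum(x & y))
    n1_ = int(np.sum(x))
    n_1 = int(np.sum(y))
    return _mi_from_counts(
        np.array([n11]), np.array([n1_]), np.array([n_1]), n
    )[0]


def _mi_from_counts(n11, n1_, n_1, n) -> np.ndarray:
    """Vectorized plug-in MI (bits) from joint/marginal counts."""
    n11 = np.asarray(n11, dtype=np.float64)
    n1_ = np.asarray(n1_, dtype=np.float64)
    n_1 = np.asarray(n_1, dtype=np.float64)
    n10 = n1_ - n11
    n01 = n_1 - n11
    n00 = n - n1_ - n01
    mi = np.zeros_like(n11)
    for nxy, nx, ny in (
        (n11, n1_, n_1),
        (n10, n1_, n - n_1),
        (n01, n - n1_, n_1),
        (n00, n - n1_, n - n_1),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (nxy / n) * np.log2(nxy * n / (nx * ny))
        mi += np.where(nxy > 0, term, 0.0)
    return np.maximum(mi, 0.0)


def pairwise_mi(states: np.ndarray, i_idx, j_idx, chunk: int = 200_000) -> np.ndarray:
    """MI (bits) for many row pairs of a binary matrix, computed in chunks."""
    i_idx = np.asarray(i_idx)
    j_idx = np.asarray(j_idx)
    n = states.shape[1]
    out = np.empty(len(i_idx), dtype=np.float64)
    row_sums = states.sum(axis=1).astype(np.int64)
    for lo in range(0, len(i_idx), chunk):
        hi = min(lo + chunk, len(i_idx))
        a = states[i_idx[lo:hi]]
        b = states[j_idx[lo:hi]]
        n11 = (a & b).sum(axis=1)
        out[lo:hi] = _mi_from_counts(
            n11, row_sums[i_idx[lo:hi]], row_sums[j_idx[lo:hi]], n
        )
    return out


@dataclass
class AutocorrelationModel:
    """Distance-binned conditional accessibility probabilities per cell type.

    ``cond_prob[b, t, s]`` is the probability that a region at distance bin
    ``b`` is accessible in cell type ``t`` given that the seed region's state
    is ``s``.  Cells with fewer than ``min_count`` supporting ordered pairs
    fall back to the cell type's marginal rate and are flagged.
    """

    upper_edges: np.ndarray  # B upper bin edges; bin B is the open far bin
    cell_types: list
    cond_prob: np.ndarray  # (B + 1, T, 2)
    marginal: np.ndarray  # (T,)
    fallback: np.ndarray  # (B + 1, T, 2) bool
    pair_counts: np.ndarray = field(default=None)  # (B + 1, T, 2)

    @property
    def n_bins(self) -> int:
        return len(self.upper_edges) + 1

    @property
    def open_bin(self) -> int:
        return len(self.upper_edges)

    def bin_of(self, distance) -> np.ndarray:
        """Bin index for distances; bin b covers (edge[b-1], edge[b]]."""
        d = np.asarray(distance)
        return np.searchsorted(self.upper_edges, d, side="left")


def estimate_autocorrelation(
    segments: pd.DataFrame,
    states: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
    min_count: int = 25,
) -> AutocorrelationModel:
    """Estimate the autocorrelation model from random genomic segments.

    For every distance bin and cell type, the conditional probability that
    the second member of an ordered same-chromosome segment pair is
    accessible is computed separately for seed state 0 and 1.  The open far
    bin pools all same-chromosome pairs beyond the last edge.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    if len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    S_all = states.to_numpy().astype(np.int64)
    T = S_all.shape[1]
    n_bins = len(edges) + 1
    k = np.zeros((n_bins, T, 2))  # partner-accessible counts
    m = np.zeros((n_bins, T, 2))  # pair counts
    lowers = np.concatenate([[0.0], edges])
    uppers = np.concatenate([edges, [np.inf]])

    chrom_arr = segments["chrom"].to_numpy()
    cent_all = interval_centers(segments)
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        if mask.sum() < 2:
            continue
        order = np.argsort(cent_all[mask], kind="stable")
        c = cent_all[mask][order].astype(np.float64)
        S = S_all[mask][order]
        ps = np.vstack([np.zeros((1, T), dtype=np.int64), np.cumsum(S, axis=0)])
        for b in range(n_bins):
            lo, hi = lowers[b], uppers[b]
            # forward windows: partners at distance in (lo, hi]
            f_lo = np.searchsorted(c, c + lo, side="right")
            f_hi = np.searchsorted(c, c + hi, side="right")
            # backward windows: partners at distance in [-hi, -lo)
            b_lo = np.searchsorted(c, c - hi, side="left")
            b_hi = np.searchsorted(c, c - lo, side="left")
            num = (f_hi - f_lo) + (b_hi - b_lo)
            cnt = (ps[f_hi] - ps[f_lo]) + (ps[b_hi] - ps[b_lo])
            for s in (0, 1):
                sel = (S == s)  # (m, T)
                k[b, :, s] += (sel * cnt).sum(axis=0)
                m[b, :, s] += (sel * num[:, None]).sum(axis=0)
    if m.sum() == 0:
        raise ValueError("no same-chromosome segment pairs in any bin")
    marginal = S_all.mean(axis=0)
    fallback = m < min_count
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = k / m
    cond = np.where(fallback, marginal[None, :, None], cond)
    return AutocorrelationModel(
        upper_edges=edges,
        cell_types=list(states.columns),
        cond_prob=cond,
        marginal=marginal,
        fallback=fallback,
        pair_counts=m,
    )


def synthesize_partner(
    x, bin_index: int, model: AutocorrelationModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw a synthetic partner vector conditioned on seed state and bin."""
    x = np.asarray(x).astype(np.int64)
    if len(x) != len(model.cell_types):
        raise ValueError("seed vector length does not match model cell types")
    if not 0 <= bin_index < model.n_bins:
        raise ValueError(f"bin {bin_index} outside model (0..{model.n_bins - 1})")
    p = model.cond_prob[bin_index, np.arange(len(x)), x]
    return (rng.random(len(x)) < p).astype(np.int8)


def synthesize_partners(
    seeds: np.ndarray, bins: np.ndarray, model: AutocorrelationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized :func:`synthesize_partner` for many (seed, bin) pairs."""
    bins = np.asarray(bins)
    if bins.min(initial=0) < 0 or bins.max(initial=0) >= model.n_bins:
        raise ValueError("bin index outside model")
    seeds = seeds.astype(np.int64)
    t_idx = np.arange(seeds.shape[1])[None, :]
    p = model.cond_prob[bins[:, None], t_idx, seeds]
    return (rng.random(seeds.shape) < p).astype(np.int8)


def _window_pairs(c: np.ndarray, max_d: float):
    """All index pairs (i < j) of sorted centers with c[j] - c[i] < max_d."""
    n = len(c)
    hi = np.searchsorted(c, c + max_d, side="left")
    lo = np.arange(n) + 1
    counts = np.maximum(hi - lo, 0)
    i_idx = np.repeat(np.arange(n), counts)
    # j indices: lo[i] .. lo[i] + counts[i] - 1, concatenated
    total = counts.sum()
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    j_idx = np.arange(total) - np.repeat(starts, counts) + np.repeat(lo, counts)
    return i_idx, j_idx


def enumerate_pairs(
    enhancers: pd.DataFrame,
    matrix: pd.DataFrame,
    model: AutocorrelationModel,
    rng: np.random.Generator,
    max_exhaustive: float = 12_500_000,
    far_sample: int = 0,
    trans_sample: int = 0,
) -> pd.DataFrame:
    """Score enhancer pairs: observed MI and one synthetic-null MI each.

    All same-chromosome pairs with centre distance < ``max_exhaustive`` are
    scored exhaustively; ``far_sample`` same-chromosome pairs beyond the
    ceiling and ``trans_sample`` inter-chromosomal pairs are sampled
    uniformly and assigned to the open far bin.  The synthetic partner is
    seeded from a randomly chosen member of each pair.
    """
    if matrix.empty:
        raise ValueError("activity matrix is empty")
    ids = enhancers["id"].to_numpy()
    states = matrix.loc[ids].to_numpy().astype(np.int8)
    cent = interval_centers(enhancers)
    chrom_arr = enhancers["chrom"].to_numpy()

    I_parts, J_parts = [], []
    for chrom in pd.unique(chrom_arr):
        where = np.where(chrom_arr == chrom)[0]
        order = np.argsort(cent[where], kind="stable")
        gpos = where[order]
        li, lj = _window_pairs(cent[gpos].astype(np.float64), max_exhaustive)
        I_parts.append(gpos[li])
        J_parts.append(gpos[lj])
    I = np.concatenate(I_parts) if I_parts else np.empty(0, dtype=np.int64)
    J = np.concatenate(J_parts) if J_parts else np.empty(0, dtype=np.int64)

    if far_sample > 0:
        fi, fj = _sample_pairs(
            chrom_arr, cent, rng, far_sample, same_chrom=True, min_d=max_exhaustive
        )
        I = np.concatenate([I, fi])
        J = np.concatenate([J, fj])
    if trans_sample > 0:
        ti, tj = _sample_pairs(chrom_arr, cent, rng, trans_sample, same_chrom=False)
        I = np.concatenate([I, ti])
        J = np.concatenate([J, tj])
    if len(I) == 0:
        raise ValueError("no candidate pairs")

    same = chrom_arr[I] == chrom_arr[J]
    distance = np.where(same, np.abs(cent[J] - cent[I]), -1)
    bins = np.where(same, model.bin_of(np.abs(cent[J] - cent[I])), model.open_bin)
    bins = np.minimum(bins, model.open_bin)

    mi = pairwise_mi(states, I, J)
    pick = rng.integers(0, 2, size=len(I))
    seed_rows = np.where(pick == 0, I, J)
    partners = synthesize_partners(states[seed_rows], bins, model, rng)
    n11 = (states[seed_rows] & partners).sum(axis=1)
    synthetic_mi = _mi_from_counts(
        n11, states[seed_rows].sum(axis=1), partners.sum(axis=1), states.shape[1]
    )

    # canonical orientation: id_a < id_b
    swap = ids[I] > ids[J]
    a = np.where(swap, J, I)
    b = np.where(swap, I, J)
    table = pd.DataFrame(
        {
            "id_a": ids[a],
            "id_b": ids[b],
            "chrom_a": chrom_arr[a],
            "chrom_b": chrom_arr[b],
            "distance": distance.astype(np.int64),
            "bin": bins.astype(np.int64),
            "mi": mi,
            "synthetic_mi": synthetic_mi,
        }
    )
    return table


def _sample_pairs(chrom_arr, cent, rng, n_wanted, same_chrom, min_d=0.0):
    """Uniform rejection sampling of index pairs with chromosome constraints."""
    n = len(chrom_arr)
    got_i, got_j = [], []
    remaining = n_wanted
    for _ in range(200):
        if remaining <= 0:
            break
        k = max(remaining * 3, 1000)
        i = rng.integers(0, n, size=k)
        j = rng.integers(0, n, size=k)
        ok = i != j
        if same_chrom:
            ok &= (chrom_arr[i] == chrom_arr[j]) & (
                np.abs(cent[j] - cent[i]) >= min_d
            )
        else:
            ok &= chrom_arr[i] != chrom_arr[j]
        i, j = i[ok][:remaining], j[ok][:remaining]
        got_i.append(i)
        got_j.append(j)
        remaining -= len(i)
    i = np.concatenate(got_i) if got_i else np.empty(0, dtype=np.int64)
    j = np.concatenate(got_j) if got_j else np.empty(0, dtype=np.int64)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    return lo, hi


@dataclass
class SignificancePolicy:
    alpha: float
    per_bin_threshold: dict  # bin index -> MI threshold (inf = nothing called)
    pooled: bool = False


def _bin_threshold(obs: np.ndarray, syn: np.ndarray, alpha: float) -> float:
    """Smallest observed MI t with monotonized q(t) <= alpha, else +inf."""
    ts = np.unique(obs)  # ascending candidate thresholds
    obs_sorted = np.sort(obs)
    syn_sorted = np.sort(syn)
    n_obs_ge = len(obs) - np.searchsorted(obs_sorted, ts, side="left")
    n_syn_ge = len(syn) - np.searchsorted(syn_sorted, ts, side="left")
    q = n_syn_ge / np.maximum(1, n_obs_ge)
    # monotonize to a non-increasing q-value in t: a pair rejected at t is
    # rejected at every lower threshold, so q(t) = min over t' <= t
    q = np.minimum.accumulate(q)
    ok = np.where(q <= alpha)[0]
    if len(ok) == 0:
        return np.inf
    return float(ts[ok[0]])


def call_significant(
    table: pd.DataFrame, alpha: float, pooled: bool = False
) -> tuple[SignificancePolicy, pd.DataFrame]:
    """Call significantly correlated pairs at a nominal empirical FDR.

    Per distance bin (or pooled across bins), the threshold is the smallest
    observed MI value ``t`` whose monotonized null-to-observed exceedance
    ratio ``q(t)`` is at or below ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if table.empty:
        raise ValueError("pair table is empty")
    thresholds: dict[int, float] = {}
    if pooled:
        t = _bin_threshold(table["mi"].to_numpy(), table["synthetic_mi"].to_numpy(),
                           alpha)
        for b in sorted(table["bin"].unique()):
            thresholds[int(b)] = t
    else:
        for b, sub in table.groupby("bin"):
            thresholds[int(b)] = _bin_threshold(
                sub["mi"].to_numpy(), sub["synthetic_mi"].to_numpy(), alpha
            )
    thr = table["bin"].map(thresholds).to_numpy()
    called = table[table["mi"].to_numpy() >= thr].reset_index(drop=True)
    return SignificancePolicy(alpha, thresholds, pooled), called


def prune_transitive(pairs: pd.DataFrame) -> pd.DataFrame:
    """Greedy reduction to a matching, strongest (highest MI) pairs first.

    A pair is retained iff neither enhancer already appears in a retained
    pair; ties in MI break lexicographically on (id_a, id_b).
    """
    if pairs.empty:
        return pairs.copy()
    ordered = pairs.sort_values(
        ["mi", "id_a", "id_b"], ascending=[False, True, True], kind="stable"
    )
    used: set = set()
    keep = []
    for row in ordered.itertuples():
        if row.id_a in used or row.id_b in used:
            continue
        used.add(row.id_a)
        used.add(row.id_b)
        keep.append(row.Index)
    return pairs.loc[keep].reset_index(drop=True)


def matched_uncorrelated_background(
    table: pd.DataFrame,
    foreground: pd.DataFrame,
    rng: np.random.Generator,
    mi_ceiling: float = 0.01,
) -> pd.DataFrame:
    """Distance-matched uncorrelated pair sample (per-bin count matching).

    For each distance bin, samples (without replacement) as many pairs with
    ``mi < mi_ceiling`` as the foreground has in that bin.
    """
    fg_key = set(zip(foreground["id_a"], foreground["id_b"]))
    low = table[table["mi"] < mi_ceiling]
    picks = []
    for b, want in foreground["bin"].value_counts().sort_index().items():
        cand = low[low["bin"] == b]
        in_fg = pd.Series(
            list(zip(cand["id_a"], cand["id_b"])), index=cand.index, dtype=object
        ).isin(fg_key) if len(cand) else pd.Series(dtype=bool)
        cand = cand[~in_fg] if len(cand) else cand
        if len(cand) < want:
            raise ValueError(
                f"bin {b}: only {len(cand)} candidates with mi < {mi_ceiling}, "
                f"need {want} (deficit {want - len(cand)})"
            )
        picks.append(cand.iloc[rng.choice(len(cand), size=want, replace=False)])
    if not picks:
        return table.iloc[0:0].copy()
    return pd.concat(picks, ignore_index=True)
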