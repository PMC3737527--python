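"""Synthetic genome generator with planted co-active enhancer modules.

The generator produces every input the analysis pipeline consumes —
enhancer intervals, a binary enhancer-by-cell-type accessibility matrix,
motif presence/absence, a motif similarity matrix, target genes with
expression, strength labels, spatial contacts, annotation terms — together
with ground-truth module membership for recovery tests.

Background (non-module) accessibility follows, per chromosome and cell
type, a stationary two-state Markov process whose state correlation at
genomic distance ``d`` equals ``exp(-d / autocorr_decay_length)`` while the
marginal accessibility rate is held at ``marginal_dhs_rate``.  Module
members instead copy a module-level latent cross-cell-type activity vector,
with independent per-entry flips at rate ``flip_noise``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from conet.config import ConfigurationError, SimulationConfig
from conet.intervals import make_intervals, overlaps_any, write_bed

__all__ = [
    "SyntheticDataset",
    "simulate_dataset",
    "simulate_background_track",
    "write_fixtures",
    "markov_track",
]


@dataclass
class SyntheticDataset:
    """A generated genome plus ground truth for all downstream analyses."""

    config: SimulationConfig
    enhancers: pd.DataFrame  # chrom, start, end, id
    activity: pd.DataFrame  # enhancer id x cell type, int8
    module_of: pd.Series  # enhancer id -> module index, -1 for none
    module_latent: pd.DataFrame  # module index x cell type, int8
    motif_matrix: pd.DataFrame  # enhancer id x motif id, int8
    motif_similarity: pd.DataFrame  # motif id x motif id, float
    driver_motifs: dict  # module index -> list of motif ids
    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    target_of: pd.Series  # enhancer id -> gene_id (nearest by construction)
    expression: pd.DataFrame  # gene_id x expression cell type, float
    expression_cell_types: list
    strength_labels: pd.Series  # enhancer id -> strong | weak | ambiguous
    contacts: pd.DataFrame  # chrom_a..end_b, confidence
    annotations: pd.DataFrame  # term_id, gene_id
    class_of_cell_type: pd.Series  # cell type -> class id
    matched_class_of_module: pd.Series  # module index -> class id
    background_segments: pd.DataFrame  # chrom, start, end, id
    background_activity: pd.DataFrame  # segment id x cell type, int8

    @property
    def cell_types(self) -> list:
        return list(self.activity.columns)

    def module_members(self, module: int) -> list:
        return list(self.module_of.index[self.module_of == module])

    def within_module_pairs(self) -> list:
        """All unordered ground-truth co-module enhancer id pairs."""
        pairs = []
        for m in range(self.config.n_modules):
            members = sorted(self.module_members(m))
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.append((members[i], members[j]))
        return pairs


def markov_track(
    positions: np.ndarray,
    n_cell_types: int,
    marginal: float,
    decay_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a stationary two-state Markov process at sorted positions.

    Returns an ``(n_positions, n_cell_types)`` int8 array.  Each cell type is
    an independent chain with marginal ``marginal`` and correlation
    ``exp(-gap / decay_length)`` across a gap.  The chain is realised as a
    renewal process: across each gap the previous state is copied with
    probability ``exp(-gap / decay_length)`` and redrawn from the marginal
    otherwise, which yields exactly the requested covariance structure.
    """
    n = len(positions)
    if n == 0:
        return np.zeros((0, n_cell_types), dtype=np.int8)
    gaps = np.diff(positions.astype(np.float64))
    if np.any(gaps < 0):
        raise ValueError("positions must be sorted")
    if decay_length > 0:
        rho = np.exp(-gaps / decay_length)
    else:
        rho = np.zeros_like(gaps)
    fresh = (rng.random((n, n_cell_types)) < marginal).astype(np.int8)
    copy = rng.random((n - 1, n_cell_types)) < rho[:, None]
    # renewal index: last row at which the chain redrew from the marginal
    renew = np.empty((n, n_cell_types), dtype=np.int64)
    renew[0] = 0
    idx = np.arange(1, n)[:, None]
    renew[1:] = np.where(copy, -1, idx)
    renew = np.maximum.accumulate(renew, axis=0)
    return np.take_along_axis(fresh, renew, axis=0)


def _place_enhancers(config: SimulationConfig, rng: np.random.Generator):
    """Uniform placement with a minimum spacing, per chromosome."""
    per_chrom = np.full(config.n_chromosomes, config.n_enhancers // config.n_chromosomes)
    per_chrom[: config.n_enhancers % config.n_chromosomes] += 1
    half = config.enhancer_length // 2
    chroms, cents = [], []
    for c in range(config.n_chromosomes):
        k = int(per_chrom[c])
        if k == 0:
            continue
        lo = half + 1
        hi = config.chrom_length - half - 1
        slack = (hi - lo) - (k - 1) * config.min_spacing
        if slack <= 0:
            raise ConfigurationError("chrom_length", "cannot honour min_spacing")
        u = np.sort(rng.random(k)) * slack + lo
        centers = (u + np.arange(k) * config.min_spacing).astype(np.int64)
        chroms.extend([f"chr{c + 1}"] * k)
        cents.append(centers)
    centers = np.concatenate(cents)
    ids = [f"enh{i:06d}" for i in range(len(centers))]
    enh = make_intervals(chroms, centers - half, centers + half, ids)
    return enh, centers


def _assign_modules(config: SimulationConfig, enhancers: pd.DataFrame, rng):
    """Plant modules as runs of consecutive enhancers on one chromosome."""
    module_of = np.full(len(enhancers), -1, dtype=np.int64)
    if config.n_modules == 0:
        return module_of
    chrom = enhancers["chrom"].to_numpy()
    taken = np.zeros(len(enhancers), dtype=bool)
    # candidate starts: windows of module_size consecutive slots on one chromosome
    valid_start = np.ones(len(enhancers), dtype=bool)
    for i in range(len(enhancers)):
        j = i + config.module_size - 1
        if j >= len(enhancers) or chrom[j] != chrom[i]:
            valid_start[i] = False
    placed = 0
    attempts = 0
    while placed < config.n_modules:
        attempts += 1
        if attempts > 10_000:
            raise ConfigurationError(
                "n_modules", "could not place all modules without overlap"
            )
        s = int(rng.integers(0, len(enhancers)))
        if not valid_start[s]:
            continue
        window = slice(s, s + config.module_size)
        if taken[window].any():
            continue
        module_of[window] = placed
        taken[window] = True
        placed += 1
    return module_of


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given ``config.seed``."""
    streams = np.random.SeedSequence(config.seed).spawn(12)
    rng_place, rng_mod, rng_act, rng_noise, rng_motif, rng_gene = (
        np.random.default_rng(s) for s in streams[:6]
    )
    rng_expr, rng_label, rng_contact, rng_term, rng_bg, rng_sim = (
        np.random.default_rng(s) for s in streams[6:]
    )

    cell_types = [f"ct{t:02d}" for t in range(config.n_cell_types)]
    enhancers, centers = _place_enhancers(config, rng_place)
    enh_ids = enhancers["id"].tolist()
    n = len(enhancers)

    module_of = _assign_modules(config, enhancers, rng_mod)

    if config.module_spacing is not None:
        # compress each module run to a fixed spacing (enhancer-cluster
        # geometry); only applied when it shrinks the run's span
        half = config.enhancer_length // 2
        for m in range(config.n_modules):
            members = np.where(module_of == m)[0]
            old_span = centers[members[-1]] - centers[members[0]]
            new_span = (len(members) - 1) * config.module_spacing
            if new_span <= old_span:
                centers[members] = centers[members[0]] + np.arange(
                    len(members)
                ) * config.module_spacing
        enhancers["start"] = centers - half
        enhancers["end"] = centers + half

    # background accessibility: Markov chain along each chromosome
    activity = np.zeros((n, config.n_cell_types), dtype=np.int8)
    chrom_arr = enhancers["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        activity[mask] = markov_track(
            centers[mask],
            config.n_cell_types,
            config.marginal_dhs_rate,
            config.autocorr_decay_length,
            rng_act,
        )

    # planted modules override the background with a shared latent vector
    latent = (
        rng_mod.random((max(config.n_modules, 1), config.n_cell_types))
        < config.module_activity_rate
    ).astype(np.int8)
    for m in range(config.n_modules):
        members = np.where(module_of == m)[0]
        flips = rng_noise.random((len(members), config.n_cell_types)) < config.flip_noise
        activity[members] = np.where(flips, 1 - latent[m], latent[m])

    activity_df = pd.DataFrame(activity, index=pd.Index(enh_ids, name="enhancer_id"),
                               columns=cell_types)

    # motifs: background rate everywhere, driver motifs boosted within modules
    motif_ids = [f"motif{k:04d}" for k in range(config.n_motifs)]
    motifs = (rng_motif.random((n, config.n_motifs)) < config.motif_base_rate).astype(
        np.int8
    )
    n_drivers = config.driver_motifs_per_module * config.n_modules
    driver_cols = rng_motif.choice(config.n_motifs, size=n_drivers, replace=False)
    driver_motifs = {}
    for m in range(config.n_modules):
        cols = driver_cols[
            m * config.driver_motifs_per_module : (m + 1) * config.driver_motifs_per_module
        ]
        driver_motifs[m] = [motif_ids[c] for c in cols]
        members = np.where(module_of == m)[0]
        motifs[np.ix_(members, cols)] = (
            rng_motif.random((len(members), len(cols))) < config.driver_motif_rate
        ).astype(np.int8)
    motif_df = pd.DataFrame(motifs, index=pd.Index(enh_ids, name="enhancer_id"),
                            columns=motif_ids)

    # motif similarity: planted blocks of 7 with high within-block similarity
    group = np.arange(config.n_motifs) // 7
    sim = 0.1 + 0.05 * rng_sim.random((config.n_motifs, config.n_motifs))
    sim = (sim + sim.T) / 2
    same = group[:, None] == group[None, :]
    boost = 0.8 + 0.05 * rng_sim.random((config.n_motifs, config.n_motifs))
    boost = (boost + boost.T) / 2
    sim[same] = boost[same]
    np.fill_diagonal(sim, 1.0)
    similarity_df = pd.DataFrame(sim, index=motif_ids, columns=motif_ids)

    # one gene adjacent to each enhancer; jittered offset keeps nearest-gene
    # assignment unambiguous because inter-enhancer spacing >> offset
    max_off = min(config.gene_offset_max, config.min_spacing // 2 - 10)
    offsets = rng_gene.integers(30, max(31, max_off), size=n)
    signs = rng_gene.choice([-1, 1], size=n)
    tss = centers + offsets * signs
    gene_ids = [f"gene{i:06d}" for i in range(n)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": enhancers["chrom"].to_numpy(),
            "tss": tss,
            "strand": rng_gene.choice(["+", "-"], size=n),
        }
    )
    target_of = pd.Series(gene_ids, index=pd.Index(enh_ids, name="enhancer_id"),
                          name="gene_id")

    # expression over a subset of cell types; module genes follow the latent
    expr_cols = sorted(
        rng_expr.choice(config.n_cell_types, size=config.n_expression_cell_types,
                        replace=False)
    )
    expr_cts = [cell_types[i] for i in expr_cols]
    base = activity[:, expr_cols].astype(np.float64)
    for m in range(config.n_modules):
        members = np.where(module_of == m)[0]
        base[members] = latent[m, expr_cols][None, :].astype(np.float64)
    expression = (
        1.0 + 2.0 * base
        + rng_expr.normal(0.0, config.expression_noise_sd, size=base.shape)
    )
    expression_df = pd.DataFrame(expression, index=pd.Index(gene_ids, name="gene_id"),
                                 columns=expr_cts)

    # strength labels: non-module enhancers at the baseline strong rate,
    # module members coherently biased by module size (planted assortativity)
    labels = np.where(
        rng_label.random(n) < config.strong_fraction, "strong", "weak"
    ).astype(object)
    module_rate = (
        config.module_strong_rate_small
        if config.module_size <= config.small_module_cutoff
        else config.module_strong_rate_large
    )
    module_label = np.where(
        rng_label.random(max(config.n_modules, 1)) < module_rate, "strong", "weak"
    )
    for m in range(config.n_modules):
        members = np.where(module_of == m)[0]
        keep = rng_label.random(len(members)) < config.label_fidelity
        other = "weak" if module_label[m] == "strong" else "strong"
        labels[members] = np.where(keep, module_label[m], other)
    ambiguous = rng_label.random(n) < config.ambiguous_fraction
    labels[ambiguous] = "ambiguous"
    labels_s = pd.Series(labels, index=pd.Index(enh_ids, name="enhancer_id"),
                         name="label")

    # contacts: within-module pairs at a high rate, sparse random background
    rows = []
    for m in range(config.n_modules):
        members = np.where(module_of == m)[0]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng_contact.random() < config.contact_within_module_rate:
                    rows.append((members[i], members[j],
                                 0.3 + 0.7 * rng_contact.random()))
    n_pairs_total = n * (n - 1) // 2
    n_bg = int(rng_contact.binomial(n_pairs_total, config.contact_background_rate))
    for _ in range(n_bg):
        i, j = rng_contact.choice(n, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        rows.append((i, j, rng_contact.random()))
    e = enhancers
    contacts = pd.DataFrame(
        {
            "chrom_a": [e["chrom"].iat[i] for i, _, _ in rows],
            "start_a": [e["start"].iat[i] for i, _, _ in rows],
            "end_a": [e["end"].iat[i] for i, _, _ in rows],
            "chrom_b": [e["chrom"].iat[j] for _, j, _ in rows],
            "start_b": [e["start"].iat[j] for _, j, _ in rows],
            "end_b": [e["end"].iat[j] for _, j, _ in rows],
            "confidence": [c for _, _, c in rows],
        }
    )

    # annotation terms: one per module (its target genes) plus random terms
    term_rows = []
    for m in range(config.n_modules):
        members = np.where(module_of == m)[0]
        for i in members:
            term_rows.append((f"term{m:04d}", gene_ids[i]))
    for t in range(config.n_modules, config.n_terms):
        size = min(config.term_background_size, n)
        for i in rng_term.choice(n, size=size, replace=False):
            term_rows.append((f"term{t:04d}", gene_ids[int(i)]))
    annotations = pd.DataFrame(term_rows, columns=["term_id", "gene_id"])

    # tissue classes (for concordance): contiguous groups of ~5 cell types;
    # a module's matched class is the one where its latent vector is most on
    class_of = pd.Series(
        [f"class{t // 5:02d}" for t in range(config.n_cell_types)],
        index=cell_types, name="class",
    )
    class_ids = sorted(class_of.unique())
    matched = []
    for m in range(config.n_modules):
        best, best_frac = class_ids[0], -1.0
        for cid in class_ids:
            cols = [i for i, ct in enumerate(cell_types) if class_of[ct] == cid]
            frac = float(latent[m, cols].mean())
            if frac > best_frac:
                best, best_frac = cid, frac
        matched.append(best)
    matched_class = pd.Series(matched, index=pd.RangeIndex(config.n_modules),
                              name="class")

    # background segments: same Markov process, disjoint from enhancers
    n_bg_segments = min(2 * n, 5_000)
    bg, bg_act = simulate_background_track(
        config, n_bg_segments, rng=rng_bg, exclude=enhancers
    )

    return SyntheticDataset(
        config=config,
        enhancers=enhancers,
        activity=activity_df,
        module_of=pd.Series(module_of, index=pd.Index(enh_ids, name="enhancer_id"),
                            name="module_id"),
        module_latent=pd.DataFrame(latent[: config.n_modules], columns=cell_types),
        motif_matrix=motif_df,
        motif_similarity=similarity_df,
        driver_motifs=driver_motifs,
        genes=genes,
        target_of=target_of,
        expression=expression_df,
        expression_cell_types=expr_cts,
        strength_labels=labels_s,
        contacts=contacts,
        annotations=annotations,
        class_of_cell_type=class_of,
        matched_class_of_module=matched_class,
        background_segments=bg,
        background_activity=bg_act,
    )


def simulate_background_track(
    config: SimulationConfig,
    n_segments: int,
    rng: np.random.Generator | None = None,
    exclude: pd.DataFrame | None = None,
):
    """Random genomic segments with Markov-process accessibility states.

    Segments of length ``config.enhancer_length`` are placed uniformly on the
    simulated genome; states are drawn from the same per-chromosome,
    per-cell-type two-state Markov process used for non-module enhancers.
    When ``exclude`` is given, segments overlapping those intervals are
    rejected and replaced.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    capacity = config.n_chromosomes * (config.chrom_length // config.enhancer_length)
    if n_segments > capacity:
        raise ValueError(
            f"n_segments = {n_segments} exceeds placeable capacity {capacity}"
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(13)[-1])
    half = config.enhancer_length // 2
    chrom_idx = rng.integers(0, config.n_chromosomes, size=n_segments)
    cents = rng.integers(half + 1, config.chrom_length - half - 1, size=n_segments)
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx], dtype=object)
    segs = pd.DataFrame({"chrom": chroms, "start": cents - half, "end": cents + half})
    if exclude is not None:
        for _ in range(50):
            bad = overlaps_any(segs, exclude)
            if not bad.any():
                break
            k = int(bad.sum())
            ci = rng.integers(0, config.n_chromosomes, size=k)
            cc = rng.integers(half + 1, config.chrom_length - half - 1, size=k)
            segs.loc[bad, "chrom"] = [f"chr{c + 1}" for c in ci]
            segs.loc[bad, "start"] = cc - half
            segs.loc[bad, "end"] = cc + half
        else:
            raise ValueError("could not place background segments clear of exclusions")
    segs = segs.sort_values(["chrom", "start"], ignore_index=True)
    segs["id"] = [f"seg{i:06d}" for i in range(n_segments)]

    cell_types = [f"ct{t:02d}" for t in range(config.n_cell_types)]
    states = np.zeros((n_segments, config.n_cell_types), dtype=np.int8)
    chrom_arr = segs["chrom"].to_numpy()
    seg_centers = (segs["start"].to_numpy() + segs["end"].to_numpy()) // 2
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        states[mask] = markov_track(
            seg_centers[mask],
            config.n_cell_types,
            config.marginal_dhs_rate,
            config.autocorr_decay_length,
            rng,
        )
    states_df = pd.DataFrame(states, index=pd.Index(segs["id"], name="segment_id"),
                             columns=cell_types)
    return segs, states_df


def write_fixtures(dataset: SyntheticDataset, directory) -> dict:
    """Write all dataset components as plain-text fixtures.

    Emits BED files for intervals and TSV files (header row, row-label first
    column) for matrices, a per-cell-type DHS peak BED directory that
    round-trips through :func:`conet.activity.build_activity_matrix`, and a
    ground-truth module membership table.  Returns a manifest mapping each
    relative path to its row count.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    def _tsv(df: pd.DataFrame, name: str, index: bool = True):
        df.to_csv(directory / name, sep="\t", index=index)
        manifest[name] = len(df)

    write_bed(dataset.enhancers, directory / "enhancers.bed")
    manifest["enhancers.bed"] = len(dataset.enhancers)

    gene_bed = make_intervals(
        dataset.genes["chrom"], dataset.genes["tss"], dataset.genes["tss"] + 1,
        dataset.genes["gene_id"],
    )
    write_bed(gene_bed, directory / "genes.bed")
    manifest["genes.bed"] = len(gene_bed)
    _tsv(dataset.genes, "genes.tsv", index=False)

    write_bed(dataset.background_segments, directory / "background.bed")
    manifest["background.bed"] = len(dataset.background_segments)
    _tsv(dataset.background_activity, "background_activity.tsv")

    _tsv(dataset.activity, "activity.tsv")
    _tsv(dataset.motif_matrix, "motifs.tsv")
    _tsv(dataset.motif_similarity, "motif_similarity.tsv")
    _tsv(dataset.expression, "expression.tsv")
    _tsv(dataset.strength_labels.rename("label").to_frame(), "labels.tsv")
    _tsv(dataset.contacts, "contacts.tsv", index=False)
    _tsv(dataset.annotations, "annotations.tsv", index=False)
    _tsv(dataset.module_of.rename("module_id").to_frame(), "modules.tsv")
    _tsv(dataset.class_of_cell_type.rename("class").to_frame(), "cell_classes.tsv")
    _tsv(
        dataset.matched_class_of_module.rename("class").rename_axis("module_id").to_frame(),
        "module_classes.tsv",
    )

    dhs_dir = directory / "dhs"
    dhs_dir.mkdir(exist_ok=True)
    for ct in dataset.cell_types:
        active = dataset.activity[ct].to_numpy().astype(bool)
        peaks = dataset.enhancers.loc[active, ["chrom", "start", "end"]]
        path = dhs_dir / f"{ct}.bed"
        peaks.to_csv(path, sep="\t", header=False, index=False)
        manifest[f"dhs/{ct}.bed"] = len(peaks)

    return manifest
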