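"""Pipeline orchestration: config validation, staged execution, manifests.

Stages run in dependency order (simulate -> matrix -> pairs ->
motifs/network -> targets/spatial), each writing TSV outputs plus a JSON
run-metadata sidecar into the output directory.  Re-running with an
identical config and seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from conet import activity as act
from conet import coactivity as coact
from conet import motifs as mot
from conet import network as net
from conet import spatial as spat
from conet import targets as tgt
from conet.config import SimulationConfig
from conet.intervals import read_bed
from conet.synthetic import simulate_dataset, write_fixtures

__all__ = ["PipelineConfig", "validate_config", "load_config", "run_pipeline",
            "STAGES"]

STAGES = ("simulate", "matrix", "pairs", "motifs", "network", "targets", "spatial")


class ConfigValidationError(ValueError):
    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(self.problems))


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "conet_out"
    simulation: dict = field(default_factory=dict)
    bin_edges: tuple = coact.DEFAULT_BIN_EDGES
    alpha_strict: float = 0.01
    alpha_relaxed: float = 0.05
    mi_ceiling: float = 0.01
    max_exhaustive: float = 12_500_000
    far_sample: int = 2000
    trans_sample: int = 1000
    min_autocorr_count: int = 25
    motif_fdr_bh: float = 0.05
    motif_fdr_empirical: float = 0.05
    motif_max_cophenetic: float = 2.0
    cluster_params: tuple = ((0.3, 3, 0.5),)  # (min_mi, min_size, min_shared_fraction)
    contact_top_fraction: float = 0.1
    spatial_tolerance: float = 0.02
    max_term_size: int = 200
    tissue_inconsistency_cutoff: float | None = None


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ConfigValidationError([f"unknown fields: {sorted(unknown)}"])
    cfg = PipelineConfig(**raw)
    if isinstance(cfg.cluster_params, list):
        cfg.cluster_params = tuple(tuple(p) for p in cfg.cluster_params)
    return validate_config(cfg)


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Check cross-field constraints; aggregate all violations."""
    problems = []
    for name in ("alpha_strict", "alpha_relaxed", "motif_fdr_bh",
                 "motif_fdr_empirical"):
        v = getattr(config, name)
        if not 0 < v < 1:
            problems.append(f"{name}: must be in (0, 1), got {v}")
    if config.alpha_strict > config.alpha_relaxed:
        problems.append(
            f"alpha_strict ({config.alpha_strict}) must be <= "
            f"alpha_relaxed ({config.alpha_relaxed})"
        )
    edges = list(config.bin_edges)
    if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
        problems.append("bin_edges: must be strictly increasing and non-empty")
    if not 0 < config.contact_top_fraction <= 1:
        problems.append("contact_top_fraction: must be in (0, 1]")
    if config.simulation:
        try:
            SimulationConfig(**config.simulation)
        except Exception as exc:
            problems.append(f"simulation: {exc}")
    if problems:
        raise ConfigValidationError(problems)
    return config


def _write(df: pd.DataFrame, path: Path, manifest: dict, index=False) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest[path.name] = len(df)


def _sidecar(out: Path, stage: str, config: PipelineConfig, elapsed: float,
             extra=None) -> None:
    meta = {
        "stage": stage,
        "seed": config.seed,
        "elapsed_s": round(elapsed, 3),
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "simulation"
        },
    }
    if extra:
        meta.update(extra)
    (out / f"{stage}.meta.json").write_text(json.dumps(meta, indent=2, default=str))


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order; return a manifest."""
    validate_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = out / "fixtures"
    manifest: dict[str, int] = {}
    requested = [s for s in STAGES if s in stages]

    sim_config = SimulationConfig(**{**config.simulation, "seed": config.seed})
    dataset = None

    def need_dataset():
        nonlocal dataset
        if dataset is None:
            dataset = simulate_dataset(sim_config)
        return dataset

    for stage in requested:
        t0 = time.monotonic()
        if stage == "simulate":
            ds = need_dataset()
            manifest.update(
                {f"fixtures/{k}": v for k, v in write_fixtures(ds, fixtures).items()}
            )
        elif stage == "matrix":
            enh = read_bed(fixtures / "enhancers.bed")
            peaks = act.read_peak_directory(fixtures / "dhs")
            matrix = act.build_activity_matrix(enh, peaks)
            if config.tissue_inconsistency_cutoff is not None:
                _, matrix = act.select_representative_tissues(
                    matrix, config.tissue_inconsistency_cutoff
                )
            act.write_activity_matrix(matrix, out / "activity_matrix.tsv")
            manifest["activity_matrix.tsv"] = len(matrix)
        elif stage == "pairs":
            ds = need_dataset()
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1]).generate_state(4)
            )
            model = coact.estimate_autocorrelation(
                ds.background_segments, ds.background_activity,
                config.bin_edges, config.min_autocorr_count,
            )
            table = coact.enumerate_pairs(
                ds.enhancers, ds.activity, model, rng,
                max_exhaustive=config.max_exhaustive,
                far_sample=config.far_sample, trans_sample=config.trans_sample,
            )
            pol_s, called_s = coact.call_significant(table, config.alpha_strict)
            pol_r, called_r = coact.call_significant(table, config.alpha_relaxed)
            pruned = coact.prune_transitive(called_r)
            _write(table, out / "pair_table.tsv", manifest)
            _write(called_s, out / "called_strict.tsv", manifest)
            _write(called_r, out / "called_relaxed.tsv", manifest)
            _write(pruned, out / "pruned_relaxed.tsv", manifest)
            thr = pd.DataFrame(
                [
                    {"bin": b, "threshold": t, "alpha": config.alpha_strict}
                    for b, t in sorted(pol_s.per_bin_threshold.items())
                ]
                + [
                    {"bin": b, "threshold": t, "alpha": config.alpha_relaxed}
                    for b, t in sorted(pol_r.per_bin_threshold.items())
                ]
            )
            _write(thr, out / "thresholds.tsv", manifest)
        elif stage == "motifs":
            ds = need_dataset()
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 2]).generate_state(4)
            )
            table = pd.read_csv(out / "pair_table.tsv", sep="\t")
            fg = coact.prune_transitive(pd.read_csv(out / "called_relaxed.tsv",
                                                    sep="\t"))
            # drop foreground bins without enough low-MI candidates to match
            pool_size = table[table["mi"] < config.mi_ceiling]["bin"].value_counts()
            ok_bins = [
                b for b, n_fg in fg["bin"].value_counts().items()
                if pool_size.get(b, 0) >= n_fg
            ]
            fg = fg[fg["bin"].isin(ok_bins)]
            bg = coact.matched_uncorrelated_background(
                table, fg, rng, config.mi_ceiling
            )
            fg_res = mot.cooccurrence_table(fg, ds.motif_matrix)
            bg_res = mot.cooccurrence_table(bg, ds.motif_matrix)
            selected = mot.select_foreground_specific_motifs(
                fg_res, bg_res, config.motif_fdr_bh, config.motif_fdr_empirical
            )
            clustering = mot.cluster_motifs(ds.motif_similarity,
                                            config.motif_max_cophenetic)
            _write(fg_res.reset_index(), out / "motif_fg.tsv", manifest)
            _write(bg_res.reset_index(), out / "motif_bg.tsv", manifest)
            _write(pd.DataFrame({"motif": selected}), out / "motif_selected.tsv",
                   manifest)
            _write(clustering.reset_index().rename(columns={"index": "motif"}),
                   out / "motif_clusters.tsv", manifest)
            _write(bg, out / "background_pairs.tsv", manifest)
        elif stage == "network":
            ds = need_dataset()
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 3]).generate_state(4)
            )
            called_s = pd.read_csv(out / "called_strict.tsv", sep="\t")
            called_r = pd.read_csv(out / "called_relaxed.tsv", sep="\t")
            network = net.build_network(called_s, called_r,
                                        nodes=list(ds.activity.index))
            table, p0 = net.strength_by_degree(network, ds.strength_labels)
            or_ss, p_ss = net.assortativity_test(network, ds.strength_labels,
                                                 rng, "strong")
            or_ww, p_ww = net.assortativity_test(network, ds.strength_labels,
                                                 rng, "weak")
            _write(table.reset_index(), out / "degree_strength.tsv", manifest)
            summary = pd.DataFrame(
                [
                    {"statistic": "degree0_vs_rest_fisher_p", "value": p0},
                    {"statistic": "assortativity_or_strong", "value": or_ss},
                    {"statistic": "assortativity_p_strong", "value": p_ss},
                    {"statistic": "assortativity_or_weak", "value": or_ww},
                    {"statistic": "assortativity_p_weak", "value": p_ww},
                ]
            )
            _write(summary, out / "network_summary.tsv", manifest)
            rows = []
            for pi, (min_mi, min_size, min_frac) in enumerate(config.cluster_params):
                clusters = net.extract_clusters(
                    called_s, ds.enhancers, ds.motif_matrix,
                    min_mi=min_mi, min_size=min_size,
                    min_shared_fraction=min_frac,
                )
                for ci, c in enumerate(clusters):
                    for m in c.members:
                        rows.append({"param_set": pi, "cluster_id": ci,
                                     "enhancer_id": m})
            _write(pd.DataFrame(rows), out / "clusters.tsv", manifest)
        elif stage == "targets":
            ds = need_dataset()
            target_map = tgt.nearest_gene(ds.enhancers, ds.genes)
            fg = pd.read_csv(out / "pruned_relaxed.tsv", sep="\t")
            bg = pd.read_csv(out / "background_pairs.tsv", sep="\t")
            expr = tgt.expression_correlation_contrast(
                fg, bg, target_map, ds.expression
            )
            share = tgt.term_sharing_contrast(
                fg, bg, target_map, ds.annotations, config.max_term_size
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 4]).generate_state(4)
            )
            table = pd.read_csv(out / "pair_table.tsv", sep="\t")
            sample = table.iloc[
                rng.choice(len(table), size=min(10_000, len(table)), replace=False)
            ]
            jac = mot.pair_jaccard_many(sample, ds.motif_matrix)
            reg = tgt.jaccard_expression_regression(
                sample, jac, target_map, ds.expression
            )
            summary = pd.DataFrame(
                [
                    {"statistic": "expr_fg_median", "value": expr["fg_median"]},
                    {"statistic": "expr_bg_median", "value": expr["bg_median"]},
                    {"statistic": "expr_p", "value": expr["p_value"]},
                    {"statistic": "share_fg_fraction", "value": share["fg_fraction"]},
                    {"statistic": "share_bg_fraction", "value": share["bg_fraction"]},
                    {"statistic": "share_p", "value": share["p_value"]},
                    {"statistic": "jaccard_slope", "value": reg["slope"]},
                    {"statistic": "jaccard_slope_p", "value": reg["p_value"]},
                ]
            )
            _write(summary, out / "target_summary.tsv", manifest)
            _write(target_map.reset_index(), out / "nearest_gene.tsv", manifest)
        elif stage == "spatial":
            ds = need_dataset()
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 5]).generate_state(4)
            )
            table = pd.read_csv(out / "pair_table.tsv", sep="\t")
            fg = pd.read_csv(out / "pruned_relaxed.tsv", sep="\t")
            cand = table[table["mi"] < config.mi_ceiling]
            # drop foreground bins whose candidate pool is too thin to match
            pool_size = cand["bin"].value_counts()
            ok_bins = []
            for b, n_fg in fg["bin"].value_counts().items():
                if pool_size.get(b, 0) < 3 * n_fg:
                    continue
                try:
                    spat.dhs_matched_background(
                        fg[fg["bin"] == b], cand, ds.activity,
                        np.random.default_rng(config.seed),
                        tolerance=config.spatial_tolerance,
                    )
                except ValueError:
                    continue  # unmatchable bin: excluded from the contrast
                ok_bins.append(b)
            fg = fg[fg["bin"].isin(ok_bins)]
            bg = spat.dhs_matched_background(
                fg, cand, ds.activity, rng, tolerance=config.spatial_tolerance
            )
            res_all = spat.contact_enrichment(fg, bg, ds.contacts, ds.enhancers)
            res_top = spat.contact_enrichment(
                fg, bg, ds.contacts, ds.enhancers,
                top_fraction=config.contact_top_fraction,
            )
            summary = pd.DataFrame(
                [
                    {"statistic": "contact_or_all", "value": res_all["odds_ratio"]},
                    {"statistic": "contact_p_all", "value": res_all["p_value"]},
                    {"statistic": "contact_or_top", "value": res_top["odds_ratio"]},
                    {"statistic": "contact_p_top", "value": res_top["p_value"]},
                ]
            )
            _write(summary, out / "spatial_summary.tsv", manifest)
        _sidecar(out, stage, config, time.monotonic() - t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
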