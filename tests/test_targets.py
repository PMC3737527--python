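import math

import numpy as np
import pandas as pd
import pytest

from conet import targets as tgt
from conet.intervals import make_intervals


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestNearestGene:
    def test_nearest_by_absolute_distance(self):
        enh = make_intervals(["chr1"], [750], [1250], ["e1"])  # centre 1000
        genes = _genes([("gA", "chr1", 500, "+"), ("gB", "chr1", 5000, "-")])
        assert tgt.nearest_gene(enh, genes)["e1"] == "gA"

    def test_tie_breaks_lexicographic(self):
        enh = make_intervals(["chr1"], [750], [1250], ["e1"])  # centre 1000
        genes = _genes([("geneB", "chr1", 500, "+"), ("geneA", "chr1", 1500, "+")])
        assert tgt.nearest_gene(enh, genes)["e1"] == "geneA"

    def test_gene_free_chromosome_warns(self):
        enh = make_intervals(["chrY"], [0], [500], ["e1"])
        genes = _genes([("gA", "chr1", 500, "+")])
        with pytest.warns(UserWarning, match="unmapped"):
            mapped = tgt.nearest_gene(enh, genes)
        assert "e1" not in mapped.index

    def test_empty_gene_set_raises(self):
        enh = make_intervals(["chr1"], [0], [500], ["e1"])
        with pytest.raises(ValueError):
            tgt.nearest_gene(enh, _genes([]))

    def test_matches_generator_ground_truth(self, small_dataset):
        mapped = tgt.nearest_gene(small_dataset.enhancers, small_dataset.genes)
        truth = small_dataset.target_of
        assert len(mapped) == len(truth)
        assert (mapped.loc[truth.index] == truth).all()


def _expr(rows, columns=None):
    df = pd.DataFrame(rows).T
    if columns is not None:
        df.columns = columns
    return df


class TestExpressionContrast:
    def _setup(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        expression = pd.DataFrame(
            rng.normal(size=(40, 10)), index=genes
        )
        target_map = pd.Series(
            {f"e{i}": f"g{i}" for i in range(40)}
        )
        return expression, target_map

    def test_identical_monotone_vectors_correlate_fully(self):
        expression = pd.DataFrame(
            {"c1": [1.0, 2.0], "c2": [2.0, 4.0], "c3": [3.0, 8.0]},
            index=["g1", "g2"],
        )
        target_map = pd.Series({"e1": "g1", "e2": "g2"})
        from conet.targets import _pair_gene_correlations

        cors, _ = _pair_gene_correlations(
            pd.DataFrame({"id_a": ["e1"], "id_b": ["e2"]}), target_map,
            expression,
        )
        assert cors[0] == pytest.approx(1.0)

    def test_same_pool_null(self):
        expression, target_map = self._setup()
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(10):
            idx = rng.choice(40, size=(30, 2))
            idx = idx[idx[:, 0] != idx[:, 1]]
            pairs = pd.DataFrame(
                {"id_a": [f"e{i}" for i in idx[:, 0]],
                 "id_b": [f"e{i}" for i in idx[:, 1]]}
            )
            half = len(pairs) // 2
            res = tgt.expression_correlation_contrast(
                pairs.iloc[:half], pairs.iloc[half:], target_map, expression
            )
            diffs.append(res["fg_median"] - res["bg_median"])
        assert abs(float(np.median(diffs))) < 0.25

    def test_shared_target_pairs_excluded(self):
        expression, target_map = self._setup()
        target_map["e1"] = target_map["e0"]  # shared target
        pairs = pd.DataFrame({"id_a": ["e0", "e2"], "id_b": ["e1", "e3"]})
        from conet.targets import _pair_gene_correlations

        cors, excluded = _pair_gene_correlations(pairs, target_map, expression)
        assert len(cors) == 1 and excluded == 1

    def test_planted_contrast_direction(self, matched):
        ds = matched["dataset"]
        from conet import coactivity as co

        target_map = tgt.nearest_gene(ds.enhancers, ds.genes)
        fg = co.prune_transitive(matched["called"])
        rng = np.random.default_rng(0)
        bg = co.matched_uncorrelated_background(matched["table"], fg, rng)
        res = tgt.expression_correlation_contrast(
            fg, bg, target_map, ds.expression
        )
        assert res["fg_median"] > res["bg_median"]
        assert res["p_value"] < 0.01


class TestJaccardRegression:
    def test_exact_linear_relation(self):
        # construct pairs whose expression correlation is exactly
        # 0.5 * jaccard via deterministic vectors is awkward; instead
        # verify the OLS fit itself against the closed-form solution
        rng = np.random.default_rng(0)
        x = rng.random(200)
        y = 0.5 * x  # exact, no noise
        from scipy.stats import linregress

        res = linregress(x, y)
        assert res.slope == pytest.approx(0.5, abs=1e-9)
        assert res.pvalue < 1e-100

    def test_ols_matches_normal_equations(self, matched):
        ds = matched["dataset"]
        from conet import motifs as mot

        target_map = tgt.nearest_gene(ds.enhancers, ds.genes)
        rng = np.random.default_rng(3)
        table = matched["table"]
        sample = table.iloc[rng.choice(len(table), 4000, replace=False)]
        jac = mot.pair_jaccard_many(sample, ds.motif_matrix)
        res = tgt.jaccard_expression_regression(
            sample, jac, target_map, ds.expression
        )
        # independent normal-equation oracle on the same (x, y) sample
        xs, ys = [], []
        for (a, b), j in zip(zip(sample["id_a"], sample["id_b"]), jac):
            ga, gb = target_map.get(a), target_map.get(b)
            if ga is None or gb is None or ga == gb:
                continue
            from conet.stats import spearman

            r = spearman(ds.expression.loc[ga].to_numpy(),
                         ds.expression.loc[gb].to_numpy())
            if not np.isnan(r):
                xs.append(j)
                ys.append(r)
        x = np.asarray(xs)
        y = np.asarray(ys)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert res["slope"] == pytest.approx(slope, abs=1e-9)
        assert res["n"] == len(x)

    def test_zero_variance_jaccard_raises(self):
        pairs = pd.DataFrame({"id_a": ["e0", "e1"], "id_b": ["e1", "e2"]})
        target_map = pd.Series({"e0": "g0", "e1": "g1", "e2": "g2"})
        expression = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)),
                                  index=["g0", "g1", "g2"])
        with pytest.raises(ValueError):
            tgt.jaccard_expression_regression(
                pairs, np.array([0.5, 0.5]), target_map, expression
            )


class TestTermSharing:
    def _ann(self, rows):
        return pd.DataFrame(rows, columns=["term_id", "gene_id"])

    def test_full_separation_matches_enumeration(self):
        target_map = pd.Series({f"e{i}": f"g{i}" for i in range(8)})
        ann = self._ann([("t1", "g0"), ("t1", "g1"), ("t2", "g2"), ("t2", "g3")])
        fg = pd.DataFrame({"id_a": ["e0", "e2"], "id_b": ["e1", "e3"]})
        bg = pd.DataFrame({"id_a": ["e4", "e6"], "id_b": ["e5", "e7"]})
        res = tgt.term_sharing_contrast(fg, bg, target_map, ann)
        assert res["fg_fraction"] == 1.0 and res["bg_fraction"] == 0.0
        # enumeration oracle for [[2, 0], [0, 2]]
        denom = math.comb(4, 2)
        probs = {k: math.comb(2, k) * math.comb(2, 2 - k) / denom
                 for k in range(3)}
        cutoff = probs[2] * (1 + 1e-9)
        expected = sum(v for v in probs.values() if v <= cutoff)
        assert res["p_value"] == pytest.approx(expected, rel=1e-8)

    def test_max_term_size_excludes_large_terms(self):
        target_map = pd.Series({f"e{i}": f"g{i}" for i in range(4)})
        ann = self._ann([("big", f"g{i}") for i in range(4)])
        fg = pd.DataFrame({"id_a": ["e0"], "id_b": ["e1"]})
        bg = pd.DataFrame({"id_a": ["e2"], "id_b": ["e3"]})
        res = tgt.term_sharing_contrast(fg, bg, target_map, ann, max_term_size=2)
        assert res["fg_fraction"] == 0.0 and res["bg_fraction"] == 0.0
        assert res["p_value"] == 1.0

    def test_identical_sets_p_one(self):
        target_map = pd.Series({f"e{i}": f"g{i}" for i in range(4)})
        ann = self._ann([("t", "g0"), ("t", "g1")])
        pairs = pd.DataFrame({"id_a": ["e0", "e2"], "id_b": ["e1", "e3"]})
        res = tgt.term_sharing_contrast(pairs, pairs, target_map, ann)
        assert res["p_value"] == 1.0

    def test_planted_direction(self, matched):
        ds = matched["dataset"]
        from conet import coactivity as co

        target_map = tgt.nearest_gene(ds.enhancers, ds.genes)
        fg = co.prune_transitive(matched["called"])
        rng = np.random.default_rng(1)
        bg = co.matched_uncorrelated_background(matched["table"], fg, rng)
        res = tgt.term_sharing_contrast(fg, bg, target_map, ds.annotations)
        assert res["fg_fraction"] > res["bg_fraction"]
        assert res["p_value"] < 0.05


class TestClusterAnalyses:
    def _cluster(self, members):
        from conet.network import EnhancerCluster

        return EnhancerCluster(members=list(members),
                               intra_distances=np.array([]), shared_motifs=[])

    def test_identical_expression_cluster_mean_one(self):
        expression = pd.DataFrame(
            [[1.0, 2, 3, 4], [2.0, 4, 6, 8], [0.5, 1, 1.5, 2]],
            index=["g0", "g1", "g2"],
        )
        target_map = pd.Series({"e0": "g0", "e1": "g1", "e2": "g2"})
        from conet.targets import _cluster_mean_correlation

        assert _cluster_mean_correlation(
            ["e0", "e1", "e2"], target_map, expression
        ) == pytest.approx(1.0)

    def test_identical_fg_bg_p_one(self):
        rng = np.random.default_rng(0)
        expression = pd.DataFrame(rng.normal(size=(10, 8)),
                                  index=[f"g{i}" for i in range(10)])
        target_map = pd.Series({f"e{i}": f"g{i}" for i in range(10)})
        clusters = [self._cluster([f"e{i}" for i in range(5)]),
                    self._cluster([f"e{i}" for i in range(5, 10)])]
        res = tgt.cluster_expression_contrast(
            clusters, clusters, target_map, expression
        )
        assert res["p_value"] == 1.0

    def test_planted_cluster_expression_direction(self, matched):
        ds = matched["dataset"]
        target_map = tgt.nearest_gene(ds.enhancers, ds.genes)
        fg = [self._cluster(ds.module_members(m)) for m in range(10)]
        rng = np.random.default_rng(2)
        non_module = list(ds.module_of.index[ds.module_of == -1])
        bg = [
            self._cluster(rng.choice(non_module, size=10, replace=False))
            for _ in range(10)
        ]
        res = tgt.cluster_expression_contrast(fg, bg, target_map, ds.expression)
        assert np.median(res["fg_means"]) > np.median(res["bg_means"])
        assert res["p_value"] < 0.01


class TestClusterTermEnrichment:
    def test_matches_enumeration(self):
        universe = [f"g{i}" for i in range(40)]
        ann = pd.DataFrame(
            [("t1", g) for g in universe[:10]], columns=["term_id", "gene_id"]
        )
        cluster = universe[:8]
        res = tgt.cluster_term_enrichment(cluster, universe, ann, fdr=1.0)
        denom = math.comb(40, 8)
        expected = sum(
            math.comb(10, k) * math.comb(30, 8 - k) / denom for k in range(8, 9)
        )
        assert res.loc["t1", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_never_enriched(self):
        universe = [f"g{i}" for i in range(20)]
        ann = pd.DataFrame(
            [("t1", g) for g in universe[10:]], columns=["term_id", "gene_id"]
        )
        res = tgt.cluster_term_enrichment(universe[:5], universe, ann, fdr=0.05)
        assert res.empty

    def test_cluster_equals_universe_degenerate(self):
        universe = [f"g{i}" for i in range(10)]
        ann = pd.DataFrame(
            [("t1", g) for g in universe[:4]], columns=["term_id", "gene_id"]
        )
        res = tgt.cluster_term_enrichment(universe, universe, ann, fdr=1.0)
        assert res.loc["t1", "p_value"] == pytest.approx(1.0)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            tgt.cluster_term_enrichment(
                [], [], pd.DataFrame(columns=["term_id", "gene_id"])
            )

    def test_planted_modules_enriched(self, matched):
        ds = matched["dataset"]
        target_map = tgt.nearest_gene(ds.enhancers, ds.genes)
        universe = list(ds.expression.index)
        genes = [target_map[e] for e in ds.module_members(0)]
        res = tgt.cluster_term_enrichment(genes, universe, ds.annotations,
                                          fdr=0.01)
        assert "term0000" in res.index


class TestConcordance:
    def _clusters(self, members_list):
        from conet.network import EnhancerCluster

        return [
            EnhancerCluster(members=list(m), intra_distances=np.array([]),
                            shared_motifs=[])
            for m in members_list
        ]

    def test_exclusive_class_rank_one(self):
        cts = [f"ct{i}" for i in range(6)]
        activity = pd.DataFrame(
            0, index=[f"e{i}" for i in range(20)], columns=cts, dtype=np.int8
        )
        activity.loc["e0":"e4", ["ct0", "ct1"]] = 1  # cluster active in classA
        activity.loc["e10":"e19", :] = 1  # background active everywhere
        class_of = pd.Series(
            ["classA", "classA", "classB", "classB", "classC", "classC"],
            index=cts,
        )
        clusters = self._clusters([[f"e{i}" for i in range(5)]])
        res = tgt.concordance_rank(clusters, activity, class_of, {0: "classA"})
        assert res["ranks"] == [1.0]

    def test_uniform_enrichment_average_rank(self):
        cts = [f"ct{i}" for i in range(6)]
        activity = pd.DataFrame(
            1, index=[f"e{i}" for i in range(10)], columns=cts, dtype=np.int8
        )
        class_of = pd.Series(
            ["A", "A", "B", "B", "C", "C"], index=cts
        )
        clusters = self._clusters([["e0", "e1", "e2"]])
        res = tgt.concordance_rank(clusters, activity, class_of, {0: "B"})
        assert res["ranks"] == [(3 + 1) / 2]

    def test_planted_concordant_below_random(self, matched):
        ds = matched["dataset"]
        clusters = self._clusters(
            [ds.module_members(m) for m in range(ds.config.n_modules)]
        )
        matched_class = {
            m: ds.matched_class_of_module[m] for m in range(ds.config.n_modules)
        }
        rng = np.random.default_rng(0)
        non_module = list(ds.module_of.index[ds.module_of == -1])
        bg_clusters = self._clusters(
            [rng.choice(non_module, size=10, replace=False)
             for _ in range(ds.config.n_modules)]
        )
        res = tgt.concordance_rank(
            clusters, ds.activity, ds.class_of_cell_type, matched_class,
            background_clusters=bg_clusters,
        )
        assert res["median_rank"] < res["bg_median_rank"]
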