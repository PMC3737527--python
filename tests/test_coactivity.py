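import numpy as np
import pandas as pd
import pytest

from conet import coactivity as co
from conet.intervals import make_intervals


def mi_oracle(x, y):
    """Independent brute-force joint-cell enumeration (bits)."""
    from math import log2

    n = len(x)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            pxy = sum(1 for u, v in zip(x, y) if u == a and v == b) / n
            px = sum(1 for u in x if u == a) / n
            py = sum(1 for v in y if v == b) / n
            if pxy > 0:
                mi += pxy * log2(pxy / (px * py))
    return mi


class TestMutualInformation:
    def test_identical_half_split_is_one_bit(self):
        assert co.mutual_information([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_empirically_independent_is_zero(self):
        assert co.mutual_information([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_known_asymmetric_case(self):
        x, y = [1, 1, 1, 0], [1, 1, 0, 0]
        expected = mi_oracle(x, y)  # = 0.31127812...
        assert expected == pytest.approx(0.311278, abs=1e-6)
        assert co.mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            co.mutual_information([1, 0], [1, 0, 1])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            co.mutual_information([1], [0])

    def test_oracle_equivalence_symmetry_and_bound(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            p = rng.uniform(0.1, 0.9)
            x = (rng.random(37) < p).astype(int)
            y = (rng.random(37) < rng.uniform(0.1, 0.9)).astype(int)
            got = co.mutual_information(x, y)
            assert got == pytest.approx(mi_oracle(list(x), list(y)), abs=1e-12)
            assert got == pytest.approx(co.mutual_information(y, x), abs=1e-15)
            bound = min(co.binary_entropy(x), co.binary_entropy(y))
            assert got <= bound + 1e-12


def _segments_line(n, gap=10_000, chrom="chr1"):
    starts = np.arange(n) * gap
    return make_intervals([chrom] * n, starts, starts + 500,
                          [f"s{i}" for i in range(n)])


def _states_df(arr):
    arr = np.asarray(arr, dtype=np.int8)
    return pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"ct{t:02d}" for t in range(arr.shape[1])],
    )


class TestEstimateAutocorrelation:
    def test_iid_states_conditionals_near_marginal(self):
        rng = np.random.default_rng(0)
        n, p = 3000, 0.4
        segs = _segments_line(n)
        states = _states_df(rng.random((n, 4)) < p)
        model = co.estimate_autocorrelation(segs, states, bin_edges=(50_000,))
        # pairs reuse segments, so the effective sample size is the number
        # of segments, not the (hugely dependent) ordered-pair count
        se = np.sqrt(p * (1 - p) / n)
        for b in range(model.n_bins):
            for s in (0, 1):
                assert np.all(np.abs(model.cond_prob[b, :, s] - p) < 3 * se)

    def test_all_identical_ones_fallback_for_zero_seed(self):
        segs = _segments_line(50)
        states = _states_df(np.ones((50, 2)))
        model = co.estimate_autocorrelation(segs, states, bin_edges=(50_000,))
        assert model.cond_prob[0, 0, 1] == 1.0
        assert model.fallback[0, 0, 0]
        assert model.cond_prob[0, 0, 0] == model.marginal[0] == 1.0

    def test_all_zero_cell_type(self):
        segs = _segments_line(50)
        states = _states_df(np.zeros((50, 2)))
        model = co.estimate_autocorrelation(segs, states, bin_edges=(50_000,))
        assert model.cond_prob[0, 0, 0] == 0.0
        assert model.fallback[0, 0, 1]

    def test_no_same_chromosome_pairs_raises(self):
        segs = make_intervals(["chr1", "chr2"], [0, 0], [500, 500], ["a", "b"])
        states = _states_df(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="no same-chromosome"):
            co.estimate_autocorrelation(segs, states, bin_edges=(50_000,))

    def test_bad_bin_edges(self):
        segs = _segments_line(10)
        states = _states_df(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="increasing"):
            co.estimate_autocorrelation(segs, states, bin_edges=(5, 5))


def _manual_model(cond11, cond10, T=8, n_bins=2, marginal=0.5):
    cond = np.zeros((n_bins, T, 2))
    cond[:, :, 1] = cond11
    cond[:, :, 0] = cond10
    return co.AutocorrelationModel(
        upper_edges=np.array([10_000.0] * (n_bins - 1)),
        cell_types=[f"ct{t}" for t in range(T)],
        cond_prob=cond,
        marginal=np.full(T, marginal),
        fallback=np.zeros((n_bins, T, 2), dtype=bool),
    )


class TestSynthesizePartner:
    def test_deterministic_copy_limit(self):
        model = _manual_model(1.0, 0.0)
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        out = co.synthesize_partner(x, 0, model, np.random.default_rng(0))
        assert (out == x).all()

    def test_marginal_model_independence(self):
        p = 0.4
        T = 37
        model = _manual_model(p, p, T=T, marginal=p)
        rng = np.random.default_rng(1)
        x = (np.arange(T) % 2).astype(np.int64)
        draws = np.array(
            [co.synthesize_partner(x, 0, model, rng) for _ in range(10_000)]
        )
        se = np.sqrt(p * (1 - p) / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - p) < 3 * se + 1e-9)
        # independence limit: mean plug-in MI is just the estimator bias,
        # approximately 1 / (2 T ln 2) ~ 0.0195 bits at T = 37
        mis = [co.mutual_information(x, d) for d in draws[:4000]]
        assert np.mean(mis) < 0.02

    def test_same_rng_state_identical(self):
        model = _manual_model(0.7, 0.2)
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        a = co.synthesize_partner(x, 1, model, np.random.default_rng(5))
        b = co.synthesize_partner(x, 1, model, np.random.default_rng(5))
        assert (a == b).all()

    def test_bin_out_of_range_raises(self):
        model = _manual_model(0.5, 0.5)
        with pytest.raises(ValueError, match="bin"):
            co.synthesize_partner(np.zeros(8, dtype=int), 7, model,
                                  np.random.default_rng(0))

    def test_length_mismatch_raises(self):
        model = _manual_model(0.5, 0.5)
        with pytest.raises(ValueError, match="length"):
            co.synthesize_partner(np.zeros(3, dtype=int), 0, model,
                                  np.random.default_rng(0))


class TestEnumeratePairs:
    def test_distance_filter(self):
        enh = make_intervals(
            ["chr1"] * 3, [0, 10_000, 30_000], [500, 10_500, 30_500],
            ["e1", "e2", "e3"],
        )
        states = _states_df(np.array([[1, 0, 1, 0]] * 3).T).T
        states.index = ["e1", "e2", "e3"]
        model = _manual_model(0.5, 0.5, T=4)
        table = co.enumerate_pairs(
            enh, states, model, np.random.default_rng(0), max_exhaustive=25_000
        )
        got = set(zip(table["id_a"], table["id_b"]))
        assert got == {("e1", "e2"), ("e2", "e3")}

    def test_synthetic_mi_finite_nonnegative(self, planted):
        t = planted["table"]
        assert np.isfinite(t["synthetic_mi"]).all()
        assert (t["synthetic_mi"] >= 0).all()
        assert np.isfinite(t["mi"]).all()

    def test_planted_pairs_beat_their_null(self, planted):
        ds = planted["dataset"]
        t = planted["table"]
        truth = set(ds.within_module_pairs())
        keys = list(zip(t["id_a"], t["id_b"]))
        mask = np.array([k in truth for k in keys])
        sub = t[mask]
        assert len(sub) == len(truth)  # all module pairs scored exhaustively
        frac = (sub["mi"] > sub["synthetic_mi"]).mean()
        assert frac >= 0.95

    def test_canonical_orientation(self, planted):
        t = planted["table"]
        assert (t["id_a"] < t["id_b"]).all()

    def test_empty_matrix_raises(self):
        enh = make_intervals(["chr1"], [0], [500], ["e1"])
        model = _manual_model(0.5, 0.5, T=2)
        with pytest.raises(ValueError):
            co.enumerate_pairs(enh, pd.DataFrame(), model,
                               np.random.default_rng(0))


def _toy_table(mi, syn, bins=None):
    n = len(mi)
    return pd.DataFrame(
        {
            "id_a": [f"a{i}" for i in range(n)],
            "id_b": [f"b{i}" for i in range(n)],
            "chrom_a": "chr1",
            "chrom_b": "chr1",
            "distance": 50_000,
            "bin": bins if bins is not None else np.zeros(n, dtype=int),
            "mi": np.asarray(mi, dtype=float),
            "synthetic_mi": np.asarray(syn, dtype=float),
        }
    )


class TestCallSignificant:
    def test_separated_distributions_all_called(self):
        rng = np.random.default_rng(0)
        table = _toy_table(rng.uniform(0.8, 1.0, 200), rng.uniform(0, 0.1, 200))
        policy, called = co.call_significant(table, alpha=0.01)
        assert len(called) == len(table)
        assert policy.per_bin_threshold[0] <= table["mi"].min()

    def test_null_permutation_calibration(self):
        # observed and synthetic from the same distribution: few calls
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals = rng.exponential(0.05, 8000)
            table = _toy_table(vals, rng.permutation(vals))
            for alpha in (0.01, 0.05):
                _, called = co.call_significant(table, alpha)
                assert len(called) / len(table) <= 2 * alpha

    def test_q_is_non_increasing(self):
        rng = np.random.default_rng(3)
        obs = rng.exponential(0.05, 2000)
        syn = rng.exponential(0.05, 2000)
        ts = np.unique(obs)
        obs_s, syn_s = np.sort(obs), np.sort(syn)
        q = (len(syn) - np.searchsorted(syn_s, ts, side="left")) / np.maximum(
            1, len(obs) - np.searchsorted(obs_s, ts, side="left")
        )
        q = np.minimum.accumulate(q)
        assert np.all(np.diff(q) <= 1e-15)

    def test_threshold_infinite_when_unattainable(self):
        # synthetic dominates observed: nothing can be called
        table = _toy_table([0.1, 0.2, 0.3], [0.5, 0.6, 0.7])
        policy, called = co.call_significant(table, 0.01)
        assert called.empty
        assert policy.per_bin_threshold[0] == np.inf

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            co.call_significant(_toy_table([0.1], [0.1]), alpha=1.5)

    def test_pooled_single_threshold(self):
        rng = np.random.default_rng(0)
        table = _toy_table(
            rng.uniform(0.5, 1.0, 100), rng.uniform(0, 0.1, 100),
            bins=rng.integers(0, 3, 100),
        )
        policy, called = co.call_significant(table, 0.05, pooled=True)
        assert len(set(policy.per_bin_threshold.values())) == 1


class TestPruneTransitive:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["id_a", "id_b", "mi"]).assign(bin=0)

    def test_chain_keeps_alternating(self):
        pruned = co.prune_transitive(
            self._pairs([("A", "B", 0.9), ("B", "C", 0.8), ("C", "D", 0.7)])
        )
        assert set(zip(pruned["id_a"], pruned["id_b"])) == {("A", "B"), ("C", "D")}

    def test_shared_endpoint_keeps_strongest(self):
        pruned = co.prune_transitive(
            self._pairs([("A", "B", 0.9), ("A", "C", 0.8)])
        )
        assert set(zip(pruned["id_a"], pruned["id_b"])) == {("A", "B")}

    def test_empty_input(self):
        assert co.prune_transitive(self._pairs([])).empty

    def test_result_is_matching(self, planted):
        pruned = co.prune_transitive(planted["called"])
        nodes = list(pruned["id_a"]) + list(pruned["id_b"])
        assert len(nodes) == len(set(nodes))

    def test_tie_break_lexicographic(self):
        pruned = co.prune_transitive(
            self._pairs([("B", "C", 0.5), ("A", "B", 0.5)])
        )
        assert set(zip(pruned["id_a"], pruned["id_b"])) == {("A", "B")}


class TestMatchedBackground:
    def test_counts_match_per_bin(self, planted):
        rng = np.random.default_rng(0)
        fg = planted["called"]
        bg = co.matched_uncorrelated_background(planted["table"], fg, rng)
        assert (
            bg["bin"].value_counts().sort_index().to_dict()
            == fg["bin"].value_counts().sort_index().to_dict()
        )

    def test_all_background_below_ceiling(self, planted):
        rng = np.random.default_rng(1)
        bg = co.matched_uncorrelated_background(
            planted["table"], planted["called"], rng
        )
        assert (bg["mi"] < 0.01).all()

    def test_background_median_below_foreground(self, planted):
        rng = np.random.default_rng(2)
        fg = planted["called"]
        bg = co.matched_uncorrelated_background(planted["table"], fg, rng)
        assert bg["mi"].median() < fg["mi"].median()

    def test_insufficient_candidates_error_reports_bin(self):
        table = _toy_table([0.5] * 10, [0.0] * 10)  # nothing below ceiling
        fg = table.iloc[:3]
        with pytest.raises(ValueError, match="bin 0"):
            co.matched_uncorrelated_background(
                table, fg, np.random.default_rng(0)
            )
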