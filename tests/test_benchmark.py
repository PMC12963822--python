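from itertools import product
from math import comb

import numpy as np
import pytest

from gatmerip import (
    GroundTruth,
    SyntheticSpec,
    auroc,
    degree_based_candidate_filter,
    degree_preserving_randomize,
    generate,
    over_representation,
    read_gmt,
    robustness_protocol,
    rwr,
    RWRConfig,
    timing_harness,
)
from gatmerip.benchmark import _consensus

from conftest import net_from_pairs


def pair_count_auroc(scores: dict, positives: set) -> float:
    """Exhaustive positive-negative pair counting (ties worth 1/2)."""
    pos = [scores[g] for g in scores if g in positives]
    neg = [scores[g] for g in scores if g not in positives]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_perfect_and_inverted_separation(self):
        scores = {"A": 0.9, "B": 0.8, "C": 0.2, "D": 0.1}
        truth = GroundTruth(frozenset({"A", "B"}))
        assert auroc(scores, truth) == 1.0
        anti = GroundTruth(frozenset({"C", "D"}))
        assert auroc(scores, anti) == 0.0

    def test_hand_example(self):
        scores = dict(zip("ABCD", [0.9, 0.8, 0.3, 0.1]))
        truth = GroundTruth(frozenset({"A", "C"}))
        assert np.isclose(auroc(scores, truth), 0.75, atol=1e-12)

    def test_matches_pair_counting_on_random_fixtures(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 50))
            scores = {f"G{i}": float(rng.choice([0.1, 0.3, 0.5, 0.7, 0.9]))
                      for i in range(n)}
            k = int(rng.integers(1, n))
            positives = set(rng.choice(sorted(scores), size=k, replace=False))
            if len(positives) == n:
                continue
            truth = GroundTruth(frozenset(positives))
            assert abs(auroc(scores, truth)
                       - pair_count_auroc(scores, positives)) < 1e-12

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = {f"G{i}": float(rng.normal()) for i in range(100)}
        positives = set(list(scores)[:30])
        truth = GroundTruth(frozenset(positives))
        genes = sorted(scores)
        expected = roc_auc_score([g in positives for g in genes],
                                 [scores[g] for g in genes])
        assert np.isclose(auroc(scores, truth), expected, atol=1e-12)

    def test_degenerate_truth_rejected(self):
        scores = {"A": 0.1, "B": 0.2}
        with pytest.raises(ValueError, match="degenerate"):
            auroc(scores, GroundTruth(frozenset({"A", "B"})))


class TestDegreeFilter:
    def test_star_hub_selected(self):
        net = net_from_pairs([("HUB", f"L{i}") for i in range(4)])
        assert degree_based_candidate_filter(net, {"L0"}, k=1) == {"HUB"}

    def test_k_equals_all_non_seeds(self, small_synth):
        net, _, _ = small_synth
        seeds = set(net.nodes[:10])
        out = degree_based_candidate_filter(net, seeds, k=net.n_nodes - 10)
        assert out == frozenset(net.nodes) - seeds

    def test_invariant_under_degree_preserving_randomization(self, small_synth):
        net, _, _ = small_synth
        seeds = set(net.nodes[:20])
        reference = degree_based_candidate_filter(net, seeds, k=50)
        for seed in range(100):
            rnd = degree_preserving_randomize(net, n_swaps=net.n_undirected_edges,
                                              seed=seed)
            assert degree_based_candidate_filter(rnd, seeds, k=50) == reference

    def test_hand_evaluated_score_order(self):
        # degrees: HUB 3, A 2, B 2, C 1; seed C (degree 1)
        net = net_from_pairs([("HUB", "A"), ("HUB", "B"), ("HUB", "C"),
                              ("A", "B")])
        out = degree_based_candidate_filter(net, {"C"}, k=2)
        assert out == {"HUB", "A"}  # A beats B lexicographically on the tie

    def test_empty_seeds_rejected(self, path_net):
        with pytest.raises(ValueError, match="empty"):
            degree_based_candidate_filter(path_net, set(), k=1)


class TestRobustnessProtocol:
    def test_consensus_rule(self):
        sets = [frozenset("AB"), frozenset("AC"), frozenset("AD"),
                frozenset("BC")]
        # A in 3/4, B and C in 2/4 (>= 50%), D in 1/4
        assert _consensus(sets) == frozenset("ABC")

    def test_degree_filter_fully_stable(self, small_synth):
        net, feats, _ = small_synth
        res = robustness_protocol(net, feats, n_seeds=20, n_networks=5, k=30,
                                  seed=1, methods=("degree_filter",))
        assert res["degree_filter"].n_differing == 0
        assert len(res["degree_filter"].per_network_a) == 5

    def test_rwr_sensitive_to_rewiring(self):
        """On a sparse 200-gene graph, rewiring changes seed-to-candidate
        distances, so the RWR consensus sets should differ."""
        net, feats, _ = generate(SyntheticSpec(n_genes=200, n_datasets=1,
                                               attachment_edges_per_node=1,
                                               seed=4))
        res = robustness_protocol(net, feats, n_seeds=10, n_networks=20, k=20,
                                  seed=2, methods=("rwr",))
        assert res["rwr"].n_differing > 0

    def test_unknown_method_rejected(self, small_synth):
        net, feats, _ = small_synth
        with pytest.raises(ValueError, match="unknown methods"):
            robustness_protocol(net, feats, n_seeds=5, n_networks=2, k=5,
                                methods=("pagerank",))


class TestOverRepresentation:
    def test_exact_overlap_extreme_case(self):
        universe = {f"G{i}" for i in range(12)}
        top = {"G0", "G1", "G2"}
        df = over_representation(top, {"hit": set(top)}, universe)
        assert np.isclose(df.loc[0, "p_value"], 1 / comb(12, 3))

    def test_tail_by_direct_summation(self):
        universe = {f"G{i}" for i in range(20)}
        top = {f"G{i}" for i in range(5)}
        gene_set = {"G0", "G1", "G2", "G19"}  # overlap 3
        df = over_representation(top, {"s": gene_set}, universe)
        expected = sum(comb(4, i) * comb(16, 5 - i) for i in (3, 4)) / comb(20, 5)
        assert np.isclose(df.loc[0, "p_value"], expected, atol=1e-12)

    def test_zero_overlap_large_set(self):
        universe = {f"G{i}" for i in range(30)}
        top = {f"G{i}" for i in range(5)}
        df = over_representation(top, {"other": {f"G{i}" for i in range(20, 30)}},
                                 universe)
        assert df.loc[0, "p_value"] > 0.8
        assert df.loc[0, "q_value"] == 1.0

    def test_bh_monotone_and_bounded(self, rng):
        universe = {f"G{i}" for i in range(50)}
        top = set(rng.choice(sorted(universe), size=10, replace=False))
        sets = {f"s{j}": set(rng.choice(sorted(universe), size=8, replace=False))
                for j in range(12)}
        df = over_representation(top, sets, universe)
        q = df["q_value"].to_numpy()
        assert np.all(np.diff(q) >= -1e-12) and np.all(q <= 1.0)
        assert np.all(df["q_value"] >= df["p_value"] - 1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            over_representation(set(), {"s": {"A"}}, set())

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("pathA\tdesc\tAGT\ttp53\npathB\tdesc\tMYC\n")
        sets = read_gmt(p)
        assert sets == {"pathA": {"AGT", "TP53"}, "pathB": {"MYC"}}


class TestTiming:
    def test_records_requested_repetitions_and_labels(self, small_synth):
        net, feats, _ = small_synth
        seeds = set(net.nodes[:10])
        out = timing_harness(
            lambda n: degree_based_candidate_filter(n, seeds, 20),
            net, repetitions=3, label="degree-filter",
        )
        assert len(out["times"]) == 3
        assert out["label"] == "degree-filter" and out["n_nodes"] == net.n_nodes

    def test_degree_filter_faster_than_rwr(self, small_synth):
        """Ordering only — the published fold-speedup is hardware-bound."""
        net, feats, _ = small_synth
        seeds = frozenset(net.nodes[:10])
        fast = timing_harness(
            lambda n: degree_based_candidate_filter(n, seeds, 20), net, 3)
        slow = timing_harness(
            lambda n: rwr(n, RWRConfig(seed_genes=seeds)), net, 3)
        assert fast["median_s"] < slow["median_s"]
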