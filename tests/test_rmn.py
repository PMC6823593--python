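"""The triplet rule engine: discretization, scoring, network assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmnet import (
    AbundanceMatrix,
    Change,
    RMNParams,
    annotate_site_category,
    classify_change,
    evaluate_all_triplets,
    evaluate_triplet,
    filter_taxa,
    infer_network,
    network_summary,
    sample_pairs,
)
from conftest import random_abundance


# -- independent oracle ----------------------------------------------------

def brute_force_counts(matrix, target, coop, comp, params):
    """Plain-Python re-derivation of support/contradiction, pair by pair."""
    support = contradiction = 0
    for before, after in sample_pairs(matrix.samples, params.pair_mode):
        def change(taxon):
            d = matrix.data.loc[taxon, after] - matrix.data.loc[taxon, before]
            if d > params.epsilon:
                return "UP"
            if d < -params.epsilon:
                return "DOWN"
            return "STEADY"

        c, k, t = change(coop), change(comp), change(target)
        if c == "UP" and k == "DOWN":
            predicted = "UP"
        elif c == "DOWN" and k == "UP":
            predicted = "DOWN"
        else:
            continue
        if t == predicted:
            support += 1
        else:
            contradiction += 1
    return support, contradiction


class TestClassifyChange:
    def test_zero_delta_steady(self):
        assert classify_change(0.10, 0.10, 0.01) is Change.STEADY

    def test_up(self):
        assert classify_change(0.10, 0.16, 0.01) is Change.UP

    def test_inside_band_steady(self):
        assert classify_change(0.10, 0.095, 0.01) is Change.STEADY

    def test_down(self):
        assert classify_change(0.20, 0.10, 0.01) is Change.DOWN


class TestSamplePairs:
    @pytest.mark.parametrize(
        "mode,n,expected",
        [("consecutive", 4, 3), ("all_pairs", 4, 6), ("consecutive", 1, 0), ("all_pairs", 1, 0)],
    )
    def test_pair_counts(self, mode, n, expected):
        samples = [f"s{i}" for i in range(n)]
        assert len(sample_pairs(samples, mode)) == expected

    def test_orientation_follows_column_order(self):
        assert sample_pairs(["a", "b", "c"], "all_pairs") == [
            ("a", "b"), ("a", "c"), ("b", "c"),
        ]


class TestFilterTaxa:
    def test_threshold(self):
        df = pd.DataFrame({"s1": [0.0005, 0.002], "s2": [0.0001, 0.001]}, index=["lo", "hi"])
        out = filter_taxa(AbundanceMatrix(df), 0.001)
        assert out.taxa == ["hi"]
        assert out.samples == ["s1", "s2"]

    def test_zero_threshold_is_identity(self):
        m = random_abundance(0)
        assert filter_taxa(m, 0.0).taxa == m.taxa

    def test_monotone_in_threshold(self):
        m = random_abundance(1)
        n_prev = m.n_taxa
        for theta in (0.01, 0.05, 0.2, 0.5):
            n = filter_taxa(m, theta).n_taxa
            assert n <= n_prev
            n_prev = n


class TestEvaluateTriplet:
    def test_toy_conforming_triplet(self, toy_matrix, toy_params):
        r = evaluate_triplet(toy_matrix, "X", "Y", "Z", toy_params)
        assert (r.support, r.contradiction) == (3, 0)
        assert r.score == 1.0
        assert r.accepted

    def test_toy_anticorrelated_target_rejected(self, toy_matrix, toy_params):
        # target moving against the prediction scores −1
        flipped = toy_matrix.data.copy()
        flipped.loc["X"] = 0.5 - flipped.loc["X"]  # invert X's direction, keep scale
        r = evaluate_triplet(AbundanceMatrix(flipped), "X", "Y", "Z", toy_params)
        assert (r.support, r.contradiction) == (0, 3)
        assert r.score == -1.0
        assert not r.accepted

    def test_constant_matrix_uninformative(self, toy_params):
        df = pd.DataFrame(
            {f"s{i}": [0.2, 0.3, 0.5] for i in range(4)}, index=["a", "b", "c"]
        )
        r = evaluate_triplet(AbundanceMatrix(df), "a", "b", "c", toy_params)
        assert r.informative == 0
        assert r.score == 0.0
        assert not r.accepted

    def test_duplicate_taxon_rejected(self, toy_matrix, toy_params):
        with pytest.raises(ValueError):
            evaluate_triplet(toy_matrix, "X", "X", "Z", toy_params)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 100_000),
        mode=st.sampled_from(["all_pairs", "consecutive"]),
        epsilon=st.sampled_from([0.001, 0.01, 0.05]),
    )
    def test_oracle_equivalence(self, seed, mode, epsilon):
        """Vectorized counts match the brute-force enumerator exactly."""
        rng = np.random.default_rng(seed)
        m = random_abundance(seed, n_taxa=int(rng.integers(3, 7)), n_samples=int(rng.integers(2, 9)))
        params = RMNParams(epsilon=epsilon, pair_mode=mode)
        taxa = rng.choice(m.taxa, size=3, replace=False)
        r = evaluate_triplet(m, *taxa, params)
        assert (r.support, r.contradiction) == brute_force_counts(m, *taxa, params)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_score_symmetric_under_pair_reversal(self, seed):
        """Reversing every pair's orientation swaps UP/DOWN everywhere and
        leaves support/contradiction unchanged."""
        m = random_abundance(seed, n_taxa=4, n_samples=6)
        params = RMNParams(epsilon=0.01, pair_mode="consecutive")
        reversed_m = AbundanceMatrix(m.data[m.data.columns[::-1]])
        for trip in [("t0", "t1", "t2"), ("t3", "t2", "t0")]:
            a = evaluate_triplet(m, *trip, params)
            b = evaluate_triplet(reversed_m, *trip, params)
            assert (a.support, a.contradiction) == (b.support, b.contradiction)


class TestInferNetwork:
    def test_constant_matrix_empty_edges(self, toy_params):
        df = pd.DataFrame(
            {f"s{i}": [0.2, 0.3, 0.5] for i in range(4)}, index=["a", "b", "c"]
        )
        net = infer_network(AbundanceMatrix(df), toy_params)
        assert net.edges() == []

    def test_toy_network_edges_and_summary(self, toy_network):
        assert toy_network.edge_set() == {
            ("Y", "X", "cooperative"),
            ("Z", "X", "competitive"),
            ("X", "Y", "cooperative"),
            ("Z", "Y", "competitive"),
        }
        assert network_summary(toy_network) == {
            "n_nodes": 3,
            "n_coop_edges": 2,
            "n_comp_edges": 2,
            "n_mutual_negative": 0,
        }

    def test_too_few_taxa_rejected(self, toy_params):
        df = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.4, 0.6]}, index=["a", "b"])
        with pytest.raises(ValueError, match="3 taxa"):
            infer_network(AbundanceMatrix(df), toy_params)

    def test_too_few_samples_rejected(self, toy_params):
        df = pd.DataFrame({"s1": [0.2, 0.3, 0.5]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="2 samples"):
            infer_network(AbundanceMatrix(df), toy_params)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_structural_rule_on_random_matrices(self, seed):
        """A cooperative in-edge is never discovered without a competitive
        in-edge at the same node."""
        m = random_abundance(seed, n_taxa=5, n_samples=6)
        net = infer_network(m, RMNParams(epsilon=0.02, s_min=0.5, m_min=2))
        net.validate()  # includes the structural rule
        coop_targets = {e.target for e in net.edges() if e.sign == "cooperative"}
        comp_targets = {e.target for e in net.edges() if e.sign == "competitive"}
        assert coop_targets <= comp_targets

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_permutation_invariance_all_pairs(self, seed):
        """Permuting sample column order leaves the accepted set unchanged."""
        m = random_abundance(seed, n_taxa=4, n_samples=6)
        params = RMNParams(epsilon=0.02, s_min=0.5, m_min=2)
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(m.samples)
        shuffled = AbundanceMatrix(m.data[perm])
        accepted = lambda mat: {
            (r.target, r.cooperator, r.competitor)
            for r in evaluate_all_triplets(mat, params)
            if r.accepted
        }
        assert accepted(m) == accepted(shuffled)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_tightening_thresholds_never_adds_edges(self, seed):
        m = random_abundance(seed, n_taxa=5, n_samples=6)
        loose = infer_network(m, RMNParams(epsilon=0.02, s_min=0.0, m_min=1))
        for s_min, m_min in [(0.5, 1), (0.5, 3), (1.0, 3)]:
            tight = infer_network(m, RMNParams(epsilon=0.02, s_min=s_min, m_min=m_min))
            assert tight.edge_set() <= loose.edge_set()

    def test_deterministic(self, toy_matrix, toy_params):
        a = infer_network(toy_matrix, toy_params)
        b = infer_network(toy_matrix, toy_params)
        assert a == b


class TestSiteCategories:
    def make(self):
        df = pd.DataFrame(
            {
                "L1": [0.05, 0.002, 0.0004, 0.9],
                "L2": [0.06, 0.0009, 0.0002, 0.9],
                "M1": [0.04, 0.0002, 0.003, 0.9],
            },
            index=["everywhere", "loihi_only", "mariana_only", "bulk"],
        )
        regions = {"L1": "Loihi", "L2": "Loihi", "M1": "Mariana"}
        return AbundanceMatrix(df), regions

    def test_categories(self):
        m, regions = self.make()
        cats = annotate_site_category(m, regions, 0.001)
        assert cats["everywhere"] == "both"
        assert cats["loihi_only"] == "regionA_only"  # Loihi < Mariana lexicographically
        assert cats["mariana_only"] == "regionB_only"

    def test_below_threshold_everywhere(self):
        df = pd.DataFrame({"L1": [0.0001, 0.5, 0.5], "M1": [0.0002, 0.5, 0.5]},
                          index=["rare", "a", "b"])
        cats = annotate_site_category(
            AbundanceMatrix(df), {"L1": "Loihi", "M1": "Mariana"}, 0.001
        )
        assert cats["rare"] == "below_threshold"

    def test_single_region_rejected(self):
        m, _ = self.make()
        with pytest.raises(ValueError, match="2 regions"):
            annotate_site_category(m, {s: "Loihi" for s in m.samples}, 0.001)

    def test_network_nodes_annotated(self, toy_matrix, toy_params):
        regions = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        net = infer_network(toy_matrix, toy_params, region_of=regions)
        for node in net.nodes():
            assert net.node_attrs(node)["category"] == "both"
            assert net.node_attrs(node)["max_abundance"] > 0
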