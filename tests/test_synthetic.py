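"""Popularity-similarity generator and planted annotations."""

import networkx as nx
import numpy as np
import pytest

from hyperptm.geometry import TWO_PI, angular_separation, hyperbolic_distance
from hyperptm.synthetic import (
    PSParams,
    fit_degree_exponent,
    generate_ps_network,
    plant_effectors,
    plant_positive_pairs,
)


class TestGenerator:
    @pytest.mark.parametrize("temperature", [0.0, 0.5])
    def test_smallest_network_is_triangle(self, temperature):
        emb = generate_ps_network(PSParams(n=3, m=2, temperature=temperature, seed=0))
        assert emb.net.number_of_edges() == 3
        assert nx.is_isomorphic(emb.net, nx.complete_graph(3))

    def test_cold_edge_count_closed_form(self):
        emb = generate_ps_network(PSParams(n=500, m=2, temperature=0.0, seed=1))
        expected = sum(min(i - 1, 2) for i in range(1, 501))
        assert emb.net.number_of_edges() == expected == 997

    def test_warm_edge_count_matches_closed_form_too(self):
        # the sweep scheme keeps exactly m links per arriving node
        emb = generate_ps_network(PSParams(n=300, m=3, temperature=0.4, seed=2))
        assert emb.net.number_of_edges() == sum(min(i - 1, 3) for i in range(1, 301))

    def test_deterministic_under_seed(self):
        a = generate_ps_network(PSParams(n=200, m=2, temperature=0.5, seed=42))
        b = generate_ps_network(PSParams(n=200, m=2, temperature=0.5, seed=42))
        assert set(a.net.edges()) == set(b.net.edges())
        assert a.coords.equals(b.coords)

    def test_degree_tail_exponent_recovers_gamma(self):
        emb = generate_ps_network(
            PSParams(n=10000, m=2, gamma=2.5, temperature=0.1, seed=3)
        )
        degrees = [d for _, d in emb.net.degree()]
        alpha = fit_degree_exponent(degrees, kmin=5)
        assert abs(alpha - 2.5) < 0.3

    def test_clustering_decreases_with_temperature(self):
        means = []
        for t in (0.0, 0.5, 0.9):
            cs = []
            for rep in range(10):
                emb = generate_ps_network(
                    PSParams(n=2000, m=2, temperature=t, seed=100 + rep)
                )
                cs.append(nx.average_clustering(emb.net))
            means.append(np.mean(cs))
        assert means[0] > means[1] > means[2]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PSParams(n=2, m=2)
        with pytest.raises(ValueError):
            PSParams(n=10, m=2, gamma=1.5)
        with pytest.raises(ValueError):
            PSParams(n=10, m=2, temperature=1.0)


class TestPlanting:
    def test_kinases_concentrate_around_center(self, planted_study):
        emb = planted_study["emb"]
        annot = planted_study["annot"]
        theta = emb.coords["theta"]
        kin = sorted(annot.kinases)
        non = sorted(set(emb.coords.index) - annot.effectors)
        sep_kin = np.mean(angular_separation(theta[kin].to_numpy(), 1.8, TWO_PI))
        sep_non = np.mean(angular_separation(theta[non].to_numpy(), 1.8, TWO_PI))
        assert sep_kin < sep_non

    def test_zero_spread_takes_angularly_closest(self):
        emb = generate_ps_network(PSParams(n=100, m=2, temperature=0.2, seed=5))
        annot = plant_effectors(
            emb, kinase_fraction=0.05, spread=1e-9, seed=1
        )
        k = len(annot.kinases)
        sep = angular_separation(emb.coords["theta"].to_numpy(), 1.8, TWO_PI)
        closest = set(emb.coords.index[np.argsort(sep, kind="stable")[:k]])
        assert annot.kinases == closest

    def test_uniform_mode_ignores_centers(self):
        emb = generate_ps_network(PSParams(n=400, m=2, temperature=0.2, seed=6))
        annot = plant_effectors(emb, mode="uniform", seed=1)
        # under uniform planting the kinases should not be confined to a sector
        sep = angular_separation(
            emb.coords.loc[sorted(annot.kinases), "theta"].to_numpy(), 1.8, TWO_PI
        )
        assert sep.max() > 0.5

    def test_positive_sources_are_effectors(self, planted_study):
        annot = planted_study["annot"]
        for eff, _, etype in annot.positive_pairs:
            assert eff in annot.effectors
            assert etype in ("kinase", "phosphatase")

    def test_positives_are_network_edges(self, planted_study):
        net = planted_study["emb"].net
        for eff, tgt, _ in planted_study["annot"].positive_pairs:
            assert net.has_edge(eff, tgt)

    def test_zero_positives(self, planted_study):
        annot = plant_positive_pairs(
            planted_study["emb"], planted_study["annot"], n_pos=0, seed=9
        )
        assert annot.positive_pairs == ()

    def test_positives_hyperbolically_closer_than_background(self, planted_study):
        emb = planted_study["emb"]
        annot = plant_positive_pairs(
            emb, planted_study["annot"], n_pos=100, lam=2.0, seed=8
        )
        r, th = emb.coords["r"], emb.coords["theta"]

        def dist(a, b):
            return hyperbolic_distance(r[a], th[a], r[b], th[b])

        d_pos = np.mean([dist(e, t) for e, t, _ in annot.positive_pairs])
        d_all = np.mean([dist(a, b) for a, b in emb.net.edges()])
        assert d_pos < d_all

    def test_too_many_positives_rejected(self, planted_study):
        with pytest.raises(ValueError, match="effector-incident"):
            plant_positive_pairs(
                planted_study["emb"], planted_study["annot"], n_pos=10**6
            )

    def test_planting_deterministic(self):
        emb = generate_ps_network(PSParams(n=200, m=2, temperature=0.2, seed=7))
        a = plant_effectors(emb, seed=3)
        b = plant_effectors(emb, seed=3)
        assert a.kinases == b.kinases and a.phosphatases == b.phosphatases
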