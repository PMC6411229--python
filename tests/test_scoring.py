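import itertools

import numpy as np
import pytest

from cophos.correlation import CoPhosNetwork, build_cophos_network
from cophos.scoring import (
    collect_shared_kinase_values,
    fit_tail_model,
    fit_tail_model_from_network,
    rank_all,
    score_kinase_site,
)
from cophos.types import KSAnnotation, PhosphoSite, PredictionTable

from _oracles import (
    exhaustive_predictions,
    shared_kinase_values_bruteforce,
    survival_countloop,
)
from conftest import make_matrix


def sites_named(n):
    return [PhosphoSite.parse(f"P{i}_S{i + 1}") for i in range(n)]


def network_from_weights(weights, sites=None):
    weights = np.asarray(weights, dtype=float)
    sites = sites or sites_named(weights.shape[0])
    return CoPhosNetwork(sites=sites, weights=weights)


class TestCollectSharedKinaseValues:
    def test_single_kinase_pair(self):
        s = sites_named(3)
        weights = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, -0.1], [0.2, -0.1, 1.0]])
        net = network_from_weights(weights, s)
        ksa = KSAnnotation.from_pairs([("K1", s[0]), ("K1", s[1])])
        np.testing.assert_array_equal(
            collect_shared_kinase_values(net, ksa), [0.5]
        )

    def test_pair_sharing_two_kinases_counts_once(self):
        s = sites_named(2)
        net = network_from_weights([[1.0, 0.7], [0.7, 1.0]], s)
        ksa = KSAnnotation.from_pairs(
            [("K1", s[0]), ("K1", s[1]), ("K2", s[0]), ("K2", s[1])]
        )
        values = collect_shared_kinase_values(net, ksa)
        assert values.tolist() == [0.7]

    def test_matches_bruteforce_double_loop(self, rng):
        s = sites_named(6)
        weights = rng.uniform(-1, 1, (6, 6))
        weights = (weights + weights.T) / 2
        np.fill_diagonal(weights, 1.0)
        net = network_from_weights(weights, s)
        ksa = KSAnnotation.from_pairs(
            [("K1", s[0]), ("K1", s[2]), ("K1", s[4]),
             ("K2", s[1]), ("K2", s[2]), ("K2", s[5])]
        )
        expected = shared_kinase_values_bruteforce(weights, s, ksa)
        assert sorted(collect_shared_kinase_values(net, ksa).tolist()) == sorted(expected)

    def test_empty_intersection_is_error(self):
        s = sites_named(2)
        net = network_from_weights([[1.0, 0.3], [0.3, 1.0]], s)
        other = PhosphoSite.parse("ELSEWHERE_S9")
        ksa = KSAnnotation.from_pairs([("K1", other)])
        with pytest.raises(ValueError, match="shared-kinase"):
            collect_shared_kinase_values(net, ksa)


class TestTailModel:
    def test_below_support_survival_is_one(self):
        tails = fit_tail_model(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert tails.survival_background(0.0) == 1.0

    def test_above_support_hits_addone_floor(self):
        tails = fit_tail_model(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert tails.survival_background(3.0) == pytest.approx(1 / 4)
        assert tails.survival_background(99.0) == pytest.approx(1 / 4)

    def test_matches_count_and_divide_loop(self, rng):
        sample = rng.standard_normal(200)
        tails = fit_tail_model(sample, sample)
        for c in rng.uniform(-3, 3, 50):
            assert tails.survival_background(c) == pytest.approx(
                survival_countloop(sample, c), abs=1e-15
            )

    def test_monotone_non_increasing(self, rng):
        sample = rng.standard_normal(100)
        tails = fit_tail_model(sample, sample)
        grid = np.linspace(-4, 4, 200)
        values = tails.survival_shared(grid)
        assert np.all(np.diff(values) <= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_tail_model(np.array([]), np.array([1.0]))


class TestScoreKinaseSite:
    def _setup(self, weights, associations):
        n = np.asarray(weights).shape[0]
        s = sites_named(n)
        net = network_from_weights(weights, s)
        ksa = KSAnnotation.from_pairs(
            [(k, s[i]) for k, i in associations]
        )
        return s, net, ksa

    def test_identical_tails_give_zero(self):
        s, net, ksa = self._setup(
            [[1.0, 0.4], [0.4, 1.0]], [("K1", 0), ("K1", 1)]
        )
        sample = np.array([-0.5, 0.0, 0.4, 0.8])
        tails = fit_tail_model(sample, sample)
        assert score_kinase_site("K1", s[0], net, ksa, tails) == 0.0

    def test_two_neighbours_ratio_two_each(self):
        # survival_S / survival_A = 2 at the queried weights
        s, net, ksa = self._setup(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]],
            [("K1", 1), ("K1", 2), ("K1", 0)],
        )
        background = np.array([0.6, 0.7, 0.8, 0.9, -1.0, -1.0, -1.0, -1.0, -1.0])
        shared = np.array([0.6, 0.7, 0.8, 0.9])  # surv(0.5): 5/5 vs 10/10... adjust
        tails = fit_tail_model(background, shared)
        # surv_S(0.5) = (4+1)/5 = 1.0 ; surv_A(0.5) = (4+1)/10 = 0.5 -> ratio 2
        h = score_kinase_site("K1", s[0], net, ksa, tails)
        assert h == pytest.approx(2.0)

    def test_unscorable_when_no_measured_neighbour(self):
        s, net, ksa = self._setup(
            [[1.0, 0.1], [0.1, 1.0]], [("K1", 0)]
        )
        sample = np.array([0.0, 0.5])
        tails = fit_tail_model(sample, sample)
        assert score_kinase_site("K1", s[0], net, ksa, tails) is None
        assert score_kinase_site("K1", s[1], net, ksa, tails) == 0.0

    def test_site_absent_from_network(self):
        s, net, ksa = self._setup([[1.0, 0.1], [0.1, 1.0]], [("K1", 0), ("K1", 1)])
        tails = fit_tail_model(np.array([0.0]), np.array([0.0]))
        with pytest.raises(KeyError):
            score_kinase_site("K1", PhosphoSite.parse("X_S1"), net, ksa, tails)

    def test_additivity_over_disjoint_neighbour_sets(self, rng):
        s = sites_named(7)
        weights = rng.uniform(-1, 1, (7, 7))
        weights = (weights + weights.T) / 2
        np.fill_diagonal(weights, 1.0)
        net = network_from_weights(weights, s)
        tails = fit_tail_model(rng.standard_normal(50), rng.standard_normal(40) + 0.3)
        part_a = KSAnnotation.from_pairs([("K", s[1]), ("K", s[2])])
        part_b = KSAnnotation.from_pairs([("K", s[3]), ("K", s[4]), ("K", s[5])])
        union = KSAnnotation.from_pairs(part_a.associations | part_b.associations)
        h_union = score_kinase_site("K", s[0], net, union, tails)
        h_a = score_kinase_site("K", s[0], net, part_a, tails)
        h_b = score_kinase_site("K", s[0], net, part_b, tails)
        assert h_union == pytest.approx(h_a + h_b, abs=1e-12)

    def test_monotone_in_neighbour_weight(self):
        """With a right-shifted shared tail, raising c_pq never lowers h.

        The shared sample sits entirely above the tested weight range, so
        the survival ratio is monotone over the grid (empirical step
        functions only guarantee this when the shift exceeds the range).
        """
        s = sites_named(3)
        background = np.linspace(-1.0, 1.0, 201)
        shared = np.full(50, 0.95)
        tails = fit_tail_model(background, shared)
        ksa = KSAnnotation.from_pairs([("K", s[1]), ("K", s[2])])
        previous = -np.inf
        for c in np.linspace(-0.9, 0.9, 25):
            weights = np.array(
                [[1.0, c, 0.1], [c, 1.0, 0.0], [0.1, 0.0, 1.0]]
            )
            net = network_from_weights(weights, s)
            h = score_kinase_site("K", s[0], net, ksa, tails)
            assert h >= previous - 1e-12
            previous = h


class TestRankAll:
    def test_constructed_separation(self, rng):
        """K1's substrates correlate with the site; K2's anti-correlate."""
        m = 12
        f = rng.standard_normal(m)
        rows = [f + 0.2 * rng.standard_normal(m) for _ in range(3)]
        rows += [-f + 0.2 * rng.standard_normal(m) for _ in range(2)]
        rows += [rng.standard_normal(m) for _ in range(3)]
        matrix = make_matrix(np.array(rows))
        s = matrix.sites
        ksa = KSAnnotation.from_pairs(
            [("K1", s[1]), ("K1", s[2]), ("K2", s[3]), ("K2", s[4])]
        )
        net = build_cophos_network(matrix)
        tails = fit_tail_model_from_network(net, ksa)
        table = rank_all(net, ksa, tails)
        assert table.top(s[0])[0] == "K1"

    def test_tie_break_by_kinase_name(self):
        s = sites_named(3)
        weights = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        net = network_from_weights(weights, s)
        # K-a and K-b have the same single substrate profile weight
        ksa = KSAnnotation.from_pairs(
            [("Kb", s[1]), ("Ka", s[2]), ("Kb", s[2]), ("Ka", s[1])]
        )
        tails = fit_tail_model(net.condensed(), net.condensed())
        table = rank_all(net, ksa, tails)
        assert table.ranks[s[0]] == ["Ka", "Kb"]

    def test_ranking_is_permutation_of_scorable_kinases(self, toy_matrix, toy_ksa):
        net = build_cophos_network(toy_matrix)
        tails = fit_tail_model_from_network(net, toy_ksa)
        table = rank_all(net, toy_ksa, tails)
        for site in table.sites:
            ranked = table.ranks[site]
            assert sorted(ranked) == sorted(set(ranked))
            for kinase in ranked:
                assert (kinase, site) in table.entries

    def test_matches_exhaustive_oracle_exactly(self, rng):
        """Randomized small instances: scores and rankings agree bit-exactly."""
        for trial in range(25):
            n = int(rng.integers(4, 9))
            n_kin = int(rng.integers(1, 4))
            weights = rng.uniform(-1, 1, (n, n))
            weights = (weights + weights.T) / 2
            np.fill_diagonal(weights, 1.0)
            s = sites_named(n)
            net = network_from_weights(weights, s)
            pairs = set()
            for k in range(n_kin):
                chosen = rng.choice(n, size=int(rng.integers(2, n + 1)),
                                    replace=False)
                pairs.update((f"K{k}", s[i]) for i in chosen)
            ksa = KSAnnotation.from_pairs(pairs)
            tails = fit_tail_model_from_network(net, ksa)
            table = rank_all(net, ksa, tails)
            expected_scores, expected_ranks = exhaustive_predictions(
                weights, s, ksa
            )
            assert table.entries == expected_scores
            assert table.ranks == expected_ranks

    def test_full_coverage_when_kinases_measured(self, toy_matrix, toy_ksa):
        net = build_cophos_network(toy_matrix)
        tails = fit_tail_model_from_network(net, toy_ksa)
        table = rank_all(net, toy_ksa, tails)
        assert table.sites == set(net.sites)

    def test_error_when_nothing_scorable(self):
        s = sites_named(2)
        net = network_from_weights([[1.0, 0.2], [0.2, 1.0]], s)
        ksa = KSAnnotation.from_pairs([("K1", s[0]), ("K1", s[1])])
        tails = fit_tail_model(net.condensed(), net.condensed())
        empty = KSAnnotation.from_pairs([])
        with pytest.raises(ValueError):
            rank_all(net, empty, tails)
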