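"""Relocation-iteration clustering: cost, pooled estimation, assignment."""

import math

import numpy as np
import pytest

from cyclefit import (
    ModelParams,
    Profile,
    adjusted_rand_index,
    assign_profiles,
    cluster_cost,
    cluster_with_restarts,
    estimate_cluster_params,
    evaluate_model,
    fit_profile,
    relocate_iterate,
)
from cyclefit.clustering import AllDegenerateError, UnknownLabelError

from .conftest import make_profile

P1 = ModelParams(alpha=-0.05, omega=0.5, a=1.5, b=0.5, c=0.02, d=0.5)
P2 = ModelParams(alpha=-0.10, omega=1.2, a=-1.0, b=1.2, c=-0.05, d=-0.8)


def two_cluster_data(n_per=20, m=18, noise_sd=0.2, seed=0):
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    for k, params in enumerate((P1, P2)):
        clean = evaluate_model(params, m, 1.0)
        for j in range(n_per):
            x = clean + noise_sd * rng.standard_normal(m)
            profiles.append(Profile(f"c{k}_{j}", x))
            labels.append(k)
    return profiles, np.array(labels)


class TestClusterCost:
    def test_zero_when_profiles_sit_on_their_curves(self):
        profiles = [make_profile(P1, 18, gene_id="a"), make_profile(P2, 18, gene_id="b")]
        assert cluster_cost(profiles, [0, 1], [P1, P2]) == pytest.approx(0.0)

    def test_hand_computed_toy(self):
        # two 3-point profiles against one shared constant model d = 1
        const = ModelParams(alpha=0, omega=1, a=0, b=0, c=0, d=1.0)
        profiles = [
            Profile("a", [1.0, 2.0, 3.0]),
            Profile("b", [0.0, 1.0, 1.0]),
        ]
        # residuals: (0,1,2) and (-1,0,0) -> 0+1+4 + 1+0+0 = 6
        assert cluster_cost(profiles, [0, 0], [const]) == pytest.approx(6.0)

    def test_single_cluster_equals_pooled_fit_residual(self):
        profiles, _ = two_cluster_data(n_per=6)
        params = estimate_cluster_params(profiles)
        curve = evaluate_model(params, 18, 1.0)
        expected = sum(float(np.sum((p.values - curve) ** 2)) for p in profiles)
        cost = cluster_cost(profiles, [0] * len(profiles), [params])
        assert cost == pytest.approx(expected)

    def test_unknown_label_is_rejected(self):
        profiles = [make_profile(P1, 18)]
        with pytest.raises(UnknownLabelError):
            cluster_cost(profiles, [2], [P1, P2])


class TestPooledEstimation:
    def test_single_member_reduces_to_profile_fit(self):
        prof = make_profile(P1, 18, noise_sd=0.1, seed=3)
        pooled = estimate_cluster_params([prof])
        single = fit_profile(prof).params
        assert pooled.as_array() == pytest.approx(single.as_array(), rel=1e-9)

    def test_duplication_invariance(self):
        prof = make_profile(P1, 18, noise_sd=0.1, seed=3)
        once = estimate_cluster_params([prof])
        thrice = estimate_cluster_params([prof] * 3)
        assert thrice.as_array() == pytest.approx(once.as_array(), rel=1e-9)

    def test_recovery_improves_with_cluster_size(self):
        clean = evaluate_model(P1, 18, 1.0)
        rng = np.random.default_rng(9)

        def error(n):
            profiles = [
                Profile(f"g{j}", clean + 0.3 * rng.standard_normal(18))
                for j in range(n)
            ]
            est = estimate_cluster_params(profiles)
            return np.linalg.norm(est.as_array() - P1.as_array())

        assert error(200) < error(4)


class TestAssignment:
    def test_profile_on_curve_gets_its_cluster(self):
        prof = make_profile(P2, 18)
        assert assign_profiles([prof], [P1, P2])[0] == 1

    def test_exact_tie_breaks_to_lowest_index(self):
        prof = make_profile(P1, 18)
        labels = assign_profiles([prof], [P2, P1, P1])
        assert labels[0] == 1  # clusters 1 and 2 tie exactly; lowest wins

    def test_degenerate_clusters_are_skipped(self):
        prof = make_profile(P1, 18)
        assert assign_profiles([prof], [None, P2])[0] == 1
        with pytest.raises(AllDegenerateError):
            assign_profiles([prof], [None, None])

    def test_separated_generators_recovered_perfectly(self):
        profiles, truth = two_cluster_data()
        labels = assign_profiles(profiles, [P1, P2])
        assert adjusted_rand_index(labels, truth) == pytest.approx(1.0)


class TestRelocateIterate:
    def test_cost_trace_is_non_increasing(self):
        profiles, _ = two_cluster_data(noise_sd=0.4)
        rng = np.random.default_rng(2)
        for _ in range(5):
            init = rng.integers(0, 2, len(profiles))
            model = relocate_iterate(profiles, 2, init)
            trace = np.array(model.cost_trace)
            assert np.all(np.diff(trace) <= 1e-9)
            assert model.cost == pytest.approx(trace[-1])

    def test_converged_partition_is_a_fixed_point(self):
        profiles, truth = two_cluster_data()
        first = relocate_iterate(profiles, 2, truth)
        again = relocate_iterate(profiles, 2, first.labels)
        assert again.n_iter == 1
        assert again.converged
        assert again.cost == pytest.approx(first.cost)
        assert np.array_equal(again.labels, first.labels)

    def test_two_separated_clusters_found_from_random_starts(self):
        profiles, truth = two_cluster_data()
        result = cluster_with_restarts(profiles, K=2, n_restarts=10, seed=1)
        assert adjusted_rand_index(result.best.labels, truth) == pytest.approx(1.0)

    def test_label_permutation_invariant_up_to_relabeling(self):
        profiles, _ = two_cluster_data(noise_sd=0.4)
        init = np.random.default_rng(8).integers(0, 2, len(profiles))
        direct = relocate_iterate(profiles, 2, init)
        swapped = relocate_iterate(profiles, 2, 1 - init)
        assert adjusted_rand_index(direct.labels, swapped.labels) == pytest.approx(1.0)
        assert swapped.cost == pytest.approx(direct.cost)

    def test_partition_accounting(self):
        profiles, truth = two_cluster_data()
        model = relocate_iterate(profiles, 2, truth)
        assert model.cluster_sizes.sum() == len(profiles)
        assert model.labels.min() >= 0 and model.labels.max() < 2


class TestRestarts:
    def test_seeding_is_reproducible(self):
        profiles, _ = two_cluster_data()
        a = cluster_with_restarts(profiles, K=2, n_restarts=3, seed=42)
        b = cluster_with_restarts(profiles, K=2, n_restarts=3, seed=42)
        assert a.best.cost == b.best.cost
        for la, lb in zip(a.label_sets, b.label_sets):
            assert np.array_equal(la, lb)

    def test_every_run_is_retained_for_aari(self):
        profiles, _ = two_cluster_data()
        result = cluster_with_restarts(profiles, K=2, n_restarts=4, seed=0)
        assert len(result.label_sets) == 4

    def test_kmeans_initialization_mode(self):
        profiles, truth = two_cluster_data()
        result = cluster_with_restarts(
            profiles, K=2, n_restarts=2, init_mode="kmeans", seed=3
        )
        assert adjusted_rand_index(result.best.labels, truth) == pytest.approx(1.0)
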