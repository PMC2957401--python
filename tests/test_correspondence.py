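"""Objectives: closest-point mapping, assignment problem, matching distance."""

import itertools

import numpy as np
import pytest

import sitealign as sa
from sitealign.correspondence import build_cost_graph, make_refiner
from sitealign.errors import (
    InfeasibleAssignmentError,
    InfeasibleGraphError,
    InvalidArgumentError,
)

IDENTITY = sa.TransformVector.identity()


def brute_force_assignment(cost: np.ndarray) -> float:
    """Exhaustive minimum over all injective maps of a finite cost matrix."""
    n, m = cost.shape
    best = np.inf
    for perm in itertools.permutations(range(m), n):
        total = sum(cost[i, j] for i, j in enumerate(perm))
        best = min(best, total)
    return best


class TestMeanSquareError:
    def test_zero_for_perfect_overlay(self, rng):
        P = rng.uniform(-5, 5, (6, 3))
        assert sa.mean_square_error(P, P, np.arange(6), IDENTITY) == 0.0

    def test_single_pair_is_squared_distance(self):
        assert sa.mean_square_error(
            np.zeros((1, 3)), np.array([[1.0, 0, 0]]), np.array([0]), IDENTITY
        ) == pytest.approx(1.0)

    def test_hand_computed_average(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0]])
        Q = np.array([[0.0, 0, 1], [1, 0, 2]])
        assert sa.mean_square_error(P, Q, np.arange(2), IDENTITY) == pytest.approx(2.5)

    def test_bad_index_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sa.mean_square_error(np.zeros((2, 3)), np.zeros((2, 3)),
                                 np.array([0, 5]), IDENTITY)


class TestClosestPointMapping:
    def test_identity_on_equal_sets(self, rng):
        P = rng.uniform(-5, 5, (7, 3))
        np.testing.assert_array_equal(sa.closest_point_mapping(P, P), np.arange(7))

    def test_non_injective_collapse(self):
        P = np.array([[0.0, 0, 0], [2, 0, 0]])
        Q = np.array([[0.1, 0, 0], [5, 0, 0]])
        np.testing.assert_array_equal(sa.closest_point_mapping(P, Q), [0, 0])

    def test_tie_broken_by_lowest_index(self):
        P = np.array([[0.0, 0, 0]])
        Q = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert sa.closest_point_mapping(P, Q)[0] == 0

    def test_no_single_swap_improves(self, rng):
        """The mapping globally minimizes the mean square error over Ψ."""
        P = rng.uniform(-5, 5, (6, 3))
        Q = rng.uniform(-5, 5, (9, 3))
        psi = sa.closest_point_mapping(P, Q)
        f0 = sa.mean_square_error(P, Q, psi, IDENTITY)
        for i in range(6):
            for j in range(9):
                trial = psi.copy()
                trial[i] = j
                assert sa.mean_square_error(P, Q, trial, IDENTITY) >= f0 - 1e-12


class TestCostGraph:
    def test_all_pairs_edge_count(self, rng):
        graph = build_cost_graph(rng.uniform(0, 1, (2, 3)), rng.uniform(0, 1, (3, 3)))
        assert (graph.n, graph.m, graph.n_edges()) == (2, 3, 6)

    def test_same_property_keeps_label_equal_edges(self):
        graph = build_cost_graph(
            np.zeros((2, 3)), np.zeros((3, 3)),
            labels_P=["ACC", "DO"], labels_Q=["DO", "ACC", "PI"],
            mode="same_property",
        )
        assert graph.n_edges() == 2
        assert {(i, j) for i, j, _ in graph.edges()} == {(0, 1), (1, 0)}

    def test_cost_is_squared_distance(self):
        graph = build_cost_graph(np.zeros((1, 3)), np.array([[3.0, 4, 0]]))
        assert graph.cost[0, 0] == pytest.approx(25.0)

    def test_unmatchable_atom_raises_with_its_index(self):
        with pytest.raises(InfeasibleGraphError) as err:
            build_cost_graph(
                np.zeros((2, 3)), np.zeros((2, 3)),
                labels_P=["PI", "ACC"], labels_Q=["ACC", "ACC"],
                mode="same_property",
            )
        assert err.value.p_index == 0 and err.value.label == "PI"

    def test_oversized_query_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_cost_graph(np.zeros((3, 3)), np.zeros((2, 3)))

    def test_tsv_export(self, tmp_path):
        graph = build_cost_graph(np.zeros((1, 3)), np.array([[3.0, 4, 0]]))
        out = tmp_path / "graph.tsv"
        graph.to_tsv(out)
        assert out.read_text().splitlines()[1] == "0\t0\t25.000000"


class TestSolveAAP:
    def test_prefers_cross_pairing(self):
        graph = sa.BipartiteCostGraph(np.array([[1.0, 2.0], [2.0, 4.0]]), "all_pairs")
        assignment, total = sa.solve_aap(graph)
        np.testing.assert_array_equal(assignment, [1, 0])
        assert total == pytest.approx(4.0)

    def test_single_row_takes_minimum(self):
        graph = sa.BipartiteCostGraph(np.array([[7.0, 2.0, 5.0]]), "all_pairs")
        assignment, total = sa.solve_aap(graph)
        assert assignment[0] == 1 and total == pytest.approx(2.0)

    def test_identity_on_superposed_sets(self, rng):
        P = rng.uniform(-5, 5, (5, 3))
        assignment, total = sa.solve_aap(build_cost_graph(P, P))
        np.testing.assert_array_equal(assignment, np.arange(5))
        assert total == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = rng.integers(1, 6)
            m = rng.integers(n, 7)
            cost = rng.uniform(0, 10, (n, m))
            _, total = sa.solve_aap(sa.BipartiteCostGraph(cost, "all_pairs"))
            assert total == pytest.approx(brute_force_assignment(cost), abs=1e-10)

    def test_structural_infeasibility_raises(self):
        graph = sa.BipartiteCostGraph(np.array([[1.0, np.inf], [2.0, np.inf]]),
                                      "same_property")
        with pytest.raises(InfeasibleAssignmentError):
            sa.solve_aap(graph)


class TestMatchingDistance:
    def test_zero_at_planted_transform(self, clone_instance):
        inst = clone_instance
        f, assignment = sa.matching_distance(
            inst.P.coords, inst.Q.coords, inst.ground_truth
        )
        assert f == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_array_equal(assignment, inst.correspondence)

    def test_injectivity_forces_higher_value(self):
        P = np.array([[0.0, 0, 0], [2, 0, 0]])
        Q = np.array([[0.1, 0, 0], [5, 0, 0]])
        f, assignment = sa.matching_distance(P, Q, IDENTITY)
        np.testing.assert_array_equal(assignment, [0, 1])
        assert f == pytest.approx((0.01 + 9.0) / 2)  # 4.505
        g_closest = sa.objective(P, Q, IDENTITY, kind="closest")
        assert g_closest == pytest.approx((0.01 + 3.61) / 2)  # 1.81
        assert f > g_closest

    def test_single_points_give_squared_distance(self):
        f, _ = sa.matching_distance(np.zeros((1, 3)), np.array([[0.0, 3, 4]]), IDENTITY)
        assert f == pytest.approx(25.0)


class TestObjective:
    def test_closest_zero_on_superposed_sets(self, rng):
        P = rng.uniform(-5, 5, (6, 3))
        assert sa.objective(P, P, IDENTITY, kind="closest") == 0.0

    def test_matching_dominates_closest(self, rng):
        for _ in range(30):
            P = rng.uniform(-5, 5, (5, 3))
            Q = rng.uniform(-5, 5, (8, 3))
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            a = sa.TransformVector(q, rng.uniform(-3, 3, 3))
            assert (
                sa.objective(P, Q, a, kind="matching")
                >= sa.objective(P, Q, a, kind="closest") - 1e-12
            )

    def test_matching_equals_exhaustive_enumeration(self, rng):
        P = rng.uniform(-5, 5, (6, 3))
        Q = rng.uniform(-5, 5, (8, 3))
        from scipy.spatial.distance import cdist

        best = brute_force_assignment(cdist(P, Q, "sqeuclidean"))
        assert sa.objective(P, Q, IDENTITY, kind="matching") == pytest.approx(best / 6)

    def test_same_property_never_below_all_pairs(self, rng):
        labels = ["ACC", "DO", "ALI", "PI", "AD"]
        for _ in range(10):
            P = rng.uniform(-5, 5, (5, 3))
            Q = rng.uniform(-5, 5, (10, 3))
            lp = rng.choice(labels, 5)
            lq = np.concatenate([lp, rng.choice(labels, 5)])
            g_all = sa.objective(P, Q, IDENTITY, kind="matching")
            g_same = sa.objective(P, Q, IDENTITY, kind="matching",
                                  labels_P=lp, labels_Q=lq, mode="same_property")
            assert g_same >= g_all - 1e-12

    def test_composition_consistency(self, rng):
        """Moving the query frame and composing the candidate accordingly
        leaves both objectives unchanged."""
        P = rng.uniform(-5, 5, (6, 3))
        Q = rng.uniform(-5, 5, (9, 3))
        q1, q2 = rng.standard_normal(4), rng.standard_normal(4)
        a = sa.TransformVector(q1 / np.linalg.norm(q1), rng.uniform(-3, 3, 3))
        T = sa.TransformVector(q2 / np.linalg.norm(q2), rng.uniform(-3, 3, 3))
        for kind in ("closest", "matching"):
            g1 = sa.objective(P, Q, a, kind=kind)
            g2 = sa.objective(T.apply(P), Q, a.compose(T.inverse()), kind=kind)
            assert g1 == pytest.approx(g2, abs=1e-9)

    def test_hall_violation_detected_up_front(self):
        with pytest.raises(InfeasibleGraphError) as err:
            sa.make_objective(
                np.zeros((3, 3)), np.zeros((4, 3)), kind="matching",
                labels_P=["ALI", "ALI", "ALI"], labels_Q=["ALI", "ACC", "ACC", "DO"],
                mode="same_property",
            )
        assert err.value.label == "ALI"

    def test_relax_mode_always_feasible_and_penalized(self):
        P = np.zeros((2, 3))
        Q = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        g_relax = sa.objective(P, Q, IDENTITY, kind="matching",
                               labels_P=["PI", "PI"], labels_Q=["ACC", "ACC"],
                               mode="relax")
        g_all = sa.objective(P, Q, IDENTITY, kind="matching")
        assert np.isfinite(g_relax) and g_relax > g_all


class TestRefiner:
    def test_descends_on_objective(self, clone_instance, rng):
        inst = clone_instance
        g = sa.make_objective(inst.P.coords, inst.Q.coords, kind="matching")
        refine = make_refiner(inst.P.coords, inst.Q.coords, kind="matching")
        for _ in range(5):
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            a = sa.TransformVector(q, rng.uniform(-5, 5, 3))
            a_new, f_new = refine(a)
            assert f_new <= g(a) + 1e-12
            assert f_new == pytest.approx(g(a_new), abs=1e-10)

    def test_exact_from_near_optimal_start(self, clone_instance):
        inst = clone_instance
        refine = make_refiner(inst.P.coords, inst.Q.coords, kind="matching")
        # perturb the ground truth slightly; one polish should land on 0
        vec = inst.ground_truth.to_vector()
        vec[4:] += 0.05
        a0 = sa.normalize_candidate(vec)
        _, f = refine(a0)
        assert f == pytest.approx(0.0, abs=1e-18)
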