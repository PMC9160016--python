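"""Inference engine: conditionals, EM against brute-force oracles, truncation,
and the two-step assembly rules."""

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simplirec.complexes import SimplicialComplex2
from simplirec.dynamics import ContagionParams, simulate_contagion
from simplirec.inference import (
    EMOptions,
    approximate_neighbors,
    em_first_step,
    em_full,
    em_responsibilities,
    empirical_conditionals,
    gap_threshold,
    reconstruct,
)
from simplirec.inference import _design_for_target


class TestEmpiricalConditionals:
    def test_hand_counted_pair_frequency(self):
        """Node 1 active in 4 rows with node 0 susceptible; node 0 infected
        next in exactly one of them -> P = 1/4."""
        S = np.zeros((10, 2), dtype=int)
        S[[0, 2, 4, 6], 1] = 1       # node 1 infected, node 0 susceptible
        S[1, 0] = 1                  # the one follow-up infection
        cond = empirical_conditionals(S, 0)
        assert cond.pair_cond[1].p == pytest.approx(0.25)
        assert cond.pair_cond[1].count == 4

    def test_two_observations_one_hit_gives_half(self):
        """Two qualifying rows, one followed by infection -> 1/2."""
        S = np.array(
            [[0, 1], [1, 1], [0, 0], [0, 1], [0, 0]], dtype=int
        )
        cond = empirical_conditionals(S, 0)
        assert cond.pair_cond[1].p == pytest.approx(0.5)

    def test_triple_conditional_always_followed(self):
        """Both sources active twice with the target susceptible, target
        infected next both times -> conditional frequency 1."""
        S = np.array(
            [[0, 1, 1], [1, 1, 1], [0, 1, 1], [1, 0, 0]], dtype=int
        )
        cond = empirical_conditionals(S, 0, candidate_pairs=[(1, 2)])
        assert cond.triple_cond[(1, 2)].p == pytest.approx(1.0)

    def test_never_active_source_is_undefined(self):
        S = np.zeros((6, 3), dtype=int)
        S[:, 2] = [1, 0, 1, 0, 1, 0]
        cond = empirical_conditionals(S, 0)
        entry = cond.pair_cond[1]
        assert not entry.defined and entry.p == 0.0 and entry.count == 0

    def test_rejects_spin_alphabet(self):
        with pytest.raises(ValueError):
            empirical_conditionals(np.array([[1, -1], [1, 1]]), 0)


def brute_force_loglik(S, i, cand, theta, eps):
    """Direct evaluation of the Poisson log-likelihood by explicit loops;
    independent of the vectorized EM path."""
    S = np.asarray(S)
    T, _ = S.shape
    total = 0.0
    cond = empirical_conditionals(S, i)
    for t in range(T - 1):
        if S[t, i] != 0:
            continue
        rate = eps
        for a, j in enumerate(cand):
            if S[t, j] == 1 and cond.pair_cond[j].defined:
                rate += theta[a] * cond.pair_cond[j].p
        if S[t + 1, i] == 1:
            total += np.log(rate) if rate > 0 else -np.inf
        total -= rate
    return total


@pytest.fixture(scope="module")
def toy_matrix():
    c = SimplicialComplex2.from_iterables(4, [(0, 1), (0, 2), (1, 2)])
    p = ContagionParams(mu=1.0, rho0=0.5, T=60, seed=21, beta1=0.7, beta2=0.0)
    S = simulate_contagion(c, p, reseed_on_extinction=True)
    return S.values


class TestEM:
    def test_zero_events_gives_all_zeros(self):
        """A target that never transitions 0->1 zeroes every parameter after
        one iteration."""
        S = np.zeros((20, 3), dtype=int)
        S[::2, 1] = 1
        res = em_full(S, 0, [1, 2], [(1, 2)])
        assert all(v == 0 for v in res.p_pair.values())
        assert all(v == 0 for v in res.p_triple.values())
        assert res.epsilon == 0.0

    def test_loglik_trace_non_decreasing(self, toy_matrix):
        res = em_full(toy_matrix, 0, [1, 2, 3])
        trace = res.loglik_trace
        assert len(trace) >= 2
        assert (np.diff(trace) >= -1e-8).all()

    def test_matches_grid_search_oracle(self, toy_matrix):
        """The EM optimum matches a brute-force grid maximization of the
        Poisson likelihood: the independently coded likelihood agrees with
        the EM's own objective at the fitted point, the EM value dominates
        every grid point, and it exceeds the grid maximum by no more than
        the discretization error."""
        cand = [1, 2]
        res = em_full(toy_matrix, 0, cand, opts=EMOptions(n_restarts=3))
        em_ll = res.loglik_trace[-1]
        em_params = (res.p_pair[1], res.p_pair[2])
        # dual-route check: independent likelihood evaluation at the EM point
        ll_at_em = brute_force_loglik(toy_matrix, 0, cand, em_params, res.epsilon)
        assert ll_at_em == pytest.approx(em_ll, abs=1e-6)
        grid = np.arange(0.0, 1.2001, 0.05)
        eps_grid = np.arange(0.0, 0.8001, 0.02)
        best = max(
            brute_force_loglik(toy_matrix, 0, cand, (t1, t2), e)
            for t1, t2, e in product(grid, grid, eps_grid)
        )
        assert em_ll >= best - 1e-9
        assert em_ll - best <= 0.5  # grid undershoot bounded by its resolution

    def test_responsibilities_sum_to_one_at_events(self, toy_matrix):
        """E-step attributions share one denominator, so they sum to one at
        every infection event."""
        cand = [1, 2, 3]
        res = em_full(toy_matrix, 0, cand)
        X, y = _design_for_target(toy_matrix, 0, cand, [])
        theta = np.array([res.p_pair[j] for j in cand])
        rho = em_responsibilities(theta, res.epsilon, X[y > 0])
        assert np.allclose(rho.sum(axis=1), 1.0)

    def test_fixed_point_at_convergence(self, toy_matrix):
        """The converged parameters are stationary under one more
        multiplicative update."""
        cand = [1, 2, 3]
        res = em_full(toy_matrix, 0, cand)
        X, y = _design_for_target(toy_matrix, 0, cand, [])
        theta = np.array([res.p_pair[j] for j in cand])
        d = X.sum(axis=0)
        live = (theta > 1e-8) & (d > 0)
        X1 = X[y > 0]
        D = X1 @ theta + res.epsilon
        update = theta[live] * (X1[:, live].T @ (1.0 / D)) / d[live]
        assert np.allclose(update, theta[live], rtol=1e-4)

    def test_empty_triples_reproduces_first_step(self, toy_matrix):
        """Restricting the full EM to zero triple candidates is structurally
        identical to the first-step EM."""
        a = em_full(
            toy_matrix, 0, [1, 2, 3], (), rng=np.random.default_rng(5)
        )
        b = em_first_step(toy_matrix, 0, rng=np.random.default_rng(5))
        assert a.p_pair == b.p_pair
        assert a.epsilon == b.epsilon

    def test_star_graph_leaves_outrank_nonneighbors(self):
        """First-pass probabilities rank the true leaves of a star above
        unconnected nodes."""
        n = 12
        star = SimplicialComplex2.from_iterables(n, [(0, j) for j in range(1, 6)])
        p = ContagionParams(mu=1.0, rho0=0.4, T=3000, seed=33, beta1=0.5, beta2=0.0)
        S = simulate_contagion(star, p, reseed_on_extinction=True)
        res = em_first_step(S.values, 0)
        leaves = [res.p_pair[j] for j in range(1, 6)]
        others = [res.p_pair[j] for j in range(6, n)]
        assert min(leaves) > max(others)


def brute_force_gap(values):
    """Reference maximum-gap search by explicit enumeration."""
    pos = sorted((v for v in values if v > 0), reverse=True)
    if len(pos) < 2:
        return len(pos), 0.0
    best_l, best_score = 1, -np.inf
    for l in range(1, len(pos)):
        score = (pos[l - 1] / pos[l]) * (pos[l - 1] - pos[l])
        if score > best_score:
            best_l, best_score = l, score
    return best_l, (pos[best_l - 1] + pos[best_l]) / 2


class TestGapThreshold:
    def test_worked_example(self):
        t = gap_threshold([0.9, 0.8, 0.1, 0.05])
        assert t.split_index == 2
        assert t.threshold == pytest.approx(0.45)
        assert not t.degenerate

    def test_constant_list_degenerate(self):
        t = gap_threshold([0.5, 0.5, 0.5])
        assert t.split_index == 1
        assert t.threshold == pytest.approx(0.5)
        assert t.degenerate

    def test_zeros_do_not_matter(self):
        base = gap_threshold([0.9, 0.8, 0.1, 0.05])
        padded = gap_threshold([0.9, 0.8, 0.1, 0.05, 0.0, 0.0, 0.0])
        assert padded.split_index == base.split_index
        assert padded.threshold == base.threshold

    def test_fewer_than_two_positives(self):
        t = gap_threshold([0.3, 0.0])
        assert t.degenerate and t.threshold == 0.0 and t.split_index == 1
        t = gap_threshold([])
        assert t.degenerate and t.split_index == 0

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            gap_threshold([0.5, -0.1])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=30,
        )
    )
    def test_matches_brute_force(self, values):
        if sum(v > 0 for v in values) < 2:
            return
        t = gap_threshold(values)
        l_ref, thr_ref = brute_force_gap(values)
        assert t.split_index == l_ref
        assert t.threshold == pytest.approx(thr_ref)


class TestApproximateNeighbors:
    def _result(self, mapping):
        from simplirec.inference import InferenceResult

        return InferenceResult(
            target=0, p_pair=mapping, p_triple={}, epsilon=0.0,
            loglik_trace=np.array([0.0]), n_restarts_used=1,
        )

    def test_two_stage_gap_keeps_borderline_neighbors(self):
        """The main gap sits after the second value, but the permissive
        second threshold retains the two mid-range values as well."""
        vals = {1: 0.31, 2: 0.30, 3: 0.02, 4: 0.015, 5: 0.0002}
        nbrs = approximate_neighbors(self._result(vals))
        assert nbrs == {1, 2, 3, 4}

    def test_all_zero_gives_empty_set(self):
        nbrs = approximate_neighbors(self._result({1: 0.0, 2: 0.0}))
        assert nbrs == set()

    def test_superset_of_true_neighbors(self, medium_instance):
        """The first-step truncation is designed to retain every real
        neighbor; require that for at least 95% of nodes."""
        truth, _, rec = medium_instance
        ok = sum(
            truth.neighbors(i) <= rec.approximate_neighborhoods[i]
            for i in range(truth.n_nodes)
        )
        assert ok >= 0.95 * truth.n_nodes


class TestReconstruct:
    def test_all_zero_matrix_gives_empty_complex(self):
        S = np.zeros((50, 8), dtype=int)
        rec = reconstruct(S)
        assert len(rec.complex.edges) == 0
        assert len(rec.complex.triangles) == 0

    def test_end_to_end_recovery(self, medium_instance):
        """Two-step reconstruction on a simulated random complex recovers
        edges and triangles with high fidelity."""
        truth, _, rec = medium_instance
        from simplirec.evaluation import score

        e = score(truth, rec.complex, "edges")
        t = score(truth, rec.complex, "triangles")
        assert e.recall >= 0.95
        assert e.f1 >= 0.85
        assert t.f1 >= 0.9

    def test_tuple_unpacking(self, medium_instance):
        _, _, rec = medium_instance
        complex_, results = rec
        assert complex_ is rec.complex and results is rec.node_results

    def test_relabeling_equivariance(self):
        """Reconstructing a column-permuted record yields the identically
        relabeled complex (deterministic single-restart EM)."""
        truth = SimplicialComplex2.from_iterables(
            12,
            [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7),
             (7, 8), (8, 9), (9, 10), (10, 11), (0, 11)],
            [(0, 1, 2)],
        )
        p = ContagionParams(alpha=0.8, omega=2.4, mu=1.0, rho0=0.3, T=3000, seed=3)
        S = simulate_contagion(truth, p, reseed_on_extinction=True)
        opts = EMOptions(n_restarts=1)
        rec = reconstruct(S.values, opts=opts)
        perm = np.roll(np.arange(12), 5)
        S_perm = S.values[:, np.argsort(perm)]
        rec_perm = reconstruct(S_perm, opts=opts)
        assert rec_perm.complex.edges == rec.complex.relabel(perm).edges
        assert rec_perm.complex.triangles == rec.complex.relabel(perm).triangles
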