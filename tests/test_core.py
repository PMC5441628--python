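import time

import numpy as np
import pytest

from sscd import (
    ConstraintSet,
    FactorModel,
    Hyperparams,
    Network,
    encode_signed,
    fit,
    hard_assign,
    laplacian,
    nmi,
    objective,
    sample_constraints,
    update_step,
)
from sscd.core import init_h

from conftest import random_network, random_signed


def _raw_signed(A: np.ndarray):
    """A SignedNetwork stand-in carrying an arbitrary symmetric real A.

    The validated types require binary adjacency; exact-factorization
    fixed points (A = HHᵀ) need real entries, and the optimizer itself
    only reads the three matrices.
    """
    from types import SimpleNamespace

    n = A.shape[0]
    return SimpleNamespace(
        base=SimpleNamespace(adjacency=A, n_nodes=n),
        positive=np.zeros((n, n)),
        negative=np.zeros((n, n)),
        n_nodes=n,
    )


class TestLaplacian:
    def test_zero_positive_matrix(self):
        L, D = laplacian(np.zeros((4, 4)))
        assert not L.any() and not D.any()

    def test_path_graph(self):
        Ap = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        L, D = laplacian(Ap)
        assert np.array_equal(np.diag(D), [1, 2, 1])
        assert np.array_equal(L, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_zero_and_psd(self, seed):
        Ap = random_network(np.random.default_rng(seed), 12, p=0.4).adjacency
        L, _ = laplacian(Ap)
        assert np.allclose(L.sum(axis=1), 0.0)
        assert np.linalg.eigvalsh(L).min() >= -1e-10


def naive_objective(signed, H, hyper):
    """Term-by-term scalar-loop evaluation of the combined objective."""
    n, k = H.shape
    A, An, Ap = signed.base.adjacency, signed.negative, signed.positive
    frob = sum(
        (A[i, j] - sum(H[i, c] * H[j, c] for c in range(k))) ** 2
        for i in range(n)
        for j in range(n)
    )
    tr_neg = sum(
        H[i, c] * An[i, j] * H[j, c] for i in range(n) for j in range(n) for c in range(k)
    )
    d = Ap.sum(axis=1)
    tr_lap = sum(
        H[i, c] * ((d[i] if i == j else 0.0) - Ap[i, j]) * H[j, c]
        for i in range(n)
        for j in range(n)
        for c in range(k)
    )
    return frob + hyper.gamma1 * tr_neg + hyper.gamma2 * tr_lap


class TestObjective:
    def test_zero_h_gives_twice_edge_count(self):
        net = random_network(np.random.default_rng(0), 10, p=0.3)
        sn = encode_signed(net, ConstraintSet())
        hyper = Hyperparams(k=3)
        assert objective(sn, np.zeros((10, 3)), hyper) == pytest.approx(
            2 * net.n_edges
        )

    def test_exact_factorization_is_zero(self):
        sn = _raw_signed(np.array([[1.0, 1.0], [1.0, 1.0]]))
        H = np.array([[1.0], [1.0]])  # A = HH^T exactly
        assert objective(sn, H, Hyperparams(k=1, gamma1=0.0, gamma2=0.0)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop(self, seed):
        rng = np.random.default_rng(seed)
        sn, _ = random_signed(rng, 8)
        hyper = Hyperparams(k=3, gamma1=0.7, gamma2=1.3)
        H = rng.uniform(0, 1, (8, 3))
        assert objective(sn, H, hyper) == pytest.approx(
            naive_objective(sn, H, hyper), abs=1e-10
        )

    def test_shape_mismatch(self):
        sn, _ = random_signed(np.random.default_rng(0), 6)
        with pytest.raises(ValueError):
            objective(sn, np.ones((5, 2)), Hyperparams(k=2))


class TestUpdateStep:
    def test_hand_evaluated_single_edge(self):
        net = Network(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        sn = encode_signed(net, ConstraintSet())
        hyper = Hyperparams(k=1, eps=0.0)
        _, D = laplacian(sn.positive)
        H = np.array([[1.0], [1.0]])
        H_new = update_step(H, sn, D, hyper)
        # numerator 2AH = [2,2]; denominator 2HH^T H = [4,4]
        assert np.allclose(H_new, [[0.5], [0.5]])

    def test_kkt_fixed_point_unchanged(self):
        """A factorization with vanishing gradient (A = HHᵀ) is a fixed point."""
        rng = np.random.default_rng(1)
        H = rng.uniform(0.5, 1.5, (6, 2))
        sn = _raw_signed(H @ H.T)  # AH = HH^T H exactly
        hyper = Hyperparams(k=2, gamma1=0.0, gamma2=0.0, eps=0.0)
        _, D = laplacian(sn.positive)
        H_new = update_step(H, sn, D, hyper)
        assert np.max(np.abs(H_new - H)) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegativity_over_100_updates(self, seed):
        rng = np.random.default_rng(seed)
        sn, _ = random_signed(rng, 20)
        hyper = Hyperparams(k=4, gamma1=0.8, gamma2=0.8, seed=seed)
        _, D = laplacian(sn.positive)
        H = init_h(20, 4, seed)
        for _ in range(100):
            H = update_step(H, sn, D, hyper)
            assert (H >= 0).all()


class TestFit:
    def test_update_rule_reduces_to_textbook_symnmf(self, easy_instance):
        """With both penalties off the update step IS H·(2AH)/(2HHᵀH)."""
        net, _ = easy_instance
        sn = encode_signed(net, ConstraintSet())
        hyper = Hyperparams(k=2, gamma1=0.0, gamma2=0.0, eps=0.0)
        _, D = laplacian(sn.positive)
        A = net.adjacency
        rng = np.random.default_rng(8)
        for _ in range(5):
            H = rng.uniform(0.01, 1, (net.n_nodes, 2))
            expected = H * (2 * (A @ H)) / (2 * (H @ (H.T @ H)))
            assert np.array_equal(update_step(H, sn, D, hyper), expected)

    def test_fit_matches_plain_symnmf_reference(self, easy_instance):
        """fit(γ1=γ2=0) tracks an independently coded unconstrained
        symmetric-NMF loop (same descent safeguard) iteration-for-iteration."""
        net, _ = easy_instance
        sn = encode_signed(net, ConstraintSet())
        hyper = Hyperparams(k=2, gamma1=0.0, gamma2=0.0, seed=4, eps=0.0,
                            max_iter=50, tol=1e-15)
        model = fit(sn, hyper)

        A = net.adjacency
        obj = lambda H: float(np.sum((A - H @ H.T) ** 2))
        H = init_h(net.n_nodes, 2, seed=4)
        for _ in range(model.n_iter):
            H_full = H * (2 * (A @ H)) / (2 * (H @ (H.T @ H)))
            prev = obj(H)
            slack = 1e-12 * max(abs(prev), 1.0)
            if obj(H_full) > prev + slack:
                beta = 0.5
                while True:
                    H_try = (1 - beta) * H + beta * H_full
                    if obj(H_try) <= prev + slack:
                        break
                    beta *= 0.5
                H = H_try
            else:
                H = H_full
        assert np.array_equal(H, model.H)

    def test_easy_planted_partition_recovered(self, easy_instance):
        net, truth = easy_instance
        sn = encode_signed(net, ConstraintSet())
        model = fit(sn, Hyperparams(k=2, seed=0))
        assert nmi(hard_assign(model), truth) == pytest.approx(1.0)

    @pytest.mark.parametrize("g1, g2", [(0, 0), (0.5, 1), (5, 5)])
    def test_monotone_descent(self, g1, g2):
        rng = np.random.default_rng(hash((g1, g2)) % 2**32)
        sn, _ = random_signed(rng, 15)
        model = fit(sn, Hyperparams(k=3, gamma1=g1, gamma2=g2, seed=1, tol=1e-15,
                                    max_iter=80))
        tr = np.array(model.objective_trace)
        rel_inc = (tr[1:] - tr[:-1]) / np.maximum(tr[:-1], 1e-12)
        assert rel_inc.max() <= 1e-8

    def test_k_larger_than_n_rejected(self):
        sn, _ = random_signed(np.random.default_rng(0), 4)
        with pytest.raises(ValueError):
            fit(sn, Hyperparams(k=5))

    def test_multi_restart_returns_best_objective(self):
        sn, _ = random_signed(np.random.default_rng(3), 12)
        hyper = Hyperparams(k=3, seed=0)
        best = fit(sn, hyper, n_restarts=4)
        single = fit(sn, hyper)
        assert best.objective_trace[-1] <= single.objective_trace[-1] + 1e-9

    def test_update_cost_scales_quadratically_in_n(self):
        """Per-iteration cost is O(n²k): doubling n multiplies time ~4x."""

        def best_time(n):
            A = random_network(np.random.default_rng(0), n, p=0.05).adjacency
            net = Network([str(i) for i in range(n)], A)
            sn = encode_signed(net, ConstraintSet())
            hyper = Hyperparams(k=5, seed=0)
            H = init_h(n, 5, 0)
            _, D = laplacian(sn.positive)
            best = np.inf
            for _ in range(7):
                t0 = time.perf_counter()
                for _ in range(20):
                    update_step(H, sn, D, hyper)
                best = min(best, time.perf_counter() - t0)
            return best

        ratio = best_time(400) / best_time(200)
        assert 2.5 <= ratio <= 6.0


class TestGradient:
    @pytest.mark.parametrize("seed", range(3))
    def test_finite_difference_matches_analytic(self, seed):
        """Central differences of the objective match the analytic gradient."""
        rng = np.random.default_rng(seed)
        sn, _ = random_signed(rng, 5, p=0.5)
        hyper = Hyperparams(k=2, gamma1=0.9, gamma2=1.1)
        H = rng.uniform(0.2, 1.0, (5, 2))
        A, An = sn.base.adjacency, sn.negative
        L, _ = laplacian(sn.positive)
        analytic = -4 * A @ H + 4 * H @ (H.T @ H) + 2 * hyper.gamma1 * (An @ H) \
            + 2 * hyper.gamma2 * (L @ H)
        h = 1e-6
        for i in range(5):
            for c in range(2):
                Hp, Hm = H.copy(), H.copy()
                Hp[i, c] += h
                Hm[i, c] -= h
                fd = (objective(sn, Hp, hyper) - objective(sn, Hm, hyper)) / (2 * h)
                assert fd == pytest.approx(analytic[i, c], abs=1e-5, rel=1e-5)


class TestHardAssign:
    def test_row_argmax(self):
        part = hard_assign(FactorModel(H=np.array([[0.1, 0.9], [0.8, 0.2]])))
        assert part.membership.tolist() == [1, 0]

    def test_tie_breaks_to_lowest_index(self):
        part = hard_assign(FactorModel(H=np.array([[0.5, 0.5]])))
        assert part.membership.tolist() == [0]

    def test_zero_row_warns_and_assigns_first(self, caplog):
        with caplog.at_level("WARNING"):
            part = hard_assign(FactorModel(H=np.array([[0.0, 0.0], [0.1, 0.6]])))
        assert part.membership.tolist() == [0, 1]
        assert any("all-zero" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_to_row_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.uniform(0.01, 1, (12, 3))
        scales = rng.uniform(0.5, 10, 12)
        a = hard_assign(FactorModel(H=H))
        b = hard_assign(FactorModel(H=H * scales[:, None]))
        assert np.array_equal(a.membership, b.membership)


class TestConstraintResponsiveness:
    def test_must_link_priors_help_on_ambiguous_fixture(self, ambiguous_instance):
        """Priors raise mean NMI over paired seeds on a hard instance."""
        net, truth = ambiguous_instance
        sn0 = encode_signed(net, ConstraintSet())
        gains_must, gains_cannot = [], []
        for s in range(8):
            base = nmi(hard_assign(fit(sn0, Hyperparams(k=3, seed=s))), truth)
            cs_m = sample_constraints(truth, 0.2, 0.0, seed=s)
            with_m = nmi(
                hard_assign(fit(encode_signed(net, cs_m), Hyperparams(k=3, seed=s))),
                truth,
            )
            cs_c = sample_constraints(truth, 0.0, 0.1, seed=s)
            with_c = nmi(
                hard_assign(fit(encode_signed(net, cs_c), Hyperparams(k=3, seed=s))),
                truth,
            )
            gains_must.append(with_m - base)
            gains_cannot.append(with_c - base)
        assert np.mean(gains_must) > 0
        assert np.mean(gains_cannot) > 0
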