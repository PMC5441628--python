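"""Constrained symmetric NMF for semi-supervised community detection.

The method factorizes a symmetric adjacency matrix ``A ≈ H Hᵀ`` with
``H ≥ 0`` an n×k membership-strength matrix, while two graph
regularizers steer the factorization with prior knowledge encoded as a
signed network:

    min_{H ≥ 0}  ‖A − H Hᵀ‖²_F  +  γ1 · tr(Hᵀ Aⁿ H)  +  γ2 · tr(Hᵀ L H)

``tr(Hᵀ Aⁿ H)`` penalizes placing negatively linked (cannot-link) nodes
in the same community; ``tr(Hᵀ L H)``, with ``L = D − A^p`` the Laplacian
of the positive (must-link) network, penalizes separating positively
linked nodes.  Both terms arise as continuous relaxations of discrete
ratio-cut-style objectives over the hard indicator vectors (the relaxed
indicator takes value ``1/|π_c|`` inside community ``c``), and the relaxed
problem is solved by the multiplicative fixed-point update derived from
the KKT conditions:

    H_ij ← H_ij · (2 A H + γ2 A^p H)_ij / (2 H Hᵀ H + γ1 Aⁿ H + γ2 D H)_ij

Each iteration costs O(n²k).  Hard communities are read off row-wise:
node i joins the community with the largest entry of row H_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constraints import SignedNetwork
from .graph_io import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "FactorModel",
    "laplacian",
    "objective",
    "update_step",
    "init_h",
    "monotone_mu_fit",
    "fit",
    "hard_assign",
    "detect_communities",
]


@dataclass(frozen=True)
class Hyperparams:
    """Settings for :func:`fit`.

    Parameters
    ----------
    k : int
        Number of communities (columns of H).
    gamma1 : float
        Weight of the negative-link penalty tr(Hᵀ Aⁿ H); 0 disables it.
    gamma2 : float
        Weight of the positive-link Laplacian penalty tr(Hᵀ L H).
    max_iter : int
        Iteration cap for the multiplicative update.
    tol : float
        Relative objective-change threshold declaring convergence.
    seed : int or None
        Seed for the uniform (0.01, 1) initialization of H.
    eps : float
        Tiny constant added to the update denominator to guard 0/0.
        Set to 0 for exact fixed-point arithmetic.
    """

    k: int
    gamma1: float = 1.0
    gamma2: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    seed: int | None = None
    eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma1 and gamma2 must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")


@dataclass
class FactorModel:
    """A fitted nonnegative factor H with its optimization trace."""

    H: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    n_backtracks: int = 0

    @property
    def k(self) -> int:
        return self.H.shape[1]


def laplacian(positive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Graph Laplacian of the positive-link matrix.

    Returns ``(L, D)`` with ``D_ii = Σ_j A^p_ij`` and ``L = D − A^p``.
    """
    positive = np.asarray(positive, dtype=float)
    D = np.diag(positive.sum(axis=1))
    return D - positive, D


def objective(signed: SignedNetwork, H: np.ndarray, hyper: Hyperparams) -> float:
    """Value of ‖A − HHᵀ‖²_F + γ1 tr(Hᵀ Aⁿ H) + γ2 tr(Hᵀ L H)."""
    H = np.asarray(H, dtype=float)
    n = signed.n_nodes
    if H.shape != (n, hyper.k):
        raise ValueError(f"H shape {H.shape} incompatible with n={n}, k={hyper.k}")
    A = signed.base.adjacency
    R = A - H @ H.T
    value = float(np.sum(R * R))
    if hyper.gamma1:
        value += hyper.gamma1 * float(np.sum(H * (signed.negative @ H)))
    if hyper.gamma2:
        L, _ = laplacian(signed.positive)
        value += hyper.gamma2 * float(np.sum(H * (L @ H)))
    return value


def update_step(
    H: np.ndarray,
    signed: SignedNetwork,
    D: np.ndarray,
    hyper: Hyperparams,
) -> np.ndarray:
    """One multiplicative update of H.

    Splits the gradient −4AH + 4HHᵀH + 2γ1 AⁿH + 2γ2 LH into the
    attractive parts (numerator) and repulsive parts (denominator), so
    nonnegativity is preserved automatically:

        H ← H · (2AH + γ2 A^p H) / (2HHᵀH + γ1 Aⁿ H + γ2 D H + eps)
    """
    A = signed.base.adjacency
    numer = 2.0 * (A @ H)
    denom = 2.0 * (H @ (H.T @ H))
    if hyper.gamma2:
        numer += hyper.gamma2 * (signed.positive @ H)
        denom += hyper.gamma2 * (D @ H)
    if hyper.gamma1:
        denom += hyper.gamma1 * (signed.negative @ H)
    H_new = H * numer / (denom + hyper.eps)
    if not np.isfinite(H_new).all():
        bad = np.argwhere(~np.isfinite(H_new))
        raise FloatingPointError(
            f"non-finite entries after update at (row, col): {bad[:5].tolist()}"
        )
    return H_new


def init_h(n: int, k: int, seed: int | None) -> np.ndarray:
    """Strictly positive start, uniform on (0.01, 1).

    Strict positivity matters: a multiplicative update can never revive
    an entry that starts at exactly zero.
    """
    rng = np.random.default_rng(seed)
    return rng.uniform(0.01, 1.0, size=(n, k))


def monotone_mu_fit(step_fn, obj_fn, H0: np.ndarray, hyper: Hyperparams) -> FactorModel:
    """Safeguarded multiplicative-update loop shared by all NMF variants.

    Takes the full multiplicative step ``step_fn(H)``; if the objective
    would increase, backtracks along the segment from H to the full step.
    That segment is always a descent direction for these split-gradient
    rules (⟨∇f, H_full − H⟩ = −2 Σ H (N − D)²/D ≤ 0 with N/D the
    numerator/denominator of the rule), so halving the step restores
    descent while the fixed points of the rule are unaffected.  Stops
    when the relative objective change drops below ``hyper.tol`` or at
    ``hyper.max_iter``.
    """
    H = np.array(H0, dtype=float)
    if np.any(H < 0):
        raise ValueError("initial H must be nonnegative")
    trace = [obj_fn(H)]
    converged = False
    n_iter = 0
    n_backtracks = 0
    for n_iter in range(1, hyper.max_iter + 1):
        H_full = step_fn(H)
        f = obj_fn(H_full)
        if not np.isfinite(f):
            raise FloatingPointError(f"objective became non-finite at iter {n_iter}")
        prev = trace[-1]
        slack = 1e-12 * max(abs(prev), 1.0)
        if f > prev + slack:
            n_backtracks += 1
            beta = 0.5
            H_try = H
            for _ in range(60):
                H_try = (1.0 - beta) * H + beta * H_full
                f = obj_fn(H_try)
                if f <= prev + slack:
                    break
                beta *= 0.5
            H = H_try
        else:
            H = H_full
        trace.append(f)
        if abs(f - prev) / max(abs(prev), 1e-12) < hyper.tol:
            converged = True
            break
    return FactorModel(
        H=H,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        n_backtracks=n_backtracks,
    )


def fit(
    signed: SignedNetwork,
    hyper: Hyperparams,
    H0: np.ndarray | None = None,
    n_restarts: int = 1,
) -> FactorModel:
    """Run the multiplicative update to convergence.

    Iterates until the relative objective change drops below
    ``hyper.tol`` or ``hyper.max_iter`` is reached.  With
    ``n_restarts > 1`` the fit is repeated from fresh seeded starts and
    the lowest-objective model is returned.
    """
    n = signed.n_nodes
    if hyper.k > n:
        raise ValueError(f"k={hyper.k} exceeds number of nodes n={n}")
    if n_restarts > 1:
        seeds = np.random.default_rng(hyper.seed).integers(0, 2**31, size=n_restarts)
        models = [
            fit(signed, replace(hyper, seed=int(s)), H0=H0, n_restarts=1)
            for s in seeds
        ]
        return min(models, key=lambda m: m.objective_trace[-1])

    H0 = np.array(H0, dtype=float) if H0 is not None else init_h(n, hyper.k, hyper.seed)
    _, D = laplacian(signed.positive)
    return monotone_mu_fit(
        lambda H: update_step(H, signed, D, hyper),
        lambda H: objective(signed, H, hyper),
        H0,
        hyper,
    )


def hard_assign(model: FactorModel) -> Partition:
    """Harden H row-wise: node i joins argmax_j H_ij (ties → lowest index)."""
    H = model.H
    zero_rows = np.flatnonzero(~H.any(axis=1))
    if zero_rows.size:
        logger.warning(
            "%d all-zero rows in H assigned to community 1: %s",
            zero_rows.size,
            zero_rows[:10].tolist(),
        )
    return Partition(np.argmax(H, axis=1), model.k)


def detect_communities(signed: SignedNetwork, hyper: Hyperparams) -> tuple[Partition, FactorModel]:
    """Convenience wrapper: fit then harden."""
    model = fit(signed, hyper)
    return hard_assign(model), model
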