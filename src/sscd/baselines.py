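"""Comparison methods: three established semi-supervised NMF variants.

All three factorize the topology ``A ≈ HHᵀ`` like the main method but
fold the pairwise priors in differently:

* **NMF_LSE** — adds a must-link Laplacian penalty ``λ·tr(Hᵀ L_m H)``
  with ``L_m`` the Laplacian of the must-link graph alone; cannot-link
  priors are modelled as absent edges and therefore have no effect.
  Default ``λ = 1``.
* **PMF** — a single penalty ``tr(Hᵀ Θ H)`` with ``Θ_ij = δ`` on cannot
  pairs, ``−θ`` on must pairs and 0 otherwise (defaults ``δ = 2``,
  ``θ = 1``); the multiplicative rule routes Θ's positive part to the
  denominator and its negative part to the numerator.  Only the
  single-network symmetric analogue of the original multi-type method is
  implemented, which is what a head-to-head comparison needs.
* **SNMF_SS** — rewrites the adjacency as ``Ã = A − α·M + β·C`` (``M``,
  ``C`` the binary must/cannot matrices; defaults ``α = 0.001``,
  ``β = 0.1``) and runs plain symmetric NMF on Ã.  As printed the
  formula subtracts weight from must-linked pairs and adds it to cannot
  pairs; it is implemented exactly so, with ``flip_signs=True``
  available for the intuitive orientation.  Negative Ã entries are
  clamped to 0 before factorization, since a multiplicative update
  cannot accept a mixed-sign target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import core
from .constraints import ConstraintSet, SignedNetwork, _link_matrix, encode_signed
from .core import FactorModel, Hyperparams
from .graph_io import Network

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineConfig",
    "fit_plain_symnmf",
    "fit_nmf_lse",
    "fit_pmf",
    "fit_snmf_ss",
    "fit_method",
    "METHODS",
]


@dataclass(frozen=True)
class BaselineConfig:
    lse_weight: float = 1.0
    delta: float = 2.0  # PMF cannot-link violation penalty
    theta: float = 1.0  # PMF must-link violation penalty
    alpha: float = 0.001  # SNMF_SS must-link weight
    beta: float = 0.1  # SNMF_SS cannot-link weight
    flip_signs: bool = False  # SNMF_SS: use Ã = A + αM − βC instead

    def __post_init__(self) -> None:
        for name in ("lse_weight", "delta", "theta", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _plain_signed(network: Network) -> SignedNetwork:
    return encode_signed(network, ConstraintSet())


def fit_plain_symnmf(network: Network, hyper: Hyperparams) -> FactorModel:
    """Unconstrained symmetric NMF, min ‖A − HHᵀ‖²_F (the 0% collapse point)."""
    return core.fit(_plain_signed(network), replace(hyper, gamma1=0.0, gamma2=0.0))


def fit_nmf_lse(
    network: Network,
    constraints: ConstraintSet,
    k: int,
    config: BaselineConfig = BaselineConfig(),
    hyper: Hyperparams | None = None,
) -> FactorModel:
    """Must-link Laplacian regularization; cannot-links are ignored.

    Structurally identical to the main objective with γ1 = 0,
    γ2 = ``lse_weight`` and A^p the must-link graph.
    """
    hyper = hyper or Hyperparams(k=k)
    signed = encode_signed(network, ConstraintSet(must=constraints.must))
    return core.fit(
        signed, replace(hyper, k=k, gamma1=0.0, gamma2=config.lse_weight)
    )


def _pmf_theta(constraints: ConstraintSet, n: int, config: BaselineConfig) -> np.ndarray:
    M = _link_matrix(constraints.must, n)
    C = _link_matrix(constraints.cannot, n)
    return config.delta * C - config.theta * M


def pmf_objective(
    network: Network, constraints: ConstraintSet, H: np.ndarray, config: BaselineConfig
) -> float:
    """‖A − HHᵀ‖²_F + tr(Hᵀ Θ H)."""
    A = network.adjacency
    R = A - H @ H.T
    theta = _pmf_theta(constraints, network.n_nodes, config)
    return float(np.sum(R * R)) + float(np.sum(H * (theta @ H)))


def fit_pmf(
    network: Network,
    constraints: ConstraintSet,
    k: int,
    config: BaselineConfig = BaselineConfig(),
    hyper: Hyperparams | None = None,
) -> FactorModel:
    """Penalized matrix factorization with the signed penalty matrix Θ."""
    hyper = hyper or Hyperparams(k=k)
    hyper = replace(hyper, k=k)
    n = network.n_nodes
    if k > n:
        raise ValueError(f"k={k} exceeds number of nodes n={n}")
    A = network.adjacency
    theta_pos = config.delta * _link_matrix(constraints.cannot, n)
    theta_neg = config.theta * _link_matrix(constraints.must, n)

    def step(H: np.ndarray) -> np.ndarray:
        numer = 2.0 * (A @ H) + theta_neg @ H
        denom = 2.0 * (H @ (H.T @ H)) + theta_pos @ H + hyper.eps
        return H * numer / denom

    return core.monotone_mu_fit(
        step,
        lambda H: pmf_objective(network, constraints, H, config),
        core.init_h(n, k, hyper.seed),
        hyper,
    )


def snmf_ss_adjacency(
    network: Network, constraints: ConstraintSet, config: BaselineConfig = BaselineConfig()
) -> np.ndarray:
    """Modified adjacency Ã = A − α·M + β·C, clamped at 0."""
    n = network.n_nodes
    M = _link_matrix(constraints.must, n)
    C = _link_matrix(constraints.cannot, n)
    a, b = (config.alpha, config.beta) if not config.flip_signs else (
        -config.alpha,
        -config.beta,
    )
    A_mod = network.adjacency - a * M + b * C
    n_clamped = int(np.count_nonzero(A_mod < 0))
    if n_clamped:
        logger.info("SNMF_SS: clamped %d negative entries of Ã to 0", n_clamped)
    return np.maximum(A_mod, 0.0)


def fit_snmf_ss(
    network: Network,
    constraints: ConstraintSet,
    k: int,
    config: BaselineConfig = BaselineConfig(),
    hyper: Hyperparams | None = None,
) -> FactorModel:
    """Plain symmetric NMF on the prior-modified adjacency Ã."""
    hyper = hyper or Hyperparams(k=k)
    hyper = replace(hyper, k=k, gamma1=0.0, gamma2=0.0)
    A_mod = snmf_ss_adjacency(network, constraints, config)
    n = network.n_nodes
    if k > n:
        raise ValueError(f"k={k} exceeds number of nodes n={n}")

    def step(H: np.ndarray) -> np.ndarray:
        return H * (2.0 * (A_mod @ H)) / (2.0 * (H @ (H.T @ H)) + hyper.eps)

    return core.monotone_mu_fit(
        step,
        lambda H: float(np.sum((A_mod - H @ H.T) ** 2)),
        core.init_h(n, k, hyper.seed),
        hyper,
    )


def fit_method(
    method: str,
    network: Network,
    constraints: ConstraintSet,
    k: int,
    hyper: Hyperparams | None = None,
    config: BaselineConfig = BaselineConfig(),
) -> FactorModel:
    """Dispatch by method name: 'sscd' or one of the baselines."""
    hyper = hyper or Hyperparams(k=k)
    hyper = replace(hyper, k=k)
    if method == "sscd":
        return core.fit(encode_signed(network, constraints), hyper)
    if method == "nmf_lse":
        return fit_nmf_lse(network, constraints, k, config, hyper)
    if method == "pmf":
        return fit_pmf(network, constraints, k, config, hyper)
    if method == "snmf_ss":
        return fit_snmf_ss(network, constraints, k, config, hyper)
    raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")


METHODS = ("sscd", "nmf_lse", "pmf", "snmf_ss")
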