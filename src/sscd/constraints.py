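"""Pairwise prior constraints and their signed-network encoding.

Must-link constraints (two nodes belong to the same community) become
positive links and cannot-link constraints (two nodes belong to different
communities) become negative links, giving a signed network
``(A, A^p, A^n)`` over one node set.  Prior *budgets* are counted against
the ground truth: with community sizes ``N_1..N_K`` there are

    M_pairs = Σ_k N_k (N_k − 1) / 2        intra-community (must-link) pairs
    C_pairs = Σ_{i<j} N_i N_j              inter-community (cannot-link) pairs

and a "p% must-link prior" experiment samples ``floor(p · M_pairs)`` intra
pairs uniformly without replacement (likewise for cannot-link priors).
Constraint pairs are stored canonically with ``i < j``.

The original topology stays solely in ``A``; ``A^p`` carries only prior
must-links.  ``encode_signed(fold_topology=True)`` additionally ORs the
topological edges into ``A^p`` for users who want the original links
treated as positive links, but this is off by default because the
objective and update rule weight ``A`` and ``A^p`` separately.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .graph_io import GraphParseError, Network, Partition

__all__ = [
    "ConstraintSet",
    "SignedNetwork",
    "ConstraintConflictError",
    "max_must_pairs",
    "max_cannot_pairs",
    "sample_constraints",
    "encode_signed",
    "read_constraints",
    "write_constraints",
]

Pair = tuple[int, int]


class ConstraintConflictError(ValueError):
    """A pair is declared both must-link and cannot-link."""


def _canonical(pairs) -> frozenset[Pair]:
    out = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-pair ({i},{i}) is not a valid constraint")
        out.add((min(i, j), max(i, j)))
    return frozenset(out)


@dataclass(frozen=True)
class ConstraintSet:
    """Must-link and cannot-link node-index pairs, canonicalized to i < j."""

    must: frozenset[Pair] = frozenset()
    cannot: frozenset[Pair] = frozenset()
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "must", _canonical(self.must))
        object.__setattr__(self, "cannot", _canonical(self.cannot))
        overlap = self.must & self.cannot
        if overlap:
            raise ConstraintConflictError(
                f"pairs declared both must and cannot: {sorted(overlap)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.must) + len(self.cannot)

    @property
    def n_must(self) -> int:
        return len(self.must)

    @property
    def n_cannot(self) -> int:
        return len(self.cannot)


@dataclass
class SignedNetwork:
    """Topology ``A`` plus prior links ``A^p`` (positive) and ``A^n`` (negative)."""

    base: Network
    positive: np.ndarray
    negative: np.ndarray

    def __post_init__(self) -> None:
        n = self.base.n_nodes
        for name in ("positive", "negative"):
            M = np.asarray(getattr(self, name), dtype=float)
            if M.shape != (n, n):
                raise ValueError(f"{name} matrix shape {M.shape} != ({n}, {n})")
            if not np.array_equal(M, M.T):
                raise ValueError(f"{name} matrix must be symmetric")
            if np.any(np.diag(M) != 0):
                raise ValueError(f"{name} matrix must have zero diagonal")
            if not np.isin(M, (0.0, 1.0)).all():
                raise ValueError(f"{name} matrix entries must be 0 or 1")
            setattr(self, name, M)
        if np.any((self.positive != 0) & (self.negative != 0)):
            raise ConstraintConflictError("a pair is both a positive and a negative link")

    @property
    def n_nodes(self) -> int:
        return self.base.n_nodes


def max_must_pairs(partition: Partition) -> int:
    """Budget of intra-community pairs, Σ_k N_k(N_k−1)/2."""
    sizes = partition.sizes()
    return int((sizes * (sizes - 1) // 2).sum())


def max_cannot_pairs(partition: Partition) -> int:
    """Budget of inter-community pairs, Σ_{i<j} N_i N_j."""
    sizes = [int(s) for s in partition.sizes()]
    return sum(
        sizes[i] * sizes[j] for i in range(len(sizes)) for j in range(i + 1, len(sizes))
    )


def _pair_pools(partition: Partition) -> tuple[np.ndarray, np.ndarray]:
    """All (i<j) pairs split into intra- and inter-community pools."""
    n = partition.n_nodes
    ii, jj = np.triu_indices(n, k=1)
    intra = partition.membership[ii] == partition.membership[jj]
    pairs = np.column_stack([ii, jj])
    return pairs[intra], pairs[~intra]


def sample_constraints(
    partition: Partition,
    pct_must: float,
    pct_cannot: float,
    seed: int | None = None,
) -> ConstraintSet:
    """Sample priors uniformly without replacement from the ground truth.

    ``floor(pct_must · M_pairs)`` intra-community pairs become must-links
    and ``floor(pct_cannot · C_pairs)`` inter-community pairs become
    cannot-links.  Deterministic for a given seed.
    """
    for name, pct in (("pct_must", pct_must), ("pct_cannot", pct_cannot)):
        if not 0.0 <= pct <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {pct}")
    intra, inter = _pair_pools(partition)
    n_must = int(np.floor(pct_must * len(intra)))
    n_cannot = int(np.floor(pct_cannot * len(inter)))
    rng = np.random.default_rng(seed)
    must = intra[rng.choice(len(intra), size=n_must, replace=False)] if n_must else []
    cannot = (
        inter[rng.choice(len(inter), size=n_cannot, replace=False)] if n_cannot else []
    )
    return ConstraintSet(
        must=frozenset(map(tuple, must)),
        cannot=frozenset(map(tuple, cannot)),
        seed=seed,
    )


def _link_matrix(pairs: frozenset[Pair], n: int) -> np.ndarray:
    M = np.zeros((n, n))
    if pairs:
        idx = np.array(sorted(pairs))
        M[idx[:, 0], idx[:, 1]] = 1.0
        M[idx[:, 1], idx[:, 0]] = 1.0
    return M


def encode_signed(
    network: Network,
    constraints: ConstraintSet,
    *,
    fold_topology: bool = False,
) -> SignedNetwork:
    """Encode priors as the positive/negative link matrices of a signed network.

    ``A^p`` has 1 exactly at must pairs (both orientations) and ``A^n``
    at cannot pairs; the topology ``A`` passes through unchanged.  With
    ``fold_topology=True`` the original edges are also ORed into ``A^p``
    (any edge that is also a cannot-link stays negative only).
    """
    n = network.n_nodes
    for i, j in list(constraints.must) + list(constraints.cannot):
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"constraint pair ({i},{j}) out of range for n={n}")
    positive = _link_matrix(constraints.must, n)
    negative = _link_matrix(constraints.cannot, n)
    if fold_topology:
        positive = np.maximum(positive, network.adjacency)
        positive[negative != 0] = 0.0
    return SignedNetwork(network, positive, negative)


def read_constraints(path: str | os.PathLike, network: Network) -> ConstraintSet:
    """Read a 3-column TSV ``(node_a, node_b, must|cannot)``."""
    index = {nid: i for i, nid in enumerate(network.node_ids)}
    must, cannot = set(), set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 3 or toks[2] not in ("must", "cannot"):
                raise GraphParseError(
                    f"{path}:{lineno}: expected (node_a, node_b, must|cannot)"
                )
            try:
                pair = (index[toks[0]], index[toks[1]])
            except KeyError as exc:
                raise GraphParseError(
                    f"{path}:{lineno}: unknown node id {exc.args[0]!r}"
                ) from None
            (must if toks[2] == "must" else cannot).add(pair)
    return ConstraintSet(must=frozenset(must), cannot=frozenset(cannot))


def write_constraints(
    constraints: ConstraintSet, network: Network, path: str | os.PathLike
) -> None:
    ids = network.node_ids
    with open(path, "w") as fh:
        for i, j in sorted(constraints.must):
            fh.write(f"{ids[i]}\t{ids[j]}\tmust\n")
        for i, j in sorted(constraints.cannot):
            fh.write(f"{ids[i]}\t{ids[j]}\tcannot\n")
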