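"""Planted-partition generator and prior-corruption utilities.

A planted partition places ``n = Σ block_sizes`` nodes into blocks and
draws each intra-block pair as an edge independently with probability
``p_in`` and each inter-block pair with ``p_out``.  With ``p_in`` close
to ``p_out`` the blocks become undetectable from topology alone — the
regime where pairwise priors are the only way to recover the ground
truth, which is exactly what the semi-supervised method targets.

:func:`fixture_suite` materializes three standard regimes on disk in the
package's own TSV formats:

* ``easy`` — 2 blocks of 20, p_in = 0.5, p_out = 0.02: unsupervised
  symmetric NMF recovers the blocks exactly.
* ``ambiguous`` — 3 blocks of 40, p_in = 0.12, p_out = 0.08: near the
  detectability threshold; topology-only accuracy is poor and priors
  raise it sharply.
* ``unbalanced`` — blocks of 60/30/15, p_in = 0.3, p_out = 0.05:
  unequal community sizes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .constraints import ConstraintSet
from .graph_io import Network, Partition, write_edge_list, write_labels

__all__ = [
    "PlantedPartitionSpec",
    "generate",
    "corrupt_constraints",
    "fixture_suite",
    "FIXTURE_REGIMES",
]

FIXTURE_VERSION = 1


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Parameters of the planted-partition model."""

    block_sizes: tuple[int, ...]
    p_in: float
    p_out: float
    seed: int | None = None
    allow_disassortative: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ValueError("block_sizes must be positive integers")
        if sum(self.block_sizes) < 2:
            raise ValueError("need at least 2 nodes")
        for name, p in (("p_in", self.p_in), ("p_out", self.p_out)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.p_out > self.p_in and not self.allow_disassortative:
            raise ValueError(
                "p_out > p_in is disassortative; pass allow_disassortative=True"
            )

    @property
    def n_nodes(self) -> int:
        return sum(self.block_sizes)

    @property
    def k(self) -> int:
        return len(self.block_sizes)


def generate(spec: PlantedPartitionSpec) -> tuple[Network, Partition]:
    """Draw one network + ground truth from the model, deterministically per seed."""
    n = spec.n_nodes
    labels = np.repeat(np.arange(spec.k), spec.block_sizes)
    rng = np.random.default_rng(spec.seed)
    ii, jj = np.triu_indices(n, k=1)
    p = np.where(labels[ii] == labels[jj], spec.p_in, spec.p_out)
    draws = rng.random(ii.size) < p
    A = np.zeros((n, n))
    A[ii[draws], jj[draws]] = 1.0
    A += A.T
    node_ids = [f"n{i}" for i in range(n)]
    return Network(node_ids, A), Partition(labels, spec.k, node_ids)


def corrupt_constraints(
    cs: ConstraintSet, flip_fraction: float, seed: int | None = None
) -> ConstraintSet:
    """Swap the type (must ↔ cannot) of a random subset of constraint pairs.

    Exactly ``floor(flip_fraction · |cs|)`` pairs are flipped, chosen
    uniformly over the union of both sets.  Models incorrect prior
    knowledge: a flipped pair actively contradicts the ground truth.
    """
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError(f"flip_fraction must lie in [0, 1], got {flip_fraction}")
    pool = sorted(cs.must) + sorted(cs.cannot)
    n_flip = int(np.floor(flip_fraction * len(pool)))
    rng = np.random.default_rng(seed)
    flip_idx = set(
        rng.choice(len(pool), size=n_flip, replace=False).tolist() if n_flip else []
    )
    n_must = len(cs.must)
    must = {p for i, p in enumerate(pool[:n_must]) if i not in flip_idx}
    cannot = {p for i, p in enumerate(pool[n_must:], start=n_must) if i not in flip_idx}
    must |= {p for i, p in enumerate(pool[n_must:], start=n_must) if i in flip_idx}
    cannot |= {p for i, p in enumerate(pool[:n_must]) if i in flip_idx}
    return ConstraintSet(must=frozenset(must), cannot=frozenset(cannot), seed=cs.seed)


FIXTURE_REGIMES: dict[str, PlantedPartitionSpec] = {
    "easy": PlantedPartitionSpec((20, 20), p_in=0.5, p_out=0.02, seed=11),
    "ambiguous": PlantedPartitionSpec((40, 40, 40), p_in=0.12, p_out=0.08, seed=13),
    "unbalanced": PlantedPartitionSpec((60, 30, 15), p_in=0.3, p_out=0.05, seed=17),
}


def fixture_suite(path: str | os.PathLike) -> dict[str, PlantedPartitionSpec]:
    """Write all fixture regimes under ``path`` as edges.tsv + labels.tsv.

    Also writes a ``manifest.json`` recording the generator parameters
    and fixture-format version.  Returns the regime specs.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"version": FIXTURE_VERSION, "regimes": {}}
    for name, spec in FIXTURE_REGIMES.items():
        d = root / name
        d.mkdir(exist_ok=True)
        network, truth = generate(spec)
        write_edge_list(network, d / "edges.tsv")
        write_labels(truth, d / "labels.tsv")
        manifest["regimes"][name] = asdict(spec)  # type: ignore[index]
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return dict(FIXTURE_REGIMES)
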