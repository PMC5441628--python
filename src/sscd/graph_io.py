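"""Network, partition and report I/O in plain-text formats.

Networks are undirected, unweighted simple graphs held as dense symmetric
0/1 adjacency matrices with a zero diagonal.  Node identifiers are opaque
strings; internal indices are 0-based and assigned by first appearance, so
a given input file always yields the same node ordering and therefore
reproducible runs.

Supported formats:

* edge list — one edge per line, two whitespace-separated node tokens,
  ``#`` comments; a third (weight) column is tolerated and ignored.
* GML — standard ``node``/``id`` and ``edge``/``source``/``target``
  records, parsed through :mod:`networkx`.
* labels — two-column TSV of ``(node_id, community_label)``; labels are
  opaque tokens mapped to contiguous community indices by first appearance.
* membership/report — two-column TSV of assignments plus a JSON sidecar
  carrying metrics, hyperparameters, seed and the objective trace.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "Partition",
    "GraphParseError",
    "read_edge_list",
    "write_edge_list",
    "read_gml",
    "write_gml",
    "read_labels",
    "write_labels",
    "write_report",
    "read_report",
]


class GraphParseError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class Network:
    """An undirected, unweighted simple graph.

    Attributes
    ----------
    node_ids : list of str
        Opaque node identifiers, in first-appearance order.  Index ``i``
        of ``adjacency`` corresponds to ``node_ids[i]``.
    adjacency : ndarray of shape (n, n)
        Symmetric 0/1 matrix with zero diagonal.
    """

    node_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        n = len(self.node_ids)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} does not match {n} node ids")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be exactly 0 or 1")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown node id: {node_id!r}") from None

    def with_nodes(self, extra_ids: Iterable[str]) -> "Network":
        """Return a network extended with any unseen ids as degree-0 nodes."""
        new_ids = [i for i in extra_ids if i not in set(self.node_ids)]
        if not new_ids:
            return self
        n_old, n_new = self.n_nodes, self.n_nodes + len(new_ids)
        A = np.zeros((n_new, n_new))
        A[:n_old, :n_old] = self.adjacency
        return Network(self.node_ids + new_ids, A)


@dataclass
class Partition:
    """A hard assignment of every node to exactly one of ``k`` communities.

    Community indices are 0-based internally (reports print them 1-based).
    ``k`` may exceed the number of non-empty communities; use
    :meth:`compact` to renumber occupied communities contiguously.
    """

    membership: np.ndarray
    k: int
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=int)
        if m.ndim != 1:
            raise ValueError("membership must be a 1-D array")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if m.size and (m.min() < 0 or m.max() >= self.k):
            raise ValueError("community indices must lie in [0, k)")
        if self.node_ids is not None and len(self.node_ids) != m.size:
            raise ValueError("node_ids length does not match membership")
        self.membership = m

    @property
    def n_nodes(self) -> int:
        return int(self.membership.size)

    def sizes(self) -> np.ndarray:
        """Counts per community, length ``k`` (empty communities included)."""
        return np.bincount(self.membership, minlength=self.k)

    def compact(self) -> "Partition":
        """Renumber so occupied community indices are contiguous from 0."""
        occupied = np.unique(self.membership)
        remap = {int(c): i for i, c in enumerate(occupied)}
        m = np.array([remap[int(c)] for c in self.membership], dtype=int)
        return Partition(m, len(occupied), self.node_ids)

    def communities(self) -> list[list[int]]:
        """Node indices per community, skipping empty communities."""
        return [
            list(np.flatnonzero(self.membership == c))
            for c in range(self.k)
            if np.any(self.membership == c)
        ]

    def reindex(self, node_ids: Sequence[str]) -> "Partition":
        """Reorder to match ``node_ids``; every id must be labelled."""
        if self.node_ids is None:
            raise ValueError("partition has no node ids to align with")
        pos = {nid: i for i, nid in enumerate(self.node_ids)}
        missing = [nid for nid in node_ids if nid not in pos]
        if missing:
            raise KeyError(f"nodes missing from label file: {missing[:5]}")
        m = self.membership[[pos[nid] for nid in node_ids]]
        return Partition(m, self.k, list(node_ids))


def _network_from_edges(
    edges: Iterable[tuple[str, str]], order: Sequence[str]
) -> Network:
    index: dict[str, int] = {}
    for tok in order:
        index.setdefault(tok, len(index))
    n = len(index)
    A = np.zeros((n, n))
    for u, v in edges:
        i, j = index[u], index[v]
        if i == j:
            continue
        A[i, j] = A[j, i] = 1.0
    return Network(list(index), A)


def read_edge_list(path: str | os.PathLike) -> Network:
    """Read a whitespace-separated edge list.

    Duplicate and reciprocal edges collapse to one undirected edge;
    self-loops are dropped.  A third column (edge weight) is ignored with
    a warning, since the model is binary.
    """
    order: list[str] = []
    edges: list[tuple[str, str]] = []
    warned_weights = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) == 3 and not warned_weights:
                logger.warning(
                    "%s:%d: third column ignored (edges are unweighted)", path, lineno
                )
                warned_weights = True
            if len(toks) not in (2, 3):
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 node tokens, got {len(toks)}"
                )
            u, v = toks[0], toks[1]
            order.extend((u, v))
            edges.append((u, v))
    if not edges:
        raise GraphParseError(f"{path}: no edges found")
    return _network_from_edges(edges, order)


def write_edge_list(network: Network, path: str | os.PathLike) -> None:
    """Write each undirected edge once (i < j), tab-separated."""
    ii, jj = np.nonzero(np.triu(network.adjacency, k=1))
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{network.node_ids[i]}\t{network.node_ids[j]}\n")


def read_gml(path: str | os.PathLike) -> Network:
    """Read a GML file; directed or duplicated edges are symmetrized."""
    try:
        g = nx.read_gml(path, label="label")
    except Exception:
        try:
            g = nx.read_gml(path, label="id")  # GML without node labels
        except Exception as exc:  # networkx raises several parse exception types
            raise GraphParseError(f"{path}: not valid GML ({exc})") from exc
    order = [str(v) for v in g.nodes()]
    edges = [(str(u), str(v)) for u, v in g.edges()]
    if not order:
        raise GraphParseError(f"{path}: GML contains no nodes")
    return _network_from_edges(edges, order)


def write_gml(network: Network, path: str | os.PathLike) -> None:
    g = nx.Graph()
    for i, nid in enumerate(network.node_ids):
        g.add_node(i, label=str(nid))
    ii, jj = np.nonzero(np.triu(network.adjacency, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    nx.write_gml(g, path)


def read_labels(path: str | os.PathLike) -> Partition:
    """Read a two-column TSV of (node_id, community_label).

    Labels are mapped to community indices by first appearance.  A node
    listed twice with conflicting labels is an error; an exact duplicate
    row is tolerated.
    """
    assignment: dict[str, int] = {}
    label_index: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected (node_id, label), got {len(toks)} tokens"
                )
            nid, lab = toks
            c = label_index.setdefault(lab, len(label_index))
            if nid in assignment and assignment[nid] != c:
                raise GraphParseError(
                    f"{path}:{lineno}: node {nid!r} labelled with conflicting labels"
                )
            assignment[nid] = c
    if not assignment:
        raise GraphParseError(f"{path}: no labels found")
    node_ids = list(assignment)
    m = np.array([assignment[nid] for nid in node_ids], dtype=int)
    return Partition(m, len(label_index), node_ids)


def write_labels(partition: Partition, path: str | os.PathLike) -> None:
    ids = partition.node_ids or [str(i) for i in range(partition.n_nodes)]
    with open(path, "w") as fh:
        for nid, c in zip(ids, partition.membership):
            fh.write(f"{nid}\t{int(c) + 1}\n")


def write_report(
    partition: Partition,
    metrics: Mapping[str, float],
    trace: Sequence[float],
    path: str | os.PathLike,
    *,
    params: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> None:
    """Write a membership TSV at ``path`` plus a ``.json`` sidecar.

    The sidecar holds ``{"metrics", "params", "seed", "n_iter",
    "objective_trace", "k"}``; community indices in the TSV are 1-based
    and compacted (empty communities removed).
    """
    compacted = partition.compact()
    write_labels(compacted, path)
    sidecar = {
        "metrics": {k: float(v) for k, v in metrics.items()},
        "params": dict(params) if params else {},
        "seed": seed,
        "k": int(compacted.k),
        "n_iter": len(trace),
        "objective_trace": [float(v) for v in trace],
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


def read_report(path: str | os.PathLike) -> dict:
    """Read back the JSON sidecar written by :func:`write_report`."""
    with open(str(path) + ".json") as fh:
        return json.load(fh)
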