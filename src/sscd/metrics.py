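"""Partition-agreement scores: normalized mutual information and purity.

Both compare a detected partition C against a ground truth G through the
confusion matrix ``F`` with ``F_ij = |C_i ∩ G_j|``:

    NMI(C, G) = −2 Σ_ij F_ij log(F_ij n / (F_i· F_·j))
                ───────────────────────────────────────
                Σ_i F_i· log(F_i·/n) + Σ_j F_·j log(F_·j/n)

    Purity(C, G) = (1/n) Σ_i max_j F_ij

NMI is 1 when the partitions are identical up to relabelling and 0 when
they are independent; the log base cancels in the ratio.  Purity is the
fraction of nodes whose community's plurality truth label matches their
own; it never decreases when a detected community is split.  Empty
detected communities contribute nothing to either score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph_io import Partition

__all__ = ["ConfusionMatrix", "confusion", "nmi", "purity", "score"]


@dataclass
class ConfusionMatrix:
    """Count matrix F (rows: detected communities, cols: truth communities)."""

    F: np.ndarray
    n: int

    @property
    def row_marginals(self) -> np.ndarray:
        return self.F.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.F.sum(axis=0)


def _check_aligned(detected: Partition, truth: Partition) -> None:
    if detected.n_nodes != truth.n_nodes:
        raise ValueError(
            f"partitions cover different node counts: "
            f"{detected.n_nodes} vs {truth.n_nodes}"
        )
    if (
        detected.node_ids is not None
        and truth.node_ids is not None
        and detected.node_ids != truth.node_ids
    ):
        if set(detected.node_ids) != set(truth.node_ids):
            raise ValueError("partitions cover different node sets")
        raise ValueError("partitions order nodes differently; reindex() one first")


def confusion(detected: Partition, truth: Partition) -> ConfusionMatrix:
    """F_ij = number of nodes in detected community i with truth label j.

    Rows for empty detected communities (and columns for empty truth
    communities) are dropped.
    """
    _check_aligned(detected, truth)
    d, t = detected.compact(), truth.compact()
    F = np.zeros((d.k, t.k), dtype=int)
    np.add.at(F, (d.membership, t.membership), 1)
    return ConfusionMatrix(F=F, n=detected.n_nodes)


def nmi(detected: Partition, truth: Partition) -> float:
    """Normalized mutual information in [0, 1] (natural log; 0·log 0 ≡ 0)."""
    cm = confusion(detected, truth)
    F = cm.F.astype(float)
    n = float(cm.n)
    ri = cm.row_marginals.astype(float)
    cj = cm.col_marginals.astype(float)
    nz = F > 0
    numer = -2.0 * float(
        np.sum(F[nz] * np.log(F[nz] * n / np.outer(ri, cj)[nz]))
    )
    denom = float(np.sum(ri * np.log(ri / n)) + np.sum(cj * np.log(cj / n)))
    if denom == 0.0:
        # both partitions trivial (single community): entropies vanish
        equal = np.array_equal(
            detected.compact().membership, truth.compact().membership
        )
        warnings.warn(
            "NMI denominator is zero (both partitions trivial); "
            f"returning {1.0 if equal else 0.0}",
            stacklevel=2,
        )
        return 1.0 if equal else 0.0
    return numer / denom


def purity(detected: Partition, truth: Partition) -> float:
    """Fraction of nodes in their detected community's plurality truth label."""
    cm = confusion(detected, truth)
    return float(cm.F.max(axis=1).sum()) / cm.n


def score(detected: Partition, truth: Partition) -> dict[str, float]:
    """Both metrics as a name → value map (for reports)."""
    return {"nmi": nmi(detected, truth), "purity": purity(detected, truth)}
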