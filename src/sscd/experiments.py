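"""Sweep protocols: prior-percentage curves and (γ1, γ2) parameter grids.

Each sweep cell is averaged over repeated runs; every run resamples both
the constraint set and the initialization of H, with a per-run seed
derived deterministically from the master seed, the method name, the
cell coordinates and the run index (so a full sweep is reproducible
bit-for-bit, and cells can be recomputed independently).

Prior mixing modes:

* ``must_only`` — x% of the must-link budget M_pairs, no cannot-links.
* ``cannot_only`` — x% of the cannot-link budget C_pairs, no must-links.
* ``half_half`` — half the prior volume of each type: x/2 % of M_pairs
  as must-links and x/2 % of C_pairs as cannot-links.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics
from .baselines import METHODS, BaselineConfig, fit_method
from .constraints import sample_constraints
from .core import Hyperparams, hard_assign
from .graph_io import Network, Partition

__all__ = ["SweepResult", "run_seed", "prior_sweep", "param_grid", "MIXES"]

MIXES = ("must_only", "cannot_only", "half_half")


def run_seed(master_seed: int, *parts: object) -> int:
    """Deterministic per-run seed < 2^31 from the master seed and cell tags."""
    key = "|".join([str(master_seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)


@dataclass
class SweepResult:
    """Per-cell means and variances of NMI/Purity over repeated runs."""

    table: pd.DataFrame
    runs: int
    master_seed: int

    def cell(self, **coords: object) -> pd.Series:
        sub = self.table
        for name, value in coords.items():
            sub = sub[sub[name] == value]
        if len(sub) != 1:
            raise KeyError(f"coordinates {coords} select {len(sub)} cells, not 1")
        return sub.iloc[0]


def _split_pcts(percentage: float, mix: str) -> tuple[float, float]:
    if mix == "must_only":
        return percentage, 0.0
    if mix == "cannot_only":
        return 0.0, percentage
    if mix == "half_half":
        return percentage / 2.0, percentage / 2.0
    raise ValueError(f"unknown mix {mix!r}; choose from {MIXES}")


def _one_run(
    network: Network,
    truth: Partition,
    method: str,
    pct_must: float,
    pct_cannot: float,
    hyper: Hyperparams,
    config: BaselineConfig,
    seed: int,
) -> dict[str, float]:
    cs = sample_constraints(truth, pct_must, pct_cannot, seed=run_seed(seed, "cs"))
    h = Hyperparams(
        k=hyper.k,
        gamma1=hyper.gamma1,
        gamma2=hyper.gamma2,
        max_iter=hyper.max_iter,
        tol=hyper.tol,
        seed=run_seed(seed, "init"),
        eps=hyper.eps,
    )
    model = fit_method(method, network, cs, hyper.k, h, config)
    return metrics.score(hard_assign(model), truth)


def _aggregate(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    keys = [c for c in df.columns if c not in ("nmi", "purity", "error")]
    out = (
        df.groupby(keys, sort=False)
        .agg(
            nmi_mean=("nmi", "mean"),
            nmi_var=("nmi", "var"),
            purity_mean=("purity", "mean"),
            purity_var=("purity", "var"),
            runs=("nmi", "count"),
            errors=("error", "sum"),
        )
        .reset_index()
    )
    # population variance of a single run is 0, not NaN
    out[["nmi_var", "purity_var"]] = out[["nmi_var", "purity_var"]].fillna(0.0)
    return out


def prior_sweep(
    network: Network,
    truth: Partition,
    methods: Sequence[str] = METHODS,
    percentages: Sequence[float] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    mix: str = "must_only",
    runs: int = 50,
    seed: int = 0,
    hyper: Hyperparams | None = None,
    config: BaselineConfig = BaselineConfig(),
) -> SweepResult:
    """Mean NMI/Purity per (method, prior percentage) cell.

    ``percentages`` are fractions of the respective budgets in [0, 1].
    A failed fit is recorded (``errors`` count per cell) rather than
    aborting the sweep.
    """
    if mix not in MIXES:
        raise ValueError(f"unknown mix {mix!r}; choose from {MIXES}")
    hyper = hyper or Hyperparams(k=truth.k)
    rows: list[dict] = []
    for method in methods:
        for pct in percentages:
            if not 0.0 <= pct <= 1.0:
                raise ValueError(f"percentage {pct} outside [0, 1]")
            pm, pc = _split_pcts(pct, mix)
            for r in range(runs):
                cell_seed = run_seed(seed, method, f"pct={pct}", mix, r)
                row = {"method": method, "percentage": pct, "error": 0}
                try:
                    row.update(
                        _one_run(network, truth, method, pm, pc, hyper, config, cell_seed)
                    )
                except (FloatingPointError, ValueError):
                    row.update({"nmi": np.nan, "purity": np.nan, "error": 1})
                rows.append(row)
    return SweepResult(table=_aggregate(rows), runs=runs, master_seed=seed)


def param_grid(
    network: Network,
    truth: Partition,
    gamma1_values: Sequence[float],
    gamma2_values: Sequence[float],
    pct_must: float = 0.05,
    pct_cannot: float = 0.05,
    runs: int = 50,
    seed: int = 0,
    hyper: Hyperparams | None = None,
) -> SweepResult:
    """Mean NMI/Purity on a (γ1, γ2) grid at fixed prior percentages."""
    if not gamma1_values or not gamma2_values:
        raise ValueError("gamma grids must be nonempty")
    hyper = hyper or Hyperparams(k=truth.k)
    rows: list[dict] = []
    for g1 in gamma1_values:
        for g2 in gamma2_values:
            h = Hyperparams(
                k=hyper.k, gamma1=g1, gamma2=g2,
                max_iter=hyper.max_iter, tol=hyper.tol, eps=hyper.eps,
            )
            for r in range(runs):
                cell_seed = run_seed(seed, "sscd", f"g1={g1}", f"g2={g2}", r)
                row = {"gamma1": g1, "gamma2": g2, "error": 0}
                try:
                    row.update(
                        _one_run(
                            network, truth, "sscd", pct_must, pct_cannot,
                            h, BaselineConfig(), cell_seed,
                        )
                    )
                except (FloatingPointError, ValueError):
                    row.update({"nmi": np.nan, "purity": np.nan, "error": 1})
                rows.append(row)
    return SweepResult(table=_aggregate(rows), runs=runs, master_seed=seed)
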