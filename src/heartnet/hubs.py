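"""Permutation-based hub detection on weighted connectivity.

A hub is a gene with a statistically detectable concentration of strong
connections: its weighted connectivity k_i = sum_j a_ij exceeds what random
reassignment of the network's edge weights would produce. The default null
shuffles the multiset of retained edge weights over the fixed edge set
(topology preserved), which isolates weight concentration from raw degree;
a degree-preserving rewiring null is available as an alternative.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import HubResult, WeightedNetwork
from .diffexpr import bh_adjust

__all__ = ["weighted_connectivity", "permutation_hub_test"]


def weighted_connectivity(net: WeightedNetwork) -> pd.Series:
    """k_i = sum over retained edges of a_ij, per node."""
    return pd.Series(net.connectivity(), index=list(net.nodes), name="k")


def _rewired_edges(
    iu: np.ndarray, ju: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Degree-preserving double edge swaps; weights stay with edge slots."""
    iu, ju = iu.copy(), ju.copy()
    m = iu.size
    existing = set(zip(iu.tolist(), ju.tolist()))
    done = 0
    attempts = 0
    while done < n_swaps and attempts < 20 * n_swaps:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = iu[e1], ju[e1]
        c, d = iu[e2], ju[e2]
        # swap to (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        p1 = (min(a, d), max(a, d))
        p2 = (min(c, b), max(c, b))
        if p1 in existing or p2 in existing:
            continue
        existing.discard((min(a, b), max(a, b)))
        existing.discard((min(c, d), max(c, d)))
        existing.add(p1)
        existing.add(p2)
        iu[e1], ju[e1] = p1
        iu[e2], ju[e2] = p2
        done += 1
    return iu, ju


def permutation_hub_test(
    net: WeightedNetwork,
    B: int = 1000,
    seed: int = 0,
    null: str = "weight-shuffle",
    alpha: float = 0.05,
) -> HubResult:
    """Empirical one-sided permutation test for high weighted connectivity.

    For each of ``B`` permutations the retained edge weights are shuffled
    over the fixed edge set (``null='weight-shuffle'``) or the topology is
    rewired preserving degrees (``null='rewire'``); connectivities are
    recomputed and p_i = (1 + #{k_i^perm >= k_i^obs}) / (B + 1). Hubs are
    genes with BH-adjusted p < ``alpha``. Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    if net.tau <= 0:
        raise ValueError("hub test requires a thresholded network (tau > 0)")
    if null not in ("weight-shuffle", "rewire"):
        raise ValueError(f"unknown null model {null!r}")
    n = net.n_nodes
    iu, ju, w = net.edge_list()
    k_obs = net.connectivity()

    if w.size == 0:
        warnings.warn("empty edge set; all permutation p-values are 1")
        table = pd.DataFrame(
            {"k": np.zeros(n), "pval": np.ones(n), "fdr": np.ones(n),
             "is_hub": np.zeros(n, dtype=bool)},
            index=list(net.nodes),
        )
        return HubResult(table=table, B=B, seed=seed, null=null, alpha=alpha)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n, dtype=np.int64)
    tol = 1e-9 * max(1.0, float(np.abs(k_obs).max()))
    for _ in range(B):
        if null == "weight-shuffle":
            wp = rng.permutation(w)
            ip, jp = iu, ju
        else:
            # several sweeps of swaps so the edge ends decorrelate from the
            # observed topology; residual correlation can only make the
            # null conservative
            ip, jp = _rewired_edges(iu, ju, n_swaps=3 * w.size, rng=rng)
            wp = w
        kp = np.bincount(ip, weights=wp, minlength=n) + np.bincount(
            jp, weights=wp, minlength=n
        )
        exceed += kp >= k_obs - tol
    pval = (1.0 + exceed) / (B + 1.0)
    fdr = bh_adjust(pval)
    table = pd.DataFrame(
        {"k": k_obs, "pval": pval, "fdr": fdr, "is_hub": fdr < alpha},
        index=list(net.nodes),
    )
    return HubResult(table=table, B=B, seed=seed, null=null, alpha=alpha)
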