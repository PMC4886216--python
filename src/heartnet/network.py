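"""Weighted co-expression network construction and topology diagnostics.

The network is unsigned: edge weight a_ij = |r_ij|^beta where r is the
Pearson correlation over all samples and beta (default 6) the soft
threshold. At beta = 6 a weight cutoff of 0.26 corresponds to filtering on
|r| < 0.8 (0.8^6 = 0.262144), the default edge filter of the pipeline.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    NetworkStats,
    ScaleFreeFit,
    WeightedNetwork,
)

__all__ = [
    "correlation_matrix",
    "soft_threshold",
    "threshold_edges",
    "tau_from_correlation",
    "scale_free_fit",
    "scale_free_fit_from_connectivity",
    "network_stats",
    "beta_sweep",
]


def correlation_matrix(
    expr: ExpressionMatrix, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlations between genes over all samples.

    Zero-variance genes are dropped with a warning before computation.
    Returns a symmetric DataFrame with unit diagonal.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    sub = expr if genes is None else expr.subset_genes(list(genes))
    X = sub.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(sub.values.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance genes (e.g. {dropped[:3]})"
        )
        X = X[keep]
    idx = sub.values.index[keep]
    if len(idx) < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=idx, columns=idx)


def soft_threshold(corr: pd.DataFrame, beta: int = 6) -> WeightedNetwork:
    """Raise absolute correlations to the power beta: a_ij = |r_ij|^beta.

    The diagonal is zeroed and the correlation signs are retained for
    export. The result is unthresholded (tau = 0).
    """
    if not isinstance(beta, (int, np.integer)) or beta < 1:
        raise ValueError("beta must be a positive integer")
    r = np.asarray(corr, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    a = np.minimum(a, 1.0)
    a = (a + a.T) / 2.0  # enforce exact symmetry against float noise
    sign = np.sign(r).astype(np.int8)
    np.fill_diagonal(sign, 0)
    nodes = tuple(str(g) for g in corr.index)
    return WeightedNetwork(nodes=nodes, weights=a, beta=int(beta), tau=0.0, corr_sign=sign)


def tau_from_correlation(r: float, beta: int) -> float:
    """Edge-weight threshold equivalent to filtering on |correlation| < r."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("correlation threshold must lie in [0, 1]")
    return float(r) ** beta


def threshold_edges(net: WeightedNetwork, tau: float) -> WeightedNetwork:
    """Remove edges with weight below tau; weights >= tau kept exactly.

    The boundary is inclusive ("below tau" is removed). Isolated nodes stay
    in the node list. tau = 0 returns the network unchanged (new object).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    w = net.weights.copy()
    if tau > 0:
        w[w < tau] = 0.0
    return WeightedNetwork(
        nodes=net.nodes,
        weights=w,
        beta=net.beta,
        tau=max(tau, net.tau),
        corr_sign=None if net.corr_sign is None else net.corr_sign.copy(),
        provenance={**net.provenance, "tau_applied": tau},
    )


def scale_free_fit_from_connectivity(k: np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """R^2 and slope of log10(frequency) vs log10(mean k) over k bins.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are skipped. Degenerate inputs (all k equal, or fewer than 3 usable
    bins) are reported as an invalid fit with R^2 = 0 and a warning.
    """
    k = np.asarray(k, dtype=float)
    if k.size < 10:
        raise ValueError("need at least 10 nodes for a scale-free fit")
    if np.ptp(k) == 0:
        warnings.warn("all connectivities equal; scale-free R^2 undefined, reporting 0")
        return ScaleFreeFit(r2=0.0, slope=float("nan"), n_bins_used=0, valid=False)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    nonempty = counts > 0
    kmean = np.where(nonempty, sums / np.maximum(counts, 1), 0.0)
    usable = nonempty & (kmean > 0)
    if usable.sum() < 3:
        warnings.warn(
            f"only {int(usable.sum())} usable connectivity bins; scale-free fit degenerate"
        )
        return ScaleFreeFit(r2=0.0, slope=float("nan"), n_bins_used=int(usable.sum()), valid=False)
    x = np.log10(kmean[usable])
    y = np.log10(counts[usable] / k.size)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("degenerate connectivity binning; scale-free fit undefined")
        return ScaleFreeFit(r2=0.0, slope=float("nan"), n_bins_used=int(usable.sum()), valid=False)
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return ScaleFreeFit(
        r2=float(r * r), slope=float(slope), n_bins_used=int(usable.sum()), valid=True
    )


def scale_free_fit(net: WeightedNetwork, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit of a network's weighted connectivities."""
    if net.n_nodes < 10:
        raise ValueError("need at least 10 nodes for a scale-free fit")
    return scale_free_fit_from_connectivity(net.connectivity(), n_bins=n_bins)


def network_stats(net: WeightedNetwork, n_bins: int = 10) -> NetworkStats:
    """Density, heterogeneity, median connectivity, scale-free fit, edges.

    density = mean off-diagonal weight; heterogeneity = sd(k)/mean(k)
    (population sd) over weighted connectivities.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    k = net.connectivity()
    iu, ju = np.triu_indices(n, k=1)
    upper = net.weights[iu, ju]
    density = float(upper.sum() / (n * (n - 1) / 2.0))
    kmean = k.mean()
    heterogeneity = float(k.std() / kmean) if kmean > 0 else 0.0
    if n >= 10:
        sf = scale_free_fit(net, n_bins=n_bins)
    else:
        sf = ScaleFreeFit(r2=0.0, slope=float("nan"), n_bins_used=0, valid=False)
    return NetworkStats(
        density=density,
        heterogeneity=heterogeneity,
        median_connectivity=float(np.median(k)),
        scale_free_r2=sf.r2,
        scale_free_slope=sf.slope,
        n_edges=int(np.count_nonzero(upper)),
    )


def beta_sweep(
    corr: pd.DataFrame,
    betas: Iterable[int] = range(1, 13),
    corr_threshold: float = 0.8,
) -> pd.DataFrame:
    """Diagnostic sweep over soft-threshold powers.

    For each beta reports scale-free R^2 and slope, median connectivity,
    density and heterogeneity of the unthresholded network, plus the
    modularity Q of a greedy partition of the |r| >= corr_threshold graph
    weighted by |r|^beta. Purely diagnostic — it never selects beta.
    """
    import networkx as nx

    rows = []
    r = np.abs(np.asarray(corr, dtype=float))
    np.fill_diagonal(r, 0.0)
    iu, ju = np.triu_indices(r.shape[0], k=1)
    strong = r[iu, ju] >= corr_threshold
    for beta in betas:
        net = soft_threshold(corr, beta=int(beta))
        st = network_stats(net)
        G = nx.Graph()
        G.add_nodes_from(range(r.shape[0]))
        G.add_weighted_edges_from(
            (int(i), int(j), float(w) ** beta)
            for i, j, w in zip(iu[strong], ju[strong], r[iu, ju][strong])
        )
        if G.number_of_edges() > 0:
            comms = nx.algorithms.community.greedy_modularity_communities(G, weight="weight")
            q = nx.algorithms.community.modularity(G, comms, weight="weight")
        else:
            q = float("nan")
        rows.append(
            {
                "beta": int(beta),
                "scale_free_r2": st.scale_free_r2,
                "scale_free_slope": st.scale_free_slope,
                "median_connectivity": st.median_connectivity,
                "density": st.density,
                "heterogeneity": st.heterogeneity,
                "modularity_q": q,
            }
        )
    return pd.DataFrame(rows)
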