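"""Co-expression module detection by two complementary algorithms.

Hierarchical route: topological-overlap similarity, average-linkage
clustering of 1 - TOM, a static height cut, and iterative merging of
modules with correlated eigengenes (disjoint modules, ids 1A..nA by
decreasing size).

Cohesiveness route: greedy growth of overlapping clusters on the
thresholded edge list, maximising f(V) = w_in / (w_in + w_out + p*|V|),
with overlap-based merging, density/size filters and a per-cluster
Mann-Whitney significance test (ids 1B..nB).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, Module, ModuleSet, WeightedNetwork
from .diffexpr import bh_adjust

__all__ = [
    "topological_overlap",
    "module_eigengene",
    "detect_modules_hierarchical",
    "cohesiveness",
    "detect_modules_clusterone",
    "compare_modules_jaccard",
    "JaccardComparison",
]


def topological_overlap(net: WeightedNetwork) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal. High TOM means two genes are directly connected and
    share their neighbourhoods.
    """
    a = net.weights
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is zero, so u = i, j terms vanish
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=list(net.nodes), columns=list(net.nodes))


def module_eigengene(
    expr: ExpressionMatrix, genes
) -> tuple[pd.Series, float]:
    """First principal component of the standardised module submatrix.

    Returns the per-sample eigengene, sign-oriented to correlate
    non-negatively with the module's mean standardised profile, and the
    fraction of variance it explains.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("a module eigengene needs at least 2 genes")
    sub = expr.subset_genes(genes).values.to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    if np.all(sd == 0):
        raise ValueError("constant module submatrix has no eigengene")
    if np.any(sd == 0):
        dropped = [g for g, s in zip(genes, sd) if s == 0]
        warnings.warn(f"dropping {len(dropped)} constant genes from eigengene")
        keep = sd > 0
        sub, genes = sub[keep], [g for g, k_ in zip(genes, keep) if k_]
        sd = sd[keep]
        if len(genes) < 2:
            raise ValueError("fewer than 2 non-constant genes in module")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.sample_ids), var_explained


def _merge_by_eigengene(
    clusters: list[list[str]], expr: ExpressionMatrix, merge_threshold: float
) -> list[list[str]]:
    """Iteratively merge the most eigengene-correlated pair above threshold."""
    clusters = [list(c) for c in clusters]
    while len(clusters) > 1:
        eigs = []
        for c in clusters:
            e, _ = module_eigengene(expr, c)
            eigs.append(e.to_numpy())
        E = np.corrcoef(np.asarray(eigs))
        np.fill_diagonal(E, -np.inf)
        i, j = np.unravel_index(np.argmax(E), E.shape)
        if E[i, j] <= merge_threshold:
            break
        merged = sorted(set(clusters[i]) | set(clusters[j]))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return clusters


def _module_revealing_cut(Z: np.ndarray, min_size: int, max_candidates: int | None = None) -> float:
    """Static cut height that reveals the most clusters of usable size.

    Candidate cuts are the midpoints of the widest gaps between consecutive
    merge heights; among them, pick the one yielding the largest number of
    clusters with at least ``min_size`` members (ties resolved toward the
    wider gap, then the lower cut). Cutting too low merely fragments
    modules, which the eigengene-merge step repairs, so the rule errs on
    the low side by construction.
    """
    heights = np.sort(Z[:, 2])
    if heights.size == 0:
        return 0.0
    if heights.size == 1:
        return float(heights[0] / 2)
    gaps = np.diff(heights)
    order = np.argsort(gaps)[::-1]
    if max_candidates is not None:
        order = order[:max_candidates]
    best = None
    for g in order:
        if gaps[g] <= 0:
            continue
        cut = float((heights[g] + heights[g + 1]) / 2)
        labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
        sizes = np.bincount(labels)
        n_ok = int((sizes >= min_size).sum())
        key = (n_ok, gaps[g], -cut)
        if best is None or key > best[0]:
            best = (key, cut)
    return best[1] if best is not None else float(heights[-1] / 2)


def detect_modules_hierarchical(
    tom: pd.DataFrame,
    expr: ExpressionMatrix,
    cut_height: float | None = None,
    cut_quantile: float | None = None,
    min_size: int = 30,
    merge_threshold: float = 0.75,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_size`` go to the unassigned pool; modules
    whose eigengenes correlate above ``merge_threshold`` are merged
    iteratively. Ids 1A..nA by decreasing size.

    The cut height can be given explicitly (``cut_height``), as a quantile
    of the dendrogram merge heights (``cut_quantile``), or left to the
    default rule: cut in the middle of the largest gap in the upper half of
    the sorted merge heights — the static analogue of choosing the most
    self-evident split of tight clusters from their loose joins.
    """
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    nodes = [str(g) for g in tom.index]
    if list(expr.genes) != nodes:
        expr = expr.subset_genes(nodes)
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    if cut_height is None:
        if cut_quantile is not None:
            cut_height = float(np.quantile(Z[:, 2], cut_quantile))
        else:
            cut_height = _module_revealing_cut(Z, min_size)
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), []).append(g)
    kept = [c for c in clusters.values() if len(c) >= min_size]
    unassigned = sorted(g for c in clusters.values() if len(c) < min_size for g in c)

    if len(kept) > 1 and merge_threshold < 1.0:
        kept = _merge_by_eigengene(kept, expr, merge_threshold)

    kept.sort(key=lambda c: (-len(c), min(c)))
    modules = []
    for i, c in enumerate(kept, start=1):
        genes = tuple(sorted(c))
        try:
            _, ve = module_eigengene(expr, genes)
        except ValueError:
            ve = float("nan")
        modules.append(Module(id=f"{i}A", genes=genes, stats={"size": len(genes), "var_explained": ve}))
    return ModuleSet(
        method="hierarchical-TOM",
        modules=modules,
        unassigned=tuple(unassigned),
        params={
            "cut_height": cut_height,
            "cut_quantile": cut_quantile,
            "min_size": min_size,
            "merge_threshold": merge_threshold,
        },
    )


# ---------------------------------------------------------------------------
# cohesiveness-based overlapping clustering

def cohesiveness(w_in: float, w_out: float, size: int, penalty: float) -> float:
    """f(V) = w_in / (w_in + w_out + penalty * |V|)."""
    denom = w_in + w_out + penalty * size
    return w_in / denom if denom > 0 else 0.0


@dataclass
class _Growth:
    members: set[int]
    f_log: list[float] = field(default_factory=list)


def _grow_cluster(
    seed: int,
    neighbors: dict[int, dict[int, float]],
    k: np.ndarray,
    penalty: float,
) -> _Growth:
    members = {seed}
    conn = dict(neighbors[seed])  # node -> weight into current cluster
    w_in = 0.0
    ksum = float(k[seed])
    g = _Growth(members=members)
    f = cohesiveness(w_in, ksum - 2 * w_in, len(members), penalty)
    g.f_log.append(f)
    while True:
        best_gain, best_action = 0.0, None
        # candidate additions: external nodes touching the cluster
        for v, wv in conn.items():
            if v in members:
                continue
            nw_in = w_in + wv
            nk = ksum + float(k[v])
            nf = cohesiveness(nw_in, nk - 2 * nw_in, len(members) + 1, penalty)
            if nf - f > best_gain + 1e-12:
                best_gain, best_action = nf - f, ("add", v)
        # candidate removals (the seed stays, guaranteeing termination)
        for v in list(members):
            if v == seed or len(members) <= 1:
                continue
            wv = conn.get(v, 0.0)
            nw_in = w_in - wv
            nk = ksum - float(k[v])
            nf = cohesiveness(nw_in, nk - 2 * nw_in, len(members) - 1, penalty)
            if nf - f > best_gain + 1e-12:
                best_gain, best_action = nf - f, ("remove", v)
        if best_action is None:
            break
        op, v = best_action
        if op == "add":
            members.add(v)
            w_in += conn.get(v, 0.0)
            ksum += float(k[v])
            for u, w in neighbors[v].items():
                conn[u] = conn.get(u, 0.0) + w
        else:
            members.discard(v)
            w_in -= conn.get(v, 0.0)
            ksum -= float(k[v])
            for u, w in neighbors[v].items():
                conn[u] = conn.get(u, 0.0) - w
        f = cohesiveness(w_in, ksum - 2 * w_in, len(members), penalty)
        g.f_log.append(f)
    return g


def overlap_score(a: frozenset, b: frozenset) -> float:
    """omega(A, B) = |A ∩ B|^2 / (|A| * |B|)."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def detect_modules_clusterone(
    net: WeightedNetwork,
    penalty: float = 2.0,
    min_size: int = 5,
    min_density: float = 0.5,
    overlap_merge: float = 0.8,
    alpha: float = 0.05,
) -> ModuleSet:
    """Greedy cohesiveness clustering of the thresholded network.

    Seeds are taken in decreasing weighted-connectivity order (ties broken
    by gene id); each cluster grows by the best add/remove step until no
    step improves f(V). Overlapping candidates (omega >= ``overlap_merge``)
    are merged, small or sparse clusters dropped, and each survivor is
    tested for significance with a one-sided Mann-Whitney comparison of its
    members' in-cluster vs out-of-cluster weight sums (BH across clusters,
    keep adjusted p < ``alpha``).
    """
    if net.tau <= 0:
        raise ValueError("cohesiveness clustering requires a thresholded network (tau > 0)")
    nodes = list(net.nodes)
    n = len(nodes)
    iu, ju, w = net.edge_list()
    if w.size == 0:
        warnings.warn("empty edge list; returning empty module set")
        return ModuleSet(method="cohesiveness", modules=[], params={"penalty": penalty})
    neighbors: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    for i, j, ww in zip(iu, ju, w):
        neighbors[int(i)][int(j)] = float(ww)
        neighbors[int(j)][int(i)] = float(ww)
    k = net.connectivity()

    order = sorted(range(n), key=lambda i: (-k[i], nodes[i]))
    visited: set[int] = set()
    candidates: list[frozenset] = []
    growth_logs: list[list[float]] = []
    for seed in order:
        if seed in visited or not neighbors[seed]:
            continue
        g = _grow_cluster(seed, neighbors, k, penalty)
        visited |= g.members
        candidates.append(frozenset(g.members))
        growth_logs.append(g.f_log)

    # merge highly-overlapping candidates until a fixed point
    merged = True
    while merged:
        merged = False
        out: list[frozenset] = []
        while candidates:
            c = candidates.pop()
            for idx, o in enumerate(out):
                if overlap_score(c, o) >= overlap_merge:
                    out[idx] = frozenset(c | o)
                    merged = True
                    break
            else:
                out.append(c)
        candidates = out

    W = net.weights
    kept: list[frozenset] = []
    for c in candidates:
        if len(c) < min_size:
            continue
        idx = np.fromiter(c, dtype=int)
        sub = W[np.ix_(idx, idx)]
        density = sub.sum() / (len(c) * (len(c) - 1)) if len(c) > 1 else 0.0
        if density >= min_density:
            kept.append(c)

    if not kept:
        return ModuleSet(
            method="cohesiveness",
            modules=[],
            params={"penalty": penalty, "min_size": min_size, "min_density": min_density,
                    "overlap_merge": overlap_merge, "alpha": alpha},
        )

    pvals = []
    details = []
    for c in kept:
        idx = np.fromiter(sorted(c), dtype=int)
        sub = W[np.ix_(idx, idx)]
        in_sums = sub.sum(axis=1)
        out_sums = k[idx] - in_sums
        try:
            _, p = stats.mannwhitneyu(in_sums, out_sums, alternative="greater")
        except ValueError:  # all values identical
            p = 1.0
        pvals.append(float(p))
        density = float(sub.sum() / (len(idx) * (len(idx) - 1)))
        details.append({"density": density, "w_in": float(sub.sum() / 2.0)})
    fdrs = bh_adjust(np.array(pvals))

    survivors = [
        (c, p, q, d)
        for c, p, q, d in zip(kept, pvals, fdrs, details)
        if q < alpha
    ]
    survivors.sort(key=lambda t: (-len(t[0]), min(nodes[i] for i in t[0])))
    modules = []
    for i, (c, p, q, d) in enumerate(survivors, start=1):
        genes = tuple(sorted(nodes[j] for j in c))
        modules.append(
            Module(
                id=f"{i}B",
                genes=genes,
                stats={"size": len(genes), "pval": p, "fdr": q, **d},
            )
        )
    return ModuleSet(
        method="cohesiveness",
        modules=modules,
        params={
            "penalty": penalty,
            "min_size": min_size,
            "min_density": min_density,
            "overlap_merge": overlap_merge,
            "alpha": alpha,
            "growth_logs": growth_logs,
        },
    )


@dataclass
class JaccardComparison:
    """Pairwise Jaccard matrix between two module catalogues."""

    matrix: pd.DataFrame  # rows = modules of A, columns = modules of B
    best_pair: tuple[str, str]
    best_value: float


def compare_modules_jaccard(setA: ModuleSet, setB: ModuleSet) -> JaccardComparison:
    """J(A, B) = |A ∩ B| / |A ∪ B| for every module pair, plus the arg max."""
    if not setA.modules or not setB.modules:
        raise ValueError("both module sets must be non-empty")
    rows = {}
    for ma in setA.modules:
        sa = set(ma.genes)
        rows[ma.id] = {
            mb.id: len(sa & set(mb.genes)) / len(sa | set(mb.genes))
            for mb in setB.modules
        }
    matrix = pd.DataFrame(rows).T
    matrix = matrix.loc[[m.id for m in setA.modules], [m.id for m in setB.modules]]
    flat = matrix.stack()
    best = flat.idxmax()
    return JaccardComparison(matrix=matrix, best_pair=(str(best[0]), str(best[1])), best_value=float(flat.max()))
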