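"""Shared in-memory containers for the co-expression analysis.

The pipeline moves a small set of objects between stages: a log2 expression
matrix with sample metadata, a weighted (soft-thresholded) network, module
catalogues from the two detection algorithms, and the hub-test result. They
are thin dataclasses around pandas/numpy objects so every stage can be used
on its own.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "AnnotationTable",
    "WeightedNetwork",
    "NetworkStats",
    "ScaleFreeFit",
    "Module",
    "ModuleSet",
    "HubResult",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) id, one column per sample.
    samples
        DataFrame indexed by sample id with at least ``group`` and
        ``replicate`` columns. Column order of ``values`` must match the
        metadata index.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a DataFrame")
        missing = {"group", "replicate"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        vcols = list(self.values.columns)
        mrows = list(self.samples.index)
        if vcols != mrows:
            only_v = sorted(set(vcols) - set(mrows))
            only_m = sorted(set(mrows) - set(vcols))
            raise ValueError(
                "expression columns and sample metadata disagree: "
                f"only in matrix {only_v}, only in metadata {only_m}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        """Group label per sample, aligned to the matrix columns."""
        return self.samples["group"]

    def samples_in_groups(self, groups: Iterable[str]) -> list[str]:
        groups = set(groups)
        return [s for s in self.sample_ids if self.samples.at[s, "group"] in groups]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}...")
        return ExpressionMatrix(self.values.loc[list(genes)], self.samples)


@dataclass(frozen=True)
class GeneSet:
    """A named gene selection, typically the outcome of an FDR cut."""

    genes: tuple[str, ...]
    name: str = ""
    fdr_threshold: float | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class AnnotationTable:
    """GMT-convention annotation: term -> (description, gene tuple)."""

    terms: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def restricted_to(self, universe: Iterable[str]) -> "AnnotationTable":
        uni = set(universe)
        terms = {
            t: tuple(g for g in genes if g in uni) for t, genes in self.terms.items()
        }
        terms = {t: g for t, g in terms.items() if g}
        return AnnotationTable(terms, {t: self.descriptions.get(t, "") for t in terms})


@dataclass
class WeightedNetwork:
    """Soft-thresholded co-expression network.

    ``weights[i, j] = |r_ij| ** beta`` with zero diagonal; ``tau`` is the
    edge-weight threshold already applied to ``weights`` (0 = unthresholded).
    ``corr_sign`` preserves the sign of the underlying Pearson correlation so
    exports can report whether an association is positive or negative.
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    beta: int
    tau: float = 0.0
    corr_sign: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.nodes):
            raise ValueError("node list and weight matrix size disagree")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.size and (w.min() < -1e-12 or w.max() > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def connectivity(self) -> np.ndarray:
        """Weighted connectivity k_i = sum_j a_ij over retained edges."""
        return self.weights.sum(axis=1)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (i, j, weight) arrays of retained (nonzero) edges."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        w = self.weights[iu, ju]
        keep = w > 0
        return iu[keep], ju[keep], w[keep]

    @property
    def n_edges(self) -> int:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu, ju]))


@dataclass(frozen=True)
class ScaleFreeFit:
    """Log-log linear fit of the binned connectivity distribution."""

    r2: float
    slope: float
    n_bins_used: int
    valid: bool = True


@dataclass(frozen=True)
class NetworkStats:
    density: float
    heterogeneity: float
    median_connectivity: float
    scale_free_r2: float
    scale_free_slope: float
    n_edges: int


@dataclass(frozen=True)
class Module:
    id: str
    genes: tuple[str, ...]
    stats: Mapping[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    """Catalogue of detected modules.

    ``method`` is ``hierarchical-TOM`` (disjoint modules, WGCNA-style ids
    1A..nA by decreasing size) or ``cohesiveness`` (possibly overlapping,
    ids 1B..nB).
    """

    method: str
    modules: list[Module]
    unassigned: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def gene_sets(self) -> dict[str, frozenset[str]]:
        return {m.id: frozenset(m.genes) for m in self.modules}

    def module_of(self) -> dict[str, str]:
        """Gene -> module id map (first module wins for overlapping sets)."""
        out: dict[str, str] = {}
        for m in self.modules:
            for g in m.genes:
                out.setdefault(g, m.id)
        return out


@dataclass
class HubResult:
    """Per-gene permutation-test result for weighted connectivity.

    ``table`` is indexed by gene with columns ``k`` (weighted connectivity),
    ``pval`` (empirical permutation p, floored at 1/(B+1)), ``fdr``
    (Benjamini-Hochberg) and ``is_hub`` (fdr < alpha).
    """

    table: pd.DataFrame
    B: int
    seed: int
    null: str = "weight-shuffle"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        required = {"k", "pval", "fdr", "is_hub"}
        if not required <= set(self.table.columns):
            raise ValueError(f"hub table missing columns {required - set(self.table.columns)}")

    @property
    def hubs(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["is_hub"]])

    @property
    def n_hubs(self) -> int:
        return int(self.table["is_hub"].sum())


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
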