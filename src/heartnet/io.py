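"""Readers and writers for the pipeline's plain-text formats.

Expression: TSV (rows = genes, columns = samples) plus a sidecar sample
metadata TSV (sample, group, replicate). Annotations: GMT (term,
description, genes...). Orthology and miR-target tables: headered TSV.
Networks: edge-list TSV or GraphML with node attributes.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AnnotationTable, ExpressionMatrix, HubResult, ModuleSet, WeightedNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
    "write_network",
]


def read_expression(path, metadata_path) -> ExpressionMatrix:
    """Read an expression TSV and its sample-metadata sidecar.

    Validates that matrix columns and metadata samples agree (errors name
    the offenders) and rejects duplicate gene ids — probe-level matrices
    must be collapsed through a probe map instead.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample" not in meta.columns:
        raise ValueError("metadata must have a 'sample' column")
    meta = meta.set_index("sample")
    dup = values.index[values.index.duplicated()].unique()
    if len(dup):
        raise ValueError(
            f"duplicate gene ids in expression matrix (e.g. {list(dup[:3])}); "
            "supply a probe map and collapse first"
        )
    only_m = [s for s in values.columns if s not in meta.index]
    only_d = [s for s in meta.index if s not in values.columns]
    if only_m or only_d:
        raise ValueError(
            f"sample mismatch between expression and metadata: "
            f"matrix-only {only_m}, metadata-only {only_d}"
        )
    meta = meta.loc[list(values.columns)]
    return ExpressionMatrix(values, meta)


def write_expression(expr: ExpressionMatrix, path, metadata_path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    expr.samples.to_csv(metadata_path, sep="\t", index_label="sample")


def read_gmt(path) -> AnnotationTable:
    terms: dict[str, tuple[str, ...]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                warnings.warn(f"skipping malformed GMT line: {line[:40]!r}")
                continue
            terms[parts[0]] = tuple(g for g in parts[2:] if g)
            desc[parts[0]] = parts[1]
    return AnnotationTable(terms, desc)


def write_gmt(annotations: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for term, genes in annotations.terms.items():
            d = annotations.descriptions.get(term, "")
            fh.write("\t".join([term, d, *genes]) + "\n")


def read_table(path, required_columns) -> pd.DataFrame:
    """Read a headered TSV and check required columns are present."""
    df = pd.read_csv(path, sep="\t")
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_network(
    net: WeightedNetwork,
    path,
    fmt: str = "edgelist",
    modules: ModuleSet | None = None,
    hubres: HubResult | None = None,
) -> None:
    """Write the network as an edge-list TSV or GraphML file.

    Edge list columns: gene_a, gene_b, weight, correlation_sign. GraphML
    nodes carry module_id ('0' for unassigned), connectivity, is_hub and
    adjusted p when module/hub results are given.
    """
    path = Path(path)
    iu, ju, w = net.edge_list()
    nodes = list(net.nodes)
    if fmt == "edgelist":
        sign = (
            net.corr_sign[iu, ju]
            if net.corr_sign is not None
            else np.ones(len(w), dtype=int)
        )
        df = pd.DataFrame(
            {
                "gene_a": [nodes[i] for i in iu],
                "gene_b": [nodes[j] for j in ju],
                "weight": w,
                "correlation_sign": sign.astype(int),
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        import networkx as nx

        G = nx.Graph()
        module_of = modules.module_of() if modules is not None else {}
        k = net.connectivity()
        for idx, g in enumerate(nodes):
            attrs = {"connectivity": float(k[idx]), "module_id": module_of.get(g, "0")}
            if hubres is not None:
                attrs["is_hub"] = bool(hubres.table.at[g, "is_hub"])
                attrs["adjusted_p"] = float(hubres.table.at[g, "fdr"])
            G.add_node(g, **attrs)
        for i, j, ww in zip(iu, ju, w):
            G.add_edge(nodes[i], nodes[j], weight=float(ww))
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown network format {fmt!r} (use 'edgelist' or 'graphml')")
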