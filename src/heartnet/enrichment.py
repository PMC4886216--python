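"""Functional enrichment, hub conservation, and miR-target intersection.

All three analyses run against user-supplied local tables: a GMT-style
annotation table (hypergeometric module enrichment), an orthology table
(chi-square test of hub conservation per species), and a miR-target table
(join of hub orthologs against regeneration-driver miRs).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationTable, HubResult, ModuleSet
from .diffexpr import bh_adjust

__all__ = [
    "EnrichmentResult",
    "ConservationTest",
    "MiRInteractionSet",
    "hypergeometric_enrichment",
    "conservation_chisq",
    "map_mir_targets",
]


@dataclass
class EnrichmentResult:
    """Per (module, term) hypergeometric enrichment table.

    Columns: module, term, overlap, module_size, term_size, universe_size,
    pval, fdr, significant (fdr < alpha).
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def n_enriched_modules(self) -> int:
        return self.table.loc[self.table["significant"], "module"].nunique()


def hypergeometric_enrichment(
    modules: ModuleSet,
    annotations: AnnotationTable,
    universe,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided hypergeometric enrichment of every (module, term) pair.

    Annotations and modules are restricted to the universe (the network's
    gene set) before testing; only pairs with overlap >= 1 are tested; BH
    correction is applied across all tested pairs.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    ann = annotations.restricted_to(universe)
    M = len(universe)
    rows = []
    for mod in modules:
        mod_genes = set(mod.genes) & universe
        if len(mod_genes) < len(mod.genes):
            warnings.warn(f"module {mod.id} has genes outside the universe; restricted")
        n = len(mod_genes)
        if n == 0:
            continue
        for term, term_genes in ann.terms.items():
            K = len(term_genes)
            overlap = len(mod_genes & set(term_genes))
            if overlap < 1:
                continue
            # P(X >= overlap), X ~ Hypergeom(M, K, n)
            p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
            rows.append(
                {
                    "module": mod.id,
                    "term": term,
                    "overlap": overlap,
                    "module_size": n,
                    "term_size": K,
                    "universe_size": M,
                    "pval": min(p, 1.0),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["module", "term", "overlap", "module_size", "term_size",
                 "universe_size", "pval"],
    )
    if len(table):
        table["fdr"] = bh_adjust(table["pval"].to_numpy())
        table["significant"] = table["fdr"] < alpha
        table = table.sort_values(["fdr", "pval", "module", "term"], kind="mergesort")
        table = table.reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(table=table, alpha=alpha)


@dataclass
class ConservationTest:
    """2x2 chi-square test of ortholog presence in hubs vs non-hubs."""

    species: str
    contingency: np.ndarray  # rows: hub / non-hub; cols: ortholog / none
    chi2: float
    pval: float
    hub_ortholog_fraction: float
    defined: bool = True
    correction: bool = False


def conservation_chisq(
    hubres: HubResult,
    orthology: pd.DataFrame,
    species: str,
    correction: bool = False,
) -> ConservationTest:
    """Pearson chi-square (1 d.f., no continuity correction by default).

    A gene counts as conserved if it has at least one orthology record for
    the species, regardless of source. Network genes missing from the table
    count as non-conserved (logged).
    """
    need = {"gene", "species", "ortholog"}
    if not need <= set(orthology.columns):
        raise ValueError(f"orthology table missing columns {need - set(orthology.columns)}")
    genes = list(hubres.table.index)
    sp_rows = orthology[orthology["species"] == species]
    if sp_rows.empty:
        warnings.warn(f"no orthology rows for species {species!r}")
    conserved_set = set(sp_rows["gene"])
    covered = set(orthology["gene"])
    missing = [g for g in genes if g not in covered]
    if missing:
        warnings.warn(
            f"{len(missing)} network genes absent from the orthology table; "
            "counted as having no ortholog"
        )
    is_hub = hubres.table["is_hub"].to_numpy()
    has_orth = np.array([g in conserved_set for g in genes])
    tab = np.array(
        [
            [int((is_hub & has_orth).sum()), int((is_hub & ~has_orth).sum())],
            [int((~is_hub & has_orth).sum()), int((~is_hub & ~has_orth).sum())],
        ]
    )
    n_hub = tab[0].sum()
    frac = tab[0, 0] / n_hub if n_hub else float("nan")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        warnings.warn("a margin of the contingency table is zero; test undefined")
        return ConservationTest(species, tab, float("nan"), float("nan"), frac,
                                defined=False, correction=correction)
    res = stats.chi2_contingency(tab, correction=correction)
    return ConservationTest(
        species=species,
        contingency=tab,
        chi2=float(res.statistic),
        pval=float(res.pvalue),
        hub_ortholog_fraction=float(frac),
        defined=True,
        correction=correction,
    )


@dataclass
class MiRInteractionSet:
    """Unique (miR, hub, species) interactions with evidence labels.

    ``table`` columns: mir, hub, ortholog, species, evidence. ``summary``
    maps (species, evidence) -> count of unique interactions.
    """

    table: pd.DataFrame
    summary: dict[tuple[str, str], int]

    def count(self, species: str | None = None, evidence: str | None = None) -> int:
        sub = self.table
        if species is not None:
            sub = sub[sub["species"] == species]
        if evidence is not None:
            sub = sub[sub["evidence"] == evidence]
        return len(sub)


def map_mir_targets(
    hubres: HubResult,
    orthology: pd.DataFrame,
    mir_table: pd.DataFrame,
    species: tuple[str, ...] = ("human", "mouse", "rat"),
    mir_whitelist=None,
) -> MiRInteractionSet:
    """Intersect hub orthologs with a miR-target table.

    Hubs are mapped to their per-species orthologs and joined against
    ``mir_table`` (columns mir, target, species, evidence with evidence in
    {validated, predicted}), optionally restricted to a miR whitelist.
    Duplicate (miR, hub, species) triples are collapsed, keeping the
    stronger evidence (validated over predicted).
    """
    need = {"mir", "target", "species", "evidence"}
    if not need <= set(mir_table.columns):
        raise ValueError(f"mir table missing columns {need - set(mir_table.columns)}")
    known_species = (
        set(orthology["species"]) | set(mir_table["species"]) | {"human", "mouse", "rat"}
    )
    unknown = [s for s in species if s not in known_species]
    if unknown:
        raise ValueError(f"unknown species requested: {unknown}")
    bad_ev = set(mir_table["evidence"]) - {"validated", "predicted"}
    if bad_ev:
        raise ValueError(f"unknown evidence labels: {sorted(bad_ev)}")

    hubs = set(hubres.hubs)
    orth = orthology[orthology["gene"].isin(hubs) & orthology["species"].isin(species)]
    orth = orth[["gene", "species", "ortholog"]].drop_duplicates()
    mir = mir_table[mir_table["species"].isin(species)]
    if mir_whitelist is not None:
        mir = mir[mir["mir"].isin(set(mir_whitelist))]
    joined = mir.merge(
        orth, left_on=["target", "species"], right_on=["ortholog", "species"], how="inner"
    )
    joined = joined.rename(columns={"gene": "hub"})[
        ["mir", "hub", "ortholog", "species", "evidence"]
    ]
    # keep validated over predicted for the same (mir, hub, species) triple
    order = pd.Categorical(joined["evidence"], categories=["validated", "predicted"], ordered=True)
    joined = joined.assign(_ev=order).sort_values(
        ["mir", "hub", "species", "_ev"], kind="mergesort"
    )
    joined = joined.drop_duplicates(subset=["mir", "hub", "species"], keep="first")
    joined = joined.drop(columns="_ev").reset_index(drop=True)
    summary = {
        (sp, ev): int(((joined["species"] == sp) & (joined["evidence"] == ev)).sum())
        for sp in sorted(set(joined["species"]) | set(species))
        for ev in ("validated", "predicted")
    }
    return MiRInteractionSet(table=joined, summary=summary)
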