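"""Gene-set over-representation analysis and table-driven disease annotation.

ORA tests a query gene set against user-supplied pathway collections (GMT)
with the hypergeometric upper tail and Benjamini-Hochberg correction,
against an explicit background (by default the regulatory network's gene
universe). Disease annotation maps genes to MeSH identifiers through a
curated gene-disease link table and reports overlaps with an externally
derived comorbid MeSH set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrich import EnrichmentInput, hypergeom_survival

logger = logging.getLogger(__name__)

MESH_PATTERN = r"^D\d+$"


@dataclass
class PathwayResult:
    pathway_id: str
    pathway_name: str
    overlap_genes: frozenset[str]
    k: int       # overlap size
    K: int       # pathway size within the background
    n_set: int   # query size
    n_bg: int    # background size
    p_raw: float
    p_adj: float


def ora_test(query_genes, pathway_collections: dict[str, dict],
             background_genes, alpha: float = 0.05) -> list[PathwayResult]:
    """Hypergeometric over-representation of ``query_genes`` in each pathway.

    Query genes outside the background are dropped with a warning; pathways
    are truncated to the background before testing. BH correction runs
    across all tested pathways; results sort by adjusted p.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene set")
    query = set(query_genes)
    stray = query - background
    if stray:
        logger.warning("query genes outside background dropped: %s",
                       sorted(stray))
        query &= background

    results = []
    p_raw = []
    for pid, entry in pathway_collections.items():
        members = set(entry["genes"]) & background
        overlap = query & members
        urn = EnrichmentInput(M=len(background), n=len(members),
                              N=len(query), x=len(overlap))
        p = hypergeom_survival(urn)
        p_raw.append(p)
        results.append(PathwayResult(pid, entry.get("name", pid),
                                     frozenset(overlap), len(overlap),
                                     len(members), len(query),
                                     len(background), p, 1.0))
    if results:
        adj = multipletests(p_raw, method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.p_adj = float(q)
    return sorted(results, key=lambda r: (r.p_adj, r.p_raw, r.pathway_id))


def ora_frame(results: list[PathwayResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pathway_id": r.pathway_id, "pathway_name": r.pathway_name,
        "overlap_genes": ";".join(sorted(r.overlap_genes)),
        "k": r.k, "K": r.K, "n_set": r.n_set, "n_bg": r.n_bg,
        "p_raw": r.p_raw, "p_adj": r.p_adj,
    } for r in results])


def map_genes_to_mesh(genes, links: pd.DataFrame):
    """Map genes to MeSH identifier sets through a gene-disease link table.

    Returns ``(mapping, unmatched)``: a dict gene -> set of MeSH ids for
    genes with at least one link, and the sorted list of genes without any.
    """
    required = {"gene_id", "mesh_id"}
    if not required.issubset(links.columns):
        raise ValueError(f"link table needs columns {sorted(required)}")
    by_gene = links.groupby("gene_id")["mesh_id"].apply(set)
    mapping: dict[str, set[str]] = {}
    unmatched: list[str] = []
    for g in set(genes):
        if g in by_gene.index:
            mapping[g] = set(by_gene[g])
        else:
            unmatched.append(g)
    return mapping, sorted(unmatched)


@dataclass
class MeshOverlap:
    genes: dict[str, set[str]]     # gene -> shared MeSH terms
    shared_terms: set[str]
    n_genes_queried: int
    n_terms_queried: int
    n_comorbid_terms: int


def overlap_mesh(network_gene_mesh: dict[str, set[str]],
                 comorbid_mesh_terms) -> MeshOverlap:
    """Genes whose MeSH annotations intersect the comorbid term set."""
    comorbid = set(comorbid_mesh_terms)
    hits = {g: terms & comorbid
            for g, terms in network_gene_mesh.items() if terms & comorbid}
    all_terms = set().union(*network_gene_mesh.values()) \
        if network_gene_mesh else set()
    return MeshOverlap(
        genes=hits,
        shared_terms=set().union(*hits.values()) if hits else set(),
        n_genes_queried=len(network_gene_mesh),
        n_terms_queried=len(all_terms),
        n_comorbid_terms=len(comorbid),
    )
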