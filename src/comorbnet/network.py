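"""Level-wise expansion of a protein-interaction network from seed genes.

Level 0 is the seed gene set (causal genes from MR, or the regulatory
targets of GWAS SNPs and their strong-LD partners) together with every
regulatory-network SNP targeting those genes. Each subsequent level adds
the score-filtered protein-interaction neighbours of the previous level
that have not appeared at any earlier level (minimal-level assignment), so
the layering coincides with breadth-first search on the filtered graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import grn as grn_mod
from .io import LDTable

logger = logging.getLogger(__name__)

MAX_LEVEL = 5
DEFAULT_SCORE_MIN = 0.7  # conventional high-confidence interaction cutoff


@dataclass
class NetworkLevel:
    """One expansion level: genes first reached at this depth, the SNPs
    regulating them, and each gene's parents at the previous level."""

    level: int
    genes: frozenset[str]
    sceqtls: frozenset[str]
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)
    assigned: frozenset[str] = frozenset()  # all genes at levels <= level

    def __post_init__(self):
        if not self.assigned:
            self.assigned = frozenset(self.genes)


def ppi_graph(ppi: pd.DataFrame, score_min: float = DEFAULT_SCORE_MIN) -> nx.Graph:
    """Undirected graph of interactions with combined_score >= cutoff."""
    g = nx.Graph()
    kept = ppi[ppi["combined_score"] >= score_min]
    g.add_edges_from(kept[["protein_a", "protein_b"]].itertuples(index=False))
    return g


def seed_from_genes(seed_genes, grn: pd.DataFrame) -> NetworkLevel:
    """Level 0 from an explicit gene list (e.g. MR risk genes). Genes absent
    from the regulatory network's gene universe are logged and skipped."""
    seeds = set(seed_genes)
    if not seeds:
        raise ValueError("empty seed gene set")
    universe = grn_mod.grn_genes(grn)
    missing = seeds - universe
    if missing:
        logger.warning("seed genes absent from the regulatory network, "
                       "skipped: %s", sorted(missing))
    kept = seeds & universe
    if not kept:
        raise ValueError("no seed gene present in the regulatory network")
    for g in kept:
        if not grn_mod.snps_targeting(grn, {g}):
            logger.warning("seed gene %s has no regulatory SNPs", g)
    return NetworkLevel(0, frozenset(kept),
                        frozenset(grn_mod.snps_targeting(grn, kept)))


def seed_from_gwas_snps(snps, ld: LDTable, grn: pd.DataFrame,
                        positions: dict[str, int] | None = None,
                        r2_min: float = 0.8,
                        window_bp: int = 5000) -> NetworkLevel:
    """Level 0 from GWAS SNPs: the query set is the input SNPs plus SNPs in
    strong LD (r² >= ``r2_min``) within ±``window_bp``; L0 genes are the
    regulatory targets of the query set."""
    query = set(snps)
    if not query:
        raise ValueError("empty GWAS SNP set")
    pos = positions or {}
    expanded = set(query)
    for s in query:
        for mate, r2 in ld.mates(s, r2_min=r2_min).items():
            if pos and abs(pos.get(mate, 0) - pos.get(s, 0)) > window_bp:
                continue
            expanded.add(mate)
    genes = set(grn.loc[grn["snp_id"].isin(expanded), "gene_id"])
    orphans = query - set(grn["snp_id"])
    if orphans:
        logger.info("input SNPs without regulatory targets: %d", len(orphans))
    if not genes:
        raise ValueError("no GWAS SNP (or LD partner) targets a network gene")
    return NetworkLevel(0, frozenset(genes),
                        frozenset(grn_mod.snps_targeting(grn, genes)))


def expand_level(current: NetworkLevel, ppi: nx.Graph | pd.DataFrame,
                 grn: pd.DataFrame,
                 score_min: float = DEFAULT_SCORE_MIN) -> NetworkLevel:
    """The next level: score-filtered neighbours of the current genes minus
    everything already assigned, with provenance back to their parents."""
    if current.level >= MAX_LEVEL:
        raise ValueError(f"expansion beyond level {MAX_LEVEL} not supported")
    graph = ppi if isinstance(ppi, nx.Graph) else ppi_graph(ppi, score_min)
    provenance: dict[str, set[str]] = {}
    for parent in current.genes:
        if parent not in graph:
            continue  # no curated interactions: stays a leaf of its level
        for nb in graph.neighbors(parent):
            if nb in current.assigned:
                continue
            provenance.setdefault(nb, set()).add(parent)
    genes = frozenset(provenance)
    return NetworkLevel(
        current.level + 1, genes,
        frozenset(grn_mod.snps_targeting(grn, set(genes))),
        {g: frozenset(p) for g, p in provenance.items()},
        current.assigned | genes,
    )


def expand_levels(seed: NetworkLevel, ppi: pd.DataFrame, grn: pd.DataFrame,
                  max_level: int = MAX_LEVEL,
                  score_min: float = DEFAULT_SCORE_MIN) -> list[NetworkLevel]:
    """Seed level plus expansions up to ``max_level`` (inclusive)."""
    graph = ppi_graph(ppi, score_min)
    levels = [seed]
    for _ in range(max_level):
        levels.append(expand_level(levels[-1], graph, grn, score_min))
    return levels


def levels_frame(levels: list[NetworkLevel]) -> pd.DataFrame:
    """Flat per-gene table: level, gene, parents, sceqtls of the level."""
    rows = []
    for lv in levels:
        sceqtls = ";".join(sorted(lv.sceqtls))
        for g in sorted(lv.genes):
            parents = ";".join(sorted(lv.provenance.get(g, ())))
            rows.append((lv.level, g, parents, sceqtls))
    return pd.DataFrame(rows, columns=["level", "gene", "parents", "sceqtls"])
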