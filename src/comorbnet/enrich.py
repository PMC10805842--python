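"""Per-level GWAS-trait enrichment of regulatory SNPs with a Monte-Carlo null.

For each protein-interaction level the level's regulatory SNPs (expanded by
strong LD, r² >= 0.8 within ±5 kb) are intersected with a trait catalog and
each trait is scored with the hypergeometric upper-tail probability
P(X >= x) on the urn (M = catalog SNP universe, n = trait SNPs, N = level
SNPs in the universe, x = their overlap). Bonferroni across the traits
tested at a level gives the significance call; an optional Monte-Carlo null
re-runs the whole expansion from random seed-gene sets and reports, per
(trait, level), the add-one-smoothed fraction of replicates in which the
trait came out significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import grn as grn_mod
from . import network as network_mod
from .io import LDTable

LD_R2_MIN = 0.8
LD_WINDOW_BP = 5000
ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentInput:
    """The hypergeometric urn for one (trait, level) pair."""

    M: int  # unique SNPs in the catalog
    n: int  # SNPs associated with the trait
    N: int  # level sceQTLs (LD-expanded) present in the catalog universe
    x: int  # overlap between trait SNPs and the level set

    def __post_init__(self):
        if not (0 <= self.n <= self.M and 0 <= self.N <= self.M):
            raise ValueError(f"inconsistent urn: {self}")
        if not 0 <= self.x <= min(self.n, self.N):
            raise ValueError(f"overlap outside urn bounds: {self}")


def ld_expand(snps, ld: LDTable, positions: dict[str, int] | None = None,
              r2_min: float = LD_R2_MIN, window_bp: int = LD_WINDOW_BP) -> set[str]:
    """Single-pass strong-LD expansion: the input SNPs plus partners with
    r² >= ``r2_min`` within ±``window_bp``. Not transitive by design."""
    base = set(snps)
    pos = positions or {}
    out = set(base)
    for s in base:
        for mate, _ in ld.mates(s, r2_min=r2_min).items():
            if pos and abs(pos.get(mate, 0) - pos.get(s, 0)) > window_bp:
                continue
            out.add(mate)
    return out


def hypergeom_survival(urn: EnrichmentInput) -> float:
    """Upper-tail probability P(X >= x) of drawing at least x trait SNPs in
    N draws without replacement from M SNPs of which n are trait-associated."""
    if urn.x == 0:
        return 1.0
    return float(stats.hypergeom.sf(urn.x - 1, urn.M, urn.n, urn.N))


@dataclass
class TraitEnrichmentResult:
    trait: str
    level: int
    input: EnrichmentInput
    p_raw: float
    p_adj: float
    significant: bool
    mc_empirical_p: float | None = None


def enrich_level(level: network_mod.NetworkLevel, catalog: pd.DataFrame,
                 ld: LDTable, positions: dict[str, int] | None = None,
                 alpha: float = ALPHA,
                 method: str = "bonferroni") -> list[TraitEnrichmentResult]:
    """Trait enrichment of one level's LD-expanded regulatory SNP set.

    The urn is made coherent by intersecting the expanded level set with the
    catalog's SNP universe (a SNP unknown to the catalog cannot be drawn).
    ``method`` is ``bonferroni`` (default) or ``bh``; the family is the
    number of traits tested at this level. Results sort by adjusted p.
    """
    if catalog.empty:
        raise ValueError("empty trait catalog")
    universe = set(catalog["snp"])
    M = len(universe)
    expanded = ld_expand(level.sceqtls, ld, positions)
    level_set = expanded & universe
    N = len(level_set)

    traits = catalog.groupby("trait")["snp"].apply(set)
    p_raw = []
    urns = []
    for trait, tsnps in traits.items():
        n = len(tsnps)
        x = len(tsnps & level_set)
        urn = EnrichmentInput(M=M, n=n, N=N, x=x)
        urns.append((trait, urn))
        p_raw.append(hypergeom_survival(urn))
    family = len(urns)
    if method == "bonferroni":
        p_adj = np.minimum(1.0, np.asarray(p_raw) * family)
    elif method == "bh":
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction method {method!r}")
    results = [
        TraitEnrichmentResult(trait, level.level, urn, float(p),
                              float(padj), bool(padj < alpha))
        for (trait, urn), p, padj in zip(urns, p_raw, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_adj, r.p_raw, r.trait))


def enrich_all_levels(levels, catalog, ld, positions=None, alpha=ALPHA,
                      method="bonferroni") -> list[TraitEnrichmentResult]:
    out = []
    for lv in levels:
        out.extend(enrich_level(lv, catalog, ld, positions, alpha, method))
    return out


def significant_pairs(results) -> set[tuple[str, int]]:
    return {(r.trait, r.level) for r in results if r.significant}


def monte_carlo_null(grn: pd.DataFrame, ppi: pd.DataFrame,
                     catalog: pd.DataFrame, ld: LDTable,
                     seed_set_size: int, n_sims: int = 1000,
                     rng_seed: int = 0, max_level: int = 3,
                     score_min: float = network_mod.DEFAULT_SCORE_MIN,
                     positions: dict[str, int] | None = None,
                     alpha: float = ALPHA) -> dict[tuple[str, int], float]:
    """Random-seed-gene null for the whole expansion-plus-enrichment chain.

    Each replicate draws ``seed_set_size`` genes uniformly without
    replacement from the regulatory network's gene universe, expands them to
    ``max_level`` and records which (trait, level) pairs come out
    significant. Returns add-one-smoothed empirical probabilities
    (1 + hits) / (1 + n_sims) per (trait, level); with ``n_sims=0`` the
    null is undefined and an empty map is returned.
    """
    if n_sims == 0:
        return {}
    genes = sorted(grn_mod.grn_genes(grn))
    if seed_set_size > len(genes):
        raise ValueError("seed_set_size exceeds network gene count")
    rng = np.random.default_rng(rng_seed)
    graph = network_mod.ppi_graph(ppi, score_min)
    traits = sorted(set(catalog["trait"]))
    hits = {(t, lv): 0 for t in traits for lv in range(max_level + 1)}
    for _ in range(n_sims):
        seeds = rng.choice(genes, size=seed_set_size, replace=False)
        level = network_mod.seed_from_genes(seeds, grn)
        for lv_idx in range(max_level + 1):
            for res in enrich_level(level, catalog, ld, positions, alpha):
                if res.significant:
                    hits[(res.trait, lv_idx)] += 1
            if lv_idx < max_level:
                level = network_mod.expand_level(level, graph, grn, score_min)
    return {k: (1 + v) / (1 + n_sims) for k, v in hits.items()}


def results_frame(results: list[TraitEnrichmentResult],
                  mc: dict[tuple[str, int], float] | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "trait": r.trait, "level": r.level,
            "M": r.input.M, "n": r.input.n, "N": r.input.N, "x": r.input.x,
            "p_raw": r.p_raw, "p_adj": r.p_adj, "significant": r.significant,
            "mc_empirical_p": (mc or {}).get((r.trait, r.level),
                                             r.mc_empirical_p),
        })
    return pd.DataFrame(rows, columns=["trait", "level", "M", "n", "N", "x",
                                       "p_raw", "p_adj", "significant",
                                       "mc_empirical_p"])
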