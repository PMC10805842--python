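"""End-to-end orchestration of the two analysis arms.

One run generates (or loads) the inputs, builds the regulatory network,
runs transcriptome-wide MR, then expands and enriches two
protein-interaction networks: the *causal* arm seeded with the MR risk
genes and the *associated* arm seeded with genome-wide-significant outcome
SNPs (plus strong-LD partners). Both arms share the regulatory network, LD
panel, PPI graph and trait catalog; the run cross-references traits
significant in both arms and intersects the associated-arm genes with the
suggestive MR genes. A comorbidity pass over the synthetic registry and
MeSH mapping closes the loop from molecular networks to co-occurring
medical conditions.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, comorbid, enrich, grn as grn_mod, mr as mr_mod
from . import network as network_mod, synth
from .io import LDTable, write_tsv

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {"causal_effect": 1.0, "n_individuals": 1000},
    "mr": {"p_threshold": 1e-5},
    "network": {"score_min": 0.7, "max_level": 5, "analysis_levels": 3},
    "enrich": {"method": "bonferroni", "alpha": 0.05, "n_sims": 0},
    "comorbid": {"min_patients": 6},
    "associated_arm": {"p_threshold": 5e-8, "max_snps": 90},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    digests: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config": self.config, "seeds": self.seeds,
                "digests": self.digests, "timings": self.timings,
                "versions": self.versions}


@dataclass
class PipelineResult:
    manifest: RunManifest
    bundle: dict                      # synthetic inputs
    grn: pd.DataFrame
    mr_results: pd.DataFrame
    causal_levels: list
    associated_levels: list
    causal_enrichment: pd.DataFrame
    associated_enrichment: pd.DataFrame
    shared_traits: set
    overlap_suggestive: set
    comorbidity: pd.DataFrame
    prevalence_percent: float
    mesh_overlap: annotate.MeshOverlap


def _merge_config(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode()).hexdigest()[:16]


def run_all(config: dict | None = None,
            outdir: str | Path | None = None) -> PipelineResult:
    """Execute both arms and the comorbidity pass; returns everything plus a
    reproducibility manifest. A stage failure aborts with the stage named;
    previously written outputs are left in place."""
    cfg = _merge_config(config)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seeds={"master": seed},
                           versions={"pandas": pd.__version__})
    out = Path(outdir) if outdir is not None else None

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest.timings[name] = round(time.perf_counter() - t0, 3)
        return result

    def _generate():
        synth_cfg = synth.SynthConfig(**{"seed": seed, **cfg["synth"]})
        return synth.generate_all(synth_cfg, out)

    bundle = stage("synth", _generate)
    cohort = bundle["cohort"]
    ld = LDTable(bundle["ld"])
    positions = dict(zip(cohort.snps["snp"], cohort.snps["pos"].astype(int)))

    grn = stage("grn", lambda: grn_mod.build_grn(
        cohort.genotypes, cohort.expression, cohort.hic_support,
        cohort.snps, cohort.genes))
    mr_results = stage("mr", lambda: mr_mod.run_mr(
        grn, bundle["gwas"], ld, cohort.snps,
        p_threshold=float(cfg["mr"]["p_threshold"])))

    net_cfg = cfg["network"]
    score_min = float(net_cfg["score_min"])
    k_analysis = int(net_cfg["analysis_levels"])
    enr_cfg = cfg["enrich"]

    def build_arm(seed_level):
        levels = network_mod.expand_levels(
            seed_level, bundle["ppi"], grn,
            max_level=int(net_cfg["max_level"]), score_min=score_min)
        analysed = levels[: k_analysis + 1]
        results = enrich.enrich_all_levels(
            analysed, bundle["catalog"], ld, positions,
            alpha=float(enr_cfg["alpha"]), method=enr_cfg["method"])
        return levels, results

    risk_genes = set(mr_results.loc[
        mr_results["classification"] == "risk", "gene_id"])
    causal_levels, causal_res = stage("causal_arm", lambda: build_arm(
        network_mod.seed_from_genes(risk_genes, grn)))

    assoc_cfg = cfg["associated_arm"]
    gwas = bundle["gwas"]
    hits = gwas[gwas["pval"] < float(assoc_cfg["p_threshold"])]
    hits = hits.nsmallest(int(assoc_cfg["max_snps"]), "pval")
    associated_levels, assoc_res = stage("associated_arm", lambda: build_arm(
        network_mod.seed_from_gwas_snps(hits["snp"], ld, grn, positions)))

    n_sims = int(enr_cfg.get("n_sims", 0))
    if n_sims:
        mc = stage("monte_carlo", lambda: enrich.monte_carlo_null(
            grn, bundle["ppi"], bundle["catalog"], ld,
            seed_set_size=len(causal_levels[0].genes), n_sims=n_sims,
            rng_seed=seed + 17, max_level=k_analysis,
            score_min=score_min, positions=positions,
            alpha=float(enr_cfg["alpha"])))
    else:
        mc = {}

    shared = enrich.significant_pairs(causal_res) \
        & enrich.significant_pairs(assoc_res)
    shared_traits = {t for t, _lv in shared}

    suggestive = set(mr_results.loc[
        mr_results["classification"] == "suggestive", "gene_id"])
    assoc_genes = set().union(*(lv.genes
                                for lv in associated_levels[: k_analysis + 1]))
    overlap_suggestive = assoc_genes & suggestive

    registry = bundle["registry"]
    com_results, prevalence = stage("comorbid", lambda: comorbid.run_comorbidity(
        registry.records, registry.index_code,
        min_patients=int(cfg["comorbid"]["min_patients"])))
    com_df = comorbid.results_frame(com_results)

    sig_codes = [r.code_b for r in com_results
                 if r.excluded_reason == "none" and r.q_value < 0.05]
    code_mesh, _fallback, _unmapped = comorbid.icd_to_mesh(
        sig_codes, registry.icd_mesh)
    comorbid_terms = set().union(*code_mesh.values()) if code_mesh else set()
    causal_genes_all = set().union(*(lv.genes
                                     for lv in causal_levels[: k_analysis + 1]))
    gene_mesh, _ = annotate.map_genes_to_mesh(causal_genes_all,
                                              registry.gene_mesh)
    mesh_overlap = annotate.overlap_mesh(gene_mesh, comorbid_terms)

    causal_enr = enrich.results_frame(causal_res, mc)
    assoc_enr = enrich.results_frame(assoc_res)

    if out is not None:
        write_tsv(grn, out / "grn.tsv")
        write_tsv(mr_results, out / "mr.tsv")
        write_tsv(network_mod.levels_frame(causal_levels),
                  out / "causal_levels.tsv")
        write_tsv(network_mod.levels_frame(associated_levels),
                  out / "associated_levels.tsv")
        write_tsv(causal_enr, out / "causal_enrichment.tsv")
        write_tsv(assoc_enr, out / "associated_enrichment.tsv")
        write_tsv(com_df, out / "comorbidity.tsv")

    for name, df in [("grn", grn), ("mr", mr_results),
                     ("causal_enrichment", causal_enr),
                     ("associated_enrichment", assoc_enr),
                     ("comorbidity", com_df)]:
        manifest.digests[name] = _digest(df)

    if out is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, default=str)

    return PipelineResult(
        manifest=manifest, bundle=bundle, grn=grn, mr_results=mr_results,
        causal_levels=causal_levels, associated_levels=associated_levels,
        causal_enrichment=causal_enr, associated_enrichment=assoc_enr,
        shared_traits=shared_traits, overlap_suggestive=overlap_suggestive,
        comorbidity=com_df, prevalence_percent=prevalence,
        mesh_overlap=mesh_overlap)
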