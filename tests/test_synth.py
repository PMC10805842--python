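"""Generator contracts: determinism, schemas, planted-signal calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comorbnet import comorbid, grn, synth
from comorbnet.io import LDTable


def _frames(bundle):
    c = bundle["cohort"]
    yield from [c.genotypes, c.expression, c.hic_support, c.snps, c.genes,
                bundle["gwas"], bundle["ld"], bundle["catalog"],
                bundle["ppi"], bundle["registry"].records]


def test_identical_seed_reproduces_every_table_byte_for_byte():
    cfg = synth.SynthConfig(seed=1)
    b1, b2 = synth.generate_all(cfg), synth.generate_all(cfg)
    for f1, f2 in zip(_frames(b1), _frames(b2)):
        assert f1.to_csv(index=False) == f2.to_csv(index=False)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        synth.SynthConfig(n_snps=0)
    with pytest.raises(ValueError):
        synth.SynthConfig(ld_within_r2=1.5)
    with pytest.raises(ValueError):
        synth.SynthConfig(planted_trait_level=6)
    with pytest.raises(ValueError):
        synth.SynthConfig(comorbid_or=0.5)


def test_dosages_follow_hardy_weinberg_support(bundle):
    dosage = bundle["cohort"].dosage_matrix()
    assert set(np.unique(dosage)) <= {0, 1, 2}
    mafs = bundle["cohort"].snps["maf"]
    assert ((mafs >= 0.05) & (mafs <= 0.5)).all()


def test_null_eqtl_effect_gives_uniform_association_pvalues():
    """With eqtl_effect_sd=0 expression is independent of genotype, so
    association p-values over candidate pairs are U(0,1) (KS, alpha=0.01)."""
    cfg = synth.SynthConfig(seed=5, eqtl_effect_sd=0.0)
    cohort = synth.generate_regulatory_cohort(cfg)
    supported = grn.filter_hic_support(cohort.hic_support)
    geno = cohort.genotypes.drop(columns=["individual"])
    expr = cohort.expression.drop(columns=["individual"])
    pvals = [grn.test_eqtl(geno[s], expr[g])[2]
             for s, g in supported.itertuples(index=False)]
    assert len(pvals) > 50
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_planted_eqtl_slope_recovered_by_regression():
    """A planted effect of 1.0 with noise sd 0.1 at n=500 is recovered
    within ±0.05 (OLS consistency, checked against the closed form)."""
    rng = np.random.default_rng(11)
    dosage = rng.integers(0, 3, size=500).astype(float)
    expression = 1.0 * dosage + rng.normal(0, 0.1, size=500)
    beta, se, _ = grn.test_eqtl(dosage, expression)
    assert abs(beta - 1.0) < 0.05
    # independent closed-form OLS oracle
    x, y = dosage - dosage.mean(), expression - expression.mean()
    assert beta == pytest.approx(float(x @ y / (x @ x)), rel=1e-12)


def test_null_outcome_gwas_is_calibrated():
    """causal_effect=0: about 5% of SNPs reach p<0.05 (binomial bounds)."""
    cfg = synth.SynthConfig(seed=2, causal_effect=0.0)
    cohort = synth.generate_regulatory_cohort(cfg)
    gwas = synth.generate_outcome_gwas(cfg, cohort)
    frac = (gwas["pval"] < 0.05).mean()
    m = len(gwas)
    # blocks correlate SNPs; allow 4 sd of the binomial on block count
    n_eff = m / cfg.ld_block_size
    bound = 4 * np.sqrt(0.05 * 0.95 / n_eff)
    assert abs(frac - 0.05) < bound


def test_strong_causal_gene_instruments_hit_outcome():
    """Strong planted eQTLs of the causal gene give outcome associations far
    below 1e-4 (geometric mean over 3 seeds)."""
    logs = []
    for seed in range(3):
        cfg = synth.SynthConfig(seed=seed, n_individuals=2000,
                                causal_effect=1.5, eqtl_effect_sd=1.5)
        cohort = synth.generate_regulatory_cohort(cfg)
        gwas = synth.generate_outcome_gwas(cfg, cohort)
        gene = next(iter(cohort.truth.causal_genes))
        snps = cohort.truth.gene_snps(gene)
        sub = gwas[gwas["snp"].isin(snps)]
        assert len(sub) > 0
        logs += list(np.log10(np.clip(sub["pval"], 1e-300, None)))
    assert np.mean(logs) < -4


def test_gwas_schema_alleles_and_columns(bundle):
    gwas = bundle["gwas"]
    assert list(gwas.columns) == ["snp", "chr", "pos", "effect_allele",
                                  "other_allele", "eaf", "beta", "se",
                                  "pval", "n"]
    assert gwas["effect_allele"].isin(list("ACGT")).all()
    assert gwas["other_allele"].isin(list("ACGT")).all()
    assert (gwas["effect_allele"] != gwas["other_allele"]).all()
    assert (gwas["se"] > 0).all()


def test_ld_panel_block_structure():
    cfg = synth.SynthConfig(seed=1, ld_within_r2=0.95)
    panel = LDTable(synth.generate_ld_panel(cfg))
    snps = synth.snp_map(cfg)
    assert panel.r2("rs00001", "rs00001") == 1.0
    by_block = snps.groupby("block")["snp"].apply(list)
    chr_of = dict(zip(snps["snp"], snps["chr"]))
    # proxy lookup at 0.9 finds exactly the block mates (exhaustive scan)
    for block, members in list(by_block.items())[:10]:
        for s in members:
            mates = set(panel.mates(s, r2_min=0.9))
            assert mates == set(members) - {s}
    # cross-chromosome pairs are unlinked
    a = snps[snps["chr"] == "1"]["snp"].iloc[0]
    b = snps[snps["chr"] == "2"]["snp"].iloc[0]
    assert panel.r2(a, b) == 0.0


def test_genotype_ld_matches_panel_target():
    """Realized within-block genotype r² tracks ld_within_r2."""
    cfg = synth.SynthConfig(seed=4, n_individuals=4000)
    cohort = synth.generate_regulatory_cohort(cfg)
    geno = cohort.dosage_matrix()
    snps = cohort.snps
    r2s = []
    for _, members in list(snps.groupby("block"))[:25]:
        idx = members.index.to_numpy()
        for i in range(len(idx) - 1):
            a, b = geno[:, idx[i]], geno[:, idx[i + 1]]
            if a.std() and b.std():
                r2s.append(np.corrcoef(a, b)[0, 1] ** 2)
    assert abs(np.mean(r2s) - cfg.ld_within_r2) < 0.05


def test_hic_support_planted_pairs_all_pass(bundle):
    cohort = bundle["cohort"]
    kept = grn.filter_hic_support(cohort.hic_support)
    kept_pairs = set(zip(kept["snp"], kept["gene"]))
    assert set(cohort.truth.true_eqtl_effects) <= kept_pairs
    # decoys both pass and fail the rule
    decoys = kept_pairs - set(cohort.truth.true_eqtl_effects)
    all_pairs = set(zip(cohort.hic_support["snp"], cohort.hic_support["gene"]))
    assert decoys and (all_pairs - kept_pairs)


def test_null_registry_odds_ratio_ci_covers_one():
    """comorbid_or=1: the planted-pair OR CI covers 1 in >=90% of seeds."""
    covered = total = 0
    for seed in range(30):
        cfg = synth.SynthConfig(seed=seed, comorbid_or=1.0, n_patients=4000)
        truth = _truth_only(cfg)
        reg = synth.generate_registry(cfg, truth)
        for code in truth.planted_comorbid_codes:
            c = comorbid.build_counts(reg.records, reg.index_code, code)
            _, lo, hi, _ = comorbid.odds_ratio(c)
            covered += lo <= 1.0 <= hi
            total += 1
    assert covered / total >= 0.9


def test_planted_comorbid_or_recovered():
    ors = []
    for seed in range(5):
        cfg = synth.SynthConfig(seed=seed, comorbid_or=4.0, n_patients=20000)
        truth = _truth_only(cfg)
        reg = synth.generate_registry(cfg, truth)
        for code in truth.planted_comorbid_codes:
            c = comorbid.build_counts(reg.records, reg.index_code, code)
            ors.append(comorbid.odds_ratio(c)[0])
    assert 2.5 <= np.mean(ors) <= 6.0


def test_ppi_wires_planted_genes_at_exact_level():
    cfg = synth.SynthConfig(seed=9, planted_trait_level=3)
    cohort = synth.generate_regulatory_cohort(cfg)
    import networkx as nx
    from comorbnet import network
    graph = network.ppi_graph(synth.generate_ppi(cfg, cohort.genes["gene"],
                                                 cohort.truth))
    seed_gene = next(iter(cohort.truth.causal_genes))
    dist = nx.single_source_shortest_path_length(graph, seed_gene)
    for g in cohort.truth.planted_genes:
        assert dist[g] == 3


def _truth_only(cfg):
    rng = np.random.default_rng(cfg.seed)
    return synth._plant_truth(cfg, synth.snp_map(cfg),
                              synth._gene_map(cfg, rng), rng)
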