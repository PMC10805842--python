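# Methods

This note documents the models, defaults and numerical choices behind
`comorbnet`, and what the synthetic validation does and does not
demonstrate.

## Regulatory network (grn)

A candidate SNP–gene pair enters the network only when both evidence
layers agree: physical chromatin contact and statistical association.

- **Contact support.** Contact count ≥ 2 in ≥ 2 distinct Hi-C biological
  replicates. The rule is a conjunction with the association filter and is
  order-independent. Raw Hi-C processing (fragment assignment) is out of
  scope; the input is a pre-tabulated per-replicate contact table.
- **Association.** OLS of expression on allele dosage with a two-sided t
  test. Expression is standardized to unit variance per gene before
  testing so downstream causal estimates are per 1 SD of expression.
  Constant expression is a well-defined null (β=0, p=1); constant dosage
  is a monomorphic-SNP error. No covariate adjustment: the synthetic
  cohorts have no confounding by construction.
- **Multiplicity.** Benjamini–Hochberg within each *SNP-chromosome*
  family, keeping FDR < 0.05. The family choice is SNP-anchored because
  eQTL mapping is SNP-anchored; it is a named, overridable argument
  (`family_col`) since the gene's chromosome is an equally defensible
  family.
- **Geometry.** cis iff same chromosome and |SNP − TSS| < 1 Mb (strict);
  exactly 1 Mb is trans-intra. Different chromosomes: trans-inter.

## Mendelian randomization (mr)

Two-sample MR of gene expression (exposure, SD units) on a binary
disease (outcome, log-odds units).

- **Instrument selection**: network associations with p < 1e-5 (strict)
  and FDR < 0.05. The lenient instrument threshold reflects the small
  sample sizes of tissue-specific eQTL resources.
- **Clumping**: greedy by ascending p; a SNP is kept iff r² < 0.001 with
  every kept SNP within 10 Mb on the same chromosome. Pairs absent from
  the sparse LD table count as unlinked. Ties in p break on SNP id.
- **Proxies**: an instrument missing from the outcome table is replaced
  by the available SNP with maximal r² > 0.9 (ties: nearest, then
  lexicographic). Replace-and-proceed: the original exposure
  coefficients are kept and the proxy's outcome row is aligned against
  the proxy's own dose-allele annotation; no r²-attenuation adjustment.
- **Harmonisation**: swapped alleles flip β_out and eaf; strand
  complements are aligned; palindromic SNPs are oriented by allele
  frequency and dropped when either frequency lies in (0.42, 0.58)
  (conventional window, configurable). Harmonising an aligned row is a
  no-op.
- **Estimators**: Wald ratio β_out/β_exp with first-order delta SE
  (se_out/|β_exp|; ignores se_exp, matching common two-sample MR
  defaults); fixed-effects IVW over per-instrument ratios. Fixed effects
  because heterogeneous exposures are excluded rather than down-weighted:
  Cochran's Q (χ², k−1 df) with q_p < 0.05 marks an exposure
  `excluded_heterogeneity`.
- **Pleiotropy**: MR-Egger intercept from a 1/se_out²-weighted regression
  with exposure effects oriented positive, t test with k−2 df. Requires
  ≥ 3 instruments (the 2-instrument model is saturated); it flags, never
  excludes — the analogous published analyses report the test without
  stating removal.
- **Classification**: with n exposures carrying a usable (non-excluded)
  estimate, *risk* iff p < 0.05/n, *suggestive* iff p < 0.05, else null.
  Whether heterogeneity-excluded exposures should count in n is
  ambiguous in the upstream literature; they are excluded here and the
  count is reported alongside the results.

## Protein-interaction expansion (network)

L0 is the seed gene set plus all network SNPs regulating it. Seeding is
either explicit genes (risk genes) or GWAS SNPs expanded by strong LD
(r² ≥ 0.8 within ±5 kb). Each subsequent level adds score-filtered
neighbours not assigned to any earlier level (minimal-level assignment),
so k applications equal BFS layering of the filtered graph — this is
enforced by a brute-force BFS oracle in the tests. The interaction score
cutoff defaults to 0.7, the conventional "high-confidence" threshold for
curated interaction databases, and is a visible, required argument of the
run configuration. Genes without curated interactions simply stop
expanding (a known limitation of interaction-database coverage).
Expansion runs to L5; analyses default to L0–L3 to limit chance traits.

## Trait enrichment (enrich)

For one level and one catalog trait the statistic is the hypergeometric
upper tail P(X ≥ x) with M = unique catalog SNPs, n = trait SNPs,
N = the level's LD-expanded SNP set intersected with the catalog
universe, x = overlap. The intersection keeps the urn coherent (a SNP the
catalog has never seen cannot be drawn); x = 0 gives p = 1 exactly. LD
expansion is single-pass (not transitive) at r² ≥ 0.8 within ±5 kb.
Bonferroni across the traits tested at a level (α = 0.05) is the default
correction; BH is available behind a switch. The Monte-Carlo null redraws
seed-gene sets of the same size uniformly from the network's gene
universe, re-runs expansion and enrichment, and reports add-one-smoothed
empirical probabilities (1 + hits)/(1 + n_sims) per (trait, level) —
smoothing avoids zero p from finite replicates. Empirical probabilities
annotate results; they do not filter them (a configurable cutoff, default
0.05, marks "chance-explainable" traits).

## Annotation (annotate)

Over-representation uses the same hypergeometric tail on the urn
(background, pathway∩background, query, overlap) with BH across pathways;
the background defaults to the regulatory network's gene universe.
Pathway collections are user-supplied GMT files; gene→disease links are a
user-supplied table mapping genes to MeSH identifiers. No live database
access anywhere, for reproducibility.

## Comorbidity (comorbid)

Patients aged ≥ 100 are removed; a patient has a code if any record
matches. For index A vs code B the population partitions into C_AB, C_A
(A only), C_B (B only) and H, with margins P_A = C_A + C_AB,
P_B = C_B + C_AB. The three measures are

    RR    = C_AB·N / (P_A·P_B)
    OR    = C_AB·H / (C_A·C_B)          (Woolf CI on ln OR)
    score = log2((C_AB + 1)/(P_A·P_B/N + 1))

Two reading decisions are deliberate: P_A, P_B are patient *counts* (the
formulas are only dimensionless that way), and C_A, C_B in the OR are
*exclusive* counts (with inclusive counts the expression is not an odds
ratio and the four cells would not partition N). "OR confidence interval
overlapping zero" is implemented as the ln-OR CI containing 0 — a literal
OR CI can never reach 0. Any zero cell triggers the Haldane–Anscombe
+0.5 correction (flagged). Codes with fewer than 6 carriers are excluded
(`small_count`), then the CI rule (`ci_rule`); survivors get a two-sided
Fisher exact test with BH q-values — the upstream tooling names
"q-values" without a method, so the procedure is configurable. ICD→MeSH
conversion falls back from a full code to its 3-character category
(C434 → C43) and flags the fallback.

## Synthetic data (synth)

The generator emulates the schemas and statistical structure of the real
resources at desk scale, with planted, recorded truth. One integer seed
fans out to fixed per-generator substreams (seed + offset) so individual
files can be regenerated.

- **Genotypes.** Dosages are Hardy–Weinberg draws from a per-block MAF in
  [0.05, 0.5] (the common-variant regime). Within an LD block each
  haplotype copies a latent block allele with probability
  `ld_within_r2**(1/4)`, giving pairwise genotype r² = `ld_within_r2`
  (default 0.95) in expectation — consistent with the block-diagonal LD
  panel the analysis modules consume. SNPs sit at 1 kb spacing; blocks
  never span chromosomes.
- **eQTLs.** Effect magnitudes are uniform in [0.5, 1.5]·`eqtl_effect_sd`
  with random sign, so a nonzero setting guarantees detectable effects
  and zero gives an exact null. Assignment is *block-exclusive*: all of a
  gene's eQTL SNPs come from LD blocks no other gene uses. Without this,
  block-mates of a causal gene's instruments that instrument other genes
  inherit the causal outcome association through LD, which violates the
  exclusion-restriction assumption and plants systematic false "risk"
  genes — realistic (it is exactly what dense haplotypes such as
  inversion supergenes do) but wrong for a generator whose purpose is
  calibrated recovery testing. Causal genes get 3 instruments on 3
  distinct blocks (clumping keeps all three); planted trait genes get 2.
- **Outcome GWAS.** Case status is drawn from a logistic model whose
  linear predictor is `causal_effect` × the standardized expression of
  each causal gene, so the conditional log-OR per 1 SD of expression
  equals `causal_effect` exactly. Each SNP is tested with the logistic
  *score* test against the intercept-only null, reported in the
  convention of large-scale association tools (β = U/I, se = 1/√I), whose
  null tail is well calibrated. A 5% random subset of SNPs is withheld
  (exercising proxy lookup) and allele orientation is scrambled for ~30%
  (swap) and ~10% (strand complement) of rows (exercising harmonisation).
- **PPI.** High-confidence edges (scores 0.75–0.99) wire the causal genes
  to the planted genes through a shared path of exactly
  `planted_trait_level` hops, with two filler neighbours per level;
  low-score decoys (0.1–0.5) and random background edges never touch the
  planted path, so the planted level is exact at any cutoff ≥ 0.5.
- **Catalog.** Null traits draw 5–15 SNPs uniformly; the planted trait's
  SNPs are exactly the planted genes' regulatory SNPs.
- **Registry.** Everyone carries a generic encounter code (so the
  registry enumerates the population); the index code has 5% prevalence;
  background codes are independent Bernoulli draws (1–8%); planted
  comorbid codes get their joint probability with the index code set by
  the Plackett solution so the population odds ratio equals
  `comorbid_or`. About 1% of patients are aged ≥ 100 to exercise the age
  filter. A third of codes (always including the planted ones) map to
  MeSH; planted and causal genes link to the planted codes' MeSH terms.

Defaults (n_individuals 500, n_snps 480, n_genes 120 over 4 chromosomes,
1 causal gene with log-OR 0.3 per SD, eqtl_effect_sd 0.8, 20 traits with
the planted trait at level 2, 20 000 patients with planted OR 4) are the
study conditions of the validation experiments; the recovery experiments
raise n_individuals to 2000 and eqtl_effect_sd to 1.2 so the causal
gene's three instruments all clear the p < 1e-5 instrument threshold.
The end-to-end demo configuration uses causal_effect 1.0 and
n_individuals 1000 so the causal arm has nonempty risk-gene seeds at
desk scale.

**What passing tests do not show.** The generator has no LD decay (r² is
constant within a block, zero across), no population structure, no
cross-gene regulatory correlation, no confounding, sex chromosomes or
imputation error, and its outcome cohort shares individuals with the
eQTL cohort (harmless here because expression noise is independent of
liability, but real two-sample designs exist precisely because that
cannot be assumed). Recovery on this generator validates the pipeline's
logic and calibration, not its behaviour on real tissue eQTL or registry
data.

## Numerical choices

- Hypergeometric tails via `scipy.stats.hypergeom.sf(x−1, M, n, N)`;
  exhaustive enumeration is the independent test oracle (exact agreement
  to 1e-12 for all urns with M ≤ 12).
- p-values emitted by the regulatory network are clamped into (0, 1] at
  the smallest positive double.
- Wald/IVW p-values are two-sided normal; Q is χ²(k−1); the Egger
  intercept uses a t reference with k−2 df.
- Clumping, proxy choice and enrichment sorting all carry deterministic
  tie-breaks (p, then id; r², then distance, then id; p_adj, p_raw,
  trait) so identical inputs give identical outputs on any platform.
- Monte-Carlo and all generators use `numpy.random.default_rng` with
  explicit seeds; two runs with one seed are byte-identical.

## Known limitations

- The MR false-positive guarantee is the Bonferroni family-wise bound
  (≈0.05 per run); over 20 validation runs roughly one run with a single
  false risk gene is therefore *expected*, a property of the threshold
  rule rather than of the implementation.
- Single-instrument exposures cannot be screened for heterogeneity or
  pleiotropy; their Wald p is exactly the outcome association p.
- The enrichment urn treats catalog SNPs as exchangeable; real catalogs
  have massive per-trait ascertainment structure.
- Comorbidity measures are cross-sectional: no temporal ordering or
  directionality.
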