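"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate, at desk scale, the schemas and statistical structure
of the resources a tissue-specific regulatory-network multimorbidity study
draws on: a genotyped expression cohort with Hi-C-supported candidate
SNP-gene pairs, case/control outcome GWAS summary statistics, a
block-structured LD reference panel, a GWAS-catalog-style SNP-trait table, a
scored protein-protein interaction graph, and a patient diagnosis registry
with ICD->MeSH and gene->MeSH mapping tables.

Signal is *planted* and recorded in :class:`GroundTruth` so downstream
recovery tests have a known answer: causal genes with a chosen log-odds
effect on disease per SD of expression, eQTL SNPs with known per-allele
effects, a trait whose catalog SNPs coincide with the regulatory SNPs of
genes wired to sit at a chosen protein-interaction level, and diagnosis-code
pairs with a chosen co-occurrence odds ratio.

A single integer seed fans out to fixed per-generator substreams
(``seed + offset``) so each file can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

# Substream offsets: each generator owns seed + offset.
_OFF_COHORT = 0
_OFF_GWAS = 1
_OFF_CATALOG = 3
_OFF_PPI = 4
_OFF_REGISTRY = 5

_NUCLEOTIDES = np.array(["A", "C", "G", "T"])


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    ``causal_effect`` is the log-odds effect of disease per 1-SD change in
    the expression of each causal gene; ``eqtl_effect_sd`` scales per-allele
    eQTL effects (magnitudes are uniform in [0.5, 1.5] x this value);
    ``comorbid_or`` is the odds ratio targeted, in expectation, for the
    planted comorbid diagnosis-code pairs.
    """

    seed: int = 0
    n_individuals: int = 500
    n_snps: int = 480
    n_genes: int = 120
    n_chromosomes: int = 4
    n_causal_genes: int = 1
    causal_effect: float = 0.3
    eqtl_effect_sd: float = 0.8
    ld_block_size: int = 4
    ld_within_r2: float = 0.95
    n_traits: int = 20
    planted_trait_level: int = 2
    n_patients: int = 20000
    comorbid_or: float = 4.0
    # secondary knobs (defaults are part of the study conditions)
    noise_sd: float = 1.0
    n_planted_genes: int = 2
    n_hic_replicates: int = 3
    n_decoy_pairs: int | None = None  # default: 2 x n_genes
    decoy_pass_fraction: float = 0.5
    base_case_rate: float = 0.2
    outcome_missing_rate: float = 0.05
    index_prevalence: float = 0.05
    comorbid_baseline_prev: float = 0.05
    n_registry_codes: int = 30
    n_comorbid_codes: int = 2

    def __post_init__(self):
        counts = dict(
            n_individuals=self.n_individuals, n_snps=self.n_snps,
            n_genes=self.n_genes, n_chromosomes=self.n_chromosomes,
            n_causal_genes=self.n_causal_genes, ld_block_size=self.ld_block_size,
            n_traits=self.n_traits, n_patients=self.n_patients,
            n_hic_replicates=self.n_hic_replicates,
            n_registry_codes=self.n_registry_codes,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name, v in [("ld_within_r2", self.ld_within_r2),
                        ("decoy_pass_fraction", self.decoy_pass_fraction),
                        ("base_case_rate", self.base_case_rate),
                        ("outcome_missing_rate", self.outcome_missing_rate),
                        ("index_prevalence", self.index_prevalence),
                        ("comorbid_baseline_prev", self.comorbid_baseline_prev)]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.planted_trait_level <= 5:
            raise ValueError("planted_trait_level must be in 0..5")
        if self.comorbid_or < 1.0:
            raise ValueError("comorbid_or must be >= 1")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes exceeds n_genes")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted signal: what a recovery test should find."""

    causal_genes: set[str]
    planted_genes: set[str]
    planted_trait: str
    planted_trait_level: int
    planted_trait_snps: dict[str, set[str]]
    planted_comorbid_codes: set[str]
    true_eqtl_effects: dict[tuple[str, str], float]

    def gene_snps(self, gene: str) -> set[str]:
        return {s for (s, g) in self.true_eqtl_effects if g == gene}


@dataclass
class Cohort:
    """Outputs of :func:`generate_regulatory_cohort`."""

    genotypes: pd.DataFrame      # individual x SNP dosage matrix (+ 'individual')
    expression: pd.DataFrame     # individual x gene matrix (+ 'individual')
    hic_support: pd.DataFrame    # snp, gene, replicate_id, contact_count
    snps: pd.DataFrame           # snp, chr, pos, block, effect_allele, other_allele, maf
    genes: pd.DataFrame          # gene, chr, tss
    truth: GroundTruth

    def dosage_matrix(self) -> np.ndarray:
        return self.genotypes.drop(columns=["individual"]).to_numpy(float)

    def expression_matrix(self) -> np.ndarray:
        return self.expression.drop(columns=["individual"]).to_numpy(float)


def snp_map(config: SynthConfig) -> pd.DataFrame:
    """Deterministic SNP layout: id, chromosome, position, LD block.

    SNPs are spread evenly over chromosomes at 1 kb spacing; LD blocks are
    runs of ``ld_block_size`` consecutive SNPs that never span a chromosome
    boundary. The layout depends only on counts, never on the RNG, so the
    LD panel can be regenerated without the cohort.
    """
    per_chr = math.ceil(config.n_snps / config.n_chromosomes)
    rows = []
    for i in range(config.n_snps):
        chrom = i // per_chr + 1
        idx = i % per_chr
        block = f"{chrom}b{idx // config.ld_block_size}"
        rows.append((f"rs{i + 1:05d}", str(chrom), (idx + 1) * 1000, block))
    return pd.DataFrame(rows, columns=["snp", "chr", "pos", "block"])


def _gene_map(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = [str(i % config.n_chromosomes + 1) for i in range(config.n_genes)]
    tss = rng.integers(1, 2_000_001, size=config.n_genes)
    return pd.DataFrame({
        "gene": [f"GENE{i + 1:04d}" for i in range(config.n_genes)],
        "chr": chroms,
        "tss": tss,
    })


def _plant_truth(config: SynthConfig, snps: pd.DataFrame,
                 genes: pd.DataFrame, rng: np.random.Generator) -> GroundTruth:
    gene_ids = list(genes["gene"])
    order = rng.permutation(len(gene_ids))
    causal = [gene_ids[i] for i in order[: config.n_causal_genes]]
    if config.planted_trait_level == 0:
        planted = list(causal)
    else:
        planted = [gene_ids[i]
                   for i in order[config.n_causal_genes:
                                  config.n_causal_genes + config.n_planted_genes]]

    # eQTL SNP assignment is block-exclusive: all of a gene's eQTL SNPs come
    # from LD blocks no other gene uses, so no gene inherits another gene's
    # outcome association through linkage. Causal genes get 3 SNPs on 3
    # distinct blocks (clumping keeps all three as instruments), planted
    # genes 2 on 2 blocks, other genes 0-3 SNPs inside a single block.
    by_block: dict[str, list[str]] = {}
    for s, b in snps[["snp", "block"]].itertuples(index=False):
        by_block.setdefault(b, []).append(s)
    free_blocks = list(by_block)
    rng.shuffle(free_blocks)

    def take_distinct_blocks(k: int) -> list[str]:
        if len(free_blocks) < k:
            raise ValueError("not enough LD blocks to place planted eQTLs")
        chosen = []
        for _ in range(k):
            members = by_block[free_blocks.pop()]
            chosen.append(members[rng.integers(len(members))])
        return chosen

    def take(k: int) -> list[str]:
        if k == 0 or not free_blocks:
            return []
        members = list(by_block[free_blocks.pop()])
        rng.shuffle(members)
        return members[: min(k, len(members))]

    effects: dict[tuple[str, str], float] = {}

    def effect() -> float:
        mag = rng.uniform(0.5, 1.5) * config.eqtl_effect_sd
        return float(mag * rng.choice([-1.0, 1.0]))

    for g in causal:
        for s in take_distinct_blocks(3):
            effects[(s, g)] = effect()
    for g in planted:
        if g in causal:
            continue
        for s in take_distinct_blocks(2):
            effects[(s, g)] = effect()
    special = set(causal) | set(planted)
    for g in gene_ids:
        if g in special:
            continue
        for s in take(int(rng.integers(0, 4))):
            effects[(s, g)] = effect()

    trait = "trait_planted"
    trait_snps = {s for (s, g) in effects if g in planted}
    return GroundTruth(
        causal_genes=set(causal),
        planted_genes=set(planted),
        planted_trait=trait,
        planted_trait_level=config.planted_trait_level,
        planted_trait_snps={trait: trait_snps},
        planted_comorbid_codes=set(_code_universe(config)[1][: config.n_comorbid_codes]),
        true_eqtl_effects=effects,
    )


def generate_regulatory_cohort(config: SynthConfig) -> Cohort:
    """Genotypes, expression, Hi-C contact support and the planted truth.

    Dosages are drawn under Hardy-Weinberg from a per-block MAF in
    [0.05, 0.5]; within an LD block alleles are copied from a latent block
    haplotype with probability ``ld_within_r2**(1/4)`` per haplotype, which
    yields pairwise genotype r² equal to ``ld_within_r2`` in expectation —
    consistent with the block LD panel. Expression is the additive eQTL
    signal plus Gaussian noise. Every true eQTL pair passes the Hi-C
    replicate-support rule (contact >= 2 in >= 2 replicates); a configurable
    fraction of decoy pairs passes it too.
    """
    rng = np.random.default_rng(config.seed + _OFF_COHORT)
    snps = snp_map(config)
    genes = _gene_map(config, rng)
    truth = _plant_truth(config, snps, genes, rng)

    n = config.n_individuals
    copy_p = config.ld_within_r2 ** 0.25
    dosage = np.zeros((n, config.n_snps), dtype=np.int8)
    col_of = {s: j for j, s in enumerate(snps["snp"])}
    mafs = np.empty(config.n_snps)
    for block, members in snps.groupby("block", sort=False):
        p = rng.uniform(0.05, 0.5)
        cols = [col_of[s] for s in members["snp"]]
        for _hap in range(2):
            tag = rng.random(n) < p
            for j in cols:
                copy = rng.random(n) < copy_p
                fresh = rng.random(n) < p
                dosage[:, j] += np.where(copy, tag, fresh)
        mafs[cols] = p

    if not dosage.std(axis=0).any():
        raise ValueError("degenerate cohort: every SNP is monomorphic")

    expr = rng.normal(0.0, config.noise_sd, size=(n, config.n_genes))
    gcol = {g: j for j, g in enumerate(genes["gene"])}
    for (s, g), eff in truth.true_eqtl_effects.items():
        expr[:, gcol[g]] += eff * dosage[:, col_of[s]]

    # allele labels (effect allele = the counted dose allele)
    eff_idx = rng.integers(0, 4, size=config.n_snps)
    oth_idx = (eff_idx + rng.integers(1, 4, size=config.n_snps)) % 4
    snps = snps.assign(effect_allele=_NUCLEOTIDES[eff_idx],
                       other_allele=_NUCLEOTIDES[oth_idx],
                       maf=mafs)

    hic = _hic_support(config, snps, genes, truth, rng)

    individuals = [f"IND{i + 1:05d}" for i in range(n)]
    geno_df = pd.DataFrame(dosage, columns=list(snps["snp"]))
    geno_df.insert(0, "individual", individuals)
    expr_df = pd.DataFrame(expr, columns=list(genes["gene"]))
    expr_df.insert(0, "individual", individuals)
    return Cohort(geno_df, expr_df, hic, snps, genes, truth)


def _hic_support(config: SynthConfig, snps: pd.DataFrame, genes: pd.DataFrame,
                 truth: GroundTruth, rng: np.random.Generator) -> pd.DataFrame:
    reps = [f"rep{i + 1}" for i in range(config.n_hic_replicates)]
    rows: list[tuple[str, str, str, int]] = []

    def passing_counts() -> list[int]:
        counts = [int(rng.integers(0, 2)) for _ in reps]
        strong = rng.choice(len(reps), size=2, replace=False)
        for i in strong:
            counts[i] = int(rng.integers(2, 6))
        return counts

    def failing_counts() -> list[int]:
        counts = [int(rng.integers(0, 2)) for _ in reps]
        counts[int(rng.integers(0, len(reps)))] = int(rng.integers(2, 6))
        return counts

    true_pairs = set(truth.true_eqtl_effects)
    for (s, g) in sorted(true_pairs):
        for rep, c in zip(reps, passing_counts()):
            if c > 0:
                rows.append((s, g, rep, c))

    n_decoy = config.n_decoy_pairs
    if n_decoy is None:
        n_decoy = 2 * config.n_genes
    snp_ids, gene_ids = list(snps["snp"]), list(genes["gene"])
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoy:
        pair = (snp_ids[rng.integers(len(snp_ids))],
                gene_ids[rng.integers(len(gene_ids))])
        if pair not in true_pairs:
            decoys.add(pair)
    for i, (s, g) in enumerate(sorted(decoys)):
        counts = passing_counts() if rng.random() < config.decoy_pass_fraction \
            else failing_counts()
        for rep, c in zip(reps, counts):
            if c > 0:
                rows.append((s, g, rep, c))
    return pd.DataFrame(rows, columns=["snp", "gene", "replicate_id", "contact_count"])


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def generate_outcome_gwas(config: SynthConfig, cohort: Cohort) -> pd.DataFrame:
    """Case/control GWAS summary statistics for the simulated disease.

    Disease status is drawn from a logistic model whose linear predictor is
    ``causal_effect`` x the standardized expression of each causal gene, so
    the conditional log-odds per 1-SD expression equals ``causal_effect``
    exactly. Each polymorphic SNP is then tested by per-SNP logistic
    regression on the simulated cohort (Wald z). A fraction of SNPs is
    withheld from the table (proxy-lookup territory) and allele orientation
    is scrambled for a fraction of rows (harmonisation territory).
    """
    if not cohort.truth.causal_genes:
        raise ValueError("no causal genes planted")
    rng = np.random.default_rng(config.seed + _OFF_GWAS)
    dosage = cohort.dosage_matrix()
    if not dosage.std(axis=0).any():
        raise ValueError("no SNP has variance; cannot run association tests")
    expr = cohort.expression_matrix()
    gene_ids = list(cohort.genes["gene"])

    liability = np.zeros(len(dosage))
    for g in cohort.truth.causal_genes:
        x = expr[:, gene_ids.index(g)]
        liability += config.causal_effect * (x - x.mean()) / x.std()
    alpha0 = math.log(config.base_case_rate / (1 - config.base_case_rate))
    prob = 1.0 / (1.0 + np.exp(-(alpha0 + liability)))
    case = (rng.random(len(prob)) < prob).astype(float)

    betas, ses, pvals = _logistic_score_test(case, dosage.astype(float))
    keep_poly = dosage.std(axis=0) > 0
    out = pd.DataFrame({
        "snp": cohort.snps["snp"].to_numpy(),
        "beta": betas, "se": ses, "pval": pvals,
        "eaf": dosage.mean(axis=0) / 2.0,
    }).loc[keep_poly].reset_index(drop=True)
    meta = cohort.snps.set_index("snp")
    out["chr"] = meta.loc[out["snp"], "chr"].to_numpy()
    out["pos"] = meta.loc[out["snp"], "pos"].to_numpy()
    out["effect_allele"] = meta.loc[out["snp"], "effect_allele"].to_numpy()
    out["other_allele"] = meta.loc[out["snp"], "other_allele"].to_numpy()
    out["n"] = config.n_individuals

    # scramble orientation: swapped alleles (sign flip) for ~30%, strand
    # complement for ~10%; harmonisation must undo both
    swap = rng.random(len(out)) < 0.3
    out.loc[swap, ["effect_allele", "other_allele"]] = \
        out.loc[swap, ["other_allele", "effect_allele"]].to_numpy()
    out.loc[swap, "beta"] *= -1
    out.loc[swap, "eaf"] = 1 - out.loc[swap, "eaf"]
    comp = rng.random(len(out)) < 0.1
    for col in ("effect_allele", "other_allele"):
        out.loc[comp, col] = out.loc[comp, col].map(_COMPLEMENT)

    keep = rng.random(len(out)) >= config.outcome_missing_rate
    out = out.loc[keep].reset_index(drop=True)
    return out[["snp", "chr", "pos", "effect_allele", "other_allele",
                "eaf", "beta", "se", "pval", "n"]]


def _logistic_score_test(y: np.ndarray, X: np.ndarray):
    """Per-SNP logistic score test against the intercept-only null.

    With U = x'(y - ȳ) and I = ȳ(1-ȳ) Σ(x - x̄)², the reported effect is
    the standard score-test approximation beta = U/I with se = 1/sqrt(I)
    (the convention of large-scale association tools), so beta/se is the
    score z and the p-value is its two-sided normal tail. Vectorized over
    the columns of ``X``; monomorphic columns give NaN.
    """
    from scipy import stats

    ybar = y.mean()
    resid = y - ybar
    xbar = X.mean(axis=0)
    U = X.T @ resid
    ssx = ((X - xbar) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = ybar * (1 - ybar) * ssx
        beta = np.where(info > 0, U / info, np.nan)
        se = np.where(info > 0, 1.0 / np.sqrt(info), np.nan)
        z = np.where(info > 0, U / np.sqrt(info), np.nan)
    pval = 2 * stats.norm.sf(np.abs(z))
    return beta, se, pval


def generate_ld_panel(config: SynthConfig) -> pd.DataFrame:
    """Block-diagonal pairwise r² table: ``ld_within_r2`` within a block,
    nothing across blocks (sparse convention: absent pair = unlinked)."""
    snps = snp_map(config)
    rows = []
    for _, members in snps.groupby("block", sort=False):
        ids = list(members["snp"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], config.ld_within_r2))
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def generate_trait_catalog(config: SynthConfig, snps: list[str] | pd.Series,
                           truth: GroundTruth, planted: bool = True) -> pd.DataFrame:
    """GWAS-catalog-style (snp, trait) table.

    Null traits draw SNP sets uniformly from the SNP universe. When
    ``planted`` is true the planted trait's SNP set is exactly the
    regulatory SNPs of the genes wired to appear at
    ``planted_trait_level`` of the protein-interaction expansion.
    """
    rng = np.random.default_rng(config.seed + _OFF_CATALOG)
    universe = list(snps)
    rows = []
    n_null = config.n_traits - (1 if planted else 0)
    for t in range(n_null):
        size = int(rng.integers(5, 16))
        chosen = rng.choice(universe, size=min(size, len(universe)), replace=False)
        rows += [(s, f"trait_{t + 1:03d}") for s in chosen]
    if planted:
        for s in sorted(truth.planted_trait_snps[truth.planted_trait]):
            rows.append((s, truth.planted_trait))
    return pd.DataFrame(rows, columns=["snp", "trait"])


def generate_ppi(config: SynthConfig, genes: list[str] | pd.Series,
                 truth: GroundTruth) -> pd.DataFrame:
    """Scored undirected PPI edge list wired so the planted genes sit at
    exactly ``planted_trait_level`` hops from the causal (seed) genes.

    High-confidence edges score in [0.75, 0.99]; decoy edges among
    background genes score in [0.1, 0.5] and vanish at the conventional
    high-confidence cutoff (0.7). Background edges never touch the planted
    path, so the planted level is exact at any cutoff.
    """
    rng = np.random.default_rng(config.seed + _OFF_PPI)
    gene_ids = list(genes)
    causal = sorted(truth.causal_genes)
    planted = sorted(truth.planted_genes)
    level = truth.planted_trait_level
    reserved = set(causal) | set(planted)
    spare = [g for g in gene_ids if g not in reserved]
    rng.shuffle(spare)

    if level > 0 and len(spare) < level - 1 + 2 * level:
        raise ValueError(
            f"planted_trait_level={level} unreachable with {len(gene_ids)} genes")

    edges: list[tuple[str, str]] = []
    path_nodes: list[str] = []
    if level > 0:
        chain = [spare.pop() for _ in range(level - 1)]
        path_nodes = chain
        hops = [causal[0]] + chain
        for a, b in zip(hops[:-1], hops[1:]):
            edges.append((a, b))
        for p in planted:
            edges.append((hops[-1], p))
    # filler neighbors keep intermediate levels non-trivial
    for k in range(1, level + 1):
        parent = causal[0] if k == 1 else path_nodes[k - 2]
        for _ in range(2):
            if spare:
                edges.append((parent, spare.pop()))

    protected = set(causal) | set(planted) | set(path_nodes)
    background = [g for g in gene_ids if g not in protected]
    high, low = [], []
    for a, b in edges:
        high.append((a, b, float(rng.uniform(0.75, 0.99))))
    n_bg = 2 * len(background)
    for _ in range(n_bg):
        a, b = rng.choice(background, size=2, replace=False)
        score = float(rng.uniform(0.75, 0.99)) if rng.random() < 0.5 \
            else float(rng.uniform(0.1, 0.5))
        (high if score >= 0.7 else low).append((a, b, score))
    df = pd.DataFrame(high + low, columns=["protein_a", "protein_b", "combined_score"])
    return df.drop_duplicates(subset=["protein_a", "protein_b"]).reset_index(drop=True)


def _code_universe(config: SynthConfig) -> tuple[str, list[str]]:
    """Deterministic diagnosis-code universe: the index code plus ICD-like
    background codes. The first ``n_comorbid_codes`` background codes are
    the planted comorbid pair partners."""
    letters = "EFCIJKMNR"
    codes = []
    i = 0
    while len(codes) < config.n_registry_codes - 1:
        codes.append(f"{letters[i % len(letters)]}{10 + i // len(letters) * 7 + i % 7:02d}")
        i += 1
    codes = list(dict.fromkeys(codes))[: config.n_registry_codes - 1]
    return "G20", codes


@dataclass
class Registry:
    records: pd.DataFrame    # patient_id, age, code
    icd_mesh: pd.DataFrame   # icd10, mesh_id
    gene_mesh: pd.DataFrame  # gene_id, mesh_id, mesh_label, source_score
    index_code: str


def _joint_prob(p_a: float, p_b: float, theta: float) -> float:
    """P(A and B) for given margins and odds ratio (Plackett)."""
    if abs(theta - 1.0) < 1e-12:
        return p_a * p_b
    s = 1 + (p_a + p_b) * (theta - 1)
    disc = s * s - 4 * theta * (theta - 1) * p_a * p_b
    return (s - math.sqrt(disc)) / (2 * (theta - 1))


def generate_registry(config: SynthConfig, truth: GroundTruth) -> Registry:
    """Patient-diagnosis registry with planted excess co-occurrence.

    Background codes are independent Bernoulli draws; for each planted
    comorbid code the joint probability with the index code is set so the
    population odds ratio equals ``comorbid_or``. Every patient carries a
    generic encounter code so the registry enumerates the full population.
    About 1% of patients are aged >= 100 to exercise the age filter.
    """
    rng = np.random.default_rng(config.seed + _OFF_REGISTRY)
    index_code, background = _code_universe(config)
    planted = sorted(truth.planted_comorbid_codes)
    n = config.n_patients

    ages = rng.integers(20, 100, size=n)
    old = rng.random(n) < 0.01
    ages = np.where(old, rng.integers(100, 105, size=n), ages)

    p_a = config.index_prevalence
    has_a = rng.random(n) < p_a

    rows_pid, rows_age, rows_code = [], [], []
    pids = np.array([f"P{i + 1:06d}" for i in range(n)])

    def emit(mask: np.ndarray, code: str) -> None:
        rows_pid.append(pids[mask])
        rows_age.append(ages[mask])
        rows_code.append(np.full(mask.sum(), code))

    emit(np.ones(n, bool), "Z00")
    emit(has_a, index_code)

    for code in background:
        p_b = config.comorbid_baseline_prev if code in planted \
            else float(rng.uniform(0.01, 0.08))
        if code in planted:
            p_ab = _joint_prob(p_a, p_b, config.comorbid_or)
            p_given_a = p_ab / p_a
            p_given_not = (p_b - p_ab) / (1 - p_a)
            has_b = np.where(has_a, rng.random(n) < p_given_a,
                             rng.random(n) < p_given_not)
        else:
            has_b = rng.random(n) < p_b
        emit(has_b.astype(bool), code)

    records = pd.DataFrame({
        "patient_id": np.concatenate(rows_pid),
        "age": np.concatenate(rows_age),
        "code": np.concatenate(rows_code),
    })

    # ICD->MeSH: about a third of codes map; planted codes always map
    all_codes = [index_code] + background
    mapped = set(planted) | {index_code}
    for c in background:
        if c not in mapped and rng.random() < 0.28:
            mapped.add(c)
    icd_mesh = pd.DataFrame(
        [(c, f"D{1000 + i:06d}") for i, c in enumerate(sorted(mapped))],
        columns=["icd10", "mesh_id"])

    # gene->MeSH: planted + causal genes link to the planted codes' MeSH
    # terms; a few background genes link to random terms
    mesh_of = dict(icd_mesh.itertuples(index=False))
    glinks = []
    for g in sorted(truth.planted_genes | truth.causal_genes):
        for c in planted:
            glinks.append((g, mesh_of[c], f"condition {c}", 0.8))
    extra_meshes = sorted(set(mesh_of.values()))
    for i in range(5):
        glinks.append((f"GENE{900 + i:04d}", extra_meshes[i % len(extra_meshes)],
                       "background condition", 0.3))
    gene_mesh = pd.DataFrame(
        glinks, columns=["gene_id", "mesh_id", "mesh_label", "source_score"])
    return Registry(records, icd_mesh, gene_mesh, index_code)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Serialise every cohort table to TSV under ``outdir``."""
    outdir = Path(outdir)
    paths = {}
    for name, df in [("genotypes", cohort.genotypes),
                     ("expression", cohort.expression),
                     ("hic_support", cohort.hic_support),
                     ("snps", cohort.snps), ("genes", cohort.genes)]:
        p = outdir / f"{name}.tsv"
        io.write_tsv(df, p)
        paths[name] = p
    return paths


def generate_all(config: SynthConfig, outdir: str | Path | None = None):
    """Run every generator; optionally write all files under ``outdir``."""
    cohort = generate_regulatory_cohort(config)
    gwas = generate_outcome_gwas(config, cohort)
    ld = generate_ld_panel(config)
    catalog = generate_trait_catalog(config, cohort.snps["snp"], cohort.truth)
    ppi = generate_ppi(config, cohort.genes["gene"], cohort.truth)
    registry = generate_registry(config, cohort.truth)
    bundle = {
        "cohort": cohort, "gwas": gwas, "ld": ld, "catalog": catalog,
        "ppi": ppi, "registry": registry,
    }
    if outdir is not None:
        outdir = Path(outdir)
        write_cohort(cohort, outdir)
        io.write_tsv(gwas, outdir / "gwas.tsv")
        io.write_tsv(ld, outdir / "ld.tsv")
        io.write_tsv(catalog, outdir / "catalog.tsv")
        io.write_tsv(ppi, outdir / "ppi.tsv")
        registry.records.to_csv(outdir / "registry.csv", index=False)
        io.write_tsv(registry.icd_mesh, outdir / "icd_mesh.tsv")
        io.write_tsv(registry.gene_mesh, outdir / "gene_mesh.tsv")
    return bundle
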