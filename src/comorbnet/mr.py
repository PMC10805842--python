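"""Transcriptome-wide two-sample Mendelian randomization.

Gene expression levels are the exposures, a binary disease the outcome, and
regulatory-network eQTLs the instruments. The chain is the standard one:
instrument selection (association p < 1e-5 and network FDR < 0.05), greedy
LD clumping (10 Mb window, r² < 0.001), proxy substitution for instruments
absent from the outcome statistics (r² > 0.9), allele harmonisation, then
the Wald ratio for single-instrument exposures or fixed-effects IVW for
multi-instrument ones, with Cochran's Q heterogeneity exclusion and an
MR-Egger intercept pleiotropy flag. Per-exposure p-values are Bonferroni
classified: risk (p < 0.05/n exposures), suggestive (< 0.05), else null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import LDTable

P_THRESHOLD = 1e-5
CLUMP_WINDOW_BP = 10_000_000
CLUMP_R2 = 0.001
PROXY_R2 = 0.9
PALINDROME_WINDOW = (0.42, 0.58)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class Instrument:
    """A harmonised exposure/outcome effect pair for one SNP."""

    snp_id: str
    exposure_gene: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    beta_out: float
    se_out: float
    pval_out: float
    effect_allele: str
    other_allele: str
    eaf_exp: float
    eaf_out: float
    is_proxy: bool = False
    proxy_for: str = ""


@dataclass
class MRResult:
    gene_id: str
    n_instruments: int
    method: str                      # wald_ratio | ivw
    estimate: float                  # log-OR per 1-SD expression
    se: float
    pval: float
    q_stat: float = math.nan
    q_pval: float = math.nan
    egger_intercept: float = math.nan
    egger_intercept_se: float = math.nan
    egger_intercept_pval: float = math.nan
    classification: str = "null"

    @property
    def or_value(self) -> float:
        return math.exp(self.estimate)

    @property
    def ci_low(self) -> float:
        return math.exp(self.estimate - 1.959963984540054 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.estimate + 1.959963984540054 * self.se)


def select_instruments(grn: pd.DataFrame, p_threshold: float = P_THRESHOLD,
                       fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Exposure table: associations with p < threshold (strict) and FDR < 0.05."""
    mask = (grn["pval"] < p_threshold) & (grn["fdr"] < fdr_threshold)
    return grn.loc[mask].reset_index(drop=True)


def clump(instruments: pd.DataFrame, ld: LDTable,
          window_bp: int = CLUMP_WINDOW_BP, r2_max: float = CLUMP_R2) -> pd.DataFrame:
    """Greedy LD clumping of one gene's candidate instruments.

    SNPs are taken in ascending association p order; a SNP is accepted iff
    it has r² < ``r2_max`` with every already-accepted SNP on the same
    chromosome within ``window_bp``. Pairs absent from the LD table count
    as unlinked. Ties in p break on SNP id for determinism.
    """
    if instruments.empty:
        return instruments
    df = instruments.sort_values(["pval", "snp_id"]).reset_index(drop=True)
    accepted: list[int] = []
    for i, row in df.iterrows():
        ok = True
        for j in accepted:
            prev = df.loc[j]
            if (str(prev["snp_chr"]) == str(row["snp_chr"])
                    and abs(int(prev["snp_pos"]) - int(row["snp_pos"])) <= window_bp
                    and ld.r2(prev["snp_id"], row["snp_id"]) >= r2_max):
                ok = False
                break
        if ok:
            accepted.append(i)
    return df.loc[accepted].reset_index(drop=True)


def find_proxy(snp_id: str, outcome: pd.DataFrame, ld: LDTable,
               positions: dict[str, int] | None = None,
               r2_min: float = PROXY_R2) -> str | None:
    """Best replacement for an instrument missing from the outcome table:
    the available SNP with maximal r² > ``r2_min`` (strict); ties break on
    smallest genomic distance, then lexicographic id."""
    available = set(outcome["snp"])
    cands = [(s, r2) for s, r2 in ld.mates(snp_id).items()
             if r2 > r2_min and s in available]
    if not cands:
        return None
    pos = positions or {}

    def key(item):
        s, r2 = item
        dist = abs(pos.get(s, 0) - pos.get(snp_id, 0)) if pos else 0
        return (-r2, dist, s)

    return sorted(cands, key=key)[0][0]


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonise(exposure: dict, outcome: dict) -> Instrument | None:
    """Align the outcome effect to the exposure's effect allele.

    Swapped alleles flip the outcome beta (and eaf); strand-complemented
    alleles are complemented then aligned. Palindromic SNPs (A/T, C/G) are
    oriented by allele frequency and dropped when the frequency on either
    side falls in the uninformative window (0.42, 0.58). Incompatible
    allele sets drop the instrument. Returns None on a drop.
    """
    for side, row in (("exposure", exposure), ("outcome", outcome)):
        for k in ("effect_allele", "other_allele"):
            if k not in row or row[k] not in _COMPLEMENT:
                raise ValueError(f"{side} row lacks a valid {k}")
    e1, e2 = exposure["effect_allele"], exposure["other_allele"]
    o1, o2 = outcome["effect_allele"], outcome["other_allele"]
    beta_out, se_out = float(outcome["beta"]), float(outcome["se"])
    pval_out = float(outcome.get("pval", math.nan))
    eaf_out = float(outcome.get("eaf", math.nan))
    eaf_exp = float(exposure.get("eaf", math.nan))

    if _is_palindromic(e1, e2):
        if {o1, o2} != {e1, e2}:
            return None
        lo, hi = PALINDROME_WINDOW
        for f in (eaf_exp, eaf_out):
            if math.isnan(f) or lo < f < hi:
                return None
        # orient by frequency: effect alleles agree iff frequencies fall on
        # the same side of 0.5
        if (eaf_exp - 0.5) * (eaf_out - 0.5) < 0:
            beta_out = -beta_out
            eaf_out = 1 - eaf_out
    else:
        if (o1, o2) == (e1, e2):
            pass
        elif (o1, o2) == (e2, e1):
            beta_out = -beta_out
            eaf_out = 1 - eaf_out
        elif (_COMPLEMENT[o1], _COMPLEMENT[o2]) == (e1, e2):
            pass  # strand flip, same orientation
        elif (_COMPLEMENT[o1], _COMPLEMENT[o2]) == (e2, e1):
            beta_out = -beta_out
            eaf_out = 1 - eaf_out
        else:
            return None

    return Instrument(
        snp_id=str(exposure["snp_id"]),
        exposure_gene=str(exposure.get("gene_id", "")),
        beta_exp=float(exposure["beta"]), se_exp=float(exposure["se"]),
        pval_exp=float(exposure["pval"]),
        beta_out=beta_out, se_out=se_out, pval_out=pval_out,
        effect_allele=e1, other_allele=e2,
        eaf_exp=eaf_exp, eaf_out=eaf_out,
        is_proxy=bool(exposure.get("is_proxy", False)),
        proxy_for=str(exposure.get("proxy_for", "")),
    )


def wald_ratio(inst: Instrument) -> MRResult:
    """Single-instrument causal estimate: beta_out / beta_exp, first-order
    delta-method SE (se_out / |beta_exp|), two-sided normal p."""
    if inst.beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    est = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    p = _normal_p(est, se)
    return MRResult(inst.exposure_gene, 1, "wald_ratio", est, se, p)


def _normal_p(est: float, se: float) -> float:
    if se == 0:
        return 1.0 if est == 0 else 0.0
    return float(2 * stats.norm.sf(abs(est) / se))


def _ratios(insts: list[Instrument]) -> tuple[np.ndarray, np.ndarray]:
    r = np.array([i.beta_out / i.beta_exp for i in insts])
    se = np.array([i.se_out / abs(i.beta_exp) for i in insts])
    return r, se


def ivw(insts: list[Instrument]) -> MRResult:
    """Fixed-effects inverse-variance-weighted combination of per-instrument
    Wald ratios (>= 2 instruments)."""
    if len(insts) < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio")
    if any(i.beta_exp == 0 for i in insts):
        raise ZeroDivisionError("IVW undefined with beta_exp = 0 instrument")
    r, se = _ratios(insts)
    w = 1.0 / se**2
    est = float(np.sum(w * r) / np.sum(w))
    se_ivw = float(math.sqrt(1.0 / np.sum(w)))
    res = MRResult(insts[0].exposure_gene, len(insts), "ivw",
                   est, se_ivw, _normal_p(est, se_ivw))
    res.q_stat, res.q_pval = cochran_q(insts)
    return res


def cochran_q(insts: list[Instrument]) -> tuple[float, float]:
    """Cochran's Q across per-instrument ratios (chi-square, k-1 df)."""
    if len(insts) < 2:
        raise ValueError("Cochran's Q requires >= 2 instruments")
    r, se = _ratios(insts)
    w = 1.0 / se**2
    est = np.sum(w * r) / np.sum(w)
    q = float(np.sum(w * (r - est) ** 2))
    p = float(stats.chi2.sf(q, df=len(insts) - 1))
    return q, p


def egger_intercept(insts: list[Instrument]):
    """MR-Egger intercept: weighted regression of outcome betas on exposure
    betas (weights 1/se_out², exposure effects oriented positive). The
    intercept flags directional pleiotropy; it never excludes an exposure.
    Returns (intercept, se, p) or None with < 3 instruments.
    """
    if len(insts) < 3:
        return None
    sign = np.array([1.0 if i.beta_exp >= 0 else -1.0 for i in insts])
    bx = np.array([i.beta_exp for i in insts]) * sign
    by = np.array([i.beta_out for i in insts]) * sign
    w = np.array([1.0 / i.se_out**2 for i in insts])
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    dof = len(insts) - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = np.linalg.inv(xtwx) * sigma2
    se0 = math.sqrt(cov[0, 0])
    if se0 == 0:
        p = 1.0 if coef[0] == 0 else 0.0
    else:
        p = float(2 * stats.t.sf(abs(coef[0]) / se0, df=dof))
    return float(coef[0]), se0, p


def classify_genes(results: list[MRResult], n_exposures_tested: int) -> list[MRResult]:
    """Bonferroni classification: risk (p < 0.05/n), suggestive (< 0.05),
    null otherwise; heterogeneity exclusions are preserved."""
    if n_exposures_tested < 1:
        raise ValueError("n_exposures_tested must be >= 1")
    bonf = 0.05 / n_exposures_tested
    out = []
    for res in results:
        if res.classification == "excluded_heterogeneity":
            out.append(res)
            continue
        if res.pval < bonf:
            cls = "risk"
        elif res.pval < 0.05:
            cls = "suggestive"
        else:
            cls = "null"
        out.append(replace(res, classification=cls))
    return out


def run_mr(grn: pd.DataFrame, outcome: pd.DataFrame, ld: LDTable,
           snps: pd.DataFrame, p_threshold: float = P_THRESHOLD,
           q_alpha: float = 0.05) -> pd.DataFrame:
    """The full per-gene MR chain over a regulatory network.

    ``snps`` is the exposure-side SNP annotation (snp, effect_allele,
    other_allele, maf) — the dosage-counted allele each eQTL beta refers to.
    Returns one row per exposure with all MRResult fields. Exposures whose
    instruments show significant heterogeneity (Q p < ``q_alpha``) are kept
    in the table but classified ``excluded_heterogeneity``; the Bonferroni
    family is the number of exposures with a usable (non-excluded) estimate.
    """
    exposures = select_instruments(grn, p_threshold)
    out_idx = outcome.set_index("snp")
    snp_meta = snps.set_index("snp")
    positions = dict(zip(grn["snp_id"], grn["snp_pos"]))

    def exposure_row(snp: str, gene: str, assoc: dict, **extra) -> dict:
        m = snp_meta.loc[snp]
        return {
            "snp_id": snp, "gene_id": gene, "beta": assoc["beta"],
            "se": assoc["se"], "pval": assoc["pval"],
            "effect_allele": m["effect_allele"],
            "other_allele": m["other_allele"],
            "eaf": float(m["maf"]) if "maf" in m else math.nan,
            **extra,
        }

    results: list[MRResult] = []
    for gene, block in exposures.groupby("gene_id"):
        block = clump(block, ld)
        insts: list[Instrument] = []
        for row in block.to_dict("records"):
            snp = row["snp_id"]
            if snp in out_idx.index:
                exp_row = exposure_row(snp, gene, row)
                orow = out_idx.loc[snp].to_dict()
            else:
                proxy = find_proxy(snp, outcome, ld, positions)
                if proxy is None:
                    continue
                orow = out_idx.loc[proxy].to_dict()
                # replace-and-proceed: the original exposure coefficients
                # stand in unchanged (no r²-attenuation adjustment); the
                # proxy's outcome row is aligned against the proxy's own
                # dose-allele annotation
                exp_row = exposure_row(proxy, gene, row,
                                       is_proxy=True, proxy_for=snp)
            inst = harmonise(exp_row, _outcome_dict(orow))
            if inst is not None and inst.beta_exp != 0:
                insts.append(inst)
        if not insts:
            continue
        if len(insts) == 1:
            res = wald_ratio(insts[0])
        else:
            res = ivw(insts)
            if res.q_pval < q_alpha:
                res.classification = "excluded_heterogeneity"
            eg = egger_intercept(insts)
            if eg is not None:
                res.egger_intercept, res.egger_intercept_se, \
                    res.egger_intercept_pval = eg
        results.append(res)

    n_tested = sum(1 for r in results
                   if r.classification != "excluded_heterogeneity")
    if n_tested:
        results = classify_genes(results, n_tested)
    return results_frame(results, n_tested)


def _outcome_dict(orow: dict) -> dict:
    return {
        "effect_allele": orow["effect_allele"],
        "other_allele": orow["other_allele"],
        "beta": orow["beta"], "se": orow["se"],
        "pval": orow.get("pval", math.nan), "eaf": orow.get("eaf", math.nan),
    }


def results_frame(results: list[MRResult], n_exposures: int) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "gene_id": r.gene_id, "n_instruments": r.n_instruments,
            "method": r.method, "estimate": r.estimate, "se": r.se,
            "or_value": r.or_value, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "pval": r.pval, "q_stat": r.q_stat, "q_pval": r.q_pval,
            "egger_intercept": r.egger_intercept,
            "egger_intercept_pval": r.egger_intercept_pval,
            "classification": r.classification,
            "n_exposures_tested": n_exposures,
        })
    cols = ["gene_id", "n_instruments", "method", "estimate", "se",
            "or_value", "ci_low", "ci_high", "pval", "q_stat", "q_pval",
            "egger_intercept", "egger_intercept_pval", "classification",
            "n_exposures_tested"]
    return pd.DataFrame(rows, columns=cols)
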