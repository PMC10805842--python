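"""Registry-based pairwise comorbidity of an index diagnosis.

For an index code A (e.g. G20, Parkinson's disease) against every other
code B in a patient-diagnosis registry, the module builds the partition of
the patient population into C_AB (both), C_A (A only), C_B (B only) and H
(neither), and computes three co-occurrence measures on those counts:

    relative risk     RR  = C_AB * N / (P_A * P_B)        with P = C + C_AB
    odds ratio        OR  = C_AB * H / (C_A * C_B)        (Woolf 95% CI)
    comorbidity score     = log2((C_AB + 1) / (P_A*P_B/N + 1))

Patients aged >= 100 are removed before counting. Codes carried by fewer
than 6 patients are excluded, as are codes whose ln-OR confidence interval
contains 0 (OR CI containing 1); the remainder are tested with a two-sided
Fisher exact test and BH-adjusted q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AGE_MAX = 100
MIN_PATIENTS = 6
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ComorbidityCounts:
    """2x2-plus-margins patient counts for the pair (index A, code B)."""

    code_b: str
    C_AB: int  # both A and B
    C_A: int   # A only
    C_B: int   # B only
    H: int     # neither
    N: int     # total patients

    def __post_init__(self):
        if min(self.C_AB, self.C_A, self.C_B, self.H) < 0:
            raise ValueError("negative cell count")
        if self.C_AB + self.C_A + self.C_B + self.H != self.N:
            raise ValueError("cells do not partition the population")

    @property
    def P_A(self) -> int:
        return self.C_A + self.C_AB

    @property
    def P_B(self) -> int:
        return self.C_B + self.C_AB


def _indicator_matrix(registry: pd.DataFrame, age_max: int) -> pd.DataFrame:
    """Patient x code boolean matrix after the age filter."""
    required = {"patient_id", "age", "code"}
    missing = required - set(registry.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    young = registry.loc[registry["age"] < age_max,
                         ["patient_id", "code"]].drop_duplicates()
    return pd.crosstab(young["patient_id"], young["code"]).astype(bool)


def _counts_from_indicators(has_a: pd.Series, has_b: pd.Series,
                            code_b: str) -> ComorbidityCounts:
    both = int((has_a & has_b).sum())
    return ComorbidityCounts(
        code_b=code_b,
        C_AB=both,
        C_A=int(has_a.sum()) - both,
        C_B=int(has_b.sum()) - both,
        H=int((~has_a & ~has_b).sum()),
        N=int(len(has_a)),
    )


def build_counts(registry: pd.DataFrame, index_code: str, code_b: str,
                 age_max: int = AGE_MAX) -> ComorbidityCounts:
    """Counts for one code pair; a patient 'has' a code if any row matches."""
    mat = _indicator_matrix(registry, age_max)
    if index_code not in mat.columns or not mat[index_code].any():
        raise ValueError(f"index code {index_code!r} absent from registry")
    has_a = mat[index_code]
    has_b = mat[code_b] if code_b in mat.columns \
        else pd.Series(False, index=mat.index)
    return _counts_from_indicators(has_a, has_b, code_b)


def relative_risk(c: ComorbidityCounts) -> float:
    """RR = C_AB * N / (P_A * P_B); NaN when a margin is empty."""
    if c.P_A == 0 or c.P_B == 0:
        return math.nan
    return c.C_AB * c.N / (c.P_A * c.P_B)


def odds_ratio(c: ComorbidityCounts, ci_level: float = 0.95):
    """OR = C_AB * H / (C_A * C_B) with a Woolf (log) confidence interval.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all four
    cells. Returns (or_value, ci_low, ci_high, corrected_flag).
    """
    cells = [c.C_AB, c.C_A, c.C_B, c.H]
    corrected = 0 in cells
    a, b, d, h = (x + 0.5 for x in cells) if corrected else cells
    or_value = a * h / (b * d)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / d + 1 / h)
    lo = math.exp(math.log(or_value) - z * se)
    hi = math.exp(math.log(or_value) + z * se)
    return or_value, lo, hi, corrected


def comorbidity_score(c: ComorbidityCounts) -> float:
    """log2 of add-one-smoothed observed over expected co-diagnoses,
    expected C_AB = P_A * P_B / N."""
    if c.N <= 0:
        raise ValueError("empty population")
    expected = c.P_A * c.P_B / c.N
    return math.log2((c.C_AB + 1) / (expected + 1))


@dataclass
class ComorbidityResult:
    counts: ComorbidityCounts
    rr: float
    or_value: float
    or_ci_low: float
    or_ci_high: float
    score: float
    p_raw: float = math.nan
    q_value: float = math.nan
    excluded_reason: str = "none"  # none | small_count | ci_rule

    @property
    def code_b(self) -> str:
        return self.counts.code_b


def run_comorbidity(registry: pd.DataFrame, index_code: str,
                    min_patients: int = MIN_PATIENTS,
                    q_threshold: float = 0.05,
                    age_max: int = AGE_MAX):
    """Index code vs every other registry code.

    Exclusions: codes with fewer than ``min_patients`` carriers
    (small_count) and codes whose ln-OR 95% CI contains 0 (ci_rule).
    Surviving codes get a two-sided Fisher exact p on the 2x2 and BH
    q-values across that family. Returns ``(results, prevalence_percent)``
    where prevalence is 100 * P_A / N for the index code.
    """
    if registry.empty:
        raise ValueError("empty registry")
    mat = _indicator_matrix(registry, age_max)
    if index_code not in mat.columns or not mat[index_code].any():
        raise ValueError(f"index code {index_code!r} absent from registry")
    has_a = mat[index_code]
    n_total = len(mat)
    p_a = int(has_a.sum())

    results: list[ComorbidityResult] = []
    for code_b in sorted(c for c in mat.columns if c != index_code):
        c = _counts_from_indicators(has_a, mat[code_b], code_b)
        orv, lo, hi, _ = odds_ratio(c)
        res = ComorbidityResult(c, relative_risk(c), orv, lo, hi,
                                comorbidity_score(c))
        if c.P_B < min_patients:
            res.excluded_reason = "small_count"
        elif lo <= 1.0 <= hi:  # ln-OR CI contains 0
            res.excluded_reason = "ci_rule"
        results.append(res)

    tested = [r for r in results if r.excluded_reason == "none"]
    if tested:
        pvals = []
        for r in tested:
            c = r.counts
            table = [[c.C_AB, c.C_A], [c.C_B, c.H]]
            pvals.append(stats.fisher_exact(table, alternative="two-sided")[1])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, p, q in zip(tested, pvals, qvals):
            r.p_raw = float(p)
            r.q_value = float(q)

    prevalence = prevalence_percent(p_a, n_total)
    return results, prevalence


def prevalence_percent(n_index: int, n_total: int) -> float:
    """Index-condition prevalence as a percentage of the population."""
    if n_total <= 0:
        raise ValueError("empty population")
    return 100.0 * n_index / n_total


def icd_to_mesh(codes, mapping: pd.DataFrame):
    """Table-driven ICD-10 -> MeSH conversion with 3-character fallback.

    When an exact code is absent, its 3-character category row (C434 ->
    C43) is used and flagged. Returns ``(mapping_dict, fallback_codes,
    unmapped_codes)``; the mapping dict gives each mappable code its MeSH
    id set.
    """
    required = {"icd10", "mesh_id"}
    if not required.issubset(mapping.columns):
        raise ValueError(f"mapping table needs columns {sorted(required)}")
    by_code = mapping.groupby("icd10")["mesh_id"].apply(set)
    out: dict[str, set[str]] = {}
    fallback: list[str] = []
    unmapped: list[str] = []
    for code in dict.fromkeys(codes):  # preserve order, dedupe
        if code in by_code.index:
            out[code] = set(by_code[code])
        elif len(code) > 3 and code[:3] in by_code.index:
            out[code] = set(by_code[code[:3]])
            fallback.append(code)
        else:
            unmapped.append(code)
    return out, fallback, unmapped


def results_frame(results: list[ComorbidityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.counts
        rows.append({
            "code_b": c.code_b, "C_AB": c.C_AB, "C_A": c.C_A, "C_B": c.C_B,
            "P_A": c.P_A, "P_B": c.P_B, "H": c.H, "N": c.N,
            "rr": r.rr, "or_value": r.or_value,
            "or_ci_low": r.or_ci_low, "or_ci_high": r.or_ci_high,
            "score": r.score, "p_raw": r.p_raw, "q_value": r.q_value,
            "excluded_reason": r.excluded_reason,
        })
    return pd.DataFrame(rows)
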