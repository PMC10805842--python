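"""Mendelian-randomization chain: selection, clumping, proxies,
harmonisation, estimators, heterogeneity, pleiotropy, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comorbnet import mr
from comorbnet.io import LDTable


def _inst(beta_exp=0.5, se_exp=0.05, beta_out=0.1, se_out=0.05, snp="rs1",
          gene="G1", **kw):
    return mr.Instrument(
        snp_id=snp, exposure_gene=gene, beta_exp=beta_exp, se_exp=se_exp,
        pval_exp=1e-8, beta_out=beta_out, se_out=se_out, pval_out=0.01,
        effect_allele="A", other_allele="G", eaf_exp=0.3, eaf_out=0.3, **kw)


def _ld(pairs):
    return LDTable(pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"]))


class TestSelectInstruments:
    def test_thresholds_are_strict(self):
        grn = pd.DataFrame({
            "gene_id": ["G1", "G1", "G1"],
            "pval": [9.9e-6, 1e-5, 1e-7],
            "fdr": [0.01, 0.01, 0.2],
        })
        out = mr.select_instruments(grn)
        assert list(out["pval"]) == [9.9e-6]

    def test_empty_grn(self):
        grn = pd.DataFrame({"gene_id": [], "pval": [], "fdr": []})
        assert mr.select_instruments(grn).empty


class TestClump:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "snp_chr", "snp_pos",
                                           "pval"])

    def test_block_mates_keep_most_significant(self):
        df = self._frame([("a", "1", 1000, 1e-8), ("b", "1", 2000, 1e-6)])
        out = mr.clump(df, _ld([("a", "b", 0.95)]))
        assert list(out["snp_id"]) == ["a"]

    def test_different_chromosomes_both_survive(self):
        df = self._frame([("a", "1", 1000, 1e-8), ("b", "2", 1000, 1e-6)])
        out = mr.clump(df, _ld([("a", "b", 0.95)]))
        assert set(out["snp_id"]) == {"a", "b"}

    def test_outside_window_both_survive(self):
        df = self._frame([("a", "1", 1, 1e-8),
                          ("b", "1", 10_000_002, 1e-6)])
        out = mr.clump(df, _ld([("a", "b", 0.9)]))
        assert set(out["snp_id"]) == {"a", "b"}

    def test_clumped_sets_are_maximal(self, rng):
        """No removed SNP could be re-added without violating the rule
        (brute-force check on random instances)."""
        for _ in range(20):
            n = int(rng.integers(5, 40))
            snps = [f"s{i}" for i in range(n)]
            df = self._frame([
                (s, str(rng.integers(1, 3)), int(rng.integers(1, 2_000_000)),
                 float(rng.uniform(1e-10, 1e-5))) for s in snps])
            pairs = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.2:
                        pairs.append((snps[i], snps[j],
                                      float(rng.uniform(0.002, 1.0))))
            ld = _ld(pairs) if pairs else _ld([("x", "y", 0.0)])
            kept = mr.clump(df, ld)
            kept_ids = set(kept["snp_id"])
            meta = df.set_index("snp_id")
            for s in set(snps) - kept_ids:
                row = meta.loc[s]
                conflicts = any(
                    str(meta.loc[k, "snp_chr"]) == str(row["snp_chr"])
                    and abs(int(meta.loc[k, "snp_pos"]) - int(row["snp_pos"]))
                    <= mr.CLUMP_WINDOW_BP
                    and ld.r2(k, s) >= mr.CLUMP_R2
                    for k in kept_ids)
                assert conflicts


class TestFindProxy:
    outcome = pd.DataFrame({"snp": ["b", "c"]})

    def test_block_mate_returned(self):
        assert mr.find_proxy("a", self.outcome, _ld([("a", "b", 0.95)])) == "b"

    def test_below_threshold_returns_none(self):
        assert mr.find_proxy("a", self.outcome, _ld([("a", "b", 0.85)])) is None

    def test_tie_breaks_on_distance(self):
        ld = _ld([("a", "b", 0.95), ("a", "c", 0.95)])
        pos = {"a": 1000, "b": 1200, "c": 1100}
        assert mr.find_proxy("a", self.outcome, ld, pos) == "c"


class TestHarmonise:
    exposure = {"snp_id": "rs1", "gene_id": "G1", "beta": 0.3, "se": 0.05,
                "pval": 1e-8, "effect_allele": "A", "other_allele": "G",
                "eaf": 0.3}

    def test_swapped_alleles_flip_outcome_beta(self):
        out = {"effect_allele": "G", "other_allele": "A", "beta": 0.2,
               "se": 0.05, "pval": 0.01, "eaf": 0.7}
        inst = mr.harmonise(self.exposure, out)
        assert inst.beta_out == pytest.approx(-0.2)
        assert inst.eaf_out == pytest.approx(0.3)
        assert inst.effect_allele == "A"

    def test_strand_complement_aligned(self):
        out = {"effect_allele": "T", "other_allele": "C", "beta": 0.2,
               "se": 0.05, "pval": 0.01, "eaf": 0.3}
        inst = mr.harmonise(self.exposure, out)
        assert inst.beta_out == pytest.approx(0.2)

    def test_unresolvable_palindrome_dropped(self):
        exp = dict(self.exposure, effect_allele="A", other_allele="T",
                   eaf=0.50)
        out = {"effect_allele": "A", "other_allele": "T", "beta": 0.2,
               "se": 0.05, "pval": 0.01, "eaf": 0.5}
        assert mr.harmonise(exp, out) is None

    def test_orientable_palindrome_flipped_by_frequency(self):
        exp = dict(self.exposure, effect_allele="A", other_allele="T",
                   eaf=0.2)
        out = {"effect_allele": "A", "other_allele": "T", "beta": 0.2,
               "se": 0.05, "pval": 0.01, "eaf": 0.8}
        inst = mr.harmonise(exp, out)
        assert inst.beta_out == pytest.approx(-0.2)

    def test_incompatible_alleles_dropped(self):
        out = {"effect_allele": "A", "other_allele": "C", "beta": 0.2,
               "se": 0.05, "pval": 0.01, "eaf": 0.3}
        assert mr.harmonise(self.exposure, out) is None

    def test_idempotent_on_aligned_rows(self):
        out = {"effect_allele": "A", "other_allele": "G", "beta": 0.2,
               "se": 0.05, "pval": 0.01, "eaf": 0.3}
        first = mr.harmonise(self.exposure, out)
        again = mr.harmonise(self.exposure, {
            "effect_allele": first.effect_allele,
            "other_allele": first.other_allele, "beta": first.beta_out,
            "se": first.se_out, "pval": first.pval_out,
            "eaf": first.eaf_out})
        assert again.beta_out == first.beta_out
        assert again.eaf_out == first.eaf_out

    def test_missing_allele_is_schema_error(self):
        with pytest.raises(ValueError):
            mr.harmonise(dict(self.exposure, effect_allele=None),
                         {"effect_allele": "A", "other_allele": "G",
                          "beta": 0.2, "se": 0.05})


class TestWaldRatio:
    def test_hand_arithmetic(self):
        res = mr.wald_ratio(_inst(beta_exp=0.5, beta_out=0.1, se_out=0.05))
        assert res.estimate == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)
        assert res.or_value == pytest.approx(math.exp(0.2))

    def test_null_outcome(self):
        res = mr.wald_ratio(_inst(beta_out=0.0))
        assert res.estimate == 0.0
        assert res.pval == pytest.approx(1.0)

    def test_sign_carried(self):
        res = mr.wald_ratio(_inst(beta_exp=-0.5, beta_out=0.1))
        assert res.estimate == pytest.approx(-0.2)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            mr.wald_ratio(_inst(beta_exp=0.0))


class TestIvw:
    def test_equal_weights_average(self):
        insts = [_inst(beta_exp=1.0, beta_out=0.2, se_out=0.1),
                 _inst(beta_exp=1.0, beta_out=0.4, se_out=0.1, snp="rs2")]
        assert mr.ivw(insts).estimate == pytest.approx(0.3)

    def test_hand_weighted_mean(self):
        insts = [_inst(beta_exp=1.0, beta_out=0.2, se_out=0.1),
                 _inst(beta_exp=1.0, beta_out=0.4, se_out=0.2, snp="rs2")]
        # (0.2/0.01 + 0.4/0.04) / (1/0.01 + 1/0.04) = 0.24
        assert mr.ivw(insts).estimate == pytest.approx(0.24)

    def test_constant_ratio_invariance(self):
        insts = [_inst(beta_exp=b, beta_out=0.37 * b, se_out=s, snp=f"rs{i}")
                 for i, (b, s) in enumerate([(0.5, 0.1), (1.0, 0.3),
                                             (2.0, 0.05)])]
        assert mr.ivw(insts).estimate == pytest.approx(0.37)

    def test_duplicate_instrument_degeneracy_matches_wald(self):
        inst = _inst()
        assert mr.ivw([inst, inst]).estimate == pytest.approx(
            mr.wald_ratio(inst).estimate)

    def test_single_instrument_is_contract_error(self):
        with pytest.raises(ValueError):
            mr.ivw([_inst()])


class TestCochranQ:
    def test_identical_ratios(self):
        q, p = mr.cochran_q([_inst(), _inst(snp="rs2")])
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_against_chi_square(self):
        insts = [_inst(beta_exp=1.0, beta_out=0.0, se_out=0.1),
                 _inst(beta_exp=1.0, beta_out=1.0, se_out=0.1, snp="rs2")]
        q, p = mr.cochran_q(insts)
        assert q == pytest.approx(50.0)
        assert p == pytest.approx(float(stats.chi2.sf(50.0, df=1)))

    def test_permutation_invariance(self):
        insts = [_inst(beta_out=b, snp=f"rs{i}")
                 for i, b in enumerate([0.1, 0.3, 0.2])]
        q1, _ = mr.cochran_q(insts)
        q2, _ = mr.cochran_q(insts[::-1])
        assert q1 == pytest.approx(q2)


class TestEggerIntercept:
    def test_proportional_effects_zero_intercept(self):
        insts = [_inst(beta_exp=b, beta_out=0.3 * b, snp=f"rs{i}")
                 for i, b in enumerate([0.4, 0.8, 1.5, 2.0])]
        intercept, _, _ = mr.egger_intercept(insts)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_planted_intercept_recovered(self):
        """beta_out = 0.1 + 0.2 beta_exp with negligible noise: the weighted
        regression recovers the pleiotropic intercept (WLS oracle)."""
        rng = np.random.default_rng(3)
        insts = [_inst(beta_exp=b, beta_out=0.1 + 0.2 * b + rng.normal(0, 1e-6),
                       snp=f"rs{i}")
                 for i, b in enumerate([0.4, 0.8, 1.5, 2.0, 3.0])]
        intercept, se, p = mr.egger_intercept(insts)
        assert intercept == pytest.approx(0.1, abs=1e-4)
        assert p < 0.05

    def test_two_instruments_not_evaluable(self):
        assert mr.egger_intercept([_inst(), _inst(snp="rs2")]) is None


class TestClassifyGenes:
    def _res(self, p, cls="null"):
        return mr.MRResult("G", 1, "wald_ratio", 0.1, 0.05, p,
                           classification=cls)

    @pytest.mark.parametrize("n,p,expected", [
        (3968, 1e-6, "risk"),          # 1e-6 < 0.05/3968
        (100, 0.01, "suggestive"),
        (100, 0.2, "null"),
    ])
    def test_thresholds(self, n, p, expected):
        out = mr.classify_genes([self._res(p)], n)
        assert out[0].classification == expected

    def test_heterogeneity_exclusion_preserved(self):
        out = mr.classify_genes([self._res(1e-9, "excluded_heterogeneity")],
                                10)
        assert out[0].classification == "excluded_heterogeneity"


class TestRunMr:
    def test_full_chain_on_synthetic_bundle(self, bundle, grn_df, ld, cohort):
        res = mr.run_mr(grn_df, bundle["gwas"], ld, cohort.snps)
        assert not res.empty
        assert set(res["method"]) <= {"wald_ratio", "ivw"}
        # OR/CI consistency per row
        assert np.allclose(res["or_value"], np.exp(res["estimate"]))
        assert (res["ci_low"] <= res["or_value"]).all()
        assert (res["or_value"] <= res["ci_high"]).all()
        causal = next(iter(cohort.truth.causal_genes))
        assert causal in set(res["gene_id"])
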