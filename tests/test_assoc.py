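"""Association-scan contracts: additive coding, logistic and multinomial
fits (cross-checked against statsmodels), screening and calibration."""

import numpy as np
import pandas as pd
import pytest

from abokit.assoc import (
    ScanConfig,
    code_additive,
    fit_logistic_snp,
    fit_multinomial_snp,
    run_scan,
    screen_hits,
)
from abokit.simulate import noiseless_three_tag_config, simulate_cohort

from conftest import make_genotype_matrix


class TestAdditiveCoding:
    def _gm(self, dosages, ref="A", alt="G"):
        gm = make_genotype_matrix(np.asarray(dosages, float)[:, None])
        gm.snps.loc[0, "ref"] = ref
        gm.snps.loc[0, "alt"] = alt
        return gm

    def test_common_alt_allele_flipped_to_ref_counts(self):
        # ALT frequency 0.7: effect allele becomes REF
        d = [2, 2, 2, 1, 1, 2, 2, 1, 1, 0]
        gm = self._gm(d)
        coded, alleles = code_additive(gm)
        assert alleles.loc[0, "effect_allele"] == "A"
        assert np.array_equal(coded[:, 0], 2 - np.array(d, float))

    def test_minor_alt_allele_left_unchanged(self):
        d = [0, 0, 1, 0, 1, 0, 0, 0, 1, 1]
        gm = self._gm(d)
        coded, alleles = code_additive(gm)
        assert alleles.loc[0, "effect_allele"] == "G"
        assert np.array_equal(coded[:, 0], np.array(d, float))

    def test_exact_tie_breaks_to_lexicographically_smaller_allele(self):
        d = [0, 1, 2, 1]  # ALT frequency exactly 0.5
        gm = self._gm(d, ref="G", alt="A")
        coded, alleles = code_additive(gm)
        assert alleles.loc[0, "effect_allele"] == "A"
        assert np.array_equal(coded[:, 0], np.array(d, float))

    def test_multiallelic_site_rejected_by_name(self):
        gm = self._gm([0, 1, 2], alt="G,T")
        with pytest.raises(ValueError, match="snp0"):
            code_additive(gm)


def _two_group_fixture():
    # dosage 0: 10 cases / 30 controls; dosage 1: 20 cases / 20 controls
    dosage = np.concatenate([np.zeros(40), np.ones(40)])
    y = np.concatenate([np.ones(10), np.zeros(30), np.ones(20), np.zeros(20)])
    return dosage, y


class TestLogisticFit:
    def test_two_group_odds_ratio_closed_form(self):
        dosage, y = _two_group_fixture()
        res = fit_logistic_snp(dosage, y)
        assert res.beta == pytest.approx(np.log(3.0), abs=1e-6)
        assert res.OR == pytest.approx(3.0, abs=1e-5)
        assert res.converged

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 400
        dosage = rng.binomial(2, 0.3, n).astype(float)
        cov = rng.normal(size=(n, 2))
        logit = -0.5 + 0.4 * dosage + 0.3 * cov[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        res = fit_logistic_snp(dosage, y, cov)
        X = sm.add_constant(np.column_stack([dosage, cov]))
        ref = sm.Logit(y, X).fit(disp=0)
        assert res.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert res.se == pytest.approx(ref.bse[1], rel=1e-4)
        assert res.p == pytest.approx(ref.pvalues[1], rel=1e-3)

    def test_separation_flagged_with_finite_beta(self):
        dosage = np.concatenate([np.zeros(30), np.full(30, 2.0)])
        y = np.concatenate([np.zeros(30), np.ones(30)])
        res = fit_logistic_snp(dosage, y)
        assert not res.converged
        assert np.isfinite(res.beta)

    def test_monomorphic_dosage_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fit_logistic_snp(np.ones(50), np.tile([0.0, 1.0], 25))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic_snp(np.tile([0.0, 1.0], 25), np.ones(50))

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(33)
        n_sims, n = 400, 150
        hits = 0
        for _ in range(n_sims):
            dosage = rng.binomial(2, 0.3, n).astype(float)
            y = rng.integers(0, 2, n).astype(float)
            try:
                res = fit_logistic_snp(dosage, y)
            except ValueError:
                continue
            hits += res.p < 0.05
        rate = hits / n_sims
        assert rate == pytest.approx(
            0.05, abs=2 * np.sqrt(0.05 * 0.95 / n_sims)
        )


class TestMultinomialFit:
    def _cohort_dosage(self, seed=11, n=900):
        cohort = simulate_cohort(noiseless_three_tag_config(n, seed))
        gm = cohort.genotypes()
        sero = cohort.samples["serotype"].to_numpy(dtype=object)
        return gm, sero

    def test_matches_statsmodels_mnlogit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 500
        dosage = rng.binomial(2, 0.4, n).astype(float)
        # serotypes weakly associated with dosage
        probs = np.column_stack([
            0.3 + 0.05 * dosage, 0.3 - 0.02 * dosage,
            0.25 - 0.02 * dosage, 0.15 - 0.01 * dosage,
        ])
        probs /= probs.sum(axis=1, keepdims=True)
        types = np.array(["O", "A", "B", "AB"], dtype=object)
        sero = np.array([types[rng.choice(4, p=p)] for p in probs])
        results = fit_multinomial_snp(dosage, sero)
        # statsmodels codes categories alphabetically: A, AB, B, O;
        # re-reference to O by subtracting the O column
        y_codes = pd.Categorical(sero, categories=["O", "A", "B", "AB"]).codes
        X = sm.add_constant(dosage)
        ref = sm.MNLogit(y_codes, X).fit(disp=0, method="newton")
        ref_params = np.asarray(ref.params)  # (2, K-1), columns A, B, AB vs O
        for k, res in enumerate(results):
            assert res.beta == pytest.approx(ref_params[1, k], abs=1e-5)

    def test_null_dosage_gives_flat_contrasts(self):
        rng = np.random.default_rng(8)
        n = 800
        sero = rng.choice(
            np.array(["O", "A", "B", "AB"], dtype=object), size=n,
            p=[0.3, 0.3, 0.3, 0.1],
        )
        dosage = rng.binomial(2, 0.3, n).astype(float)
        results = fit_multinomial_snp(dosage, sero)
        for res in results:
            assert abs(res.beta) < 0.5
            assert res.p > 1e-3

    def test_o_tag_strongly_negative_in_all_contrasts(self):
        gm, sero = self._cohort_dosage()
        dosages, alleles = code_additive(gm)
        j = gm.snp_ids.index("rs8176719")
        # effect allele is the minor allele; orient to count O-tag copies
        o_dosage = dosages[:, j]
        if alleles.loc[j, "effect_allele"] != "T":  # T tags the O allele
            o_dosage = 2 - o_dosage
        results = fit_multinomial_snp(o_dosage, sero)
        for res in results:
            assert res.beta < -1
            assert res.p < 5e-8 or not res.converged

    def test_missing_reference_class_rejected(self):
        sero = np.array(["A", "B", "AB"] * 20, dtype=object)
        dosage = np.tile([0.0, 1.0, 2.0], 20)
        with pytest.raises(ValueError, match="O"):
            fit_multinomial_snp(dosage, sero)

    def test_binomial_and_multinomial_agree_on_null_snps(self):
        rng = np.random.default_rng(9)
        agree = 0
        n_sims = 40
        for _ in range(n_sims):
            n = 400
            sero = rng.choice(
                np.array(["O", "A", "B", "AB"], dtype=object), size=n,
                p=[0.3, 0.3, 0.3, 0.1],
            )
            dosage = rng.binomial(2, 0.3, n).astype(float)
            multi = fit_multinomial_snp(dosage, sero)
            binom = fit_logistic_snp(dosage, (sero != "O").astype(float))
            multi_sig = any(r.p < 0.05 / 3 for r in multi)
            binom_sig = binom.p < 0.05
            agree += multi_sig == binom_sig
        assert agree / n_sims >= 0.85


@pytest.fixture(scope="module")
def scan_fixture():
    """Noiseless three-tag cohort plus 300 null SNPs."""
    from abokit.simulate import noiseless_three_tag_config

    cfg = noiseless_three_tag_config(n_samples=600, rng_seed=44)
    cfg.n_null_snps = 300
    # small typing error so perfect tags do not separate the fits
    cfg.typing_error_rate = 0.02
    cohort = simulate_cohort(cfg)
    gm = cohort.genotypes()
    pheno = cohort.samples.rename(columns={"serotype": "abo"})
    return cohort, gm, pheno


class TestScan:
    def test_all_hits_map_to_abo_locus(self, scan_fixture):
        cohort, gm, pheno = scan_fixture
        results = run_scan(gm, pheno, "binomial",
                           ScanConfig(covariates=[], n_pcs=0))
        hits = screen_hits(results, 5e-8)
        hit_snps = set(hits["snp_id"])
        assert hit_snps  # the locus is found
        assert hit_snps <= set(cohort.tag_snps["snp_id"])

    def test_scan_is_deterministic(self, scan_fixture):
        _, gm, pheno = scan_fixture
        cfg = ScanConfig(covariates=[], n_pcs=0)
        a = run_scan(gm.subset_snps(list(gm.snp_ids[:20])), pheno,
                     "multinomial", cfg)
        b = run_scan(gm.subset_snps(list(gm.snp_ids[:20])), pheno,
                     "multinomial", cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_covariates_do_not_change_hit_identity(self, scan_fixture):
        _, gm, pheno = scan_fixture
        sub = gm.subset_snps(list(gm.snp_ids[:30]))
        with_cov = run_scan(sub, pheno, "binomial",
                            ScanConfig(covariates=["sex", "age"], n_pcs=0))
        without = run_scan(sub, pheno, "binomial",
                           ScanConfig(covariates=[], n_pcs=0))
        h1 = set(screen_hits(with_cov, 5e-8)["snp_id"])
        h2 = set(screen_hits(without, 5e-8)["snp_id"])
        assert h1 == h2

    def test_binomial_mode_produces_four_contrasts(self, scan_fixture):
        _, gm, pheno = scan_fixture
        sub = gm.subset_snps(list(gm.snp_ids[:5]))
        res = run_scan(sub, pheno, "binomial", ScanConfig(covariates=[],
                                                          n_pcs=0))
        assert set(res["contrast"]) == {
            "O-vs-nonO", "A-vs-nonA", "B-vs-nonB", "AB-vs-nonAB"
        }
        assert (res.groupby("snp_id").size() == 4).all()


class TestScreenHits:
    def _results(self, ps):
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(ps))],
                "chrom": "9",
                "pos": np.arange(len(ps)),
                "beta": np.ones(len(ps)),
                "p": ps,
            }
        )

    def test_threshold_straddle(self):
        hits = screen_hits(self._results([4e-8, 6e-8]), alpha=5e-8)
        assert list(hits["snp_id"]) == ["s0"]

    def test_empty_input_gives_empty_output(self):
        out = screen_hits(self._results([]), alpha=5e-8)
        assert len(out) == 0

    def test_sorted_ascending_with_beta_tiebreak(self):
        df = self._results([1e-9, 1e-10, 1e-9])
        df.loc[2, "beta"] = 5.0
        hits = screen_hits(df, 5e-8)
        assert list(hits["snp_id"]) == ["s1", "s2", "s0"]

    def test_genomewide_threshold_on_log_scale(self):
        assert round(-np.log10(5e-8), 2) == 7.30
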