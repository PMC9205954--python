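"""Logistic association engine: closed forms, invariances, null behaviour
and scan mechanics."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gsassoc.association import fit_logistic, make_design, run_scan, top_hit
from gsassoc.containers import GenotypeMatrix, SomaticGeneMatrix, VariantSet
from gsassoc.multiple_testing import significance_threshold


def _two_by_two(a, b, c, d):
    """y/dosage vectors for the table [[a, b], [c, d]] (rows: dosage 1/0)."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    dose = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return y, dose


class TestFitLogistic:
    def test_single_predictor_mle_equals_cross_product_ratio(self):
        # [[50, 950], [20, 980]]: OR = 50*980 / (950*20)
        y, dose = _two_by_two(50, 950, 20, 980)
        res = fit_logistic(y, dose)
        expected = np.log(50 * 980 / (950 * 20))
        assert res.beta == pytest.approx(expected, abs=1e-6)
        assert res.OR == pytest.approx(np.exp(expected), rel=1e-6)
        assert res.converged

    def test_or_and_ci_consistency(self):
        y, dose = _two_by_two(30, 70, 10, 90)
        res = fit_logistic(y, dose)
        assert res.OR == pytest.approx(np.exp(res.beta))
        assert res.ci_low == pytest.approx(np.exp(res.beta - 1.959963984540054 * res.se))
        assert res.ci_high == pytest.approx(np.exp(res.beta + 1.959963984540054 * res.se))
        assert 0 < res.p <= 1

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError, match="carrier"):
            fit_logistic(np.ones(10), np.arange(10) % 3)

    def test_null_fit_is_near_one_at_large_n(self, rng):
        n = 5000
        dose = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 0.2, n).astype(float)
        res = fit_logistic(y, dose)
        assert 0.9 < res.OR < 1.1

    def test_exactly_balanced_covariate_leaves_beta_unchanged(self, rng):
        # duplicating the data with a sign-flipped extra covariate is a
        # symmetric design: its coefficient is 0 and beta is unaffected
        n = 10_000
        dose = rng.binomial(2, 0.25, n).astype(float)
        y = rng.binomial(1, expit(-1.5 + 0.4 * dose)).astype(float)
        y2, dose2 = np.tile(y, 2), np.tile(dose, 2)
        cov = np.concatenate([np.ones(n), -np.ones(n)])[:, None]
        base = fit_logistic(y2, dose2)
        adjusted = fit_logistic(y2, dose2, covariates=cov)
        assert adjusted.beta == pytest.approx(base.beta, abs=1e-6)

    def test_parameter_recovery_is_nearly_unbiased(self, rng):
        beta_true = np.log(2.19)
        betas = []
        for _ in range(40):
            n = 5000
            dose = rng.binomial(2, 0.13, n).astype(float)
            p = expit(np.log(0.144 / 0.856) + beta_true * dose)
            y = (rng.random(n) < p).astype(float)
            betas.append(fit_logistic(y, dose).beta)
        bias = np.mean(betas) - beta_true
        assert abs(bias) < 0.05 * beta_true

    def test_separated_fit_flagged_not_raised(self):
        # dosage perfectly predicts the outcome: quasi-separation
        y = np.array([1.0] * 20 + [0.0] * 20)
        dose = np.array([2.0] * 20 + [0.0] * 20)
        res = fit_logistic(y, dose)
        assert not res.converged

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(400):
            n = 400
            dose = rng.binomial(2, 0.3, n).astype(float)
            y = rng.binomial(1, 0.3, n).astype(float)
            pvals.append(fit_logistic(y, dose).p)
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRunScan:
    @pytest.fixture()
    def scan_inputs(self, rng):
        n, m, g = 250, 6, 3
        variants = pd.DataFrame({
            "id": [f"v{i}" for i in range(m)], "chrom": "1",
            "pos": np.arange(m) + 1, "ref": "A", "alt": "G", "eaf": 0.3})
        gm = GenotypeMatrix(
            samples=[f"S{i}" for i in range(n)], variants=variants,
            dosages=rng.binomial(2, 0.3, (n, m)).astype(float))
        ind = pd.DataFrame(rng.binomial(1, 0.3, (n, g)), index=gm.samples,
                           columns=[f"g{j}" for j in range(g)])
        counts = pd.DataFrame({
            "nonsilent_snv": ind.sum(axis=1) + 1, "nonsilent_indel": 0,
            "nonsyn_point": ind.sum(axis=1) + 1}, index=gm.samples)
        som = SomaticGeneMatrix(indicators=ind, counts=counts)
        hyper = pd.Series(rng.binomial(1, 0.15, n), index=gm.samples)
        pairs = pd.DataFrame([(v, ge, "fixture") for v in variants["id"]
                              for ge in ind.columns],
                             columns=["variant_id", "gene", "rules"])
        vs = VariantSet(name="fixture", pairs=pairs)
        cov = pd.DataFrame({
            "age": rng.normal(60, 10, n),
            "sex": rng.binomial(1, 0.5, n),
            "study": rng.choice(["A", "B"], n),
        }, index=gm.samples)
        return gm, som, cov, vs, hyper

    def test_one_row_per_pair_and_top_hit(self, scan_inputs):
        gm, som, cov, vs, hyper = scan_inputs
        thr = significance_threshold(0.05, 3, 6)
        table, signif = run_scan(gm, som, cov, vs, "combined", thr,
                                 hyper_status=hyper)
        assert len(table) == vs.n_pairs
        best = top_hit(table)
        assert best["p"] == table["p"].min()
        assert set(signif.columns) == set(table.columns)

    def test_non_hyper_stratum_drops_hypermutated(self, scan_inputs):
        gm, som, cov, vs, hyper = scan_inputs
        thr = significance_threshold(0.05, 3, 6)
        table, _ = run_scan(gm, som, cov, vs, "non_hyper", thr,
                            hyper_status=hyper)
        assert (table["n"] == (hyper == 0).sum()).all()

    def test_joint_sample_permutation_leaves_p_identical(self, scan_inputs):
        gm, som, cov, vs, hyper = scan_inputs
        thr = significance_threshold(0.05, 3, 6)
        t1, _ = run_scan(gm, som, cov, vs, "combined", thr, hyper_status=hyper)
        perm = list(reversed(gm.samples))
        gm2 = gm.subset_samples(perm)
        som2 = SomaticGeneMatrix(indicators=som.indicators.loc[perm],
                                 counts=som.counts.loc[perm])
        t2, _ = run_scan(gm2, som2, cov.loc[perm], vs, "combined", thr,
                         hyper_status=hyper.loc[perm])
        k1 = t1.set_index(["variant", "gene"])["p"]
        k2 = t2.set_index(["variant", "gene"])["p"]
        assert np.allclose(k1.sort_index(), k2.sort_index())

    def test_empty_pair_list_rejected(self, scan_inputs):
        gm, som, cov, _, hyper = scan_inputs
        vs = VariantSet(name="empty",
                        pairs=pd.DataFrame(columns=["variant_id", "gene",
                                                    "rules"]))
        thr = significance_threshold(0.05, 1, 1)
        with pytest.raises(ValueError):
            run_scan(gm, som, cov, vs, "combined", thr, hyper_status=hyper)


def test_planted_effect_is_top_hit_of_cna_scan():
    """A planted germline-to-somatic effect (OR 2.19) inside a CNA region is
    recovered as the most associated pair of the non-hypermutated CNA-set
    scan."""
    from gsassoc.synthetic import (PlantedEffect, SimulationConfig,
                                   simulate_annotations, simulate_covariates,
                                   simulate_genotypes, simulate_somatic)
    from gsassoc.variant_sets import build_cna_set

    cfg = SimulationConfig(
        seed=41, n_samples=1375, n_blocks=12, variants_per_block=5,
        n_genes=12, baseline_carrier_freq=0.144, carrier_freq_jitter_sd=0.3,
        planted_effects=(PlantedEffect("v00002", "G000", np.log(2.19)),))
    gm = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    som, truth = simulate_somatic(cfg, gm, cov)
    annot = simulate_annotations(cfg)
    vs = build_cna_set(gm.variants, annot.cna_regions, annot.gene_chrom())
    thr = significance_threshold(0.05, 12, 50)
    table, _ = run_scan(gm, som, cov, vs, "non_hyper", thr,
                        hyper_status=truth.hyper_status)
    best = top_hit(table)
    assert (best["variant"], best["gene"]) == ("v00002", "G000")
    assert best["OR"] > 1.5


def test_make_design_encodes_study_contrasts(small_cohort):
    design = make_design(small_cohort.covariates, small_cohort.genotypes.samples)
    n_studies = small_cohort.covariates["study"].nunique()
    # age + sex + 10 PCs + (n_studies - 1) indicator contrasts
    assert design.shape == (small_cohort.genotypes.n_samples,
                            12 + n_studies - 1)
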