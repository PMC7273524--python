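"""Association scan calibration, conditional regression, and
Haseman-Elston variance components."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tpewas import (
    CollinearityError,
    GeneticArchitecture,
    InvalidParameterError,
    conditional_regression,
    genetic_correlation_he,
    genomic_inflation,
    gwas,
    heritability_he,
    simulate_cohort,
)
from tpewas.simulate import GenotypeCohort


def _flip_variant(cohort, j):
    """Return a cohort with variant j's alleles relabelled (dosage 2-g)."""
    dosages = cohort.dosages.copy()
    dosages[:, j] = 2 - dosages[:, j]
    variants = cohort.variants.copy()
    variants.loc[j, ["ref", "alt"]] = variants.loc[j, ["alt", "ref"]].values
    return GenotypeCohort(dosages=dosages, variants=variants, sample_ids=cohort.sample_ids)


class TestGwas:
    def test_null_p_values_uniform(self, null_cohort):
        cohort, traits = null_cohort
        res = gwas(cohort, traits["trait_a"].to_numpy(), maf_min=0.01)
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        lam = genomic_inflation(res["p"])
        assert 0.95 <= lam <= 1.05
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_variant_reaches_genome_wide_significance(self):
        beta = np.zeros(50)
        beta[0] = np.sqrt(0.01)
        arch = GeneticArchitecture(
            n_individuals=20000, n_variants=50, h2=0.01, causal_effects=beta, seed=21
        )
        cohort, traits = simulate_cohort(arch)
        res = gwas(cohort, traits["trait_a"].to_numpy())
        assert res.loc[res["snv_id"] == "snv00000", "p"].iloc[0] < 5e-8

    def test_allele_flip_antisymmetry(self, small_cohort):
        cohort, traits = small_cohort
        y = traits["trait_a"].to_numpy()
        a = gwas(cohort, y)
        b = gwas(_flip_variant(cohort, 3), y)
        ra, rb = a.iloc[3], b.iloc[3]
        assert rb["beta"] == pytest.approx(-ra["beta"], abs=1e-12)
        assert rb["eaf"] == pytest.approx(1 - ra["eaf"], abs=1e-12)
        assert rb["p"] == pytest.approx(ra["p"], rel=1e-12)

    def test_sample_and_variant_order_invariance(self, small_cohort):
        cohort, traits = small_cohort
        y = traits["trait_a"].to_numpy()
        base = gwas(cohort, y)
        rng = np.random.default_rng(1)
        perm = rng.permutation(cohort.n_individuals)
        shuffled = GenotypeCohort(
            dosages=cohort.dosages[perm],
            variants=cohort.variants.copy(),
            sample_ids=cohort.sample_ids[perm],
        )
        again = gwas(shuffled, y[perm])
        assert np.allclose(base["beta"], again["beta"], atol=1e-10)
        assert np.allclose(base["p"], again["p"], rtol=1e-8)

    def test_collinear_covariates_rejected(self, small_cohort):
        cohort, traits = small_cohort
        n = cohort.n_individuals
        cov = pd.DataFrame({"a": np.arange(n), "b": 2.0 * np.arange(n)})
        with pytest.raises(CollinearityError):
            gwas(cohort, traits["trait_a"].to_numpy(), cov)

    def test_monomorphic_variant_skipped(self):
        arch = GeneticArchitecture(n_individuals=500, n_variants=10, h2=0.1, seed=3)
        cohort, traits = simulate_cohort(arch)
        cohort.dosages[:, 0] = 0
        res = gwas(cohort, traits["trait_a"].to_numpy())
        assert "snv00000" not in set(res["snv_id"])


class TestConditional:
    def test_lead_equals_candidate_rejected(self, small_cohort):
        cohort, traits = small_cohort
        with pytest.raises(InvalidParameterError):
            conditional_regression(
                cohort, traits["trait_a"].to_numpy(), None, "snv00001", "snv00001"
            )

    def test_perfect_ld_dropped_with_flag(self, small_cohort):
        cohort, traits = small_cohort
        dosages = cohort.dosages.copy()
        dosages[:, 5] = dosages[:, 4]
        twin = GenotypeCohort(
            dosages=dosages, variants=cohort.variants.copy(), sample_ids=cohort.sample_ids
        )
        res = conditional_regression(
            twin, traits["trait_a"].to_numpy(), None, "snv00004", "snv00005"
        )
        assert res.dropped
        assert res.p == 1.0
        assert "perfect_ld_with_lead" in res.flags

    def test_orthogonal_lead_leaves_coefficient_unchanged(self):
        # exactly orthogonal centered dosages by construction
        lead = np.tile([0, 0, 1, 1], 50).astype(np.int8)
        cand = np.tile([0, 1, 0, 1], 50).astype(np.int8)
        rng = np.random.default_rng(5)
        y = 0.3 * cand + rng.normal(size=200)
        variants = pd.DataFrame(
            {
                "snv_id": ["lead", "cand"],
                "chrom": [1, 1],
                "pos": [1000, 2000],
                "ref": "A",
                "alt": "G",
                "eaf": [0.25, 0.25],
            }
        )
        cohort = GenotypeCohort(
            dosages=np.column_stack([lead, cand]),
            variants=variants,
            sample_ids=np.array([f"s{i}" for i in range(200)]),
        )
        marginal = gwas(cohort, y)
        cond = conditional_regression(cohort, y, None, "lead", "cand")
        beta_marg = marginal.loc[marginal["snv_id"] == "cand", "beta"].iloc[0]
        assert cond.beta == pytest.approx(beta_marg, abs=1e-8)

    def test_independent_causal_pair_both_survive(self):
        # two unlinked causal variants: conditioning on one leaves the
        # other strongly associated
        beta = np.zeros(20)
        beta[0] = beta[1] = np.sqrt(0.01)
        arch = GeneticArchitecture(
            n_individuals=10000, n_variants=20, h2=0.02, causal_effects=beta, seed=8
        )
        cohort, traits = simulate_cohort(arch)
        y = traits["trait_a"].to_numpy()
        res = conditional_regression(cohort, y, None, "snv00000", "snv00001")
        assert res.p < 1e-6


class TestHasemanElston:
    def test_null_trait_recovers_zero(self, small_cohort, rng):
        cohort, _ = small_cohort
        noise = rng.normal(size=cohort.n_individuals)
        est = heritability_he(cohort, noise)
        assert abs(est.h2) < 2 * est.se

    def test_generating_h2_recovered(self, small_cohort):
        cohort, traits = small_cohort
        est = heritability_he(cohort, traits["trait_a"].to_numpy())
        assert est.h2 == pytest.approx(0.156, abs=2 * est.se)

    def test_affine_invariance(self, small_cohort):
        cohort, traits = small_cohort
        y = traits["trait_a"].to_numpy()
        a = heritability_he(cohort, y)
        b = heritability_he(cohort, 3.7 * y - 12.0)
        assert b.h2 == pytest.approx(a.h2, abs=1e-10)

    def test_rg_identity_when_traits_equal(self, small_cohort):
        cohort, traits = small_cohort
        y = traits["trait_a"].to_numpy()
        est = genetic_correlation_he(cohort, y, y)
        assert est.rg == pytest.approx(1.0, abs=1e-10)

    def test_rg_null_recovered(self):
        arch = GeneticArchitecture(
            n_individuals=2000, n_variants=500, h2=0.3, rg=0.0, seed=17
        )
        cohort, traits = simulate_cohort(arch)
        est = genetic_correlation_he(
            cohort, traits["trait_a"].to_numpy(), traits["trait_b"].to_numpy()
        )
        assert abs(est.rg) < 2 * est.se
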