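"""Locus definition, stage decisions, secondary signals, PVE, tally."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tpewas import (
    GeneticArchitecture,
    InvalidParameterError,
    bonferroni_threshold,
    define_loci,
    fulldata_decide,
    load_lead_snvs,
    replication_decide,
    secondary_signal_rule,
    sex_stratified,
    simulate_cohort,
    simulate_covariates,
    tally,
)
from tpewas.multistage import percent_variance_explained
from tpewas.published import stage_tables


def snv_table(rows):
    return pd.DataFrame(rows, columns=["snv_id", "chrom", "pos", "p"])


class TestBonferroni:
    def test_printed_rounding(self):
        assert bonferroni_threshold(21)[1] == 2.4e-3
        assert bonferroni_threshold(7)[1] == 7.1e-3
        assert bonferroni_threshold(4)[1] == 1.3e-2

    def test_exact_value(self):
        exact, _ = bonferroni_threshold(21)
        assert exact == pytest.approx(0.05 / 21)


class TestDefineLoci:
    def test_two_close_snvs_one_locus(self):
        rows = snv_table(
            [("a", 1, 1_000_000, 1e-9), ("b", 1, 1_100_000, 1e-8)]
        )
        loci = define_loci(rows)
        assert len(loci) == 1
        assert loci[0].lead_snv == "a"
        assert set(loci[0].member_snvs) == {"a", "b"}

    def test_chained_spacing_with_boundary_member(self):
        # 0 / 600 kb / 1.1 Mb with p 1e-12, 1e-9, 1e-10: the middle SNV
        # is 600 kb from the first lead (separate) but exactly 500 kb
        # from the second lead, and the documented boundary convention
        # (<= 500 kb absorbs) assigns it there
        rows = snv_table(
            [
                ("a", 1, 1, 1e-12),
                ("b", 1, 600_001, 1e-9),
                ("c", 1, 1_100_001, 1e-10),
            ]
        )
        loci = define_loci(rows)
        assert [l.lead_snv for l in loci] == ["a", "c"]
        assert set(loci[1].member_snvs) == {"b", "c"}

    def test_well_separated_snvs_form_own_loci(self):
        rows = snv_table(
            [
                ("a", 1, 1, 1e-12),
                ("b", 1, 600_001, 1e-9),
                ("c", 1, 1_200_001, 1e-10),
            ]
        )
        assert len(define_loci(rows)) == 3

    def test_member_at_exactly_500kb_absorbed(self):
        rows = snv_table([("a", 1, 1, 1e-12), ("b", 1, 500_001, 1e-9)])
        loci = define_loci(rows)
        assert len(loci) == 1

    def test_no_candidates_gives_empty(self):
        rows = snv_table([("a", 1, 1, 1e-3)])
        assert define_loci(rows) == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_loci_partition_candidates(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        rows = snv_table(
            [
                (f"s{i}", int(rng.integers(1, 4)), int(rng.integers(1, 5_000_000)),
                 float(10 ** rng.uniform(-12, -1)))
                for i in range(n)
            ]
        )
        loci = define_loci(rows)
        members = [s for l in loci for s in l.member_snvs]
        candidates = set(rows.loc[rows["p"] < 1e-6, "snv_id"])
        assert len(members) == len(set(members))  # no SNV in two loci
        assert set(members) == candidates
        # each lead has the smallest p among its members
        p_of = dict(zip(rows["snv_id"], rows["p"]))
        for locus in loci:
            assert p_of[locus.lead_snv] == min(p_of[s] for s in locus.member_snvs)


class TestStageDecisions:
    def test_published_rows_classify_as_printed(self):
        disc, repl, _ = stage_tables()
        dec = replication_decide(disc, repl, m_candidates=21)
        by_id = dec.set_index("snv_id")
        assert bool(by_id.loc["rs10864434", "replicated"])  # strong, concordant
        assert bool(by_id.loc["rs1424077", "candidate"])  # p 1.7e-8
        assert not bool(by_id.loc["rs1424077", "replicated"])  # repl p 7.5e-3

    def test_discordant_direction_fails_replication(self):
        disc = pd.DataFrame(
            {"snv_id": ["a"], "beta": [0.1], "p": [1e-8]}
        )
        repl = pd.DataFrame(
            {"snv_id": ["a"], "beta": [-0.1], "p": [1e-4]}
        )
        dec = replication_decide(disc, repl, m_candidates=21)
        assert not dec["replicated"].iloc[0]
        assert "discordant" in dec["reason"].iloc[0]

    def test_missing_candidate_marked_not_testable(self):
        disc = pd.DataFrame({"snv_id": ["a"], "beta": [0.1], "p": [1e-8]})
        repl = pd.DataFrame({"snv_id": [], "beta": [], "p": []})
        dec = replication_decide(disc, repl, m_candidates=1)
        assert not dec["replicated"].iloc[0]
        assert "not testable" in dec["reason"].iloc[0]

    def test_fulldata_boundary_and_exclusion(self):
        combined = pd.DataFrame(
            {"snv_id": ["x", "y", "z"], "p": [6e-8, 5e-8, 5.8e-28]}
        )
        dec = fulldata_decide(combined, already_replicated={"z"})
        by_id = dec.set_index("snv_id")["fulldata_significant"]
        assert not by_id["x"]  # 6e-8 misses the threshold
        assert by_id["y"]  # boundary value counts
        assert not by_id["z"]  # replicated SNVs are not "additional"

    def test_threshold_monotonicity(self):
        disc, repl, _ = stage_tables()
        loose = replication_decide(disc, repl, m_candidates=21, p_select=1e-6)
        tight = replication_decide(disc, repl, m_candidates=21, p_select=1e-8)
        loose_c = set(loose.loc[loose["candidate"], "snv_id"])
        tight_r = set(tight.loc[tight["replicated"], "snv_id"])
        # tightening selection never produces a replicated SNV that was
        # not already a candidate at the looser threshold
        assert tight_r <= loose_c


class TestSecondarySignalRule:
    @pytest.mark.parametrize(
        "p_lead,p_sec,p_cond,expected",
        [
            (1e-10, 1e-8, 1e-7, True),  # ratios 1.25 and 8/7
            (1e-10, 1e-5, 1e-5, False),  # fails candidate threshold
            (1e-30, 1e-8, 1e-8, False),  # 30/8 >= 1.5
            (1e-10, 1e-8, 1e-5, False),  # 8/5 >= 1.5
            (1e-7, 1e-8, 1e-8, True),  # secondary stronger than lead
        ],
    )
    def test_truth_table(self, p_lead, p_sec, p_cond, expected):
        assert secondary_signal_rule(p_lead, p_sec, p_cond) is expected

    def test_zero_p_rejected(self):
        with pytest.raises(InvalidParameterError):
            secondary_signal_rule(0.0, 1e-8, 1e-7)

    def test_p_at_or_above_one_fails(self):
        assert not secondary_signal_rule(1e-10, 1e-8, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        exp_cond=st.floats(1.0, 30.0),
        exp_cond2=st.floats(0.0, 10.0),
    )
    def test_monotone_in_conditional_p(self, exp_cond, exp_cond2):
        p_lead, p_sec = 1e-10, 1e-8
        p_cond = 10.0 ** (-exp_cond)
        p_cond_smaller = p_cond * 10.0 ** (-exp_cond2)
        if secondary_signal_rule(p_lead, p_sec, p_cond):
            assert secondary_signal_rule(p_lead, p_sec, p_cond_smaller)


@pytest.fixture(scope="module")
def sex_cohort():
    arch = GeneticArchitecture(n_individuals=6000, n_variants=30, h2=0.0, seed=31)
    cohort, _ = simulate_cohort(arch)
    cov = simulate_covariates(6000, seed=31)
    sex = cov["sex"].to_numpy()
    rng = np.random.default_rng(31)
    g = cohort.standardized()[:, 0]
    # male-limited effect sized so the male stratum is expected well
    # past genome-wide significance (ncp ~ 50) while the sex-diluted
    # combined scan is expected short of it (ncp ~ 25)
    y = 0.13 * g * (sex == 1) + rng.normal(size=6000)
    return cohort, cov, sex, y


class TestSexStratified:
    def test_male_only_effect_flagged(self, sex_cohort):
        cohort, cov, sex, y = sex_cohort
        res = sex_stratified(cohort, y, cov, sex)
        flag = res.flags.set_index("snv_id").loc["snv00000"]
        assert flag["sex_specific"]
        assert flag["specific_in"] == "male"

    def test_shared_effect_not_flagged(self):
        arch = GeneticArchitecture(n_individuals=6000, n_variants=30, h2=0.0, seed=32)
        cohort, _ = simulate_cohort(arch)
        cov = simulate_covariates(6000, seed=32)
        sex = cov["sex"].to_numpy()
        rng = np.random.default_rng(32)
        y = 0.35 * cohort.standardized()[:, 0] + rng.normal(size=6000)
        res = sex_stratified(cohort, y, cov, sex)
        flag = res.flags.set_index("snv_id").loc["snv00000"]
        assert not flag["sex_specific"]

    def test_small_stratum_rejected(self):
        arch = GeneticArchitecture(n_individuals=300, n_variants=10, h2=0.0, seed=33)
        cohort, traits = simulate_cohort(arch)
        cov = simulate_covariates(300, seed=33)
        sex = np.zeros(300)
        sex[:10] = 1
        with pytest.raises(InvalidParameterError):
            sex_stratified(cohort, traits["trait_a"].to_numpy(), cov, sex)


@pytest.fixture(scope="module")
def planted():
    # enough variants that the 10 principal components in the base
    # model overlap only negligibly with the causal direction
    beta = np.zeros(500)
    beta[0] = np.sqrt(0.032)
    arch = GeneticArchitecture(
        n_individuals=20000, n_variants=500, h2=0.032, causal_effects=beta, seed=41
    )
    return simulate_cohort(arch)


class TestPercentVarianceExplained:
    def test_empty_variant_set_explains_nothing(self, planted):
        cohort, traits = planted
        pve, _ = percent_variance_explained(
            cohort, traits["trait_a"].to_numpy(), None, []
        )
        assert abs(pve) < 0.1

    def test_planted_share_recovered(self, planted):
        cohort, traits = planted
        pve, flags = percent_variance_explained(
            cohort, traits["trait_a"].to_numpy(), None, ["snv00000"]
        )
        assert pve == pytest.approx(3.2, abs=0.6)
        assert flags == []

    def test_duplicated_variant_dropped_and_flagged(self, planted):
        cohort, traits = planted
        y = traits["trait_a"].to_numpy()
        a, _ = percent_variance_explained(cohort, y, None, ["snv00000"])
        b, flags = percent_variance_explained(
            cohort, y, None, ["snv00000", "snv00000"]
        )
        assert b == pytest.approx(a, abs=1e-9)
        assert flags == ["dropped_collinear:snv00000"]

    def test_too_many_pcs_rejected(self, planted):
        cohort, traits = planted
        with pytest.raises(InvalidParameterError):
            percent_variance_explained(
                cohort, traits["trait_a"].to_numpy()[:5],
                None, [], n_pcs=10,
            )


class TestTally:
    def test_headline_counts(self):
        reps = {f"r{i}" for i in range(15)}
        adds = {f"a{i}" for i in range(13)}
        secs = {f"s{i}" for i in range(4)}
        summary = tally(reps, adds, secs, pve_pct=3.20, h2_pct=15.6)
        assert summary.n_lead == 28
        assert summary.n_total == 32
        assert summary.heritability_fraction_pct == 21

    def test_overlap_rejected(self):
        with pytest.raises(InvalidParameterError):
            tally({"x"}, {"x"}, set())
        with pytest.raises(InvalidParameterError):
            tally({"x"}, {"y"}, {"x"})

    def test_empty_inputs_all_zero(self):
        summary = tally(set(), set(), set())
        assert summary.n_total == 0
        assert summary.heritability_fraction_pct is None
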