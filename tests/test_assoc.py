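"""Endpoint construction, stratified logistic/linear association, pooling,
orientation and the phenome-wide scan."""

import numpy as np
import pandas as pd
import pytest

from targetmr.assoc import (
    EffectEstimate,
    EndpointDefinition,
    StratifiedLinearAssociation,
    StratifiedLogisticAssociation,
    build_endpoint,
    default_phewas_groups,
    linear_assoc,
    logistic_assoc,
    match_codes,
    orient_per_sd_lower_ldl,
    phewas_scan,
    pool_strata,
)
from targetmr.meta import SummaryEstimate
from targetmr.simulate import (
    OutcomeModel,
    SimulationConfig,
    simulate_cohort,
)


def _toy_cohort():
    """10 participants: 2 with qualifying events, 1 baseline self-reporter."""
    participants = pd.DataFrame(
        {
            "region": [0] * 10,
            "age": np.linspace(40, 60, 10),
            "sex": [0, 1] * 5,
            "baseline_year": [2005] * 10,
            "ascertainment_category": ["population"] * 9 + ["cvd_case_control"],
            "self_report_chd": [False] * 10,
            "self_report_stroke_tia": [False] * 10,
            "self_report_copd": [False, False, True] + [False] * 7,
        },
        index=pd.RangeIndex(10, name="id"),
    )
    events = pd.DataFrame(
        {
            "id": [0, 5, 7, 9],
            "code": ["J44.1", "J44.0", "I21", "J44.9"],
            "year": [2010.0, 2012.0, 2011.0, 2013.0],
            "fatal": [False, True, False, False],
        }
    )

    class C:
        pass

    c = C()
    c.participants = participants
    c.events = events
    return c


class TestMatchCodes:
    def test_prefix_and_exact(self):
        codes = pd.Series(["J44.1", "J45", "I21", "J06.9"])
        assert match_codes(codes, ["J44"]).tolist() == [True, False, False, False]

    def test_range_matching(self):
        codes = pd.Series(["J40", "J44.1", "J45", "A09", "N99"])
        assert match_codes(codes, ["J40-J44"]).tolist() == [True, True, False, False, False]
        assert match_codes(codes, ["A00-N99"]).tolist() == [True] * 5

    def test_ill_formed_range_rejected(self):
        with pytest.raises(ValueError):
            EndpointDefinition("x", case_codes=("J44-J40",))


class TestBuildEndpoint:
    def test_toy_counts(self):
        labels = build_endpoint(
            _toy_cohort(),
            EndpointDefinition(
                "copd", case_codes=("J44",),
                baseline_self_report_exclusions=("copd",),
            ),
        )
        # 3 cases (ids 0, 5, 9); self-reporter (id 2) excluded from controls
        assert (labels == 1).sum() == 3
        assert (labels == -1).sum() == 1
        assert (labels == 0).sum() == 6

    def test_common_vascular_control_excludes_mve_during_followup(self):
        labels = build_endpoint(
            _toy_cohort(),
            EndpointDefinition("copd", case_codes=("J44",), control_set="common-vascular"),
        )
        assert labels.loc[7] == -1  # I21 event -> out of the control pool

    def test_ascertainment_exclusion_drops_participant(self):
        c = _toy_cohort()
        c.events.loc[len(c.events)] = [9, "J44.5", 2012.0, False]
        labels = build_endpoint(
            c,
            EndpointDefinition(
                "copd", case_codes=("J44",),
                ascertainment_exclusions=("cvd_case_control",),
            ),
        )
        assert labels.loc[9] == -1  # case, but genotyped for another panel

    def test_population_subset_restriction(self):
        labels = build_endpoint(
            _toy_cohort(),
            EndpointDefinition("copd", case_codes=("J44",), restrict_to_population_subset=True),
        )
        assert labels.loc[9] == -1

    def test_min_event_year_filters_cases(self):
        labels = build_endpoint(
            _toy_cohort(),
            EndpointDefinition("copd", case_codes=("J44",), min_event_year=2012),
        )
        assert labels.loc[0] == 0 and labels.loc[5] == 1

    def test_no_cases_is_an_error(self):
        with pytest.raises(ValueError, match="no cases"):
            build_endpoint(_toy_cohort(), EndpointDefinition("none", case_codes=("C50",)))

    def test_counts_partition_cohort(self, small_cohort):
        labels = build_endpoint(
            small_cohort, EndpointDefinition("move", case_codes=("I21",), control_set="common-vascular")
        )
        total = (labels == 1).sum() + (labels == 0).sum() + (labels == -1).sum()
        assert total == len(small_cohort.participants)


class TestLogisticAssoc:
    def test_two_by_two_equals_sample_odds_ratio(self):
        """Saturated logistic on a binary exposure reproduces ln of the
        2x2 odds ratio: (30*90)/(70*10)."""
        labels = np.r_[np.ones(100), np.zeros(100)]
        exposure = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        est = logistic_assoc(labels, exposure)
        assert est.beta == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-6)
        assert est.beta == pytest.approx(1.350, abs=1e-3)
        assert est.n_cases == 100 and est.n_controls == 100

    def test_excluded_labels_dropped(self, rng):
        labels = rng.integers(0, 2, 500)
        labels[:100] = -1
        est = logistic_assoc(labels, rng.normal(size=500))
        assert est.n == 400

    def test_affine_covariate_recoding_invariance(self, rng):
        n = 2000
        score = rng.normal(size=n)
        age = rng.uniform(30, 79, size=n)
        labels = (rng.uniform(size=n) < 0.2).astype(int)
        a = logistic_assoc(labels, score, covariates=age)
        b = logistic_assoc(labels, score, covariates=(age - 50.0) / 10.0)
        assert a.beta == pytest.approx(b.beta, abs=1e-8)
        assert a.se == pytest.approx(b.se, abs=1e-8)

    def test_separable_stratum_dropped_but_pooling_continues(self, rng):
        n = 600
        strata = np.r_[np.zeros(300, dtype=int), np.ones(300, dtype=int)]
        score = rng.normal(size=n)
        labels = (rng.uniform(size=n) < 0.3).astype(int)
        # stratum 1 perfectly separated
        labels[300:] = (score[300:] > 0).astype(int)
        est = logistic_assoc(labels, score, strata=strata)
        assert est.n_strata == 1

    def test_too_few_cases_everywhere_is_an_error(self, rng):
        labels = np.r_[np.ones(2), np.zeros(200)]
        with pytest.raises(ValueError):
            logistic_assoc(labels, rng.normal(size=202), min_cases=5)

    def test_recovers_simulated_protective_effect(self):
        """Mediated OR 0.80 per SD-lower LDL is recovered via the true
        score used as the exposure."""
        cfg = SimulationConfig(
            n_participants=60_000, seed=31,
            outcome_models=(OutcomeModel("move", 0.15, log_or_per_sd_ldl=np.log(0.80), code="I21"),),
        )
        cohort = simulate_cohort(cfg)
        ldl_std = (cohort.latent["ldl_latent"] - cfg.ldl_mean_mmol) / cfg.ldl_sd_mmol
        labels = cohort.latent["case_table"]["move"].astype(int).to_numpy()
        est = logistic_assoc(labels, ldl_std, strata=cohort.participants["region"].to_numpy())
        oriented = orient_per_sd_lower_ldl(est)
        assert abs(oriented.beta - np.log(0.80)) < 2 * oriented.se


class TestLinearAssoc:
    def test_trait_equal_to_score(self, rng):
        s = rng.normal(size=200)
        est = linear_assoc(s, s)
        assert est.beta == pytest.approx(1.0)
        assert est.p < 1e-100

    def test_null_trait_within_two_se(self, rng):
        est = linear_assoc(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(est.beta) < 2.5 * est.se

    def test_negative_loading_recovery(self, rng):
        n = 5000
        s = rng.normal(size=n)
        trait = -0.95 * s + rng.normal(size=n) * 0.4
        est = linear_assoc(trait, s, strata=rng.integers(0, 5, n))
        assert abs(est.beta - (-0.95)) < 2 * est.se


class TestPoolAndOrient:
    def test_single_stratum_identity(self):
        e = SummaryEstimate("s0", 0.3, 0.1)
        m = pool_strata([e])
        assert (m.beta, m.se) == (0.3, 0.1)

    def test_equal_se_average(self):
        m = pool_strata([SummaryEstimate("a", 0.2, 0.1), SummaryEstimate("b", 0.4, 0.1)])
        assert m.beta == pytest.approx(0.3)

    def test_stratified_pooling_matches_joint_model_with_region_dummies(self, rng):
        n = 100_000
        strata = rng.integers(0, 10, n)
        score = rng.normal(size=n)
        eta = -1.8 + 0.3 * score + 0.1 * strata
        labels = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        pooled = logistic_assoc(labels, score, strata=strata)
        import statsmodels.api as sm

        dummies = pd.get_dummies(pd.Series(strata), drop_first=True, dtype=float)
        X = sm.add_constant(np.column_stack([score, dummies.to_numpy()]))
        joint = sm.Logit(labels, X).fit(disp=0)
        assert abs(pooled.beta - joint.params[1]) < 0.1 * joint.bse[1]

    def test_orientation_involution_and_sign_flip(self):
        e = EffectEstimate("x", beta=np.log(1.25), se=0.1, p=0.03)
        flipped = orient_per_sd_lower_ldl(e)
        assert flipped.beta == pytest.approx(np.log(0.8))
        assert flipped.unit == "per-SD-lower-LDL"
        assert (flipped.se, flipped.p) == (e.se, e.p)
        back = orient_per_sd_lower_ldl(flipped)
        assert back.beta == pytest.approx(e.beta)

    def test_wrong_unit_rejected(self):
        e = EffectEstimate("x", beta=0.1, se=0.1, p=0.5, unit="per-allele")
        with pytest.raises(ValueError):
            orient_per_sd_lower_ldl(e)


class TestPhewas:
    def test_default_groups_disjoint_and_span(self):
        groups = default_phewas_groups(41)
        assert len(groups) == 41
        codes = pd.Series(["A00", "G55.1", "N99", "O10"])
        hits = sum(match_codes(codes, g.case_codes).astype(int) for g in groups)
        assert hits.tolist() == [1, 1, 1, 0]  # O-codes outside A00-N99

    def test_threshold_and_flagging(self):
        """A strong simulated endpoint is flagged at 0.05/(41+7)."""
        cfg = SimulationConfig(
            n_participants=30_000, seed=32,
            outcome_models=(
                OutcomeModel("hit", 0.15, log_or_per_sd_score_direct=1.6, code="G40"),
                OutcomeModel("null", 0.10, code="K30"),
            ),
        )
        cohort = simulate_cohort(cfg)
        pheno = cohort.participants.assign(age2=lambda d: d["age"] ** 2)
        score = pd.Series(cohort.latent["true_score"], index=pheno.index)
        groups = default_phewas_groups(41)
        result = phewas_scan(
            cohort, groups, score.to_numpy(),
            pheno[["age", "age2", "sex"]], pheno["region"].to_numpy(),
        )
        assert result.attrs["threshold"] == pytest.approx(0.05 / 48)
        hit_group = [g.outcome_id for g in groups if match_codes(pd.Series(["G40"]), g.case_codes)[0]][0]
        assert bool(result.loc[hit_group, "significant"])
        # endpoints with no qualifying events carry an error, scan continues
        assert (result["error"] != "").any()


class TestEstimators:
    def test_logistic_estimator_interface(self, rng):
        n = 3000
        X = pd.DataFrame(
            {
                "score": rng.normal(size=n),
                "age": rng.uniform(30, 79, n),
                "region": rng.integers(0, 3, n),
            }
        )
        y = (rng.uniform(size=n) < 0.2).astype(int)
        est = StratifiedLogisticAssociation(
            score_col="score", covariate_cols=["age"], stratum_col="region"
        ).fit(X, y)
        assert est.estimate_.unit == "per-SD-lower-LDL"
        assert est.se_ > 0 and 0 < est.p_ <= 1

    def test_linear_estimator_interface(self, rng):
        n = 1000
        X = pd.DataFrame({"score": rng.normal(size=n)})
        y = -0.5 * X["score"].to_numpy() + rng.normal(size=n)
        est = StratifiedLinearAssociation(score_col="score").fit(X, y)
        # fitted on the raising scale, reported per SD lower
        assert est.beta_ == pytest.approx(0.5, abs=0.1)
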