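"""Locus weight estimation, jackknife blocks, score construction,
instrument strength and the polygenic consistency filter."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from targetmr.score import (
    LocusScoreModel,
    ScoreWeights,
    assign_jackknife_blocks,
    build_polygenic_score,
    build_score,
    f_stat_from_r2,
    fit_locus_weights,
    instrument_strength,
    jackknife_weights,
)
from targetmr.simulate import (
    LOCUS_SNPS,
    SimulationConfig,
    simulate_covariates,
    simulate_genotypes,
    simulate_ldl,
)
from targetmr.transform import residualize, rint


def _null_fixture(n=6000, seed=0, betas=(0.0, 0.0, 0.0)):
    cfg = SimulationConfig(
        n_participants=n, locus_betas=betas, grs_n_snps=0,
        ldl_measured_fraction=1.0, seed=seed,
        locus_maf=(0.2, 0.3, 0.1),
    )
    cov = simulate_covariates(cfg)[["age", "sex"]]
    dos = simulate_genotypes(cfg)[LOCUS_SNPS]
    ldl, _ = simulate_ldl(cfg, dos, simulate_covariates(cfg))
    y = rint(residualize(ldl, cov))
    return dos, y, cov


class TestFitLocusWeights:
    def test_joint_equals_marginal_for_independent_snps(self, rng):
        n = 500
        g1 = rng.binomial(2, 0.5, n).astype(float)
        g2 = rng.binomial(2, 0.3, n).astype(float)
        y = 0.4 * g1 - 0.2 * g2 + rng.normal(size=n)
        dos = pd.DataFrame({"s1": g1, "s2": g2})
        joint = fit_locus_weights(dos, y)
        for j, g in enumerate((g1, g2)):
            marg, *_ = np.linalg.lstsq(np.column_stack([g, np.ones(n)]), y, rcond=None)
            # joint betas equal marginals up to the (small) empirical g1-g2
            # correlation; on an exactly-orthogonalized fixture they coincide
            X = np.column_stack([g1, g2, np.ones(n)])
            exact = np.linalg.lstsq(X, y, rcond=None)[0][j]
            assert joint.betas[j] == pytest.approx(exact, abs=1e-9)

    def test_recovers_true_effects_within_two_se(self):
        dos, _, cov = _null_fixture(seed=1)
        cfg = SimulationConfig(
            n_participants=6000, locus_betas=(0.65, 0.10, 0.16), grs_n_snps=0,
            ldl_measured_fraction=1.0, seed=1, locus_maf=(0.2, 0.3, 0.1),
        )
        dos = simulate_genotypes(cfg)[LOCUS_SNPS]
        ldl, _ = simulate_ldl(cfg, dos, simulate_covariates(cfg))
        y = rint(residualize(ldl, cov))
        w = fit_locus_weights(dos, y, cov)
        for b, se, truth in zip(w.betas, w.ses, (0.65, 0.10, 0.16)):
            assert abs(b - truth) < 2 * se

    def test_null_snp_within_two_se_of_zero(self):
        dos, y, cov = _null_fixture(seed=2)
        w = fit_locus_weights(dos, y, cov)
        assert (np.abs(w.betas) < 2 * w.ses).sum() >= 2

    def test_stratified_pooling_matches_single_stratum_when_homogeneous(self):
        dos, y, cov = _null_fixture(seed=3)
        strata = np.arange(len(y)) % 2
        pooled = fit_locus_weights(dos, y, cov, strata)
        single = fit_locus_weights(dos, y, cov)
        assert pooled.betas == pytest.approx(single.betas, abs=0.05)

    def test_monomorphic_snp_named_in_error(self):
        dos, y, cov = _null_fixture(seed=4)
        dos = dos.copy()
        dos["rs2495477"] = 0.0
        with pytest.raises(ValueError, match="rs2495477"):
            fit_locus_weights(dos, y, cov)

    def test_collinear_dosages_rejected(self):
        dos, y, cov = _null_fixture(seed=5)
        dos = dos.copy()
        dos["rs11206517"] = dos["rs151193009"]
        with pytest.raises(ValueError, match="collinear"):
            fit_locus_weights(dos, y, cov)


class TestJackknifeBlocks:
    def test_equal_blocks_when_divisible(self):
        bm = assign_jackknife_blocks(range(100), B=100, seed=0)
        assert bm.value_counts().eq(1).all()

    def test_near_equal_blocks(self):
        bm = assign_jackknife_blocks(range(101), B=100, seed=0)
        sizes = bm.value_counts()
        assert sorted(sizes)[-1] == 2 and (sizes == 1).sum() == 99

    def test_same_seed_reproducible(self):
        a = assign_jackknife_blocks(range(500), B=10, seed=3)
        b = assign_jackknife_blocks(range(500), B=10, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError):
            assign_jackknife_blocks(range(5), B=10, seed=0)


class TestJackknifeWeights:
    def test_leave_one_block_out_matches_brute_force_refit(self):
        """Each per-block row equals an independent full refit on the
        complementary rows (two blocks, six rows)."""
        rng = np.random.default_rng(7)
        dos = pd.DataFrame({"a": [0, 1, 2, 1, 0, 2], "b": [1, 0, 1, 2, 2, 0]}, dtype=float)
        y = rng.normal(size=6)
        bm = assign_jackknife_blocks(dos.index, B=2, seed=1)
        w = jackknife_weights(dos, y, None, None, bm)
        for b in (0, 1):
            keep = bm.index[bm.values != b]
            brute = fit_locus_weights(dos.loc[keep], y[np.asarray(keep)], None)
            assert w.per_block_betas[b] == pytest.approx(brute.betas, abs=1e-10)

    def test_noise_free_data_gives_identical_blocks(self):
        rng = np.random.default_rng(8)
        n = 400
        dos = pd.DataFrame(rng.binomial(2, 0.4, size=(n, 3)).astype(float), columns=list("abc"))
        y = dos.to_numpy() @ np.array([0.5, -0.2, 0.1]) + 2.0
        bm = assign_jackknife_blocks(dos.index, B=10, seed=2)
        w = jackknife_weights(dos, y, None, None, bm)
        assert np.ptp(w.per_block_betas, axis=0) == pytest.approx(0.0, abs=1e-8)
        assert w.per_block_betas[0] == pytest.approx(w.betas, abs=1e-8)

    def test_block_mean_near_full_sample_betas(self):
        dos, y, cov = _null_fixture(n=4000, seed=9, betas=(0.3, 0.0, 0.1))
        bm = assign_jackknife_blocks(dos.index, B=50, seed=3)
        w = jackknife_weights(dos, y, cov, None, bm)
        jack_se = np.sqrt(49 / 50 * ((w.per_block_betas - w.betas) ** 2).sum(axis=0))
        assert np.all(np.abs(w.per_block_betas.mean(axis=0) - w.betas) < 3 * np.maximum(jack_se, 1e-8))

    def test_jackknife_removes_own_phenotype_covariance(self):
        """The bias the procedure removes: under a null locus the naive
        internally-weighted score covaries positively with the phenotype by
        construction (overfitting), the jackknifed score does not."""
        cov_naive, cov_jack = [], []
        for rep in range(40):
            dos, y, cov = _null_fixture(n=2000, seed=1000 + rep)
            wf = fit_locus_weights(dos, y, cov)
            bm = assign_jackknife_blocks(dos.index, B=50, seed=rep)
            wj = jackknife_weights(dos, y, cov, None, bm)
            for w, acc in ((wf, cov_naive), (wj, cov_jack)):
                s = build_score(dos, w).to_numpy()
                acc.append(np.dot(s - s.mean(), y - y.mean()))
        # naive overfit covariance ~ n_snps * sigma^2 > 0; jackknifed ~ 0
        assert np.mean(cov_naive) > 5 * np.std(cov_naive) / np.sqrt(40)
        assert abs(np.mean(cov_jack)) < 3 * np.std(cov_jack) / np.sqrt(40)


class TestBuildScore:
    def test_forced_arithmetic(self):
        dos = pd.DataFrame([[1.0, 0.0, 2.0]], columns=list("abc"))
        w = ScoreWeights(snp_ids=list("abc"), betas=[0.65, 0.10, 0.16], ses=[0.05, 0.01, 0.03])
        assert build_score(dos, w).iloc[0] == pytest.approx(0.97)

    def test_zero_betas_zero_scores(self, rng):
        dos = pd.DataFrame(rng.binomial(2, 0.3, size=(20, 3)).astype(float), columns=list("abc"))
        w = ScoreWeights(snp_ids=list("abc"), betas=[0, 0, 0], ses=[1, 1, 1])
        assert (build_score(dos, w) == 0).all()

    def test_linearity_in_betas(self, rng):
        dos = pd.DataFrame(rng.binomial(2, 0.3, size=(20, 3)).astype(float), columns=list("abc"))
        w1 = ScoreWeights(snp_ids=list("abc"), betas=[0.1, 0.2, 0.3], ses=[1, 1, 1])
        w2 = ScoreWeights(snp_ids=list("abc"), betas=[0.2, 0.4, 0.6], ses=[1, 1, 1])
        assert build_score(dos, w2).to_numpy() == pytest.approx(2 * build_score(dos, w1).to_numpy())

    def test_missing_dosage_rejected(self):
        dos = pd.DataFrame([[1.0, np.nan, 0.0]], columns=list("abc"))
        w = ScoreWeights(snp_ids=list("abc"), betas=[0.1, 0.2, 0.3], ses=[1, 1, 1])
        with pytest.raises(ValueError, match="missing"):
            build_score(dos, w)

    def test_permutation_equivariance(self, rng):
        dos = pd.DataFrame(rng.binomial(2, 0.3, size=(30, 2)).astype(float), columns=list("ab"))
        w = ScoreWeights(snp_ids=list("ab"), betas=[0.3, -0.1], ses=[1, 1])
        perm = rng.permutation(30)
        direct = build_score(dos.iloc[perm], w)
        assert direct.to_numpy() == pytest.approx(build_score(dos, w).iloc[perm].to_numpy())

    def test_block_weights_applied_per_participant(self):
        dos = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        bm = pd.Series([0, 1], index=[0, 1])
        w = ScoreWeights(
            snp_ids=["a"], betas=[0.5], ses=[0.1], n_blocks=2,
            per_block_betas=[[0.4], [0.6]], block_map=bm,
        )
        s = build_score(dos, w)
        # rows 0,1 in the block map get leave-out weights; row 2 full-sample
        assert s.tolist() == pytest.approx([0.4, 0.6, 0.5])


class TestInstrumentStrength:
    def test_closed_form_matches_reported_magnitude(self):
        # r^2 ~ 1.15% at n=17,687 corresponds to a 1-df F of ~206
        assert f_stat_from_r2(0.0115, 17_687) == pytest.approx(205.7, abs=0.1)

    def test_perfect_fit_flags_infinity(self, rng):
        y = rng.normal(size=100)
        d = instrument_strength(y, y)
        assert np.isinf(d.f_statistic) and d.r_squared == 1.0

    def test_independent_score_mean_f_near_one(self, rng):
        """With *external* (y-independent) weights the null F is calibrated."""
        fs = []
        for _ in range(300):
            s = rng.normal(size=300)
            y = rng.normal(size=300)
            fs.append(instrument_strength(s, y).f_statistic)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            instrument_strength(rng.normal(size=5), rng.normal(size=5))

    def test_partial_r2_removes_covariate_signal(self, rng):
        x = rng.normal(size=2000)
        y = 2.0 * x + rng.normal(size=2000)
        s = 1.5 * x + rng.normal(size=2000)  # only covariate-driven overlap
        d = instrument_strength(s, y, covariates=x)
        assert d.r_squared < 0.01


class TestPolygenicScore:
    def _fixture(self, rng, n_snps=74, n_bad=10, n=400):
        """74 polymorphic candidates + 2 monomorphic; n_bad have opposite
        sign and heterogeneity beyond the Bonferroni bound."""
        mafs = rng.uniform(0.1, 0.5, n_snps)
        dos = pd.DataFrame(
            rng.binomial(2, mafs, size=(n, n_snps)).astype(float),
            columns=[f"s{i}" for i in range(n_snps)],
        )
        dos["mono1"] = 0.0
        dos["mono2"] = 0.0
        ext_b = rng.uniform(0.05, 0.2, n_snps + 2)
        ext_se = np.full(n_snps + 2, 0.01)
        int_b = ext_b.copy()
        int_se = np.full(n_snps + 2, 0.01)
        bad = rng.choice(n_snps, size=n_bad, replace=False)
        int_b[bad] = -ext_b[bad] - 0.2  # opposite sign, |z_het| huge
        return dos, ext_b, ext_se, int_b, int_se, bad

    def test_engineered_filter_keeps_64_of_76(self, rng):
        dos, eb, es, ib, isd, bad = self._fixture(rng)
        kept, score = build_polygenic_score(dos, eb, es, ib, isd)
        assert len(kept) == 64
        assert not any(f"s{i}" in kept for i in bad)
        assert "mono1" not in kept and "mono2" not in kept

    def test_identical_estimates_all_kept(self, rng):
        dos, eb, es, _, _, _ = self._fixture(rng, n_bad=0)
        kept, _ = build_polygenic_score(dos, eb, es, eb, es)
        assert len(kept) == 74

    def test_single_discordant_snp_dropped(self, rng):
        dos, eb, es, ib, isd, _ = self._fixture(rng, n_bad=0)
        ib = ib.copy()
        ib[5] = -eb[5] - 0.3
        kept, _ = build_polygenic_score(dos, eb, es, ib, isd)
        assert "s5" not in kept and len(kept) == 73

    def test_opposite_sign_but_compatible_kept(self, rng):
        """Directional inconsistency alone is not enough: a sign flip within
        heterogeneity noise survives the filter."""
        dos, eb, es, ib, isd, _ = self._fixture(rng, n_bad=0)
        ib, isd = ib.copy(), isd.copy()
        eb = eb.copy()
        eb[3] = 0.01
        ib[3] = -0.01
        isd[3] = 0.5  # z_het ~ 0.04 -> p ~ 0.97 >= 0.05/74
        kept, _ = build_polygenic_score(dos, eb, es, ib, isd)
        assert "s3" in kept

    def test_score_uses_external_weights(self, rng):
        dos, eb, es, ib, isd, _ = self._fixture(rng, n_bad=0)
        kept, score = build_polygenic_score(dos, eb, es, ib, isd)
        expected = dos[kept].to_numpy() @ np.array([eb[int(k[1:])] for k in kept])
        assert score.to_numpy() == pytest.approx(expected)


class TestLocusScoreModel:
    def test_sklearn_contract_and_calibration(self):
        """Fitted on a cohort with real effects, the score predicts the
        exposure with regression slope ~ 1 (calibration property)."""
        cfg = SimulationConfig(
            n_participants=12_000, seed=23, grs_n_snps=0,
            locus_maf=(0.2, 0.3, 0.1), ldl_measured_fraction=1.0,
            locus_betas=(0.4, 0.25, 0.3),
        )
        cov = simulate_covariates(cfg)
        dos = simulate_genotypes(cfg)
        ldl, _ = simulate_ldl(cfg, dos, cov)
        pheno = cov.assign(age2=cov["age"] ** 2)
        y = pd.Series(np.nan, index=pheno.index)
        spec_cov = ["age", "age2", "sex"]
        from targetmr.transform import TransformSpec, stratified_transform

        y = stratified_transform(
            pd.Series(ldl, index=pheno.index), pheno,
            TransformSpec(covariates=spec_cov, strata="region"),
        )
        model = LocusScoreModel(
            snp_cols=LOCUS_SNPS, covariate_cols=spec_cov, stratum_col="region",
            n_blocks=20, random_state=0,
        )
        clone(model)
        model.fit(pheno.join(dos), y)
        s = model.transform(pheno.join(dos)).to_numpy()
        ok = np.isfinite(y.to_numpy())
        sc = s[ok] - s[ok].mean()
        yc = y.to_numpy()[ok] - y.to_numpy()[ok].mean()
        slope = (sc @ yc) / (sc @ sc)
        se = np.sqrt((yc @ yc) / (sc @ sc) / len(yc))
        assert abs(slope - 1.0) < 2.5 * se

    def test_rows_without_phenotype_get_full_sample_weights(self):
        cfg = SimulationConfig(
            n_participants=3000, seed=24, grs_n_snps=0,
            locus_maf=(0.2, 0.3, 0.1), ldl_measured_fraction=0.5,
        )
        cov = simulate_covariates(cfg)
        dos = simulate_genotypes(cfg)
        ldl, obs = simulate_ldl(cfg, dos, cov)
        y = pd.Series(obs, index=cov.index)
        y[np.isfinite(y)] = rint(y[np.isfinite(y)])
        model = LocusScoreModel(snp_cols=LOCUS_SNPS, n_blocks=10).fit(cov.join(dos), y)
        s = model.transform(cov.join(dos))
        unmeasured = y.index[~np.isfinite(y.to_numpy())]
        expected = dos.loc[unmeasured, LOCUS_SNPS].to_numpy() @ model.betas_
        assert s.loc[unmeasured].to_numpy() == pytest.approx(expected)
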