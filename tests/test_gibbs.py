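import numpy as np
import pytest
from scipy import sparse

from pigeonblup.gibbs import (
    PAPER_SCHEDULE,
    GibbsConfig,
    ThresholdModel,
    geweke_z,
    sample_liabilities,
    sample_location,
    sample_variance,
)
from pigeonblup.pedigree import (
    PedigreeRecord,
    a_inverse,
    relationship_matrix,
    validate_and_sort,
)


class TestGibbsConfig:
    def test_full_schedule_retains_2000_draws(self):
        cfg = GibbsConfig().with_paper_schedule()
        assert cfg.n_iterations == 5_050_000
        assert cfg.burn_in == 50_000
        assert cfg.thinning == 2_500
        assert cfg.n_retained == 2_000

    def test_default_scaled_schedule_retains_2000_draws(self):
        assert GibbsConfig().n_retained == 2_000

    def test_retained_count_formula(self):
        cfg = GibbsConfig(n_iterations=1_007, burn_in=7, thinning=3)
        assert cfg.n_retained == 333

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            GibbsConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            GibbsConfig(thinning=0)


class TestSampleLiabilities:
    def test_truncation_sides(self):
        rng = np.random.default_rng(0)
        y = np.array([1, 2] * 50)
        L = sample_liabilities(rng, np.zeros(100), y)
        assert (L[y == 1] <= 0).all()
        assert (L[y == 2] > 0).all()

    def test_half_normal_mean_closed_form(self):
        """Mean of N(0,1) truncated to (0, inf) is sqrt(2/pi)."""
        rng = np.random.default_rng(1)
        L = sample_liabilities(rng, np.zeros(100_000), np.full(100_000, 2))
        assert abs(L.mean() - np.sqrt(2 / np.pi)) < 0.01

    def test_robust_far_from_threshold(self):
        """Means many residual SDs from the cut still give finite, correct-side draws."""
        rng = np.random.default_rng(2)
        m = np.full(1000, -30.0)
        L = sample_liabilities(rng, m, np.full(1000, 2))
        assert np.isfinite(L).all() and (L > 0).all()
        L = sample_liabilities(rng, -m, np.full(1000, 1))
        assert np.isfinite(L).all() and (L <= 0).all()

    def test_nonunit_residual_variance(self):
        rng = np.random.default_rng(3)
        L = sample_liabilities(rng, np.zeros(200_000), np.full(200_000, 2), sigma2_e=4.0)
        assert abs(L.mean() - 2 * np.sqrt(2 / np.pi)) < 0.02


class TestSampleVariance:
    def test_flat_prior_posterior_mean(self):
        """Scaled inverse chi-square: E = SS / (df - 2) = 50 / 96 at q=100."""
        rng = np.random.default_rng(4)
        draws = [sample_variance(rng, 50.0, 100) for _ in range(200_000)]
        assert np.mean(draws) == pytest.approx(50 / 96, rel=0.01)

    def test_prior_only_reproduces_prior_mean(self):
        rng = np.random.default_rng(5)
        nu, s = 6.0, 2.0
        draws = [
            sample_variance(rng, 0.0, 0, prior_df=nu, prior_scale=s)
            for _ in range(200_000)
        ]
        assert np.mean(draws) == pytest.approx(nu * s / (nu - 2), rel=0.01)

    def test_zero_quadratic_form_floored(self):
        rng = np.random.default_rng(6)
        assert sample_variance(rng, 0.0, 100, floor=1e-6) == 1e-6

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            sample_variance(np.random.default_rng(0), 1.0, 0)


def founder_problem(n=400, seed=0):
    """Unrelated founders with sexes and a probit-generated binary trait."""
    rng = np.random.default_rng(seed)
    recs = [
        PedigreeRecord(f"a{i}", sex="male" if i % 2 == 0 else "female")
        for i in range(n)
    ]
    ped = validate_and_sort(recs)
    sex = np.array(ped.sexes())
    b = {"male": 0.4, "female": -0.25}
    lin = np.array([b[s] for s in sex])
    y = np.where(lin + rng.standard_normal(n) > 0, 2, 1)
    return ped, sex, y


class TestSampleLocation:
    def test_founder_gls_oracle(self):
        """With fixed variances the mean of MME draws solves the GLS equations."""
        ped, sex, y = founder_problem(n=200, seed=1)
        rng = np.random.default_rng(2)
        L = np.array([0.3 if s == "male" else -0.2 for s in sex]) + rng.standard_normal(200)
        X = np.column_stack([(sex == "female") * 1.0, (sex == "male") * 1.0])
        Z = sparse.identity(200, format="csr")
        Ainv = a_inverse(ped)
        s2u = 0.5
        draws = np.array(
            [
                np.concatenate(sample_location(rng, L, X, Z, Ainv, s2u))
                for _ in range(4000)
            ]
        )
        lam = 1.0 / s2u
        C = np.block(
            [[X.T @ X, X.T @ np.eye(200)], [np.eye(200) @ X, np.eye(200) + Ainv.toarray() * lam]]
        )
        mme_mean = np.linalg.solve(C, np.concatenate([X.T @ L, L]))
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.abs(draws.mean(axis=0) - mme_mean).max() < 5 * se.max()

    def test_unphenotyped_offspring_mean_is_parent_average(self):
        """E[u_child | data] = (E[u_sire] + E[u_dam]) / 2 when the child has no record."""
        ped = validate_and_sort(
            [
                PedigreeRecord("s", sex="male"),
                PedigreeRecord("d", sex="female"),
                PedigreeRecord("k", "s", "d"),
            ]
        )
        L = np.array([1.2, -0.4])  # records on sire and dam only
        X = np.ones((2, 1))
        Z = sparse.csr_matrix(np.array([[1.0, 0, 0], [0, 1.0, 0]]))
        Ainv = a_inverse(ped)
        lam = 1.0 / 0.8
        C = np.block([[X.T @ X, X.T @ Z.toarray()], [Z.toarray().T @ X, Z.toarray().T @ Z.toarray() + Ainv.toarray() * lam]])
        mean = np.linalg.solve(C, np.concatenate([X.T @ L, Z.toarray().T @ L]))
        u = mean[1:]
        assert u[2] == pytest.approx(0.5 * (u[0] + u[1]), abs=1e-12)

    def test_empty_sex_class_raises(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(4), np.zeros(4)])
        Z = sparse.identity(4, format="csr")
        Ainv = sparse.identity(4, format="csr")
        with pytest.raises(ValueError, match="no records"):
            sample_location(rng, np.zeros(4), X, Z, Ainv, 0.5, sex_levels=["f", "m"])


class TestThresholdModel:
    def test_no_variation_rejected(self):
        ped, sex, _ = founder_problem(n=10)
        model = ThresholdModel(ped, ped.ids, list(sex))
        with pytest.raises(ValueError, match="no variation"):
            model.fit(np.full(10, 2), GibbsConfig(n_iterations=10, burn_in=0))

    def test_phenotyped_animal_missing_from_pedigree(self):
        ped, sex, _ = founder_problem(n=10)
        with pytest.raises(ValueError, match="missing from pedigree"):
            ThresholdModel(ped, ped.ids + ["ghost"], list(sex) + ["male"])

    def test_missing_sex_class_rejected(self):
        ped = validate_and_sort([PedigreeRecord(f"a{i}", sex="male") for i in range(6)])
        with pytest.raises(ValueError, match="no phenotyped records"):
            ThresholdModel(ped, ped.ids, ["male"] * 6, sex_levels=["male", "female"])

    def test_reproducible_given_seed(self):
        ped, sex, y = founder_problem(n=60, seed=3)
        model = ThresholdModel(ped, ped.ids, list(sex))
        cfg = GibbsConfig(n_iterations=300, burn_in=50, thinning=5, seed=9)
        a = model.fit(y, cfg)
        b = model.fit(y, cfg)
        assert np.array_equal(a.sigma2_u, b.sigma2_u)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.sex_effects, b.sex_effects)

    def test_retained_draw_count_and_h2_identity(self):
        ped, sex, y = founder_problem(n=60, seed=4)
        model = ThresholdModel(ped, ped.ids, list(sex))
        cfg = GibbsConfig(n_iterations=525, burn_in=25, thinning=10, seed=1)
        s = model.fit(y, cfg)
        assert s.n_draws == cfg.n_retained == 50
        assert np.allclose(s.h2, s.sigma2_u / (s.sigma2_u + 1.0))
        assert ((s.h2 > 0) & (s.h2 < 1)).all()

    def test_shrinkage_in_small_variance_limit(self):
        """sigma2_u -> 0 forces breeding values to zero."""
        ped, sex, y = founder_problem(n=80, seed=5)
        model = ThresholdModel(ped, ped.ids, list(sex))
        cfg = GibbsConfig(
            n_iterations=200, burn_in=100, thinning=1, seed=2, fix_sigma2_u=1e-10
        )
        s = model.fit(y, cfg)
        assert np.abs(s.u).max() < 1e-3

    def test_posterior_mean_matches_dense_mme_draws(self):
        """Fast eigen-path location draw agrees with the dense MME draw."""
        ped = validate_and_sort(
            [
                PedigreeRecord("s", sex="male"),
                PedigreeRecord("d", sex="female"),
                PedigreeRecord("k1", "s", "d", "male"),
                PedigreeRecord("k2", "s", "d", "female"),
            ]
        )
        sex = ped.sexes()
        model = ThresholdModel(ped, ped.ids, sex)
        L = np.array([0.9, -0.7, 0.3, 0.1])
        s2u = 0.6
        rng = np.random.default_rng(11)
        fast_draws = []
        for _ in range(3000):
            b, w, _ = model._draw_location(rng, L, s2u, 1.0)
            fast_draws.append(np.concatenate([b, model._T @ w]))
        fast = np.array(fast_draws)
        X = model.X
        Z = sparse.identity(4, format="csr") @ sparse.csr_matrix(
            (np.ones(4), (np.arange(4), model.obs_idx)), shape=(4, 4)
        )
        rng2 = np.random.default_rng(12)
        dense = np.array(
            [
                np.concatenate(sample_location(rng2, L, X, Z, a_inverse(ped), s2u))
                for _ in range(3000)
            ]
        )
        se = dense.std(axis=0) / np.sqrt(3000) + fast.std(axis=0) / np.sqrt(3000)
        assert np.abs(fast.mean(axis=0) - dense.mean(axis=0)).max() < 6 * se.max()

    def test_probit_limit_matches_ml_sex_effects(self):
        """With unrelated founders and sigma2_u ~ 0 the model is a probit GLM."""
        import statsmodels.api as sm
        import arviz as az

        ped, sex, y = founder_problem(n=500, seed=6)
        model = ThresholdModel(ped, ped.ids, list(sex))
        cfg = GibbsConfig(
            n_iterations=6000, burn_in=1000, thinning=5, seed=7, fix_sigma2_u=1e-8
        )
        s = model.fit(y, cfg)
        X = model.X
        ml = sm.Probit((y == 2).astype(float), X).fit(disp=0)
        for i in range(X.shape[1]):
            chain = s.sex_effects[:, i]
            ess = max(float(az.ess(chain[None, :])), 10.0)
            mcse = chain.std(ddof=1) / np.sqrt(ess)
            assert abs(chain.mean() - ml.params[i]) < 3 * mcse + 0.02

    def test_geweke_z_near_zero_for_iid_chain(self):
        rng = np.random.default_rng(8)
        assert abs(geweke_z(rng.standard_normal(2000))) < 4
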