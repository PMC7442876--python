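"""Location-scale engine: MLE correctness, AIC selection, atlas behavior."""

import numpy as np
import pytest
from scipy import optimize, stats

from rnflasym import (
    AngularField,
    CohortParams,
    DifferenceProfile,
    N_LOCATIONS,
    NormativeAtlas,
    Standardization,
    TermMask,
    enumerate_candidates,
    fit_atlas,
    fit_gaussian_ls,
    generate_population,
    normalize_and_difference,
    predict_quantile,
    screen_covariates,
    select_location_model,
)
from rnflasym.normative import full_basis, _design_columns


def brute_force_loglik(y, Xm, Xs):
    """Independent oracle: BFGS on the negative Gaussian log-likelihood."""
    n, km = len(y), Xm.shape[1]

    def nll(th):
        b, g = th[:km], th[km:]
        eta = Xs @ g
        r = y - Xm @ b
        return 0.5 * n * np.log(2 * np.pi) + eta.sum() + 0.5 * np.sum((r * np.exp(-eta)) ** 2)

    th0 = np.zeros(km + Xs.shape[1])
    th0[km] = np.log(max(y.std(), 1e-6))
    res = optimize.minimize(nll, th0, method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
    return -res.fun


class TestFitGaussianLS:
    def test_two_point_closed_form(self):
        """y = (0, 2), intercept-only: mu = 1, sigma = 1 (MLE variance is the
        mean squared deviation), loglik = -(1 + log 2pi)."""
        fit = fit_gaussian_ls(np.array([0.0, 2.0]), np.ones((2, 1)), np.ones((2, 1)))
        assert fit.beta_mu[0] == pytest.approx(1.0, abs=1e-9)
        assert np.exp(fit.beta_logsigma[0]) == pytest.approx(1.0, abs=1e-9)
        assert fit.loglik == pytest.approx(-2.837877066, abs=1e-6)
        assert fit.aic == pytest.approx(9.675754133, abs=1e-6)

    def test_intercept_only_equals_sample_moments(self):
        rng = np.random.default_rng(8)
        y = rng.normal(3.0, 2.0, 200)
        one = np.ones((200, 1))
        fit = fit_gaussian_ls(y, one, one)
        assert fit.beta_mu[0] == pytest.approx(y.mean(), abs=1e-8)
        assert np.exp(fit.beta_logsigma[0]) == pytest.approx(y.std(), abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_heteroscedastic_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        a, r = rng.standard_normal(n), rng.standard_normal(n)
        Xm = np.column_stack([np.ones(n), a])
        Xs = np.column_stack([np.ones(n), r])
        y = 1.0 - 0.5 * a + np.exp(0.4 + 0.5 * r) * rng.standard_normal(n)
        fit = fit_gaussian_ls(y, Xm, Xs)
        assert fit.converged
        assert fit.loglik == pytest.approx(brute_force_loglik(y, Xm, Xs), abs=1e-6)

    def test_numpy_fallback_agrees_with_jit_path(self, monkeypatch):
        import rnflasym.normative as nm

        y, = (np.random.default_rng(19).normal(2.0, 1.5, 400),)
        a = np.random.default_rng(20).standard_normal(400)
        Xm = np.column_stack([np.ones(400), a])
        Xs = np.column_stack([np.ones(400), a])
        fast = fit_gaussian_ls(y, Xm, Xs)
        monkeypatch.setattr(nm, "_HAVE_JIT", False)
        slow = fit_gaussian_ls(y, Xm, Xs)
        assert slow.converged and fast.converged
        assert slow.loglik == pytest.approx(fast.loglik, abs=1e-9)
        assert np.allclose(slow.beta_mu, fast.beta_mu, atol=1e-7)

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_gaussian_ls(np.ones(10), np.ones((10, 1)), np.ones((10, 1)))

    def test_aic_definition(self):
        rng = np.random.default_rng(3)
        n = 100
        a = rng.standard_normal(n)
        Xm = np.column_stack([np.ones(n), a, a**2])
        Xs = np.ones((n, 1))
        fit = fit_gaussian_ls(rng.standard_normal(n), Xm, Xs)
        assert fit.aic == pytest.approx(2 * 4 - 2 * fit.loglik)

    def test_likelihood_dominance_of_full_model(self):
        """Nesting: the all-terms model cannot have lower loglik than any
        submodel (up to optimizer tolerance)."""
        rng = np.random.default_rng(7)
        n = 300
        a, r = rng.standard_normal(n), rng.standard_normal(n)
        y = 1 + 0.3 * a + np.exp(0.2 + 0.2 * r) * rng.standard_normal(n)
        basis = full_basis(a, r)
        full_mask = TermMask((True,) * 6, (True,) * 6)
        ll_full = fit_gaussian_ls(
            y, basis[:, _design_columns(full_mask.mean_terms)],
            basis[:, _design_columns(full_mask.sigma_terms)],
        ).loglik
        rng2 = np.random.default_rng(0)
        for _ in range(20):
            mean = tuple(bool(b) for b in rng2.integers(0, 2, 6))
            sig = tuple(bool(b) for b in rng2.integers(0, 2, 6))
            sub = fit_gaussian_ls(
                y, basis[:, _design_columns(mean)], basis[:, _design_columns(sig)]
            )
            assert ll_full >= sub.loglik - 1e-4


class TestEnumeration:
    def test_4096_distinct_masks(self):
        cands = enumerate_candidates()
        assert len(cands) == 4096
        assert len(set(cands)) == 4096

    def test_two_optional_terms_give_four_masks(self):
        cands = enumerate_candidates(mean_terms=(0,), sigma_terms=(3,))
        assert len(cands) == 4
        assert cands[0] == TermMask((False,) * 6, (False,) * 6)

    def test_lexicographic_order(self):
        cands = enumerate_candidates(degree=1)
        bits = [
            tuple(m.mean_terms[i] for i in (0, 3)) + tuple(m.sigma_terms[i] for i in (0, 3))
            for m in cands
        ]
        assert bits == sorted(bits)


def _sim_cohort_linear(n, seed, mu0=-6.0, mu_age=0.08, logsd0=np.log(3.0), logsd_rd=0.01):
    """Cohort whose truth is exactly representable by the model class:
    mu linear in age, log-sigma linear in rd, no measurement noise."""
    return CohortParams(
        n_subjects=n,
        seed=seed,
        noise_sd=0.0,
        sd_link="log",
        asym_mean_field=AngularField(mu0),
        age_mean_slope_field=AngularField(mu_age),
        asym_sd_field=AngularField(logsd0),
        rd_sd_slope_field=AngularField(logsd_rd),
    )


class TestSelection:
    def test_argmin_property_and_brute_force_agreement(self):
        """Reduced 4-candidate set: selection equals an independent
        exhaustive refit ranked by brute-force AIC."""
        rng = np.random.default_rng(12)
        n = 300
        a, r = rng.standard_normal(n), rng.standard_normal(n)
        y = -2 + 0.9 * a + np.exp(0.1 + 0.4 * r) * rng.standard_normal(n)
        cands = enumerate_candidates(mean_terms=(0,), sigma_terms=(3,))
        model = select_location_model(y, a, r, cands, location=5)
        basis = full_basis(a, r)
        brute = []
        for mask in cands:
            Xm = basis[:, _design_columns(mask.mean_terms)]
            Xs = basis[:, _design_columns(mask.sigma_terms)]
            ll = brute_force_loglik(y, Xm, Xs)
            brute.append((2 * (Xm.shape[1] + Xs.shape[1]) - 2 * ll, mask))
        best_aic, best_mask = min(brute, key=lambda t: t[0])
        assert model.mask == best_mask
        assert model.aic == pytest.approx(best_aic, abs=1e-5)
        assert all(model.aic <= aic + 1e-8 for aic, _ in brute)
        assert model.location == 5

    def test_strong_cubic_age_effect_detected(self):
        rng = np.random.default_rng(30)
        n = 1000
        a, r = rng.standard_normal(n), rng.standard_normal(n)
        y = 2.0 * a**3 - 1.5 * a + 3.0 * rng.standard_normal(n)
        cands = enumerate_candidates(degree=3)
        model = select_location_model(y, a, r, cands)
        assert any(model.mask.mean_terms[:3])
        assert model.mask.mean_terms[2]  # the cubic term itself


@pytest.fixture(scope="module")
def linear_atlas():
    params = _sim_cohort_linear(400, seed=77)
    diffs = [normalize_and_difference(p) for p in generate_population(params)]
    cands = enumerate_candidates(degree=1)
    atlas = fit_atlas(diffs, candidates=cands, locations=[0, 100, 384])
    return params, diffs, cands, atlas


class TestAtlas:
    def test_exactly_768_models(self, linear_atlas):
        assert len(linear_atlas[3].models) == N_LOCATIONS

    def test_location_consistency_with_direct_selection(self, linear_atlas):
        params, diffs, cands, atlas = linear_atlas
        y = np.array([d.delta[100] for d in diffs])
        ages = np.array([d.age for d in diffs])
        rds = np.array([d.rd for d in diffs])
        a, r = atlas.standardization.transform(ages, rds)
        direct = select_location_model(y, a, r, cands, location=100)
        m = atlas.models[100]
        assert direct.mask == m.mask
        assert np.allclose(direct.beta_mu, m.beta_mu)
        assert np.allclose(direct.beta_logsigma, m.beta_logsigma)
        assert direct.aic == pytest.approx(m.aic)

    def test_serialization_roundtrip_bit_identical(self, linear_atlas, tmp_path):
        _, _, _, atlas = linear_atlas
        path = tmp_path / "atlas.json"
        atlas.save(path)
        back = NormativeAtlas.load(path)
        for angle, age, rd in [(0.0, 30.0, 5.0), (47.1, 61.0, -22.0), (359.5, 45.0, 0.0)]:
            assert back.predict_musigma(angle, age, rd) == atlas.predict_musigma(angle, age, rd)
        assert back.convention == atlas.convention

    def test_predict_quantile_gaussian_identities(self, linear_atlas):
        _, _, _, atlas = linear_atlas
        mu, sigma = atlas.predict_musigma(50.0, 45.0, 10.0)
        assert predict_quantile(atlas, 50.0, 45.0, 10.0, 0.5) == pytest.approx(mu, abs=1e-12)
        for p in (0.01, 0.1, 0.3):
            qa = predict_quantile(atlas, 50.0, 45.0, 10.0, p)
            qb = predict_quantile(atlas, 50.0, 45.0, 10.0, 1 - p)
            assert qa + qb == pytest.approx(2 * mu, abs=1e-9)
            # independent normal-quantile oracle
            assert qa == pytest.approx(mu + sigma * stats.norm.ppf(p), abs=1e-10)
        qs = [predict_quantile(atlas, 50.0, 45.0, 10.0, p) for p in (0.05, 0.25, 0.5, 0.9)]
        assert qs == sorted(qs)

    def test_extrapolation_warning(self, linear_atlas):
        _, _, _, atlas = linear_atlas
        with pytest.warns(UserWarning, match="extrapolat"):
            atlas.predict_musigma(0.0, 150.0, 0.0)

    def test_recovers_generating_distribution(self, linear_atlas):
        params, _, _, atlas = linear_atlas
        for age in (35.0, 60.0):
            for rd in (-20.0, 20.0):
                mu_t, sd_t = map(float, np.atleast_1d(true_normative_wrap(params, 0.0, age, rd)))
                mu_p, sd_p = atlas.predict_musigma(0.0, age, rd)
                assert mu_p == pytest.approx(mu_t, rel=0.15, abs=0.5)
                assert sd_p == pytest.approx(sd_t, rel=0.15)

    def test_small_cohort_warns(self, small_diffs):
        with pytest.warns(UserWarning, match="subjects"):
            fit_atlas(small_diffs[:20], candidates=[TermMask((False,) * 6, (False,) * 6)])


def true_normative_wrap(params, angle, age, rd):
    from rnflasym import true_normative

    return true_normative(params, angle, age, rd)


class TestScreening:
    def test_null_cohort_mostly_none(self, null_diffs):
        smap = screen_covariates(null_diffs)
        counts = smap.counts()
        assert counts["mean"]["none"] > 0.5 * N_LOCATIONS
        assert counts["var"]["none"] > 0.5 * N_LOCATIONS
        assert len(smap.mean_effect) == N_LOCATIONS

    def test_age_variance_band_detected(self):
        """Variance rising with age in one angular band should concentrate
        'age'/'both' variance labels there."""
        params = CohortParams(
            n_subjects=250,
            seed=13,
            noise_sd=0.5,
            asym_sd_field=AngularField(1.2),
            age_sd_slope_field=AngularField(0.0, ((90.0, 12.0, 0.035),)),
        )
        diffs = [normalize_and_difference(p) for p in generate_population(params)]
        smap = screen_covariates(diffs)
        labels = np.array(smap.var_effect)
        angles = np.arange(N_LOCATIONS) * 360.0 / N_LOCATIONS
        in_band = (angles > 70) & (angles < 110)
        hit = np.isin(labels, ("age", "both"))
        assert hit[in_band].mean() > 0.5
        assert hit[in_band].mean() > 3 * max(hit[~in_band].mean(), 0.02)
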