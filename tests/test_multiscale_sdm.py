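"""Buffer extraction, VIF screening, binomial GLM, stepwise AIC, scale search, PFA."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import photobackcast as pb
from photobackcast import RasterMap
from photobackcast import multiscale_sdm as ms
from photobackcast import synthetic_data as sd


class TestBufferProportions:
    def test_uniform_raster_is_pure(self, scheme):
        r = RasterMap(np.ones((50, 50), np.uint8), cell_size=50.0)
        c = ms.buffer_proportions(r, (1250.0, 1250.0), 600.0, scheme)
        assert c.percent("coniferous forest") == 100.0
        assert c.truncation_fraction == 0.0

    def test_tiny_radius_hits_single_cell(self, scheme):
        labels = np.ones((10, 10), np.uint8)
        labels[5, 5] = 6  # herbaceous
        r = RasterMap(labels, cell_size=100.0)
        center = (550.0, 550.0)  # center of cell (5, 5)
        c = ms.buffer_proportions(r, center, 40.0, scheme)
        assert c.percent("herbaceous") == 100.0
        assert c.n_valid == 1

    def test_checkerboard_near_half(self, scheme):
        labels = np.indices((200, 200)).sum(axis=0) % 2
        labels = np.where(labels == 0, 1, 6).astype(np.uint8)
        r = RasterMap(labels, cell_size=1.0)
        c = ms.buffer_proportions(r, (100.0, 100.0), 50.0, scheme)
        assert c.percent("coniferous forest") == pytest.approx(50.0, abs=2.0)

    def test_sums_to_100_and_truncation_reported(self, scheme, small_world):
        raster, _ = small_world
        c = ms.buffer_proportions(raster, (500.0, 500.0), 2000.0, scheme)
        assert sum(c.values.values()) == pytest.approx(100.0, abs=1e-9)
        assert 0.0 < c.truncation_fraction < 1.0

    def test_point_outside_raster_raises(self, scheme, small_world):
        raster, _ = small_world
        with pytest.raises(ValueError, match="outside"):
            ms.buffer_proportions(raster, (-100.0, 50.0), 500.0, scheme)


class TestCovariateTable:
    def test_grid_size_and_closure(self, scheme, small_world):
        raster, sites = small_world
        tab = ms.build_covariate_table(raster, sites.head(4), [250.0, 500.0], scheme)
        assert len(tab) == 8
        cats = [c for c in tab.columns if c not in ("site_id", "radius_m", "truncation")]
        assert np.allclose(tab[cats].sum(axis=1), 100.0)

    def test_disc_cover_declines_past_patch_radius(self, scheme):
        """Conifer share over a conifer disc must not increase with radius."""
        n = 201
        yy, xx = np.indices((n, n))
        disc = (xx - 100) ** 2 + (yy - 100) ** 2 <= 30**2
        labels = np.where(disc, 1, 6).astype(np.uint8)
        r = RasterMap(labels, cell_size=10.0)
        center = (1005.0, 1005.0)
        shares = [
            ms.buffer_proportions(r, center, rad, scheme).percent("coniferous forest")
            for rad in [300.0, 500.0, 700.0, 900.0]
        ]
        assert all(a >= b - 1e-9 for a, b in zip(shares, shares[1:]))


class TestVif:
    def test_orthogonal_covariates_retained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        res = ms.vif_screen(pd.DataFrame({"a": x, "b": y}))
        assert res.retained == ["a", "b"]
        assert np.allclose(res.vif["vif"], 1.0, atol=0.05)

    def test_duplicated_covariate_dropped_with_infinite_vif(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        res = ms.vif_screen(pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)}))
        assert len(res.dropped) == 1
        step0 = res.vif[res.vif.step == 0]
        assert np.isinf(step0[step0.term.isin(["a", "b"])].vif).all()

    def test_correlated_pair_matches_closed_form(self):
        """For bivariate normal with correlation r, VIF -> 1/(1-r^2)."""
        rng = np.random.default_rng(2)
        n = 200_000
        x = rng.normal(size=n)
        y = 0.95 * x + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
        res = ms.vif_screen(pd.DataFrame({"a": x, "b": y}), threshold=3.0)
        expected = 1.0 / (1.0 - 0.95**2)  # ~10.26
        step0 = res.vif[res.vif.step == 0]
        assert step0.vif.iloc[0] == pytest.approx(expected, rel=0.05)
        assert len(res.retained) == 1


def simulate_counts(rng, n, beta0, betas: dict, k=9):
    X = pd.DataFrame({t: rng.uniform(0, 100, n) for t in betas})
    eta = beta0 + sum(b * X[t] for t, b in betas.items())
    return rng.binomial(k, expit(eta)), X


class TestGlm:
    def test_intercept_only_closed_form(self):
        y = np.array([4, 5, 4, 5, 5, 4, 5, 4, 5, 4])  # 45 of 90
        fit = ms.fit_glm_binomial(y, 9, None)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_independent_likelihood_maximizer(self):
        """IRLS must land on the same optimum as direct numerical ML."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            y, X = simulate_counts(rng, 80, -2.0, {"cf": 0.03, "sh": -0.02})
            fit = ms.fit_glm_binomial(y, 9, X)
            Xd = np.column_stack([np.ones(80), X.to_numpy() / 100.0])

            def nll(b):
                mu = np.clip(expit(Xd @ b), 1e-12, 1 - 1e-12)
                return -(y * np.log(mu) + (9 - y) * np.log1p(-mu)).sum()

            opt = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
            mine = np.array([fit.intercept, fit.beta["cf"] * 100, fit.beta["sh"] * 100])
            assert np.allclose(mine, opt.x, atol=1e-6)

    def test_agrees_with_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(15)
        y, X = simulate_counts(rng, 150, -3.0, {"cf": 0.04, "sh": 0.06})
        fit = ms.fit_glm_binomial(y, 9, X)
        ref = sm.GLM(
            np.column_stack([y, 9 - y]), sm.add_constant(X),
            family=sm.families.Binomial(),
        ).fit()
        assert fit.intercept == pytest.approx(ref.params["const"], abs=1e-6)
        assert fit.beta["cf"] == pytest.approx(ref.params["cf"], abs=1e-8)
        assert fit.se["cf"] == pytest.approx(ref.bse["cf"], rel=1e-4)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_parameter_recovery_bias_shrinks_with_n(self):
        rng = np.random.default_rng(4)
        truth = {"cf": 0.04}
        errors = {}
        for n in (100, 500, 2000):
            ests = []
            for _ in range(30):
                y, X = simulate_counts(rng, n, -3.0, truth)
                ests.append(ms.fit_glm_binomial(y, 9, X).beta["cf"])
            errors[n] = abs(np.mean(ests) - truth["cf"])
        assert errors[2000] < errors[100] + 5e-4

    def test_separation_flagged(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.full(20, 100.0)]})
        y = np.r_[np.zeros(20), np.full(20, 9)].astype(int)
        fit = ms.fit_glm_binomial(y, 9, X)
        assert fit.diagnostics["separation_flag"]
        ok, reasons = ms.validate_model(fit)
        assert not ok and "separation" in reasons

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 100, 50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(np.linalg.LinAlgError):
            ms.fit_glm_binomial(rng.integers(0, 10, 50), 9, X)

    def test_aic_matches_definition(self):
        rng = np.random.default_rng(7)
        y, X = simulate_counts(rng, 60, -1.0, {"cf": 0.02})
        fit = ms.fit_glm_binomial(y, 9, X)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)


class TestStepwise:
    def test_strong_single_covariate_retained(self):
        rng = np.random.default_rng(8)
        y, X = simulate_counts(rng, 300, -3.0, {"cf": 0.05})
        fit = ms.stepwise_aic(y, 9, X)
        assert fit.terms == ("cf",)

    def test_noise_covariates_mostly_dropped(self):
        """AIC drops a pure-noise term with probability ~0.84; the per-term
        drop rate across replicates must clear 80%."""
        rng = np.random.default_rng(9)
        dropped = total = 0
        for _ in range(60):
            y, X = simulate_counts(rng, 500, -3.0, {"cf": 0.04})
            for j in range(3):
                X[f"noise{j}"] = rng.uniform(0, 100, 500)
            fit = ms.stepwise_aic(y, 9, X)
            assert "cf" in fit.terms  # the true effect always survives
            dropped += sum(f"noise{j}" not in fit.terms for j in range(3))
            total += 3
        assert dropped / total >= 0.80

    def test_aic_never_worse_than_full_model(self):
        rng = np.random.default_rng(10)
        y, X = simulate_counts(rng, 200, -2.0, {"cf": 0.03, "junk": 0.0})
        full = ms.fit_glm_binomial(y, 9, X)
        reduced = ms.stepwise_aic(y, 9, X)
        assert reduced.aic <= full.aic + 1e-9

    def test_aic_minimal_model_is_fixed_point(self):
        rng = np.random.default_rng(11)
        y, X = simulate_counts(rng, 400, -3.0, {"cf": 0.06})
        first = ms.stepwise_aic(y, 9, X)
        again = ms.stepwise_aic(y, 9, X[list(first.terms)], start_terms=first.terms)
        assert again.terms == first.terms
        assert again.aic == pytest.approx(first.aic)


class TestSelectScale:
    def test_uniform_landscape_ties_to_smallest_radius(self, scheme):
        raster = RasterMap(np.ones((120, 120), np.uint8), cell_size=50.0)
        sites = sd.random_sites(raster, 40, seed=1, margin_m=1000.0)
        cov = ms.build_covariate_table(raster, sites, [250.0, 500.0, 750.0], scheme)
        rng = np.random.default_rng(12)
        det = pd.DataFrame({"site_id": sites.site_id, "count": rng.binomial(9, 0.4, 40), "k": 9})
        sel = ms.select_scale("sp", det, cov)
        assert sel.fit.scale_m == 250.0
        assert sel.profile.aic.round(6).nunique() == 1  # flat profile

    def test_recovers_generating_scale(self, scheme, small_world):
        raster, sites = small_world
        truth = sd.SpeciesTruth("cj", 750.0, -4.41,
                                {"coniferous forest": 0.04, "shrubs": 0.06})
        cov = ms.build_covariate_table(raster, sites, [250.0, 500.0, 750.0, 1000.0, 1250.0], scheme)
        hits = []
        for rep in range(5):
            surveys = sd.simulate_surveys(raster, [truth], sites, scheme, seed=50 + rep)
            det = pd.DataFrame({
                "site_id": [s.site_id for s in surveys],
                "count": [s.detections["cj"] for s in surveys], "k": 9,
            })
            hits.append(ms.select_scale("cj", det, cov).fit.scale_m)
        assert sum(abs(h - 750.0) <= 250.0 for h in hits) >= 4


class TestPfa:
    @pytest.mark.parametrize("p,k,expected", [(0.0, 5, 1.0), (1.0, 3, 0.0), (0.5, 9, 0.5**9)])
    def test_values(self, p, k, expected):
        assert ms.pfa(p, k) == pytest.approx(expected)

    def test_strictly_decreasing_in_p_and_k(self):
        ps = np.linspace(0.05, 0.95, 19)
        vals = [ms.pfa(p, 9) for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        vals_k = [ms.pfa(0.3, k) for k in range(1, 12)]
        assert all(a > b for a, b in zip(vals_k, vals_k[1:]))

    def test_reliability_flag(self):
        est = ms.detectability("sp", p=0.5, k=9)
        assert est.reliable and est.pfa < 0.15
        assert not ms.detectability("sp", p=0.05, k=2).reliable


class TestValidateModel:
    def test_well_specified_fit_validates(self):
        rng = np.random.default_rng(13)
        y, X = simulate_counts(rng, 400, -2.0, {"cf": 0.03})
        fit = ms.fit_glm_binomial(y, 9, X)
        ok, reasons = ms.validate_model(fit)
        assert ok, reasons
        assert 0.3 < fit.diagnostics["dispersion"] < 3.0

    def test_near_constant_covariate_fails_validation(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame({"flat": np.full(100, 50.0) + rng.normal(0, 1e-7, 100)})
        fit = ms.fit_glm_binomial(rng.binomial(9, 0.4, 100), 9, X)
        ok, reasons = ms.validate_model(fit)
        assert not ok
        assert any("degenerate" in r for r in reasons)
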