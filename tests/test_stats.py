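"""Mixed-model machinery: likelihood oracles, degenerate limits, contrasts,
interaction tests, rate projection, per-patient trends."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.special import logsumexp

from cryptdrift import stats as cs
from cryptdrift.stats import _nb_logpmf


@pytest.fixture(scope="module")
def nb_table():
    rng = np.random.default_rng(17)
    return cs.simulate_nb_mixed_table(rng, rate_placebo=1.3, rate_sulindac=1.0,
                                      sigma_b=0.3)


@pytest.fixture(scope="module")
def lmm_table(nb_table):
    rng = np.random.default_rng(18)
    tab = nb_table.copy()
    codes = tab["patient_id"].astype("category").cat.codes.to_numpy()
    tab["percent_methylation_readweighted"] = (
        20.0 + 1.5 * tab["timepoint_years"]
        - 2.0 * (tab["group"] == "sulindac") * tab["timepoint_years"]
        + 2.0 * rng.standard_normal(8)[codes]
        + rng.normal(0, 4, len(tab)))
    return tab


class TestProjectRate:
    def test_one_year_projection(self):
        assert cs.project_rate(4.46, 0.96, 1) == 4.28

    def test_second_year_projection(self):
        assert cs.project_rate(4.28, 0.96, 1) == 4.11

    def test_identity_rate(self):
        assert cs.project_rate(3.5, 1.0, 7) == 3.5

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            cs.project_rate(4.0, 0.0, 1)


class TestNBMixed:
    def test_likelihood_matches_dense_grid(self, nb_table):
        """Adaptive Gauss–Hermite marginal likelihood equals brute-force
        1-D integration per patient at fixed parameters."""
        data, names, ll_fn = cs.nb_mixed_loglik_oracle_ready(nb_table, "continuous")
        params = np.array([0.8, 0.2, 0.26, -0.26, np.log(8.0), np.log(0.3)])
        beta, theta, sigma = params[:4], np.exp(params[4]), np.exp(params[5])
        eta = data.X @ beta
        grid = np.linspace(-10 * sigma, 10 * sigma, 20001)
        db = grid[1] - grid[0]
        oracle = 0.0
        for g in range(data.y.shape[0]):
            h = np.array([
                np.where(data.mask[g],
                         _nb_logpmf(data.y[g], np.exp(eta[g] + b), theta), 0).sum()
                + sps.norm.logpdf(b, 0, sigma) for b in grid])
            oracle += logsumexp(h) + np.log(db)
        agh = ll_fn(params, 25)
        assert abs(agh - oracle) / abs(oracle) < 1e-6

    def test_zero_variance_equals_plain_nb_glm(self, nb_table):
        fit0 = cs.fit_nb_mixed(nb_table, "continuous", sigma_fixed=0.0)
        X, _ = cs.build_design(nb_table, "continuous")
        ref = sm.NegativeBinomial(nb_table["diversity"].to_numpy(float), X).fit(disp=0)
        rel = np.abs(fit0.beta - ref.params[:-1]) / np.maximum(np.abs(ref.params[:-1]), 1e-8)
        assert rel.max() < 1e-4
        assert fit0.dispersion == pytest.approx(1 / ref.params[-1], rel=1e-3)
        assert fit0.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_quadrature_stability_25_to_51_nodes(self, nb_table):
        f25 = cs.fit_nb_mixed(nb_table, "continuous", quadrature_nodes=25)
        f51 = cs.fit_nb_mixed(nb_table, "continuous", quadrature_nodes=51)
        rel = np.abs(f51.beta - f25.beta) / np.maximum(np.abs(f25.beta), 1e-6)
        assert rel.max() < 1e-3

    def test_rate_and_interaction_recovered(self, nb_table):
        fit = cs.fit_nb_mixed(nb_table, "continuous")
        rates = fit.rates.set_index("group")
        assert rates.loc["placebo", "rate_per_year"] == pytest.approx(1.3, abs=0.2)
        assert rates.loc["sulindac", "rate_per_year"] == pytest.approx(1.0, abs=0.2)
        assert (rates["ci_low"] < rates["rate_per_year"]).all()
        assert (rates["ci_high"] > rates["rate_per_year"]).all()

    def test_categorical_means_positive_with_cis(self, nb_table):
        fit = cs.fit_nb_mixed(nb_table, "categorical")
        gm = fit.group_means
        assert len(gm) == 6
        assert (gm["mean"] > 0).all()
        assert ((gm["ci_low"] <= gm["mean"]) & (gm["mean"] <= gm["ci_high"])).all()

    def test_rate_mean_consistency(self, nb_table):
        """exp(continuous slope) tracks the geometric trend of the
        categorical means over the 2-year window."""
        cont = cs.fit_nb_mixed(nb_table, "continuous")
        cat = cs.fit_nb_mixed(nb_table, "categorical")
        gm = cat.group_means.set_index(["group", "timepoint_label"])
        for g in ("placebo", "sulindac"):
            geo = (gm.loc[(g, "t2y"), "mean"] / gm.loc[(g, "t0"), "mean"]) ** (1 / 2)
            rate = cont.rates.set_index("group").loc[g, "rate_per_year"]
            assert rate == pytest.approx(geo, rel=0.10)


class TestLinearMixed:
    def test_matches_statsmodels_mixedlm_ml(self, lmm_table):
        fit = cs.fit_linear_mixed(lmm_table, "continuous")
        ref = smf.mixedlm("percent_methylation_readweighted ~ group * timepoint_years",
                          lmm_table, groups=lmm_table["patient_id"]).fit(reml=False)
        assert np.allclose(fit.beta, ref.fe_params.to_numpy(), atol=1e-4)
        assert fit.random_intercept_variance == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-4)

    def test_zero_variance_limit_is_ols(self, lmm_table):
        fit = cs.fit_linear_mixed(lmm_table, "continuous", lambda_fixed=0.0)
        X, _ = cs.build_design(lmm_table, "continuous")
        ols = sm.OLS(lmm_table["percent_methylation_readweighted"].to_numpy(), X).fit()
        assert np.max(np.abs(fit.beta - ols.params)) < 1e-8

    def test_translation_equivariance(self, lmm_table):
        fit = cs.fit_linear_mixed(lmm_table, "categorical")
        shifted = lmm_table.copy()
        shifted["percent_methylation_readweighted"] += 13.0
        fit2 = cs.fit_linear_mixed(shifted, "categorical")
        assert np.allclose(fit2.group_means["mean"],
                           fit.group_means["mean"] + 13.0, atol=1e-6)
        c1 = cs.fit_linear_mixed(lmm_table, "continuous").rates["change_per_year"]
        c2 = cs.fit_linear_mixed(shifted, "continuous").rates["change_per_year"]
        assert np.allclose(c1, c2, atol=1e-6)

    def test_balanced_cell_means_closed_form(self):
        """With a balanced design, ML-GLS cell means equal raw group x time
        cell means (the closed-form balanced solution)."""
        rng = np.random.default_rng(23)
        tab = cs.simulate_nb_mixed_table(rng, n_patients_per_group=3, n_crypts=5)
        codes = tab["patient_id"].astype("category").cat.codes.to_numpy()
        tab["percent_methylation_readweighted"] = (
            15 + rng.standard_normal(6)[codes] * 2 + rng.normal(0, 3, len(tab)))
        fit = cs.fit_linear_mixed(tab, "categorical")
        raw = (tab.groupby(["group", "timepoint_label"])
               ["percent_methylation_readweighted"].mean())
        gm = fit.group_means.set_index(["group", "timepoint_label"])["mean"]
        assert np.allclose(gm.sort_index(), raw.sort_index(), atol=1e-8)


class TestInteraction:
    def test_identical_fits_give_p_one(self, nb_table):
        fit = cs.fit_nb_mixed(nb_table, "continuous")
        out = cs.test_interaction(fit, fit)
        assert out["lrt_statistic"] == 0.0 and out["p_lrt"] == 1.0

    def test_lrt_against_reduced_model(self, nb_table):
        full = cs.fit_nb_mixed(nb_table, "continuous")
        red = cs.fit_nb_mixed(nb_table, "continuous", interaction=False)
        out = cs.test_interaction(full, red)
        assert out["df"] == 1 and 0 <= out["p_lrt"] <= 1
        assert full.loglik >= red.loglik - 1e-6

    def test_power_for_strong_opposite_trends(self):
        """At the trial's scale a strong rate contrast (1.3 vs 0.8 per
        year) is detected by the Wald interaction test with power > 0.8."""
        hits = 0
        for s in range(50):
            rng = np.random.default_rng((31, s))
            tab = cs.simulate_nb_mixed_table(rng, rate_placebo=1.3,
                                             rate_sulindac=0.8,
                                             theta=8.0, sigma_b=0.3)
            hits += cs.fit_nb_mixed(tab, "continuous").interaction_p < 0.05
        assert hits / 50 > 0.8

    def test_non_nested_rejected(self, nb_table, lmm_table):
        nb = cs.fit_nb_mixed(nb_table, "continuous")
        lm = cs.fit_linear_mixed(lmm_table, "continuous")
        with pytest.raises(ValueError):
            cs.test_interaction(nb, lm)


class TestPerPatientTrends:
    def _polyps(self, counts_by_pid):
        rows = []
        for pid, (group, counts) in counts_by_pid.items():
            for (lab, yrs), n in zip((("t0", 0.0), ("t4m", 1 / 3), ("t2y", 2.0)), counts):
                rows.append({"patient_id": pid, "group": group,
                             "timepoint_label": lab, "timepoint_years": yrs,
                             "polyps": n})
        return pd.DataFrame(rows)

    def test_flat_counts_rate_one(self):
        tab = pd.DataFrame({
            "patient_id": ["p1"] * 3, "group": ["placebo"] * 3,
            "timepoint_label": ["t0", "t4m", "t2y"],
            "timepoint_years": [0.0, 1 / 3, 2.0],
            "diversity": [2, 2, 2],
            "percent_methylation_readweighted": [20.0, 20.0, 20.0],
        })
        polyps = self._polyps({"p1": ("placebo", (0, 1, 3))})
        trends, _ = cs.per_patient_trends(tab, polyps)
        assert trends.loc[0, "rate_patterns_per_year"] == pytest.approx(1.0, abs=1e-6)

    def test_polyp_slope_closed_form(self):
        # OLS slope of (0, 1, 3) on (0, 1/3, 2): closed-form arithmetic
        t = np.array([0.0, 1 / 3, 2.0])
        y = np.array([0.0, 1.0, 3.0])
        expected = ((t - t.mean()) @ (y - y.mean())) / ((t - t.mean()) @ (t - t.mean()))
        tab = pd.DataFrame({
            "patient_id": ["p1"] * 3, "group": ["placebo"] * 3,
            "timepoint_label": ["t0", "t4m", "t2y"], "timepoint_years": t,
            "diversity": [2, 3, 4],
            "percent_methylation_readweighted": [20.0, 21.0, 22.0],
        })
        polyps = self._polyps({"p1": ("placebo", (0, 1, 3))})
        trends, _ = cs.per_patient_trends(tab, polyps)
        assert trends.loc[0, "delta_polyps_per_year"] == pytest.approx(expected)
        assert expected > 0

    def test_collinear_slopes_give_r_one(self):
        rows = []
        polyp_map = {}
        for i, pid in enumerate(["p1", "p2", "p3", "p4"]):
            slope = 1.0 + i
            for lab, yrs in (("t0", 0.0), ("t4m", 1 / 3), ("t2y", 2.0)):
                rows.append({"patient_id": pid, "group": "placebo",
                             "timepoint_label": lab, "timepoint_years": yrs,
                             "diversity": 2,
                             "percent_methylation_readweighted": 10 + slope * yrs})
            polyp_map[pid] = ("placebo", (0, round(slope / 3), round(2 * slope)))
        tab = pd.DataFrame(rows)
        trends, corr = cs.per_patient_trends(tab, self._polyps(polyp_map))
        r = corr["delta_percent_per_year__vs__delta_polyps_per_year"]["r"]
        assert r == pytest.approx(1.0, abs=0.02)


class TestAgeAdjustment:
    def _ages(self, table, const=False):
        pids = sorted(table["patient_id"].unique())
        ages = [10.0] * len(pids) if const else [7.0 + i for i in range(len(pids))]
        return pd.DataFrame({"patient_id": pids, "age": ages})

    def test_constant_age_dropped(self, nb_table, caplog):
        out = cs.adjust_for_age(nb_table, self._ages(nb_table, const=True))
        assert out["adjusted"] is out["unadjusted"]

    def test_missing_ages_refused(self, nb_table):
        ages = self._ages(nb_table).iloc[:-1]
        out = cs.adjust_for_age(nb_table, ages)
        assert out["adjusted"] is None and out["unadjusted"] is not None

    def test_adjustment_keeps_rate_estimates_close(self, nb_table):
        """Random (non-confounding) ages should not move the treatment-time
        rates materially."""
        out = cs.adjust_for_age(nb_table, self._ages(nb_table))
        r0 = out["unadjusted"].rates.set_index("group")["rate_per_year"]
        r1 = out["adjusted"].rates.set_index("group")["rate_per_year"]
        assert np.allclose(r0, r1, rtol=0.1)
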