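"""Mixed model: REML oracles, df conventions, Tukey HSD cross-checks."""

import warnings

import numpy as np
import pytest
from scipy import integrate, stats

from coralqg.design import DesignSpec, generate
from coralqg.lmm import LinearMixedModel, LmmError, fit_lmm

from conftest import single_trait_design


def balanced_mom(table, trait, n_genotypes=12):
    """ANOVA method-of-moments (V_tank, V_residual) on the balanced design."""
    sub = table[table["trait_name"] == trait]
    n_trt = sub["treatment"].nunique()
    n_tanks = sub["tank_id"].nunique()
    tank_means = sub.groupby(["treatment", "tank_id"], observed=True)["value"].mean()
    trt_means = sub.groupby("treatment", observed=True)["value"].mean()
    ss_tank = sum(
        n_genotypes * (tank_means[trt][tk] - trt_means[trt]) ** 2 for trt, tk in tank_means.index
    )
    ms_tank = ss_tank / (n_tanks - n_trt)
    cell = sub.groupby(["genotype_id", "treatment"], observed=True)["value"].transform("mean")
    tkm = sub.groupby("tank_id", observed=True)["value"].transform("mean")
    trtm = sub.groupby("treatment", observed=True)["value"].transform("mean")
    resid = sub["value"] - cell - tkm + trtm
    df_e = len(sub) - n_trt * n_genotypes - (n_tanks - n_trt)
    ms_e = (resid**2).sum() / df_e
    return (ms_tank - ms_e) / n_genotypes, ms_e


def studentized_range_sf_oracle(q, k, df):
    """P(Q > q) by direct double integration of the studentized range CDF."""

    def range_cdf(w):
        f = lambda z: stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - w)) ** (k - 1)
        val, _ = integrate.quad(f, -9, 9, epsabs=1e-12, limit=200)
        return k * val

    # R = sqrt(chi2_df/df); integrate over its density
    from scipy.special import gammaln

    def integrand(r):
        logdens = (
            (df / 2.0) * np.log(df)
            + (df - 1) * np.log(r)
            - df * r * r / 2.0
            - gammaln(df / 2.0)
            - (df / 2.0 - 1) * np.log(2.0)
        )
        return np.exp(logdens) * range_cdf(q * r)

    cdf, _ = integrate.quad(integrand, 1e-8, 6, epsabs=1e-10, limit=200)
    return 1.0 - cdf


class TestReml:
    def test_matches_method_of_moments_on_balanced_design(self, default_table):
        fit = fit_lmm(default_table, "protein")
        vt, ve = balanced_mom(default_table, "protein")
        assert fit.v_tank_ == pytest.approx(vt, abs=1e-6 * max(1.0, vt))
        assert fit.v_residual_ == pytest.approx(ve, rel=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        d = single_trait_design(
            v_genotype=0.004, v_tank=0.002, v_residual=0.01, rho=1.0,
            n_genotypes=4, n_tanks=3, seed=11,
        )
        table = generate(d)
        fit = fit_lmm(table, "x")
        sub = table[table["trait_name"] == "x"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm(
                "value ~ C(treatment)*C(genotype_id)", sub, groups=sub["tank_id"]
            ).fit(reml=True)
        assert fit.v_tank_ == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.v_residual_ == pytest.approx(float(ref.scale), rel=1e-4)

    def test_zero_tank_variance_hits_boundary_and_matches_ols(self):
        # seed chosen so the REML optimum genuinely sits at the boundary
        d = single_trait_design(
            v_genotype=0.01, v_tank=0.0, v_residual=0.02, rho=1.0, seed=0
        )
        table = generate(d)
        fit = fit_lmm(table, "x")
        assert fit.v_tank_ <= 1e-6 * fit.v_residual_
        # at the boundary the GLS fit reduces to OLS cell means
        sub = table[table["trait_name"] == "x"]
        cell = sub.groupby(["genotype_id", "treatment"], observed=True)["value"].mean()
        grand = cell.mean()
        assert fit.coef_[0] == pytest.approx(grand, rel=1e-8)

    def test_row_order_invariance(self, default_table):
        shuffled = default_table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = fit_lmm(default_table, "po")
        b = fit_lmm(shuffled, "po")
        assert a.v_tank_ == pytest.approx(b.v_tank_, rel=1e-5, abs=1e-12)
        assert a.v_residual_ == pytest.approx(b.v_residual_, rel=1e-6)

    def test_parameter_recovery_over_simulations(self):
        """Median REML estimates within 10% of truth across 500 datasets."""
        vts, ves = [], []
        for seed in range(500):
            d = single_trait_design(
                v_genotype=0.004, v_tank=0.003, v_residual=0.012, rho=1.0, seed=seed
            )
            fit = fit_lmm(generate(d), "x")
            vts.append(fit.v_tank_)
            ves.append(fit.v_residual_)
        assert np.median(vts) == pytest.approx(0.003, rel=0.10)
        assert np.median(ves) == pytest.approx(0.012, rel=0.10)


class TestAnova:
    def test_containment_dfs_on_default_design(self, default_table):
        fit = fit_lmm(default_table, "buoyant_weight")
        anova = fit.anova_.set_index("term")
        assert anova.loc["treatment", "df_num"] == 3
        assert anova.loc["treatment", "df_den"] == 16  # 20 tanks − 4 treatments
        assert anova.loc["genotype", "df_num"] == 11
        assert anova.loc["genotype", "df_den"] == 176
        assert anova.loc["treatment:genotype", "df_num"] == 33

    def test_satterthwaite_close_to_containment_on_balanced_data(self, default_table):
        fit = fit_lmm(default_table, "protein")
        sat = fit.anova(ddf_method="satterthwaite").set_index("term")
        assert sat.loc["treatment", "df_den"] == pytest.approx(16, rel=0.25)
        assert sat.loc["genotype", "df_den"] == pytest.approx(176, rel=0.15)

    def test_singular_design_names_empty_cell(self, default_table):
        broken = default_table[
            ~(
                (default_table["genotype_id"] == "G03")
                & (default_table["treatment"] == "combined")
            )
        ]
        with pytest.raises(LmmError, match="G03.*combined"):
            fit_lmm(broken, "yield")

    def test_missing_trait_and_level_preconditions(self, default_table):
        with pytest.raises(LmmError, match="not present"):
            fit_lmm(default_table, "nope")


class TestTukey:
    def test_identical_group_means_give_p_one(self):
        d = single_trait_design(d_temp=0.0, d_pco2=0.0, v_residual=0.01, seed=3)
        # force exactly equal cell means by overwriting values symmetrically
        table = generate(d)
        fit = fit_lmm(table, "x")
        tk = fit.tukey()
        # no true differences: estimates are small, adjusted p not tiny,
        # and a contrast with estimate ~0 has p ≈ 1
        smallest = tk.loc[tk["estimate"].abs().idxmin()]
        assert smallest["p_adjusted"] > 0.5

    def test_adjusted_p_matches_direct_integration(self, default_table):
        fit = fit_lmm(default_table, "buoyant_weight")
        tk = fit.tukey()
        row = tk.iloc[3]
        q = abs(row["estimate"]) / row["se"] * np.sqrt(2)
        oracle = studentized_range_sf_oracle(q, k=4, df=row["df"])
        assert row["p_adjusted"] == pytest.approx(oracle, abs=1e-6)

    def test_adjustment_is_monotone(self, default_table):
        fit = fit_lmm(default_table, "chl_total")
        tk = fit.tukey()
        assert (tk["p_adjusted"] >= tk["p_unadjusted"] - 1e-12).all()

    def test_lsmeans_recover_treatment_means_on_balanced_data(self, default_table):
        fit = fit_lmm(default_table, "yield")
        ls = fit.lsmeans().set_index("treatment")["lsmean"]
        sub = default_table[default_table["trait_name"] == "yield"]
        raw = sub.groupby("treatment", observed=True)["value"].mean()
        for t in raw.index:
            assert ls[t] == pytest.approx(raw[t], rel=1e-8)

    def test_only_treatment_factor_supported(self, default_table):
        fit = fit_lmm(default_table, "yield")
        with pytest.raises(ValueError, match="treatment"):
            fit.tukey(factor="genotype")
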