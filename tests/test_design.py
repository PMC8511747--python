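"""Generator: layout arithmetic, generative formula, and component recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coralqg.design import (
    TREATMENTS,
    DesignError,
    DesignSpec,
    TraitSpec,
    default_traits,
    generate,
    ground_truth_h2,
)

from conftest import single_trait_design


class TestLayout:
    def test_default_design_has_240_fragments(self, default_table):
        assert default_table["fragment_id"].nunique() == 240
        per_trait = default_table.groupby("trait_name", observed=True).size()
        assert (per_trait == 240).all()

    def test_each_genotype_treatment_cell_has_five_distinct_tanks(self, default_table):
        one = default_table[default_table["trait_name"] == "buoyant_weight"]
        cell_tanks = one.groupby(["genotype_id", "treatment"], observed=True)["tank_id"].nunique()
        assert (cell_tanks == 5).all()
        # tanks are nested in treatments: 20 tanks, each mapping to one treatment
        assert one["tank_id"].nunique() == 20
        assert (one.groupby("tank_id", observed=True)["treatment"].nunique() == 1).all()

    def test_no_duplicate_fragment_trait_pairs(self, default_table):
        assert not default_table.duplicated(["fragment_id", "trait_name"]).any()

    def test_unsupported_fragments_per_tank_rejected(self):
        with pytest.raises(DesignError, match="n_fragments_per_tank"):
            DesignSpec(n_fragments_per_tank=6).validate()


class TestGenerativeFormula:
    def test_zero_variance_zero_delta_gives_constant(self):
        d = single_trait_design(d_temp=0.0, d_pco2=0.0, control_mean=3.5)
        table = generate(d)
        assert np.allclose(table["value"], 3.5)

    def test_noiseless_means_follow_deltas(self):
        d = single_trait_design(d_temp=-0.2, d_pco2=-0.1, mode="synergistic", magnitude=0.15)
        table = generate(d)
        means = table.groupby("treatment", observed=True)["value"].mean()
        assert means["control"] == pytest.approx(1.0)
        assert means["high_temp"] == pytest.approx(0.8)
        assert means["high_pco2"] == pytest.approx(0.9)
        assert means["combined"] == pytest.approx(1.0 - 0.45)  # null −0.3, plus 0.15 decline

    def test_additive_mode_combined_mean_matches_sum_at_large_replication(self):
        # Monte-Carlo check of the generative formula: 500 tank replicates
        d = single_trait_design(
            d_temp=-0.2, d_pco2=-0.1, mode="additive", v_genotype=0.01,
            v_tank=0.005, v_residual=0.02, rho=1.0, n_genotypes=4, n_tanks=500, seed=5,
        )
        table = generate(d)
        means = table.groupby("treatment", observed=True)["value"].mean()
        emp = (means["combined"] - means["control"]) / means["control"]
        # rho=1 cancels genotype noise in the contrast; tank MC error
        # of the mean difference ~ sqrt(2·0.005/500) ≈ 0.0045
        assert emp == pytest.approx(-0.3, abs=0.02)

    def test_antagonistic_mode_damps_the_combined_response(self):
        d = single_trait_design(d_temp=-0.3, d_pco2=-0.2, mode="antagonistic", magnitude=0.2)
        table = generate(d)
        means = table.groupby("treatment", observed=True)["value"].mean()
        assert (means["combined"] - means["control"]) == pytest.approx(-0.3)

    def test_clipping_counted_and_floor_respected(self):
        d = single_trait_design(control_mean=0.1, v_residual=0.04, floor=0.0, seed=2)
        table = generate(d)
        assert (table["value"] >= 0).all()
        assert table.attrs["clipped"]["x"] > 0

    def test_dropout_removes_fragments_across_all_traits(self):
        d = DesignSpec(seed=4, dropout_rate=0.05)
        table = generate(d)
        assert table.attrs["dropped_fragments"] > 0
        per_frag = table.groupby("fragment_id", observed=True)["trait_name"].nunique()
        assert per_frag.nunique() == 1  # a dead fragment loses every trait


class TestReproducibility:
    def test_fixed_seed_bit_reproducible(self):
        a = generate(DesignSpec(seed=42))
        b = generate(DesignSpec(seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate(DesignSpec(seed=1))
        b = generate(DesignSpec(seed=2))
        assert not np.allclose(a["value"], b["value"])


@pytest.fixture(scope="module")
def big_table():
    d = single_trait_design(
        d_temp=0.0, d_pco2=0.0, v_genotype=0.4, v_tank=0.1, v_residual=0.25,
        rho=0.6, n_genotypes=200, n_tanks=40, seed=9,
    )
    return generate(d)


class TestComponentRecovery:
    """Sample moments converge to the generating variance components."""

    def test_genotype_variance_recovered(self, big_table):
        # genotype effect within one treatment, averaged over many tanks
        sub = big_table[big_table["treatment"] == "control"]
        gmeans = sub.groupby("genotype_id", observed=True)["value"].mean()
        # var of genotype means = V_g + (V_tank+V_e)/n_reps
        correction = (0.1 + 0.25) / 40
        assert gmeans.var() - correction == pytest.approx(0.4, rel=0.25)

    def test_tank_and_residual_variance_recovered(self, big_table):
        sub = big_table[big_table["treatment"] == "control"]
        centred = sub["value"] - sub.groupby("genotype_id", observed=True)["value"].transform("mean")
        tank_means = sub.groupby("tank_id", observed=True)["value"].mean()
        within_tank = sub["value"] - sub.groupby("tank_id", observed=True)["value"].transform("mean")
        # tank means vary by V_tank + (V_g + V_e)/n_genotypes
        assert tank_means.var() - (0.4 + 0.25) / 200 == pytest.approx(0.1, rel=0.3)
        assert within_tank.var(ddof=0) == pytest.approx(0.4 + 0.25, rel=0.1)
        assert centred.notna().all()

    def test_cross_treatment_correlation_matches_rho(self):
        d = single_trait_design(
            d_temp=0.0, d_pco2=0.0, v_genotype=1.0, v_tank=0.0, v_residual=1e-4,
            rho=0.6, n_genotypes=2000, n_tanks=2, seed=13,
        )
        table = generate(d)
        gm = table.pivot_table(index="genotype_id", columns="treatment", values="value",
                               aggfunc="mean", observed=True)
        corr = gm.corr().to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.6, atol=0.06)


class TestGroundTruthH2:
    @pytest.mark.parametrize(
        "vg,vt,ve,expected",
        [(4, 2, 2, 0.5), (0, 1, 1, 0.0), (57, 13, 30, 0.57)],
    )
    def test_h2_ratio(self, vg, vt, ve, expected):
        spec = TraitSpec(name="x", v_genotype=vg, v_tank=vt, v_residual=ve)
        assert ground_truth_h2(spec) == pytest.approx(expected)

    def test_all_zero_variances_undefined(self):
        with pytest.raises(DesignError, match="undefined"):
            ground_truth_h2(TraitSpec(name="x"))

    def test_sidecar_truth_consistent(self):
        truth = DesignSpec().ground_truth()
        assert len(truth) == 12
        for spec in default_traits():
            t = truth[spec.name]
            assert t["additive_null"] == pytest.approx(
                t["delta_temp"] + t["delta_pco2"]
            )
            assert t["h2"] == pytest.approx(ground_truth_h2(spec))


class TestValidation:
    def test_negative_variance_rejected(self):
        with pytest.raises(DesignError, match="negative variance"):
            TraitSpec(name="x", v_residual=-1.0).validate()

    def test_non_psd_genetic_covariance_rejected_with_explanation(self):
        spec = TraitSpec(name="x", v_genotype=1.0, genetic_correlation=-0.9)
        with pytest.raises(DesignError, match="positive semi-definite"):
            spec.validate()

    def test_combined_delta_cannot_be_specified_directly(self):
        spec = TraitSpec(name="x", treatment_deltas={"combined": -0.5})
        with pytest.raises(DesignError, match="derived"):
            spec.validate()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    h2=st.floats(0.0, 0.9),
    rho=st.floats(-1 / 3, 1.0),
    d_temp=st.floats(-0.5, 0.2),
    d_pco2=st.floats(-0.5, 0.2),
    seed=st.integers(0, 2**16),
)
def test_generate_property_finite_and_counted(h2, rho, d_temp, d_pco2, seed):
    """Any valid spec yields a complete, finite table of the right shape."""
    d = single_trait_design(
        d_temp=d_temp, d_pco2=d_pco2, v_genotype=h2 * 0.02, v_tank=0.001,
        v_residual=(1 - h2) * 0.02, rho=rho, n_genotypes=4, n_tanks=2, seed=seed,
    )
    table = generate(d)
    assert len(table) == 4 * 4 * 2
    assert np.isfinite(table["value"]).all()
    assert set(table["treatment"]) == set(TREATMENTS)
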