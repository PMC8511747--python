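import numpy as np
import pytest

from coralqg.design import DesignSpec, TraitSpec, generate


@pytest.fixture(scope="session")
def default_table():
    """One default-design synthetic dataset shared across read-only tests."""
    return generate(DesignSpec(seed=7))


def single_trait_design(
    name="x",
    control_mean=1.0,
    d_temp=-0.2,
    d_pco2=-0.1,
    mode="additive",
    magnitude=0.0,
    v_genotype=0.0,
    v_tank=0.0,
    v_residual=0.0,
    rho=0.0,
    floor=None,
    n_genotypes=12,
    n_tanks=5,
    seed=0,
):
    """Convenience builder for one-trait designs with explicit ground truth."""
    spec = TraitSpec(
        name=name,
        control_mean=control_mean,
        treatment_deltas={"high_temp": d_temp, "high_pco2": d_pco2},
        interaction_mode=mode,
        interaction_magnitude=magnitude,
        v_genotype=v_genotype,
        v_tank=v_tank,
        v_residual=v_residual,
        genetic_correlation=rho,
        value_floor=floor,
    )
    return DesignSpec(
        n_genotypes=n_genotypes, n_tanks_per_treatment=n_tanks, traits=(spec,), seed=seed
    )


@pytest.fixture
def noiseless_design():
    return single_trait_design(v_genotype=0.0, v_tank=0.0, v_residual=0.0)


def rejection_rate(pvals, alpha=0.05):
    p = np.asarray(pvals)
    return float((p <= alpha).mean())
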