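"""Synthetic factorial multi-stressor experiment with known ground truth.

This module simulates the phenotype table of a clonal-replicate aquarium
experiment: ``n_genotypes`` coral genets, each fragmented and distributed so
that every tank holds exactly one clone-mate of each genotype, with tanks
nested in four treatments (``control``, ``high_temp``, ``high_pco2``,
``combined``).  Every downstream analysis stage of the package can therefore
be exercised against data whose genetic, tank and residual variance
components — and whose stressor-interaction structure — are known exactly.

The generative model for one trait value :math:`y_{gjk}` of genotype *g* in
tank *k* of treatment *j* is

.. math::

    y_{gjk} = \\mu (1 + \\Delta_j) + a_{gj} + t_k + e_{gjk}

where :math:`\\mu` is the control mean, :math:`\\Delta_j` the relative
treatment effect (0 for control), :math:`a_{g\\cdot}` a 4-vector of genotype
effects drawn from a multivariate normal with variance ``v_genotype`` and
exchangeable cross-treatment correlation ``genetic_correlation``
(:math:`\\rho_G`), :math:`t_k \\sim N(0, v_{tank})` and
:math:`e \\sim N(0, v_{residual})`.  For the ``combined`` treatment
:math:`\\Delta_{comb}` is the additive null :math:`\\Delta_T + \\Delta_P`
plus/minus an interaction offset depending on ``interaction_mode``.

:math:`\\rho_G > 0` emulates broad-spectrum resistance (genets good under one
stressor are good under another); :math:`\\rho_G < 0` emulates tradeoffs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Treatment levels, in canonical order.
TREATMENTS: tuple[str, ...] = ("control", "high_temp", "high_pco2", "combined")

#: The two single-stressor levels.
STRESSORS: tuple[str, str] = ("high_temp", "high_pco2")

#: Interaction modes of the combined-stressor response relative to the
#: additive null (sum of single-stressor relative effects).
INTERACTION_MODES: tuple[str, ...] = ("synergistic", "additive", "antagonistic")


class DesignError(ValueError):
    """Invalid experimental design or trait specification."""


def _sign_or_decline(x: float) -> float:
    """Sign of ``x``; a zero additive null defaults to the decline (−) side."""
    if x > 0:
        return 1.0
    return -1.0


@dataclass(frozen=True)
class TraitSpec:
    """Ground-truth specification of one simulated trait.

    Parameters
    ----------
    name
        Trait label (e.g. ``"buoyant_weight"``).
    control_mean
        Mean trait value in the control treatment, in trait units.
    treatment_deltas
        Relative single-stressor effects, keys among ``("high_temp",
        "high_pco2")``; e.g. ``-0.3`` means a 30 % decline vs control.
        The combined-treatment effect is derived, never given directly.
    interaction_mode
        ``"additive"``: the combined effect equals the additive null
        (sum of the two single-stressor deltas) exactly.
        ``"synergistic"``: ``interaction_magnitude`` is added *beyond* the
        null (extra decline when the null is a decline).
        ``"antagonistic"``: the magnitude is subtracted (damped response).
    interaction_magnitude
        Non-negative size of the deviation from the additive null, on the
        relative-difference scale.
    v_genotype, v_tank, v_residual
        Variance components, in squared trait units.
    genetic_correlation
        ρ_G: correlation of a genotype's random effect between any two
        treatments (exchangeable).  Must keep the implied 4×4 genetic
        covariance matrix positive semi-definite (ρ_G ≥ −1/3 here).
    value_floor
        Optional lower bound (e.g. 0 for concentrations); simulated values
        below it are clipped and the clip count is reported.
    """

    name: str
    control_mean: float = 1.0
    treatment_deltas: Mapping[str, float] = field(default_factory=dict)
    interaction_mode: str = "additive"
    interaction_magnitude: float = 0.0
    v_genotype: float = 0.0
    v_tank: float = 0.0
    v_residual: float = 0.0
    genetic_correlation: float = 0.0
    value_floor: float | None = None

    # -- derived quantities -------------------------------------------------

    @property
    def additive_null(self) -> float:
        """Sum of the two single-stressor relative effects."""
        return float(
            self.treatment_deltas.get("high_temp", 0.0)
            + self.treatment_deltas.get("high_pco2", 0.0)
        )

    @property
    def combined_delta(self) -> float:
        """Relative effect of the combined treatment implied by the mode."""
        null = self.additive_null
        if self.interaction_mode == "additive":
            return null
        s = _sign_or_decline(null)
        if self.interaction_mode == "synergistic":
            return null + s * self.interaction_magnitude
        return null - s * self.interaction_magnitude

    def delta(self, treatment: str) -> float:
        """Relative effect of ``treatment`` vs control (0 for control)."""
        if treatment == "control":
            return 0.0
        if treatment == "combined":
            return self.combined_delta
        if treatment in STRESSORS:
            return float(self.treatment_deltas.get(treatment, 0.0))
        raise DesignError(f"unknown treatment {treatment!r}")

    def expected_mean(self, treatment: str) -> float:
        """Expected trait mean in ``treatment`` (no clipping)."""
        return self.control_mean * (1.0 + self.delta(treatment))

    def genetic_covariance(self, n_treatments: int = len(TREATMENTS)) -> np.ndarray:
        """Exchangeable cross-treatment covariance of the genotype effect."""
        rho = self.genetic_correlation
        cov = self.v_genotype * (
            (1.0 - rho) * np.eye(n_treatments) + rho * np.ones((n_treatments, n_treatments))
        )
        return cov

    def validate(self) -> None:
        for comp in ("v_genotype", "v_tank", "v_residual"):
            if getattr(self, comp) < 0:
                raise DesignError(f"{self.name}: negative variance {comp}")
        if abs(self.genetic_correlation) > 1:
            raise DesignError(f"{self.name}: |genetic_correlation| > 1")
        if self.interaction_mode not in INTERACTION_MODES:
            raise DesignError(
                f"{self.name}: interaction_mode must be one of {INTERACTION_MODES}"
            )
        if self.interaction_magnitude < 0:
            raise DesignError(f"{self.name}: interaction_magnitude must be >= 0")
        unknown = set(self.treatment_deltas) - set(STRESSORS)
        if unknown:
            raise DesignError(
                f"{self.name}: deltas may only be given for {STRESSORS}, got {sorted(unknown)}"
                " (the combined effect is derived from the interaction mode)"
            )
        cov = self.genetic_covariance()
        min_eig = float(np.linalg.eigvalsh(cov).min()) if self.v_genotype > 0 else 0.0
        if min_eig < -1e-10 * max(self.v_genotype, 1.0):
            raise DesignError(
                f"{self.name}: genetic covariance not positive semi-definite "
                f"(rho_G = {self.genetic_correlation}; an exchangeable correlation over "
                f"{len(TREATMENTS)} treatments requires rho_G >= -1/{len(TREATMENTS) - 1})"
            )


def ground_truth_h2(spec: TraitSpec) -> float:
    """Broad-sense heritability implied by a :class:`TraitSpec`.

    H² = V_genotype / (V_genotype + V_tank + V_residual) — the genotype share
    of the summed random-factor variance.
    """
    total = spec.v_genotype + spec.v_tank + spec.v_residual
    if total <= 0:
        raise DesignError(
            f"{spec.name}: heritability undefined when all variance components are zero"
        )
    return spec.v_genotype / total


def _trait(name, mean, d_temp, d_pco2, mode, mag, h2, rho, cv=0.10, tank_share=0.05):
    """Build a default TraitSpec from target H², tank share and total CV."""
    v_total = (cv * mean) ** 2
    return TraitSpec(
        name=name,
        control_mean=mean,
        treatment_deltas={"high_temp": d_temp, "high_pco2": d_pco2},
        interaction_mode=mode,
        interaction_magnitude=mag,
        v_genotype=h2 * v_total,
        v_tank=tank_share * v_total,
        v_residual=(1.0 - h2 - tank_share) * v_total,
        genetic_correlation=rho,
        value_floor=0.0,
    )


def default_traits() -> tuple[TraitSpec, ...]:
    """Twelve traits emulating the study's holobiont/host/symbiont panel.

    Effect directions, interaction modes, heritability levels (≈0.57 for
    buoyant weight and the three immune enzymes, ≤0.2 elsewhere) and the
    sign of ρ_G follow the qualitative pattern of the experiment this
    package models; exact magnitudes are documented in docs/methods.md.
    """
    return (
        #       name               mean  Δtemp  Δpco2  mode            mag   H²    ρ_G
        _trait("buoyant_weight", 0.80, -0.15, -0.10, "synergistic", 0.25, 0.57, 0.2),
        _trait("calc_light", 0.90, -0.55, -0.50, "antagonistic", 0.40, 0.20, 0.2),
        _trait("calc_dark", 0.45, -0.55, -0.50, "antagonistic", 0.40, 0.15, 0.2),
        _trait("pr_ratio", 1.20, -0.10, 0.08, "antagonistic", 0.01, 0.20, 0.7),
        _trait("symbiont_density", 1.50, -0.25, -0.02, "synergistic", 0.30, 0.15, 0.7),
        _trait("protein", 2.50, -0.20, -0.05, "synergistic", 0.15, 0.20, 0.7),
        _trait("ppo", 0.35, -0.10, -0.10, "antagonistic", 0.15, 0.60, 0.7),
        _trait("po", 0.30, -0.10, -0.10, "antagonistic", 0.15, 0.55, 0.7),
        _trait("pox", 0.40, -0.12, -0.08, "antagonistic", 0.15, 0.55, 0.7),
        _trait("yield", 0.65, -0.20, -0.15, "additive", 0.00, 0.10, 0.2),
        _trait("etrm", 12.0, -0.35, -0.30, "synergistic", 0.10, 0.15, 0.7),
        _trait("chl_total", 3.00, -0.35, -0.02, "synergistic", 0.33, 0.20, 0.7),
    )


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout plus per-trait ground truth for the generator.

    Defaults reproduce the study design: 12 genotypes × 4 treatments ×
    5 tank replicates, one clone-mate of each genotype per tank
    (240 fragments, 20 tanks).
    """

    n_genotypes: int = 12
    n_tanks_per_treatment: int = 5
    n_fragments_per_tank: int | None = None  # None -> n_genotypes
    traits: tuple[TraitSpec, ...] = field(default_factory=default_traits)
    dropout_rate: float = 0.0
    seed: int = 0

    @property
    def treatments(self) -> tuple[str, ...]:
        return TREATMENTS

    @property
    def n_treatments(self) -> int:
        return len(TREATMENTS)

    @property
    def n_tanks(self) -> int:
        return self.n_treatments * self.n_tanks_per_treatment

    @property
    def n_fragments(self) -> int:
        return self.n_genotypes * self.n_treatments * self.n_tanks_per_treatment

    def validate(self) -> None:
        if self.n_genotypes < 1 or self.n_tanks_per_treatment < 1:
            raise DesignError("n_genotypes and n_tanks_per_treatment must be >= 1")
        frags = self.n_fragments_per_tank
        if frags is not None and frags != self.n_genotypes:
            raise DesignError(
                "only the clonal-replicate layout with one fragment of each genotype "
                f"per tank is supported (n_fragments_per_tank must equal n_genotypes="
                f"{self.n_genotypes}, got {frags})"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise DesignError("dropout_rate must be in [0, 1)")
        if not self.traits:
            raise DesignError("at least one trait is required")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise DesignError("duplicate trait names")
        for t in self.traits:
            t.validate()

    # -- ground truth -------------------------------------------------------

    def ground_truth(self) -> dict:
        """Per-trait generative truth, for sidecar files and recovery tests."""
        out = {}
        for t in self.traits:
            out[t.name] = {
                "control_mean": t.control_mean,
                "delta_temp": t.delta("high_temp"),
                "delta_pco2": t.delta("high_pco2"),
                "delta_combined": t.delta("combined"),
                "additive_null": t.additive_null,
                "interaction_mode": t.interaction_mode,
                "interaction_magnitude": t.interaction_magnitude,
                "v_genotype": t.v_genotype,
                "v_tank": t.v_tank,
                "v_residual": t.v_residual,
                "genetic_correlation": t.genetic_correlation,
                "h2": ground_truth_h2(t)
                if (t.v_genotype + t.v_tank + t.v_residual) > 0
                else None,
            }
        return out


def _layout(design: DesignSpec) -> pd.DataFrame:
    """One row per fragment: genotype, treatment, tank indices and ids."""
    G, T, K = design.n_genotypes, design.n_treatments, design.n_tanks_per_treatment
    treat_idx = np.repeat(np.arange(T), K * G)
    tank_idx = np.repeat(np.arange(T * K), G)
    geno_idx = np.tile(np.arange(G), T * K)
    frame = pd.DataFrame(
        {
            "genotype_id": [f"G{g + 1:02d}" for g in geno_idx],
            "treatment": [TREATMENTS[t] for t in treat_idx],
            "tank_id": [f"tank_{k + 1:02d}" for k in tank_idx],
        }
    )
    frame["fragment_id"] = frame["tank_id"].str.replace("tank", "frag") + "_" + frame["genotype_id"]
    frame["_geno"] = geno_idx
    frame["_treat"] = treat_idx
    frame["_tank"] = tank_idx
    return frame


def generate(design: DesignSpec) -> pd.DataFrame:
    """Simulate a long-format trait table from a :class:`DesignSpec`.

    Returns
    -------
    pandas.DataFrame
        Columns ``fragment_id, genotype_id, treatment, tank_id, trait_name,
        value``; one row per fragment × trait.  ``df.attrs["clipped"]`` maps
        trait name → number of values clipped at its floor and
        ``df.attrs["dropped_fragments"]`` counts fragments removed by the
        optional dropout (dead-fragment emulation).

    Notes
    -----
    Generation is bit-reproducible for a fixed ``design.seed``: all random
    draws flow through one ``numpy.random.default_rng`` in a fixed order.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    frame = _layout(design)
    G, T = design.n_genotypes, design.n_treatments

    # dead-fragment emulation: drawn first so trait draws stay aligned
    alive = np.ones(len(frame), dtype=bool)
    if design.dropout_rate > 0:
        alive = rng.random(len(frame)) >= design.dropout_rate
    n_dropped = int((~alive).sum())

    pieces = []
    clipped: dict[str, int] = {}
    for spec in design.traits:
        cov = spec.genetic_covariance(T)
        if spec.v_genotype > 0:
            chol = np.linalg.cholesky(cov + 1e-12 * spec.v_genotype * np.eye(T))
            g_eff = rng.standard_normal((G, T)) @ chol.T  # (genotype, treatment)
        else:
            rng.standard_normal((G, T))  # keep the stream aligned across specs
            g_eff = np.zeros((G, T))
        t_eff = rng.normal(0.0, math.sqrt(spec.v_tank), design.n_tanks)
        e = rng.normal(0.0, math.sqrt(spec.v_residual), len(frame))

        deltas = np.array([spec.delta(t) for t in TREATMENTS])
        mean = spec.control_mean * (1.0 + deltas[frame["_treat"].to_numpy()])
        value = (
            mean
            + g_eff[frame["_geno"].to_numpy(), frame["_treat"].to_numpy()]
            + t_eff[frame["_tank"].to_numpy()]
            + e
        )
        n_clip = 0
        if spec.value_floor is not None:
            below = value < spec.value_floor
            n_clip = int(below.sum())
            value = np.where(below, spec.value_floor, value)
        clipped[spec.name] = n_clip
        if n_clip:
            logger.debug("trait %s: clipped %d values at floor %s", spec.name, n_clip, spec.value_floor)
        piece = frame.loc[alive, ["fragment_id", "genotype_id", "treatment", "tank_id"]].copy()
        piece["trait_name"] = spec.name
        piece["value"] = value[alive]
        pieces.append(piece)

    table = pd.concat(pieces, ignore_index=True)
    table.attrs["clipped"] = clipped
    table.attrs["dropped_fragments"] = n_dropped
    if n_dropped:
        logger.info("dropped %d fragments (dropout_rate=%s)", n_dropped, design.dropout_rate)
    return table


def design_to_dict(design: DesignSpec) -> dict:
    """Plain-dict form of a DesignSpec (for YAML/JSON round-trips)."""
    d = asdict(design)
    d["traits"] = [asdict(t) for t in design.traits]
    for t in d["traits"]:
        t["treatment_deltas"] = dict(t["treatment_deltas"])
    return d


def design_from_dict(d: Mapping) -> DesignSpec:
    d = dict(d)
    traits: Sequence[Mapping] = d.pop("traits", None) or ()
    specs = tuple(TraitSpec(**dict(t)) for t in traits) if traits else default_traits()
    return DesignSpec(traits=specs, **d)
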