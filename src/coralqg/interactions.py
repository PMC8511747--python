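"""Additive-null classification of combined-stressor responses.

For each trait the relative effect of every stress treatment vs control is
Δ_T = (mean_T − mean_control)/mean_control, means taken over fragments.  The
additive null for the combined treatment is Δ_temp + Δ_pco2; the combined
response is called *synergistic* when it exceeds the null in magnitude (a
greater departure from control than the two single stressors predict
additively), *antagonistic* when it falls short, and *additive* otherwise.

"Exceeds" is made operational with a stratified bootstrap: fragments are
resampled with replacement within each (treatment, tank) stratum, the
magnitude deviation |Δ_combined| − |Δ_temp + Δ_pco2| is recomputed per
replicate, and the three-way call uses whether the percentile CI excludes a
tolerance band around zero.  A point-estimate mode (no CI) reproduces a
plain reading of the deviation sign.  Traits whose two single-stressor
effects have opposing signs are flagged: magnitude comparison is ambiguous
there and the call should be read with care.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["InteractionReport", "InteractionClassifier", "relative_effects", "classify_interaction"]

_ATOL = 1e-9  # numeric guard so exact-zero deviations classify as additive


@dataclass
class InteractionReport:
    """Per-trait relative effects, additive null, deviation and call."""

    trait: str
    delta_temp: float
    delta_pco2: float
    delta_combined: float
    additive_null: float
    deviation: float  # delta_combined − additive_null (signed scale)
    magnitude_deviation: float  # |delta_combined| − |additive_null|
    label: str
    ci_deviation: tuple[float, float] | None
    n_boot: int
    seed: int | None
    opposing_signs: bool = False
    boot_deviations: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "delta_temp": self.delta_temp,
            "delta_pco2": self.delta_pco2,
            "delta_combined": self.delta_combined,
            "additive_null": self.additive_null,
            "deviation": self.deviation,
            "magnitude_deviation": self.magnitude_deviation,
            "label": self.label,
            "ci_deviation": list(self.ci_deviation) if self.ci_deviation else None,
            "n_boot": self.n_boot,
            "opposing_signs": self.opposing_signs,
        }


def _deltas_from_means(means: dict[str, float]) -> tuple[float, float, float]:
    mc = means["control"]
    return (
        (means["high_temp"] - mc) / mc,
        (means["high_pco2"] - mc) / mc,
        (means["combined"] - mc) / mc,
    )


def relative_effects(table: pd.DataFrame, trait: str) -> tuple[float, float, float]:
    """(Δ_temp, Δ_pco2, Δ_combined): treatment means relative to control."""
    sub = table.loc[table["trait_name"] == trait].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    means = sub.groupby("treatment", observed=True)["value"].mean().to_dict()
    missing = {"control", "high_temp", "high_pco2", "combined"} - set(means)
    if missing:
        raise ValueError(f"trait {trait!r}: missing treatments {sorted(missing)}")
    if means["control"] <= 0:
        raise ValueError(
            f"trait {trait!r}: control mean {means['control']:.4g} <= 0 — relative "
            "effects are undefined for a non-positive baseline"
        )
    return _deltas_from_means(means)


class InteractionClassifier(BaseEstimator):
    """Classify combined-stressor responses against the additive null.

    Parameters
    ----------
    tolerance : float
        Half-width of the "similar to the line" band on the magnitude
        deviation; within ±tolerance the call is additive.
    n_boot : int
        Bootstrap replicates (stratified by treatment × tank).  Below 100 a
        warning is issued.  ``n_boot=0`` switches to point-estimate mode.
    ci : float
        Central CI mass used for the three-way call (default 0.95).
    random_state : int or None

    Attributes
    ----------
    reports_ : list of :class:`InteractionReport` (one per fitted trait)
    """

    def __init__(self, tolerance: float = 0.0, n_boot: int = 2000, ci: float = 0.95,
                 random_state: int | None = None):
        self.tolerance = tolerance
        self.n_boot = n_boot
        self.ci = ci
        self.random_state = random_state

    def _classify_value(self, mag_dev: float, lo: float | None, hi: float | None) -> str:
        tol = self.tolerance + _ATOL
        if lo is None:  # point-estimate mode
            if mag_dev > tol:
                return "synergistic"
            if mag_dev < -tol:
                return "antagonistic"
            return "additive"
        if lo > tol:
            return "synergistic"
        if hi < -tol:
            return "antagonistic"
        return "additive"

    def _one_trait(self, table: pd.DataFrame, trait: str, seed) -> InteractionReport:
        if 0 < self.n_boot < 100:
            warnings.warn(f"n_boot={self.n_boot} < 100: bootstrap CI will be unstable", stacklevel=2)
        sub = table.loc[table["trait_name"] == trait].dropna(subset=["value"])
        d_temp, d_pco2, d_comb = relative_effects(table, trait)
        null = d_temp + d_pco2
        deviation = d_comb - null
        mag_dev = abs(d_comb) - abs(null)

        opposing = (d_temp * d_pco2 < 0) and min(abs(d_temp), abs(d_pco2)) > _ATOL
        if opposing:
            warnings.warn(
                f"trait {trait!r}: single-stressor effects have opposing signs "
                f"({d_temp:+.3g} vs {d_pco2:+.3g}); the magnitude-based call is ambiguous",
                stacklevel=2,
            )

        lo = hi = None
        boot = None
        if self.n_boot > 0:
            rng = np.random.default_rng(seed)
            strata = [
                vals.to_numpy()
                for _, vals in sub.groupby(["treatment", "tank_id"], observed=True)["value"]
            ]
            keys = [k for k, _ in sub.groupby(["treatment", "tank_id"], observed=True)["value"]]
            treat_of = np.array([k[0] for k in keys])
            boot = np.empty(self.n_boot)
            for b in range(self.n_boot):
                sums = {t: 0.0 for t in ("control", "high_temp", "high_pco2", "combined")}
                cnts = {t: 0 for t in sums}
                for t, vals in zip(treat_of, strata):
                    res = vals[rng.integers(0, vals.size, vals.size)]
                    sums[t] += res.sum()
                    cnts[t] += res.size
                means = {t: sums[t] / cnts[t] for t in sums}
                if means["control"] <= 0:
                    boot[b] = np.nan
                    continue
                bt, bp, bc = _deltas_from_means(means)
                boot[b] = abs(bc) - abs(bt + bp)
            boot = boot[np.isfinite(boot)]
            alpha = 1.0 - self.ci
            lo = float(np.quantile(boot, alpha / 2))
            hi = float(np.quantile(boot, 1 - alpha / 2))

        label = self._classify_value(mag_dev, lo, hi)
        return InteractionReport(
            trait=trait,
            delta_temp=d_temp,
            delta_pco2=d_pco2,
            delta_combined=d_comb,
            additive_null=null,
            deviation=deviation,
            magnitude_deviation=mag_dev,
            label=label,
            ci_deviation=(lo, hi) if lo is not None else None,
            n_boot=self.n_boot,
            seed=seed,
            opposing_signs=opposing,
            boot_deviations=boot,
        )

    def fit(self, table: pd.DataFrame, trait: str | None = None):
        """Classify one trait, or every trait in the table when ``trait=None``."""
        traits = [trait] if trait is not None else sorted(table["trait_name"].unique())
        seeds = np.random.SeedSequence(self.random_state).spawn(len(traits))
        self.reports_ = [
            self._one_trait(table, t, int(s.generate_state(1)[0] % (2**31)))
            for t, s in zip(traits, seeds)
        ]
        self.report_ = self.reports_[0] if trait is not None else None
        return self

    def summary(self) -> pd.DataFrame:
        if not hasattr(self, "reports_"):
            raise RuntimeError("call fit first")
        return pd.DataFrame([r.to_dict() for r in self.reports_])


def classify_interaction(
    table: pd.DataFrame,
    trait: str,
    tolerance: float = 0.0,
    n_boot: int = 2000,
    seed: int | None = None,
) -> InteractionReport:
    """Functional wrapper: classify a single trait's stressor interaction."""
    est = InteractionClassifier(tolerance=tolerance, n_boot=n_boot, random_state=seed)
    est.fit(table, trait)
    return est.report_
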