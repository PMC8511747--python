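"""Bayesian broad-sense heritability via Gibbs-sampled variance partitioning.

The model for one trait is a Gaussian mixed model with fixed effects for
temperature, pCO2 and their interaction (2×2 factorial coding of the four
treatments) and scalar random intercepts for genotype and tank:

    y = Xβ + Z_g u_g + Z_t u_t + e,
    u_g ~ N(0, σ²_g I),  u_t ~ N(0, σ²_t I),  e ~ N(0, σ²_e I).

All full conditionals are conjugate (normal for β, u_g, u_t; inverse-gamma
for the three variances under IG(shape, scale) priors and an improper flat
prior on β), so the chain is a plain Gibbs sampler.  Broad-sense
heritability is computed draw-wise,

    H² = σ²_g / (σ²_g + σ²_t + σ²_e),

and then summarised (mean and 2.5/50/97.5 % quantiles) — a posterior of the
genotype share of the summed random-factor variance, not a ratio of
posterior summaries.

Defaults run a single chain of 50 000 iterations with a 10 000-iteration
burn-in sampled every 20 iterations, retaining exactly 2 000 draws per
parameter.  ``scope="per_treatment"`` refits the model inside each
treatment subset (fixed effects reduce to an intercept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["ChainConfig", "VarianceDecomposition", "GibbsHeritability", "fit_h2", "h2_report"]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain settings (defaults follow the analysis this package models)."""

    n_iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 20
    seed: int | None = None
    prior_shape: float = 0.001
    prior_scale: float = 0.001

    def __post_init__(self):
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_shape <= 0 or self.prior_scale <= 0:
            raise ValueError("prior shape/scale must be > 0")

    @property
    def n_retained(self) -> int:
        """Retained draws: the chain is sampled every ``thin`` iterations
        after the burn-in, giving floor((n_iterations − burn_in)/thin)."""
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class VarianceDecomposition:
    """Posterior draws and summaries of (V_genotype, V_tank, V_residual, H²)."""

    draws: pd.DataFrame = field(repr=False)
    summary: dict
    diagnostics: dict

    def to_dict(self) -> dict:
        return {"summary": self.summary, "diagnostics": self.diagnostics}


def _split_diagnostics(x: np.ndarray) -> dict:
    """Effective sample size and split-chain R-hat of a single chain."""
    import arviz as az

    n = x.size - (x.size % 2)
    halves = x[:n].reshape(2, n // 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(halves))
        rhat = float(az.rhat(halves))
    return {"ess": ess, "rhat_split": rhat}


def _gibbs_chain(y, X, g_idx, n_g, t_idx, n_t, cfg: ChainConfig, rng, fix_variances=None):
    """Run one Gibbs chain; returns a dict of retained-draw arrays."""
    n, p = X.shape
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate fixed-effect design (non-invertible X'X)") from exc
    chol_XtX_inv = np.linalg.cholesky(XtX_inv)
    counts_g = np.bincount(g_idx, minlength=n_g).astype(float)
    counts_t = np.bincount(t_idx, minlength=n_t).astype(float)
    if (counts_g == 0).any() or (counts_t == 0).any():
        raise ValueError("degenerate design: empty genotype or tank level")

    beta = XtX_inv @ (X.T @ y)
    resid0 = y - X @ beta
    v0 = max(float(np.var(resid0)), 1e-12)
    if fix_variances is None:
        v_g = v_t = v_e = v0 / 3.0
        fixed = False
    else:
        v_g, v_t, v_e = (max(float(v), 1e-12) for v in fix_variances)
        fixed = True
    u_g = np.zeros(n_g)
    u_t = np.zeros(n_t)
    a, b = cfg.prior_shape, cfg.prior_scale

    n_keep = cfg.n_retained
    out = {k: np.empty(n_keep) for k in ("V_genotype", "V_tank", "V_residual")}
    out_beta = np.empty((n_keep, p))
    kept = 0
    for it in range(cfg.n_iterations):
        # β | rest  ~  N((X'X)^-1 X'(y − Zg u_g − Zt u_t), σ²_e (X'X)^-1)
        r = y - u_g[g_idx] - u_t[t_idx]
        beta = XtX_inv @ (X.T @ r) + np.sqrt(v_e) * (chol_XtX_inv @ rng.standard_normal(p))
        fitted = X @ beta
        # u_g | rest: independent normals given the grouped design
        r = y - fitted - u_t[t_idx]
        s = np.bincount(g_idx, weights=r, minlength=n_g)
        var = 1.0 / (counts_g / v_e + 1.0 / v_g)
        u_g = var * s / v_e + np.sqrt(var) * rng.standard_normal(n_g)
        # u_t | rest
        r = y - fitted - u_g[g_idx]
        s = np.bincount(t_idx, weights=r, minlength=n_t)
        var = 1.0 / (counts_t / v_e + 1.0 / v_t)
        u_t = var * s / v_e + np.sqrt(var) * rng.standard_normal(n_t)
        if not fixed:
            # variances | rest: inverse-gamma
            v_g = (b + 0.5 * float(u_g @ u_g)) / rng.gamma(a + 0.5 * n_g)
            v_t = (b + 0.5 * float(u_t @ u_t)) / rng.gamma(a + 0.5 * n_t)
            resid = r - u_t[t_idx]
            v_e = (b + 0.5 * float(resid @ resid)) / rng.gamma(a + 0.5 * n)
        if it >= cfg.burn_in and (it - cfg.burn_in + 1) % cfg.thin == 0:
            out["V_genotype"][kept] = v_g
            out["V_tank"][kept] = v_t
            out["V_residual"][kept] = v_e
            out_beta[kept] = beta
            kept += 1
    assert kept == n_keep
    out["beta"] = out_beta
    return out


def _design_matrix(treatment: np.ndarray) -> np.ndarray:
    """Intercept + temperature + pCO2 + interaction indicators (2×2 coding)."""
    temp = np.isin(treatment, ("high_temp", "combined")).astype(float)
    pco2 = np.isin(treatment, ("high_pco2", "combined")).astype(float)
    return np.column_stack([np.ones_like(temp), temp, pco2, temp * pco2])


def _summarise(draws: pd.DataFrame) -> tuple[dict, dict]:
    h2 = draws["H2"].to_numpy()
    summary = {
        "h2_mean": float(h2.mean()),
        "h2_q2.5": float(np.quantile(h2, 0.025)),
        "h2_median": float(np.quantile(h2, 0.5)),
        "h2_q97.5": float(np.quantile(h2, 0.975)),
        "v_genotype_mean": float(draws["V_genotype"].mean()),
        "v_tank_mean": float(draws["V_tank"].mean()),
        "v_residual_mean": float(draws["V_residual"].mean()),
        "n_draws": int(len(draws)),
    }
    diagnostics = _split_diagnostics(h2)
    if diagnostics["ess"] < 200 or diagnostics["rhat_split"] > 1.05:
        warnings.warn(
            f"H2 chain diagnostics weak (ess={diagnostics['ess']:.0f}, "
            f"split-Rhat={diagnostics['rhat_split']:.3f}); consider a longer chain",
            stacklevel=3,
        )
    return summary, diagnostics


class GibbsHeritability(BaseEstimator):
    """Gibbs sampler for the genotype/tank variance decomposition of a trait.

    Parameters mirror :class:`ChainConfig` plus ``scope``:

    - ``scope="all_treatments"``: one model on the full table with the 2×2
      temperature × pCO2 fixed effects.
    - ``scope="per_treatment"``: refit within each treatment subset
      (intercept-only fixed part); ``decompositions_`` then maps treatment
      label → :class:`VarianceDecomposition`.

    ``fix_variances`` pins (V_genotype, V_tank, V_residual) and samples only
    the fixed effects — the conjugate special case with a closed-form normal
    posterior, kept for validation.
    """

    def __init__(
        self,
        n_iterations: int = 50_000,
        burn_in: int = 10_000,
        thin: int = 20,
        prior_shape: float = 0.001,
        prior_scale: float = 0.001,
        scope: str = "all_treatments",
        random_state: int | None = None,
        fix_variances: tuple[float, float, float] | None = None,
    ):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.prior_shape = prior_shape
        self.prior_scale = prior_scale
        self.scope = scope
        self.random_state = random_state
        self.fix_variances = fix_variances

    def _config(self) -> ChainConfig:
        return ChainConfig(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            prior_shape=self.prior_shape,
            prior_scale=self.prior_scale,
        )

    def _run(self, sub: pd.DataFrame, X: np.ndarray, cfg: ChainConfig, rng) -> VarianceDecomposition:
        genotypes, g_idx = np.unique(sub["genotype_id"].to_numpy(), return_inverse=True)
        tanks, t_idx = np.unique(sub["tank_id"].to_numpy(), return_inverse=True)
        y = sub["value"].to_numpy(dtype=float)
        raw = _gibbs_chain(
            y, X, g_idx, genotypes.size, t_idx, tanks.size, cfg, rng, self.fix_variances
        )
        draws = pd.DataFrame({k: raw[k] for k in ("V_genotype", "V_tank", "V_residual")})
        draws["H2"] = draws["V_genotype"] / (
            draws["V_genotype"] + draws["V_tank"] + draws["V_residual"]
        )
        summary, diagnostics = _summarise(draws)
        decomp = VarianceDecomposition(draws=draws, summary=summary, diagnostics=diagnostics)
        decomp.beta_draws = raw["beta"]
        return decomp

    def fit(self, table: pd.DataFrame, trait: str):
        if self.scope not in ("all_treatments", "per_treatment"):
            raise ValueError("scope must be 'all_treatments' or 'per_treatment'")
        cfg = self._config()
        sub = table.loc[table["trait_name"] == trait].dropna(subset=["value"])
        if sub.empty:
            raise ValueError(f"trait {trait!r} not present in table")
        rng = np.random.default_rng(cfg.seed)
        if self.scope == "all_treatments":
            X = _design_matrix(sub["treatment"].to_numpy())
            self.decomposition_ = self._run(sub, X, cfg, rng)
            self.decompositions_ = {"all_treatments": self.decomposition_}
        else:
            self.decompositions_ = {}
            for treatment in sorted(sub["treatment"].unique()):
                part = sub.loc[sub["treatment"] == treatment]
                X = np.ones((len(part), 1))
                self.decompositions_[treatment] = self._run(part, X, cfg, rng)
            self.decomposition_ = None
        self.trait_ = trait
        return self


def fit_h2(
    table: pd.DataFrame,
    trait: str,
    config: ChainConfig | None = None,
    scope: str = "all_treatments",
):
    """Fit the heritability model for one trait.

    Returns a :class:`VarianceDecomposition` (``scope="all_treatments"``) or
    a dict treatment → decomposition (``scope="per_treatment"``).
    """
    cfg = config or ChainConfig()
    est = GibbsHeritability(
        n_iterations=cfg.n_iterations,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
        prior_shape=cfg.prior_shape,
        prior_scale=cfg.prior_scale,
        scope=scope,
        random_state=cfg.seed,
    ).fit(table, trait)
    if scope == "all_treatments":
        return est.decomposition_
    return est.decompositions_


def h2_report(decomps: Mapping[str, VarianceDecomposition]) -> pd.DataFrame:
    """Per-trait H² summary table (mean with 95 % interval), sorted by mean."""
    if not decomps:
        raise ValueError("no fitted traits")
    rows = []
    for trait, dec in decomps.items():
        s = dec.summary
        rows.append(
            {
                "trait": trait,
                "h2_mean": s["h2_mean"],
                "h2_q2.5": s["h2_q2.5"],
                "h2_q97.5": s["h2_q97.5"],
                "ess": dec.diagnostics["ess"],
            }
        )
    return pd.DataFrame(rows).sort_values("h2_mean", ascending=False, ignore_index=True)
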