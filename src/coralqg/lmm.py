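"""Per-trait Gaussian linear mixed model with a tank random intercept.

Model: ``value ~ treatment * genotype + (1 | tank)``, fitted by REML.  The
variance structure has a single ratio λ = V_tank / V_residual, so the REML
criterion is profiled over λ and maximised in one dimension; because tanks
partition the observations, all matrix algebra uses per-tank Woodbury
identities and stays O(p²·n_tanks) per evaluation.

F-tests use Type-III Wald statistics under sum-to-zero coding (on the
balanced design these equal the classical ANOVA F ratios) with containment
denominator degrees of freedom by default — the treatment effect is tested
against tank-level replication (df = n_tanks − n_treatments), genotype and
interaction against fragment-level residual df.  A Satterthwaite
approximation is available as an alternative.  Post hoc Tukey HSD p-values
come from the studentized range distribution at the treatment test's
denominator df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = ["LinearMixedModel", "fit_lmm", "LmmError"]


class LmmError(ValueError):
    """Singular design or degenerate variance structure."""


def _sum_coding(levels: int) -> np.ndarray:
    """Rows: level -> sum-to-zero contrast codes (levels × (levels−1))."""
    s = np.vstack([np.eye(levels - 1), -np.ones(levels - 1)])
    return s


@dataclass
class _Precomp:
    """Sufficient statistics for the profiled REML criterion."""

    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    Sx: np.ndarray  # per-tank sums of X rows (n_tanks × p)
    Sy: np.ndarray  # per-tank sums of y
    m: np.ndarray  # tank sizes
    n: int
    p: int


def _reml_pieces(lam: float, pre: _Precomp):
    w = lam / (1.0 + lam * pre.m)
    XtViX = pre.XtX - pre.Sx.T @ (w[:, None] * pre.Sx)
    XtViy = pre.Xty - pre.Sx.T @ (w * pre.Sy)
    ytViy = pre.yty - float(np.sum(w * pre.Sy**2))
    try:
        chol = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded earlier
        raise LmmError("singular fixed-effect design") from exc
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - float(beta @ XtViy)
    logdet_v = float(np.log1p(lam * pre.m).sum())
    logdet_xvx = 2.0 * float(np.log(np.diag(chol)).sum())
    return beta, XtViX, rss, logdet_v, logdet_xvx


def _profiled_reml_ll(lam: float, pre: _Precomp) -> float:
    _, _, rss, logdet_v, logdet_xvx = _reml_pieces(lam, pre)
    nmp = pre.n - pre.p
    sigma2 = rss / nmp
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (nmp * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_v + logdet_xvx)


def _reml_ll_2d(v_tank: float, v_resid: float, pre: _Precomp) -> float:
    """Unprofiled REML log-likelihood at (V_tank, V_residual)."""
    lam = v_tank / v_resid
    _, _, rss, logdet_v, logdet_xvx = _reml_pieces(lam, pre)
    nmp = pre.n - pre.p
    return -0.5 * (
        nmp * np.log(2 * np.pi)
        + nmp * np.log(v_resid)
        + logdet_v
        + logdet_xvx
        + rss / v_resid
    )


class LinearMixedModel(BaseEstimator):
    """REML mixed model for one trait: fixed treatment × genotype, random tank.

    Parameters
    ----------
    ddf_method : {"containment", "satterthwaite"}
        Denominator-degrees-of-freedom method for F-tests and post hoc
        comparisons.  Containment reproduces the tank-level df for the
        treatment test (16 on the default 20-tank design).
    ratio_tol : float
        Convergence tolerance on the variance ratio λ = V_tank/V_residual.

    Attributes (after :meth:`fit`)
    ------------------------------
    v_tank_, v_residual_ : float
        REML variance components (V_tank may sit at the 0 boundary).
    coef_, coef_names_, cov_coef_ :
        Fixed effects (sum-to-zero coding) and their covariance.
    reml_loglik_ : float
    anova_ : DataFrame with columns term, F, df_num, df_den, p.
    """

    def __init__(self, ddf_method: str = "containment", ratio_tol: float = 1e-8):
        self.ddf_method = ddf_method
        self.ratio_tol = ratio_tol

    # ------------------------------------------------------------------ fit

    def fit(self, table: pd.DataFrame, trait: str):
        sub = table.loc[table["trait_name"] == trait]
        if sub.empty:
            raise LmmError(f"trait {trait!r} not present in table")
        sub = sub.dropna(subset=["value"])
        self.n_dropped_ = int((table["trait_name"] == trait).sum() - len(sub))

        treatments = np.array(sorted(sub["treatment"].unique()))
        genotypes = np.array(sorted(sub["genotype_id"].unique()))
        tanks = np.array(sorted(sub["tank_id"].unique()))
        if treatments.size < 2:
            raise LmmError("need at least 2 treatments")
        counts = sub.groupby(["genotype_id", "treatment"], observed=True).size()
        full = pd.MultiIndex.from_product([genotypes, treatments], names=["genotype_id", "treatment"])
        missing = full.difference(counts.index)
        if len(missing):
            g, t = missing[0]
            raise LmmError(f"empty design cell: genotype {g!r} has no observations in treatment {t!r}")
        tanks_per_treatment = sub.groupby("treatment", observed=True)["tank_id"].nunique()
        if (tanks_per_treatment < 2).any():
            raise LmmError("need at least 2 tanks per treatment")

        trt_idx = np.searchsorted(treatments, sub["treatment"].to_numpy())
        gen_idx = np.searchsorted(genotypes, sub["genotype_id"].to_numpy())
        tank_idx = np.searchsorted(tanks, sub["tank_id"].to_numpy())
        y = sub["value"].to_numpy(dtype=float)
        n = y.size

        s_trt = _sum_coding(treatments.size)
        s_gen = _sum_coding(genotypes.size)
        Xt = s_trt[trt_idx]
        Xg = s_gen[gen_idx]
        Xi = (Xt[:, :, None] * Xg[:, None, :]).reshape(n, -1)
        X = np.hstack([np.ones((n, 1)), Xt, Xg, Xi])
        p = X.shape[1]
        qt, qg = treatments.size - 1, genotypes.size - 1
        self.term_slices_ = {
            "treatment": slice(1, 1 + qt),
            "genotype": slice(1 + qt, 1 + qt + qg),
            "treatment:genotype": slice(1 + qt + qg, p),
        }

        n_tanks = tanks.size
        Sx = np.zeros((n_tanks, p))
        np.add.at(Sx, tank_idx, X)
        Sy = np.bincount(tank_idx, weights=y, minlength=n_tanks)
        m = np.bincount(tank_idx, minlength=n_tanks).astype(float)
        pre = _Precomp(XtX=X.T @ X, Xty=X.T @ y, yty=float(y @ y), Sx=Sx, Sy=Sy, m=m, n=n, p=p)

        # profile the REML criterion over log lambda, then check the boundary
        res = optimize.minimize_scalar(
            lambda u: -_profiled_reml_ll(np.exp(u), pre),
            bounds=(-25.0, 12.0),
            method="bounded",
            options={"xatol": 1e-11},
        )
        lam = float(np.exp(res.x))
        ll = -float(res.fun)
        ll0 = _profiled_reml_ll(0.0, pre)
        if ll0 >= ll - 1e-9 or lam < self.ratio_tol:
            lam, ll = 0.0, ll0

        beta, XtViX, rss, *_ = _reml_pieces(lam, pre)
        sigma2 = rss / (n - p)
        self.lambda_ = lam
        self.v_residual_ = float(sigma2)
        self.v_tank_ = float(lam * sigma2)
        self.reml_loglik_ = float(ll)
        self.coef_ = beta
        self.cov_coef_ = sigma2 * np.linalg.inv(XtViX)
        self.coef_names_ = (
            ["intercept"]
            + [f"treatment[{t}]" for t in treatments[:-1]]
            + [f"genotype[{g}]" for g in genotypes[:-1]]
            + [f"treatment[{t}]:genotype[{g}]" for t in treatments[:-1] for g in genotypes[:-1]]
        )
        self.treatments_ = treatments
        self.genotypes_ = genotypes
        self.n_tanks_ = n_tanks
        self.n_obs_ = n
        self._pre = pre
        self._s_trt = s_trt
        self.resid_df_ = n - p - (n_tanks - treatments.size)
        self.anova_ = self.anova()
        return self

    # -------------------------------------------------------------- helpers

    def _require_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("call fit first")

    def _containment_ddf(self, term: str) -> float:
        if term == "treatment":
            return float(self.n_tanks_ - self.treatments_.size)
        return float(self.resid_df_)

    def _theta_cov(self) -> np.ndarray:
        """Asymptotic covariance of (V_tank, V_residual) from the REML Hessian."""
        theta = np.array([max(self.v_tank_, 1e-10 * self.v_residual_), self.v_residual_])
        h = np.zeros((2, 2))
        step = np.maximum(1e-5 * theta, 1e-12)

        def f(t):
            return _reml_ll_2d(max(t[0], 1e-12), max(t[1], 1e-12), self._pre)

        for i in range(2):
            for j in range(2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = step[i]
                ej[j] = step[j]
                h[i, j] = (
                    f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * step[i] * step[j])
        return np.linalg.inv(-h)

    def _satterthwaite_1df(self, ell: np.ndarray, theta_cov: np.ndarray) -> float:
        """Satterthwaite df for a single contrast l'β."""

        def var_contrast(v_tank, v_resid):
            lam = max(v_tank, 0.0) / v_resid
            w = lam / (1.0 + lam * self._pre.m)
            XtViX = self._pre.XtX - self._pre.Sx.T @ (w[:, None] * self._pre.Sx)
            c = np.linalg.solve(XtViX, ell)
            return v_resid * float(ell @ c)

        theta = np.array([self.v_tank_, self.v_residual_])
        step = np.maximum(1e-5 * self.v_residual_, 1e-12) * np.ones(2)
        grad = np.zeros(2)
        for i in range(2):
            e = np.zeros(2)
            e[i] = step[i]
            if theta[i] > step[i]:  # interior: central difference
                grad[i] = (var_contrast(*(theta + e)) - var_contrast(*(theta - e))) / (2 * step[i])
            else:  # at or near the 0 boundary: forward difference
                grad[i] = (var_contrast(*(theta + e)) - var_contrast(*theta)) / step[i]
        denom = float(grad @ theta_cov @ grad)
        v = var_contrast(*theta)
        if denom <= 0:
            return float(self.resid_df_)
        return 2.0 * v**2 / denom

    def _satterthwaite_ddf(self, term: str) -> float:
        """Multi-df Satterthwaite: per-eigencontrast 1-df values combined."""
        sl = self.term_slices_[term]
        idx = np.arange(sl.start, sl.stop)
        C = self.cov_coef_[np.ix_(idx, idx)]
        vals, vecs = np.linalg.eigh(C)
        theta_cov = self._theta_cov()
        q = idx.size
        nus = []
        for k in range(q):
            ell = np.zeros(self._pre.p)
            ell[idx] = vecs[:, k]
            nus.append(self._satterthwaite_1df(ell, theta_cov))
        nus = np.array(nus)
        good = nus > 2.0
        if not good.all():
            return float(self.resid_df_)
        e_sum = float(np.sum(nus / (nus - 2.0)))
        if e_sum <= q:
            return float(self.resid_df_)
        return 2.0 * e_sum / (e_sum - q)

    # -------------------------------------------------------------- outputs

    def anova(self, ddf_method: str | None = None) -> pd.DataFrame:
        """Type-III F table for treatment, genotype and their interaction."""
        self._require_fitted()
        if self.v_residual_ <= 0:
            raise LmmError("zero residual variance: F-tests undefined")
        method = ddf_method or self.ddf_method
        if method not in ("containment", "satterthwaite"):
            raise ValueError("ddf_method must be 'containment' or 'satterthwaite'")
        rows = []
        for term, sl in self.term_slices_.items():
            idx = np.arange(sl.start, sl.stop)
            b = self.coef_[idx]
            C = self.cov_coef_[np.ix_(idx, idx)]
            q = idx.size
            f = float(b @ np.linalg.solve(C, b)) / q
            ddf = self._containment_ddf(term) if method == "containment" else self._satterthwaite_ddf(term)
            rows.append(
                {
                    "term": term,
                    "F": f,
                    "df_num": q,
                    "df_den": ddf,
                    "p": float(stats.f.sf(f, q, ddf)),
                }
            )
        return pd.DataFrame(rows)

    def tukey(self, factor: str = "treatment", ddf_method: str | None = None) -> pd.DataFrame:
        """Tukey HSD comparisons among treatment least-squares means.

        Adjusted p-values come from the studentized range distribution with
        k = number of treatments and the treatment test's denominator df.
        """
        self._require_fitted()
        if factor != "treatment":
            raise ValueError("post hoc comparisons are defined for the treatment factor")
        if self.treatments_.size < 2:
            raise LmmError("need at least 2 treatment levels")
        method = ddf_method or self.ddf_method
        k = self.treatments_.size
        sl = self.term_slices_["treatment"]
        rows = []
        theta_cov = None
        for i in range(k):
            for j in range(i + 1, k):
                ell = np.zeros(self._pre.p)
                ell[sl] = self._s_trt[i] - self._s_trt[j]
                est = float(ell @ self.coef_)
                se = float(np.sqrt(ell @ self.cov_coef_ @ ell))
                if method == "containment":
                    ddf = self._containment_ddf("treatment")
                else:
                    if theta_cov is None:
                        theta_cov = self._theta_cov()
                    ddf = self._satterthwaite_1df(ell, theta_cov)
                q_obs = abs(est) / se * np.sqrt(2.0)
                p_adj = float(stats.studentized_range.sf(q_obs, k, ddf))
                t_obs = abs(est) / se
                p_raw = 2.0 * float(stats.t.sf(t_obs, ddf))
                rows.append(
                    {
                        "level_a": self.treatments_[i],
                        "level_b": self.treatments_[j],
                        "estimate": est,
                        "se": se,
                        "df": ddf,
                        "p_unadjusted": min(1.0, p_raw),
                        "p_adjusted": min(1.0, p_adj),
                    }
                )
        return pd.DataFrame(rows)

    def lsmeans(self) -> pd.DataFrame:
        """Treatment least-squares means (genotype-averaged predictions)."""
        self._require_fitted()
        sl = self.term_slices_["treatment"]
        rows = []
        for i, t in enumerate(self.treatments_):
            ell = np.zeros(self._pre.p)
            ell[0] = 1.0
            ell[sl] = self._s_trt[i]
            rows.append(
                {
                    "treatment": t,
                    "lsmean": float(ell @ self.coef_),
                    "se": float(np.sqrt(ell @ self.cov_coef_ @ ell)),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        self._require_fitted()
        return {
            "v_tank": self.v_tank_,
            "v_residual": self.v_residual_,
            "reml_loglik": self.reml_loglik_,
            "n_obs": self.n_obs_,
            "n_dropped": self.n_dropped_,
            "fixed_effects": dict(zip(self.coef_names_, map(float, self.coef_))),
            "anova": self.anova_.to_dict(orient="records"),
        }


def fit_lmm(table: pd.DataFrame, trait: str, ddf_method: str = "containment") -> LinearMixedModel:
    """Fit the tank-random mixed model for one trait and return the fit."""
    return LinearMixedModel(ddf_method=ddf_method).fit(table, trait)
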