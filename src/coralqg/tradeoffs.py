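"""Genotype-mean correlation screens for tradeoffs vs broad-spectrum resistance.

Two complementary analyses on the genotype × treatment × trait mean cube:

- ``treatment_by_treatment``: for each trait, the Pearson correlation of
  genotype means between every pair of treatments.  A significantly
  negative correlation marks a *tradeoff* (genets that do well under one
  condition do poorly under another); significantly positive marks
  *broad-spectrum* resistance.  The three treatment pairs most relevant for
  future-ocean screening (high_temp–high_pco2, high_temp–combined,
  high_pco2–combined) are tagged as key comparisons.
- ``trait_by_trait``: within each treatment, correlations of genotype means
  between every pair of traits.

p-values use the exact t transform t = r·sqrt((n−2)/(1−r²)) with n−2 df,
two-sided, unadjusted by default (an optional Holm adjustment is reported
alongside, never silently substituted).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationReport", "GenotypeCorrelations", "genotype_means", "correlation_matrix"]

KEY_COMPARISONS = (
    ("high_temp", "high_pco2"),
    ("high_temp", "combined"),
    ("high_pco2", "combined"),
)


@dataclass
class CorrelationReport:
    """Pairwise correlation entries with significance and tradeoff calls."""

    mode: str
    alpha: float
    entries: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "alpha": self.alpha,
            "entries": self.entries.to_dict(orient="records"),
        }


def genotype_means(table: pd.DataFrame) -> pd.DataFrame:
    """Genotype × (trait, treatment) matrix of fragment-mean trait values.

    Raises if any genotype has no fragments in some treatment for a trait
    (the correlation screen needs a complete cube).
    """
    cells = (
        table.dropna(subset=["value"])
        .groupby(["trait_name", "genotype_id", "treatment"], observed=True)["value"]
        .mean()
    )
    wide = cells.unstack(["trait_name", "treatment"])  # genotype × (trait, treatment)
    if wide.isna().any().any():
        col = wide.columns[wide.isna().any()][0]
        geno = wide.index[wide[col].isna()][0]
        raise ValueError(
            f"empty genotype × treatment cell: genotype {geno!r} has no observations "
            f"for trait {col[0]!r} in treatment {col[1]!r}"
        )
    wide.columns.names = ["trait_name", "treatment"]
    return wide


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its exact-t two-sided p at n−2 df."""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _entry(context_name, context, a, b, x, y, alpha, method) -> dict:
    n = x.size
    degenerate = np.std(x) == 0 or np.std(y) == 0
    if degenerate:
        r, p = np.nan, np.nan
    elif method == "pearson":
        r, p = _pearson(x, y)
    else:
        rho, p = stats.spearmanr(x, y)
        r, p = float(rho), float(p)
    significant = bool(p < alpha) if np.isfinite(p) else False
    if degenerate:
        call = "undefined"
    elif significant and r < 0:
        call = "tradeoff"
    elif significant and r > 0:
        call = "broad_spectrum"
    else:
        call = "none"
    return {
        context_name: context,
        "unit_a": a,
        "unit_b": b,
        "r": r,
        "n": int(n),
        "p": p,
        "significant": significant,
        "call": call,
    }


class GenotypeCorrelations(BaseEstimator):
    """Correlation screen over genotype means.

    Parameters
    ----------
    mode : {"treatment_by_treatment", "trait_by_trait", "both"}
    alpha : float
        Significance level for the (unadjusted) per-pair test.
    method : {"pearson", "spearman"}
        Spearman is offered as a robustness option.
    adjust : None or "holm"
        Optional Holm step-down adjustment, reported in a separate
        ``p_holm``/``significant_holm`` column pair per family (a family =
        one trait's treatment pairs, or one treatment's trait pairs).

    Attributes
    ----------
    entries_ : DataFrame of pairwise results (see :func:`correlation_matrix`)
    reports_ : dict mode → :class:`CorrelationReport`
    """

    def __init__(self, mode: str = "treatment_by_treatment", alpha: float = 0.05,
                 method: str = "pearson", adjust: str | None = None):
        self.mode = mode
        self.alpha = alpha
        self.method = method
        self.adjust = adjust

    def _treatment_pairs(self, means: pd.DataFrame) -> pd.DataFrame:
        rows = []
        traits = means.columns.get_level_values("trait_name").unique()
        for trait in traits:
            block = means[trait]
            if len(block.index) < 3:
                raise ValueError("need at least 3 genotypes for a correlation")
            fam = []
            for a, b in itertools.combinations(block.columns, 2):
                e = _entry("trait", trait, a, b, block[a].to_numpy(), block[b].to_numpy(),
                           self.alpha, self.method)
                e["key_comparison"] = (a, b) in KEY_COMPARISONS or (b, a) in KEY_COMPARISONS
                fam.append(e)
            rows.extend(self._maybe_holm(fam))
        return pd.DataFrame(rows)

    def _trait_pairs(self, means: pd.DataFrame) -> pd.DataFrame:
        rows = []
        treatments = means.columns.get_level_values("treatment").unique()
        swapped = means.swaplevel(axis=1)
        for treatment in treatments:
            block = swapped[treatment]
            if len(block.index) < 3:
                raise ValueError("need at least 3 genotypes for a correlation")
            fam = []
            for a, b in itertools.combinations(block.columns, 2):
                fam.append(
                    _entry("treatment", treatment, a, b, block[a].to_numpy(),
                           block[b].to_numpy(), self.alpha, self.method)
                )
            rows.extend(self._maybe_holm(fam))
        return pd.DataFrame(rows)

    def _maybe_holm(self, family: list[dict]) -> list[dict]:
        if self.adjust is None:
            return family
        if self.adjust != "holm":
            raise ValueError("adjust must be None or 'holm'")
        ps = np.array([e["p"] for e in family])
        finite = np.isfinite(ps)
        p_holm = np.full(ps.shape, np.nan)
        if finite.any():
            _, adj, *_ = multipletests(ps[finite], alpha=self.alpha, method="holm")
            p_holm[finite] = adj
        for e, pa in zip(family, p_holm):
            e["p_holm"] = float(pa) if np.isfinite(pa) else np.nan
            e["significant_holm"] = bool(pa < self.alpha) if np.isfinite(pa) else False
        return family

    def fit(self, table: pd.DataFrame):
        if self.mode not in ("treatment_by_treatment", "trait_by_trait", "both"):
            raise ValueError("mode must be 'treatment_by_treatment', 'trait_by_trait' or 'both'")
        means = genotype_means(table)
        self.genotype_means_ = means
        self.reports_ = {}
        if self.mode in ("treatment_by_treatment", "both"):
            entries = self._treatment_pairs(means)
            self.reports_["treatment_by_treatment"] = CorrelationReport(
                mode="treatment_by_treatment", alpha=self.alpha, entries=entries
            )
        if self.mode in ("trait_by_trait", "both"):
            entries = self._trait_pairs(means)
            self.reports_["trait_by_trait"] = CorrelationReport(
                mode="trait_by_trait", alpha=self.alpha, entries=entries
            )
        first = "treatment_by_treatment" if "treatment_by_treatment" in self.reports_ else "trait_by_trait"
        self.entries_ = self.reports_[first].entries
        return self


def correlation_matrix(
    table_or_means: pd.DataFrame,
    mode: str = "treatment_by_treatment",
    alpha: float = 0.05,
    method: str = "pearson",
    adjust: str | None = None,
) -> CorrelationReport:
    """Functional wrapper: correlation screen on a long table (or mean cube)."""
    est = GenotypeCorrelations(mode=mode, alpha=alpha, method=method, adjust=adjust)
    if isinstance(table_or_means.columns, pd.MultiIndex):
        means = table_or_means
        est.genotype_means_ = means
        if mode == "treatment_by_treatment":
            entries = est._treatment_pairs(means)
        elif mode == "trait_by_trait":
            entries = est._trait_pairs(means)
        else:
            raise ValueError("mode must be a single mode when passing a mean cube")
        return CorrelationReport(mode=mode, alpha=alpha, entries=entries)
    est.fit(table_or_means)
    key = mode if mode != "both" else "treatment_by_treatment"
    return est.reports_[key]
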