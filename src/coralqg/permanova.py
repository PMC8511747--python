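"""Permutational MANOVA (pseudo-F) on multivariate phenotype profiles.

Partitions the total sum of squared pairwise distances among observations
into between- and within-group components and tests the pseudo-F ratio by
permuting group labels (Anderson's distance-based one-way PERMANOVA).  The
default analysis unit is the genotype × treatment mean profile on the
natural-log scale, so the omnibus test on the study design has total df
``n_genotypes × n_treatments − 1``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

__all__ = [
    "PermanovaResult",
    "Permanova",
    "profile_matrix",
    "permanova_test",
    "pairwise_permanova",
    "permanova_exact",
]


@dataclass
class PermanovaResult:
    """Omnibus PERMANOVA statistics plus optional pairwise table."""

    pseudo_F: float
    R2: float
    p_perm: float
    df_between: int
    df_total: int
    n_permutations: int
    metric: str
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "pseudo_F": self.pseudo_F,
            "R2": self.R2,
            "p_perm": self.p_perm,
            "df_between": self.df_between,
            "df_total": self.df_total,
            "n_permutations": self.n_permutations,
            "metric": self.metric,
        }
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        return out


def profile_matrix(
    table: pd.DataFrame,
    unit: str = "genotype_by_treatment",
    log: bool = True,
    log_offset: float = 0.0,
):
    """Wide observation × trait matrix of (log-transformed) phenotype profiles.

    Parameters
    ----------
    table
        Long-format trait table (``fragment_id, genotype_id, treatment,
        tank_id, trait_name, value``).
    unit
        ``"genotype_by_treatment"`` (default): rows are genotype × treatment
        means over fragments, taken on the raw scale before the log
        transform.  ``"fragment"``: one row per fragment.
    log
        Natural-log transform the matrix (the standardisation used before
        the multivariate test).  Non-positive values raise, with a hint to
        pass an explicit ``log_offset``; no silent offsetting.
    log_offset
        Constant added to every value before the log transform.

    Returns
    -------
    (X, groups)
        ``X``: DataFrame of observations × traits; ``groups``: aligned
        Series of treatment labels.
    """
    if unit not in ("genotype_by_treatment", "fragment"):
        raise ValueError("unit must be 'genotype_by_treatment' or 'fragment'")
    wide = table.pivot_table(
        index=["fragment_id", "genotype_id", "treatment", "tank_id"],
        columns="trait_name",
        values="value",
        aggfunc="first",
        observed=True,
    )
    n_incomplete = int(wide.isna().any(axis=1).sum())
    if n_incomplete:
        wide = wide.dropna(axis=0)
    wide = wide.reset_index()
    if unit == "genotype_by_treatment":
        trait_cols = [c for c in wide.columns if c not in ("fragment_id", "genotype_id", "treatment", "tank_id")]
        agg = wide.groupby(["genotype_id", "treatment"], observed=True)[trait_cols].mean().reset_index()
        X = agg[trait_cols].copy()
        X.index = pd.MultiIndex.from_frame(agg[["genotype_id", "treatment"]])
        groups = pd.Series(agg["treatment"].to_numpy(), index=X.index, name="treatment")
    else:
        trait_cols = [c for c in wide.columns if c not in ("fragment_id", "genotype_id", "treatment", "tank_id")]
        X = wide[trait_cols].copy()
        X.index = pd.Index(wide["fragment_id"], name="fragment_id")
        groups = pd.Series(wide["treatment"].to_numpy(), index=X.index, name="treatment")
    X = X + log_offset
    if log:
        if (X.to_numpy() <= 0).any():
            bad = int((X.to_numpy() <= 0).sum())
            raise ValueError(
                f"{bad} non-positive values under the log transform; pass an explicit "
                "log_offset (or log=False) — values are not offset silently"
            )
        X = np.log(X)
    X.attrs["n_incomplete_dropped"] = n_incomplete
    return X, groups


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    ss = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    n = d2.shape[0]
    k = uniq.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels, uniq)
    ss_between = ss_total - ss_within
    if ss_within <= 0.0:  # perfect within-group coincidence
        f = np.inf
    else:
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between, ss_within, ss_total


class Permanova(BaseEstimator):
    """One-way PERMANOVA estimator.

    Parameters
    ----------
    n_permutations : int
        Label permutations for the p-value (default 999).  The estimator
        ``p = (1 + #{F* >= F}) / (1 + n_permutations)`` never returns 0.
    metric : {"euclidean", "bray_curtis"}
        Distance between observation profiles.
    random_state : int or None
        Seed for the permutation stream.

    Attributes (after :meth:`fit`)
    ------------------------------
    pseudo_f_, r2_, p_value_ : float
    df_between_, df_total_ : int
    ss_between_, ss_within_, ss_total_ : float
    """

    def __init__(self, n_permutations: int = 999, metric: str = "euclidean", random_state: int | None = None):
        self.n_permutations = n_permutations
        self.metric = metric
        self.random_state = random_state

    def _distances(self, X: np.ndarray) -> np.ndarray:
        if self.metric == "euclidean":
            d = pdist(X, metric="euclidean")
        elif self.metric == "bray_curtis":
            d = pdist(X, metric="braycurtis")
        else:
            raise ValueError("metric must be 'euclidean' or 'bray_curtis'")
        return squareform(d)

    def fit(self, X, y):
        """Run the test on observations ``X`` with group labels ``y``."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = np.asarray(y)
        if X.shape[0] != labels.shape[0]:
            raise ValueError("X and y lengths differ")
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size < 2:
            raise ValueError("need at least 2 groups")
        if (counts < 2).any():
            raise ValueError("every group needs at least 2 observations")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")

        d2 = self._distances(X) ** 2
        if not (d2 > 0).any():
            raise ValueError("degenerate distance matrix: all pairwise distances are zero")
        f_obs, ssb, ssw, sst = self._pieces = _pseudo_f(d2, labels, uniq)

        rng = np.random.default_rng(self.random_state)
        n = labels.shape[0]
        count = 0
        for _ in range(self.n_permutations):
            perm = labels[rng.permutation(n)]
            f_perm, *_ = _pseudo_f(d2, perm, uniq)
            if f_perm >= f_obs - 1e-12:
                count += 1
        self.pseudo_f_ = float(f_obs)
        self.ss_between_ = float(ssb)
        self.ss_within_ = float(ssw)
        self.ss_total_ = float(sst)
        self.r2_ = float(ssb / sst)
        self.p_value_ = (1 + count) / (1 + self.n_permutations)
        self.df_between_ = int(uniq.size - 1)
        self.df_total_ = int(n - 1)
        self.n_obs_ = n
        self.groups_ = uniq
        return self

    def result(self, pairwise: pd.DataFrame | None = None) -> PermanovaResult:
        if not hasattr(self, "pseudo_f_"):
            raise RuntimeError("call fit first")
        return PermanovaResult(
            pseudo_F=self.pseudo_f_,
            R2=self.r2_,
            p_perm=self.p_value_,
            df_between=self.df_between_,
            df_total=self.df_total_,
            n_permutations=self.n_permutations,
            metric=self.metric,
            pairwise=pairwise,
        )


def permanova_test(
    X,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    metric: str = "euclidean",
) -> PermanovaResult:
    """Functional wrapper around :class:`Permanova`."""
    est = Permanova(n_permutations=n_permutations, metric=metric, random_state=seed)
    est.fit(X, groups)
    return est.result()


def pairwise_permanova(
    X,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """All pairwise two-group PERMANOVAs with a Bonferroni correction.

    The Bonferroni multiplier is the number of group pairs, so with 999
    permutations and 6 pairs the smallest attainable adjusted p is
    ``6 × 1/1000 = 0.006``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size < 3:
        raise ValueError("pairwise PERMANOVA needs at least 3 groups")
    pairs = list(itertools.combinations(uniq, 2))
    n_pairs = len(pairs)
    ss = np.random.SeedSequence(seed).spawn(n_pairs)
    rows = []
    for (a, b), child in zip(pairs, ss):
        mask = (labels == a) | (labels == b)
        res = permanova_test(
            X[mask],
            labels[mask],
            n_permutations=n_permutations,
            seed=int(child.generate_state(1)[0] % (2**31)),
            metric=metric,
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_F": res.pseudo_F,
                "p_raw": res.p_perm,
                "p_bonferroni": min(1.0, res.p_perm * n_pairs),
            }
        )
    return pd.DataFrame(rows)


def _distinct_assignments(labels: np.ndarray):
    """All distinct multiset orderings of a label vector (n!/(n1!..nk!))."""
    n = labels.shape[0]
    uniq, counts = np.unique(labels, return_counts=True)
    remaining = sorted(zip(uniq, counts), key=lambda t: -t[1])

    def fill(positions, rem, assign):
        if not rem:
            out = np.empty(n, dtype=labels.dtype)
            for g, pos in assign:
                out[list(pos)] = g
            yield out
            return
        g, c = rem[0]
        for combo in itertools.combinations(positions, c):
            rest = tuple(p for p in positions if p not in combo)
            yield from fill(rest, rem[1:], assign + [(g, combo)])

    return fill(tuple(range(n)), remaining, [])


def permanova_exact(X, groups, metric: str = "euclidean") -> PermanovaResult:
    """Exhaustive-enumeration PERMANOVA p over all distinct label assignments.

    Feasible only for small n; used as the brute-force oracle for the
    Monte-Carlo permutation p.  ``p = #{F* >= F} / N`` over all ``N``
    distinct assignments (the observed one included).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    n_assign = math.factorial(labels.size)
    for c in counts:
        n_assign //= math.factorial(c)
    if n_assign > 200_000:
        raise ValueError(f"{n_assign} assignments: too many for exhaustive enumeration")
    est = Permanova(n_permutations=0, metric=metric)
    d2 = est._distances(X) ** 2
    f_obs, ssb, ssw, sst = _pseudo_f(d2, labels, uniq)
    count = 0
    total = 0
    for assign in _distinct_assignments(labels):
        f, *_ = _pseudo_f(d2, assign, uniq)
        total += 1
        if f >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(ssb / sst),
        p_perm=count / total,
        df_between=int(uniq.size - 1),
        df_total=int(labels.size - 1),
        n_permutations=total,
        metric=metric,
    )
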