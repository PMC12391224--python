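"""Heteroscedastic one-way inference on per-well total heat.

Per-cell total heat is strongly heteroscedastic across media groups, so
a classical ANOVA pooling variances is inappropriate.  The model here is
the one-way generalized-least-squares (GLS) layout with a separate
variance per group.  Because the mean model is saturated, the GLS group
means are simply the sample means, and the omnibus test reduces to a
closed-form Wald F with plug-in weights

    w_g = n_g / s_g**2,
    mu_hat = sum(w_g * m_g) / sum(w_g),
    F = sum(w_g * (m_g - mu_hat)**2) / (k - 1)

referred to an F distribution on (k - 1, N - k) degrees of freedom.
Pairwise comparisons use the unequal-variance Games-Howell construction:
per-pair Welch standard errors and Satterthwaite degrees of freedom,
with family-wise adjustment from the studentized-range distribution for
k groups.  A compact letter display (CLD) summarises the resulting
significance pattern: groups that share no letter differ significantly.

With only n = 8 wells per group the plug-in Wald F is mildly
anticonservative; see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from string import ascii_lowercase
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "GroupEstimates",
    "FTestResult",
    "PairwiseComparison",
    "estimate_groups",
    "gls_wald_f",
    "pairwise_tukey",
    "compact_letters",
    "HeteroscedasticANOVA",
]


@dataclass(frozen=True)
class GroupEstimates:
    """Per-group sample sizes, means, unbiased variances and GLS weights."""

    labels: tuple[Hashable, ...]
    n: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("need at least 2 groups")

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def N(self) -> int:
        return int(self.n.sum())

    @property
    def weights(self) -> np.ndarray:
        """GLS weights ``n_g / s_g**2`` (inverse variance of each group mean)."""
        return self.n / self.variances

    def __getitem__(self, label: Hashable) -> tuple[int, float, float]:
        i = self.labels.index(label)
        return int(self.n[i]), float(self.means[i]), float(self.variances[i])


@dataclass(frozen=True)
class FTestResult:
    F: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class PairwiseComparison:
    """One Games-Howell comparison between two group means."""

    pair: tuple[Hashable, Hashable]
    estimate: float
    std_error: float
    satterthwaite_df: float
    adjusted_p: float
    significant: bool

    @property
    def statistic(self) -> float:
        return self.estimate / self.std_error


def estimate_groups(
    values: Sequence[float], groups: Sequence[Hashable]
) -> GroupEstimates:
    """Group means and unbiased (n-1) variances, in first-appearance order."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("values and groups must be parallel 1-D sequences")
    if y.size == 0:
        raise ValueError("no observations")
    if np.any([gi is None for gi in g]) or np.any(np.isnan(y)):
        raise ValueError("missing values or group labels")
    labels = tuple(dict.fromkeys(g))  # preserves first appearance
    n = np.array([int((g == lab).sum()) for lab in labels])
    if np.any(n < 2):
        bad = [lab for lab, ni in zip(labels, n) if ni < 2]
        raise ValueError(f"groups with fewer than 2 observations: {bad}")
    means = np.array([y[g == lab].mean() for lab in labels])
    variances = np.array([y[g == lab].var(ddof=1) for lab in labels])
    return GroupEstimates(labels=labels, n=n, means=means, variances=variances)


def gls_wald_f(est: GroupEstimates) -> FTestResult:
    """Wald F-test of equal group means under group-specific variances."""
    if np.any(est.variances <= 0):
        bad = [lab for lab, v in zip(est.labels, est.variances) if v <= 0]
        raise ValueError(
            f"zero within-group variance in {bad}; the weighted F is undefined"
        )
    w = est.weights
    mu = float((w * est.means).sum() / w.sum())
    df1 = est.k - 1
    df2 = est.N - est.k
    F = float((w * (est.means - mu) ** 2).sum() / df1)
    return FTestResult(F=F, df1=df1, df2=df2, p_value=float(sps.f.sf(F, df1, df2)))


def pairwise_tukey(
    est: GroupEstimates, alpha: float = 0.05
) -> list[PairwiseComparison]:
    """All-pairs Games-Howell comparisons at family-wise level ``alpha``.

    For each unordered pair the Welch statistic ``t = diff / se`` with
    ``se = sqrt(v_i/n_i + v_j/n_j)`` is referred to the studentized-range
    distribution for ``k`` groups as ``q = |t| * sqrt(2)`` on the pair's
    Satterthwaite degrees of freedom.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.any(est.variances <= 0):
        raise ValueError("zero within-group variance; comparisons undefined")
    out: list[PairwiseComparison] = []
    for i, j in combinations(range(est.k), 2):
        vi, vj = est.variances[i] / est.n[i], est.variances[j] / est.n[j]
        se = float(np.sqrt(vi + vj))
        diff = float(est.means[i] - est.means[j])
        df = (vi + vj) ** 2 / (
            vi**2 / (est.n[i] - 1) + vj**2 / (est.n[j] - 1)
        )
        q = abs(diff) / se * np.sqrt(2.0)
        p = float(np.clip(sps.studentized_range.sf(q, est.k, df), 0.0, 1.0))
        out.append(
            PairwiseComparison(
                pair=(est.labels[i], est.labels[j]),
                estimate=diff,
                std_error=se,
                satterthwaite_df=float(df),
                adjusted_p=p,
                significant=p < alpha,
            )
        )
    return out


def compact_letters(
    comparisons: Iterable[PairwiseComparison],
    group_order: Sequence[Hashable],
) -> dict[Hashable, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Starting from a single letter shared by every group, each significant
    pair splits every letter-class containing both of its members into
    two classes, one without each member; classes that become subsets of
    another are absorbed.  Letters are then assigned to classes in the
    order their first group appears in ``group_order`` (conventionally by
    descending mean), so the largest group reads 'a'.

    The output satisfies: two groups share at least one letter if and
    only if their comparison is *not* significant.
    """
    comps = list(comparisons)
    groups = list(group_order)
    seen_pairs = {frozenset(c.pair) for c in comps}
    needed = {frozenset(p) for p in combinations(groups, 2)}
    if needed - seen_pairs:
        missing = sorted(tuple(sorted(map(str, p))) for p in needed - seen_pairs)
        raise ValueError(f"comparisons missing for pairs: {missing}")

    classes: list[set[Hashable]] = [set(groups)]
    for comp in comps:
        if not comp.significant:
            continue
        a, b = comp.pair
        if a not in groups or b not in groups:
            continue
        new_classes: list[set[Hashable]] = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.append(cls - {a})
                new_classes.append(cls - {b})
            else:
                new_classes.append(cls)
        # absorb classes contained in another
        new_classes = [c for c in new_classes if c]
        classes = [
            c
            for i, c in enumerate(new_classes)
            if not any(c < d or (c == d and i > j) for j, d in enumerate(new_classes))
        ]

    order_index = {g: i for i, g in enumerate(groups)}
    classes.sort(key=lambda cls: min(order_index[g] for g in cls))
    letters: dict[Hashable, list[str]] = {g: [] for g in groups}
    for idx, cls in enumerate(classes):
        letter = ascii_lowercase[idx % 26] * (idx // 26 + 1)
        for g in groups:
            if g in cls:
                letters[g].append(letter)
    return {g: "".join(ls) for g, ls in letters.items()}


class HeteroscedasticANOVA(BaseEstimator):
    """One-way GLS inference with a separate variance per group.

    Scikit-learn style estimator: ``fit(X, y)`` takes the observations
    ``X`` (1-D, or a single-column 2-D array) and parallel group labels
    ``y``, and exposes the omnibus Wald F-test, Games-Howell pairwise
    comparisons and the compact letter display as fitted attributes.

    Parameters
    ----------
    alpha:
        Family-wise significance level for the pairwise comparisons and
        the letter display.

    Attributes
    ----------
    groups_ : tuple
        Group labels in first-appearance order.
    group_means_, group_variances_, group_sizes_ : ndarray
        Per-group summaries (unbiased variances).
    f_statistic_, df_, p_value_ :
        Omnibus Wald F on ``(k-1, N-k)`` degrees of freedom.
    comparisons_ : list of PairwiseComparison
    letters_ : dict
        Compact letter display keyed by group, letters assigned by
        descending mean.

    Examples
    --------
    >>> aov = HeteroscedasticANOVA().fit([1.0, 1.1, 5.0, 5.2], ["a", "a", "b", "b"])
    >>> aov.df_
    (1, 2)
    """

    def __init__(self, alpha: float = 0.05) -> None:
        self.alpha = alpha

    def fit(self, X, y) -> "HeteroscedasticANOVA":
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        est = estimate_groups(X, np.asarray(y, dtype=object))
        ftest = gls_wald_f(est)
        comps = pairwise_tukey(est, alpha=self.alpha)
        order = [est.labels[i] for i in np.argsort(-est.means, kind="stable")]

        self.estimates_ = est
        self.groups_ = est.labels
        self.group_sizes_ = est.n
        self.group_means_ = est.means
        self.group_variances_ = est.variances
        self.gls_weights_ = est.weights
        self.f_statistic_ = ftest.F
        self.df_ = (ftest.df1, ftest.df2)
        self.p_value_ = ftest.p_value
        self.f_test_ = ftest
        self.comparisons_ = comps
        self.letters_ = compact_letters(comps, order)
        return self

    def summary(self):
        """Tidy per-pair summary as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "group_1": [c.pair[0] for c in self.comparisons_],
                "group_2": [c.pair[1] for c in self.comparisons_],
                "estimate": [c.estimate for c in self.comparisons_],
                "std_error": [c.std_error for c in self.comparisons_],
                "df": [c.satterthwaite_df for c in self.comparisons_],
                "adjusted_p": [c.adjusted_p for c in self.comparisons_],
                "significant": [c.significant for c in self.comparisons_],
            }
        )
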