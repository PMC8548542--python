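"""Inferential statistics for the regional association analysis.

Implements the full battery used downstream: Pearson correlations with
3-SD pre-censoring and Fisher-z confidence intervals, Welch/pooled
two-sample t-tests, the Fisher exact odds-ratio analysis of the 2x2 survey
table, global Moran's I with permutation inference on the region adjacency,
and a standardised principal component analysis of the three regional
variables (income security, proportion of families with children, upload
change).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "CorrelationResult",
    "ContingencyTable",
    "FisherResult",
    "MoranResult",
    "PCAResult",
    "TTestResult",
    "censored_pearson",
    "two_sample_t",
    "fisher_exact_or",
    "morans_i",
    "pca_three_vars",
]


# ---------------------------------------------------------------------------
# correlation


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n_used: int
    n_censored: int
    defined: bool = True


def censored_pearson(x, y, sd_multiplier: float = 3.0,
                     confidence: float = 0.95) -> CorrelationResult:
    """Pearson correlation after a single 3-SD censoring pass.

    Pairs where either variable lies more than ``sd_multiplier`` standard
    deviations from its sample mean (computed once, over all complete
    pairs) are removed; the pass is not iterated.  The confidence interval
    uses the variance-stabilising arctanh transform with standard error
    1/sqrt(n - 3).

    Missing pairs are dropped before censoring and are not counted as
    censored.  Zero variance among survivors yields an undefined result
    (``defined=False``) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n_pairs = len(x)

    keep = np.ones(n_pairs, dtype=bool)
    for v in (x, y):
        sd = v.std(ddof=1) if n_pairs > 1 else 0.0
        if sd > 0:
            keep &= np.abs(v - v.mean()) <= sd_multiplier * sd
    xs, ys = x[keep], y[keep]
    n_used = len(xs)
    n_censored = n_pairs - n_used

    if n_used < 4 or xs.std() == 0 or ys.std() == 0:
        return CorrelationResult(math.nan, math.nan, math.nan,
                                 n_used, n_censored, defined=False)
    rho = float(np.corrcoef(xs, ys)[0, 1])
    if abs(rho) >= 1.0:  # degenerate CI: collinear survivors
        return CorrelationResult(rho, rho, rho, n_used, n_censored)
    z = math.atanh(rho)
    se = 1.0 / math.sqrt(n_used - 3)
    zcrit = sps.norm.ppf(0.5 + confidence / 2)
    return CorrelationResult(rho, math.tanh(z - zcrit * se),
                             math.tanh(z + zcrit * se), n_used, n_censored)


# ---------------------------------------------------------------------------
# t-test


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float
    equal_var: bool


def two_sample_t(a, b, equal_var: bool = False) -> TTestResult:
    """Two-sided two-sample t-test of mean equality.

    Welch's unequal-variance form is the default; set ``equal_var`` for the
    pooled-variance classic test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue),
                       float(res.df), equal_var)


# ---------------------------------------------------------------------------
# Fisher exact / odds ratio


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; row 1 is the group of interest (yes/no), row 2 the
    reference group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_survey(cls, survey: pd.DataFrame,
                    group_col: str = "income_group",
                    response_col: str = "changed_work_environment",
                    interest_group: str = "above_median",
                    yes: str = "yes") -> "ContingencyTable":
        """Tabulate an individual-response survey into 2x2 counts."""
        is_interest = survey[group_col] == interest_group
        is_yes = survey[response_col] == yes
        return cls(int((is_interest & is_yes).sum()),
                   int((is_interest & ~is_yes).sum()),
                   int((~is_interest & is_yes).sum()),
                   int((~is_interest & ~is_yes).sum()))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    degenerate: bool = False
    ci_method: str = "normal"


def fisher_exact_or(table: ContingencyTable, ci_method: str = "normal",
                    confidence: float = 0.95) -> FisherResult:
    """Two-tailed Fisher's exact test with the sample odds ratio.

    The odds ratio is the cross-product (a*d)/(b*c); the p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one.  The default 95% CI is
    the log-odds normal approximation ``exp(ln OR +/- z * sqrt(1/a + 1/b +
    1/c + 1/d))``; ``ci_method="exact"`` gives the conditional exact
    interval instead.

    A zero cell makes the cross-product degenerate (0 or inf); the result
    is flagged and the CI falls back to the Haldane-Anscombe +0.5
    continuity correction.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("all margins of the 2x2 table must be positive")

    p = float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])
    zcrit = float(sps.norm.ppf(0.5 + confidence / 2))
    degenerate = min(a, b, c, d) == 0

    if degenerate:
        odds_ratio = math.inf if b * c == 0 and a * d > 0 else (
            0.0 if a * d == 0 and b * c > 0 else math.nan)
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = math.log((aa * dd) / (bb * cc))
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        return FisherResult(odds_ratio, math.exp(log_or - zcrit * se),
                            math.exp(log_or + zcrit * se), p,
                            degenerate=True, ci_method="haldane")

    odds_ratio = (a * d) / (b * c)
    if ci_method == "normal":
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = math.exp(math.log(odds_ratio) - zcrit * se)
        hi = math.exp(math.log(odds_ratio) + zcrit * se)
    elif ci_method == "exact":
        res = sps.contingency.odds_ratio(table.as_array(), kind="conditional")
        ci = res.confidence_interval(confidence_level=confidence)
        lo, hi = float(ci.low), float(ci.high)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return FisherResult(float(odds_ratio), lo, hi, p, ci_method=ci_method)


# ---------------------------------------------------------------------------
# Moran's I


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_permutation: float
    n_permutations: int
    alternative: str = "two-sided"
    defined: bool = True


def _weight_matrix(region_ids: np.ndarray, adjacency: pd.DataFrame
                   ) -> np.ndarray:
    idx = {rid: i for i, rid in enumerate(region_ids)}
    W = np.zeros((len(region_ids), len(region_ids)))
    for rid, nid in zip(adjacency["region_id"], adjacency["neighbour_id"]):
        if rid in idx and nid in idx:
            W[idx[rid], idx[nid]] = 1.0
    return W


def morans_i(values: pd.Series, adjacency: pd.DataFrame,
             n_permutations: int = 999, seed: int = 0,
             alternative: str = "two-sided") -> MoranResult:
    """Global Moran's I with row-standardised binary weights.

    ``values`` is indexed by region_id; ``adjacency`` lists symmetric
    neighbour pairs (``region_id``, ``neighbour_id``).  Significance comes
    from ``n_permutations`` random relabellings of the values over regions
    (pseudo p-value ``(1 + #extreme) / (1 + n_permutations)``); under the
    null the expectation of I is -1/(n-1).  Isolated regions are dropped
    with a warning; an entirely isolated map is undefined.
    """
    values = pd.Series(values).astype(float)
    region_ids = values.index.to_numpy()
    W = _weight_matrix(region_ids, adjacency)

    connected = W.sum(axis=1) > 0
    if not connected.any():
        return MoranResult(math.nan, math.nan, math.nan, n_permutations,
                           alternative, defined=False)
    if not connected.all():
        warnings.warn(f"dropping {int((~connected).sum())} isolated regions",
                      stacklevel=2)
        W = W[np.ix_(connected, connected)]
        values = values[connected]
    n = len(values)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 connected regions")
    W = W / W.sum(axis=1, keepdims=True)  # row-standardise

    z = values.to_numpy() - values.mean()
    ss = float(z @ z)
    if ss == 0:
        return MoranResult(math.nan, -1.0 / (n - 1), math.nan, n_permutations,
                           alternative, defined=False)
    s0 = W.sum()
    observed = float(n / s0 * (z @ W @ z) / ss)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_permutations)])
    stat = n / s0 * np.einsum("ij,ij->i", perms, perms @ W.T) / ss

    if alternative == "two-sided":
        extreme = np.abs(stat - expected) >= abs(observed - expected)
    elif alternative == "greater":
        extreme = stat >= observed
    elif alternative == "less":
        extreme = stat <= observed
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + int(extreme.sum())) / (1 + n_permutations)
    return MoranResult(observed, expected, p, n_permutations, alternative)


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame        # variables x components
    variance_explained: np.ndarray
    dropped: tuple[str, ...] = ()


def pca_three_vars(variables: pd.DataFrame,
                   n_components: int | None = None) -> PCAResult:
    """PCA of standardised regional variables.

    Columns are z-scored (so components reflect the correlation structure);
    constant columns are excluded with a warning.  The sign convention
    makes the largest-magnitude loading of each component positive.
    """
    df = variables.dropna()
    if len(df) < 4:
        raise ValueError("PCA needs at least 4 complete rows")
    sd = df.std(ddof=0)
    dropped = tuple(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"excluding constant variables {list(dropped)}",
                      stacklevel=2)
        df = df.drop(columns=list(dropped))
    zed = (df - df.mean()) / df.std(ddof=0)

    k = n_components or zed.shape[1]
    pca = PCA(n_components=k)
    pca.fit(zed.to_numpy())
    loadings = pca.components_.T.copy()  # variables x components
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAResult(
        pd.DataFrame(loadings, index=zed.columns,
                     columns=[f"PC{j + 1}" for j in range(loadings.shape[1])]),
        pca.explained_variance_ratio_.copy(),
        dropped,
    )
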