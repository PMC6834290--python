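"""Statistical kernel shared by every analysis stage.

Exact and asymptotic two-group tests, Benjamini-Hochberg FDR control,
hypergeometric complex enrichment with a custom background, and the
multinomial-logit likelihood-ratio comparison used to weigh paralogy
features against each other.

Conventions recorded once and used everywhere:

* Odds ratios are sample (cross-product) odds ratios ``a*d / (b*c)``.
* Fisher p-values are two-sided by the point-probability method unless an
  enrichment direction is explicitly requested (``alternative="greater"``).
* The t test is the pooled-variance Student form; Welch is available behind
  a flag but is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("contingency counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class TestResult:
    """A named statistic with its p-value and directional summary."""

    statistic_name: str
    statistic: float
    p_value: float
    df: float | None = None
    effect: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Sample odds ratio a*d/(b*c); inf if only b*c vanishes, NaN if both do."""
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        return math.nan if ad == 0 else math.inf
    return ad / bc


def fisher_exact_or(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> TestResult:
    """Fisher's exact test with the sample odds ratio as the statistic."""
    _, p = sps.fisher_exact(table.as_array(), alternative=alternative)
    return TestResult("OR", odds_ratio(table), float(p), effect={
        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
    })


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> TestResult:
    """Two-sided two-sample t test (pooled-variance Student by default).

    Degenerate zero-variance inputs are resolved explicitly: equal means give
    t=0, p=1; unequal means give p=0 flagged as degenerate in ``effect``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    df = x.size + y.size - 2 if equal_var else None
    mean_diff = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if mean_diff == 0.0:
            return TestResult("t", 0.0, 1.0, df=df, effect={"mean_diff": 0.0})
        sign = math.copysign(1.0, mean_diff)
        return TestResult(
            "t", sign * math.inf, 0.0, df=df,
            effect={"mean_diff": mean_diff, "degenerate": 1.0},
        )
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    if not equal_var:
        # Welch-Satterthwaite df, reported for completeness
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return TestResult("t", float(t), float(p), df=df, effect={"mean_diff": mean_diff})


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U (two-sided); exact for small tie-free samples.

    Exact enumeration when n1+n2 <= 12 and the pooled sample has no ties,
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs at least 1 observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence either way
        return TestResult("U", x.size * y.size / 2.0, 1.0)
    small = x.size + y.size <= 12 and np.unique(pooled).size == pooled.size
    method = "exact" if small else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("U", float(res.statistic), float(res.pvalue))


def chi_squared(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-squared on an r x c table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult("chi2", float(chi2), float(p), df=float(df))


def multinomial_logit_lrt(
    features_full: pd.DataFrame,
    features_reduced: pd.DataFrame | None,
    outcome: Sequence,
) -> dict:
    """Likelihood-ratio test of nested multinomial (3-class) logit models.

    Both models include an intercept. ``features_reduced=None`` means the
    intercept-only model. Returns log-likelihoods, the LRT statistic
    2*(logL_full - logL_reduced), its df (2 free parameters per added
    feature for a 3-level outcome), and the chi-squared p-value.
    """
    import statsmodels.api as sm

    outcome = pd.Series(outcome).reset_index(drop=True)
    levels = outcome.unique()
    if len(levels) != 3:
        raise ValueError("outcome must have exactly 3 levels")
    codes = pd.Categorical(outcome).codes

    full = features_full.reset_index(drop=True)
    reduced = (
        features_reduced.reset_index(drop=True)
        if features_reduced is not None
        else pd.DataFrame(index=full.index)
    )
    if not set(reduced.columns) <= set(full.columns):
        raise ValueError("reduced features must be a subset of full features")

    def _fit(feats: pd.DataFrame) -> float:
        X = sm.add_constant(feats.astype(float), has_constant="add")
        model = sm.MNLogit(codes, X)
        fit = model.fit(method="newton", maxiter=200, disp=False)
        return float(fit.llf)

    ll_full = _fit(full)
    ll_reduced = _fit(reduced)
    n_added = len(set(full.columns) - set(reduced.columns))
    df = 2 * n_added
    lrt = max(2.0 * (ll_full - ll_reduced), 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(lrt, df))
    return {
        "logL_full": ll_full,
        "logL_reduced": ll_reduced,
        "lrt": lrt,
        "df": df,
        "p": p,
    }


def complex_enrichment(
    query: set,
    background: set,
    complexes: Mapping[str, set],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per complex.

    Membership is intersected with the custom background; complexes with no
    background members are skipped. BH-FDR is applied across the tested
    complexes. Returns a DataFrame sorted by p.
    """
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    N = len(background)
    n = len(query)
    rows = []
    for cid, members in complexes.items():
        members = set(members) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        # P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"complex_id": cid, "n_members": K, "n_overlap": k, "p": p})
    result = pd.DataFrame(rows, columns=["complex_id", "n_members", "n_overlap", "p"])
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
        result = result.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        result["q"] = []
    return result
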