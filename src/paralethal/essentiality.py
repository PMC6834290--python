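"""Fitness-score binarization and essentiality categories.

A Gaussian mixture (1-5 components, AIC-selected) is fit to the pooled
gene-score distribution. With components sorted by mean, the essentiality
threshold tau is the equal-weighted-density boundary between the lowest
("essential") and second-lowest ("moderate fitness defect") components —
equivalently, the point of equal posterior responsibility between them. A
gene scoring at or below tau in a line is called essential in that line.

Genes are then categorized across lines: never essential (0% of lines),
broadly essential (>= 90%), and sometimes essential (everything between).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

BROADLY_CUTOFF = 0.90


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture, components sorted by ascending mean."""

    k: int
    weights: list[float]
    means: list[float]
    sds: list[float]
    log_likelihood: float
    aic: float
    seed: int
    n_restarts: int
    boundary_rule: str = "equal weighted density (= equal posterior)"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def fit_score_mixture(
    scores,
    k_range=range(1, 6),
    seed: int = 0,
    n_restarts: int = 10,
) -> MixtureFit:
    """AIC-selected Gaussian mixture over the pooled finite scores.

    Each k is fit with ``n_restarts`` random EM initializations (best
    likelihood kept). AIC = 2*(3k-1) - 2*logL, the free parameters being k
    means, k variances and k-1 weights.
    """
    x = np.asarray(scores, dtype=float).ravel()
    x = x[np.isfinite(x)]
    k_range = list(k_range)
    if x.size < 10 * max(k_range):
        raise ValueError("too few finite scores for a stable mixture fit")
    X = x.reshape(-1, 1)
    best: MixtureFit | None = None
    for k in k_range:
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=n_restarts,
                random_state=seed,
                max_iter=1000,
                tol=1e-6,
            ).fit(X)
        except Exception as exc:  # pragma: no cover - EM failure is pathological
            warnings.warn(f"mixture fit failed for k={k}: {exc}")
            continue
        if not gm.converged_:
            warnings.warn(f"EM did not converge for k={k}; skipping")
            continue
        order = np.argsort(gm.means_.ravel())
        n_params = 3 * k - 1
        logL = float(gm.score(X) * X.shape[0])
        fit = MixtureFit(
            k=k,
            weights=list(gm.weights_.ravel()[order]),
            means=list(gm.means_.ravel()[order]),
            sds=list(np.sqrt(gm.covariances_.ravel()[order])),
            log_likelihood=logL,
            aic=2.0 * n_params - 2.0 * logL,
            seed=seed,
            n_restarts=n_restarts,
        )
        if best is None or fit.aic < best.aic:
            best = fit
    if best is None:
        raise RuntimeError("mixture fitting failed for every component count")
    return best


def mixture_boundary(
    w1: float, mu1: float, sd1: float, w2: float, mu2: float, sd2: float,
    tol: float = 1e-8,
) -> float:
    """Equal-weighted-density point between two Gaussian components.

    Finds x in (mu1, mu2) with w1*N(x; mu1, sd1) = w2*N(x; mu2, sd2) by
    bisection; if several crossings exist, returns the one closest to mu2.
    """
    if not mu1 < mu2:
        raise ValueError("components must be ordered by mean")

    def diff(x: float) -> float:
        return w1 * norm.pdf(x, mu1, sd1) - w2 * norm.pdf(x, mu2, sd2)

    grid = np.linspace(mu1, mu2, 2049)
    vals = np.array([diff(g) for g in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_changes) == 0:
        raise ValueError(
            "no weighted-density crossing between the two lowest components "
            f"(means {mu1:.3f}, {mu2:.3f}; weights {w1:.3f}, {w2:.3f})"
        )
    i = sign_changes[-1]  # crossing closest to mu2
    lo, hi = float(grid[i]), float(grid[i + 1])
    flo = diff(lo)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        fmid = diff(mid)
        if (flo < 0) == (fmid < 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return (lo + hi) / 2


def essentiality_threshold(fit: MixtureFit) -> float:
    """Threshold tau from the fitted mixture's two lowest-mean components."""
    if fit.k < 2:
        raise ValueError("threshold requires a mixture with k >= 2")
    return mixture_boundary(
        fit.weights[0], fit.means[0], fit.sds[0],
        fit.weights[1], fit.means[1], fit.sds[1],
    )


def binarize(scores: pd.DataFrame, tau: float) -> pd.DataFrame:
    """1 where score <= tau (inclusive), 0 above, NaN stays NaN."""
    if not math.isfinite(tau):
        raise ValueError("threshold must be finite")
    return (scores <= tau).astype(float).where(scores.notna())


@dataclass
class GeneEssentialitySummary:
    gene: str
    n_lines_scored: int
    n_lines_essential: int
    fraction_essential: float
    category: str


def categorize(fraction: float, n_essential: int) -> str:
    if n_essential == 0:
        return "never"
    if fraction >= BROADLY_CUTOFF:
        return "broadly"
    return "sometimes"


def summarize_genes(binary: pd.DataFrame) -> dict:
    """Per-gene summaries, per-line essential counts, and decile bins.

    Genes scored in zero lines are excluded (with a warning). Deciles bin
    the genes with fraction > 0 into (0-10], (10-20], ..., (90-100].
    """
    if binary.size == 0:
        raise ValueError("empty essentiality matrix")
    scored = binary.notna().sum(axis=1)
    skipped = scored.index[scored == 0].tolist()
    if skipped:
        warnings.warn(f"{len(skipped)} genes scored in zero lines; excluded")
    keep = scored.index[scored > 0]
    ess = binary.loc[keep].sum(axis=1, skipna=True).astype(int)
    frac = ess / scored.loc[keep]
    summaries = pd.DataFrame(
        {
            "gene": keep,
            "n_lines_scored": scored.loc[keep].to_numpy(),
            "n_lines_essential": ess.to_numpy(),
            "fraction_essential": frac.to_numpy(),
        }
    )
    summaries["category"] = [
        categorize(f, n)
        for f, n in zip(summaries["fraction_essential"], summaries["n_lines_essential"])
    ]
    per_line = binary.sum(axis=0, skipna=True).astype(int)
    nonzero = summaries[summaries["fraction_essential"] > 0]
    bins = pd.cut(
        nonzero["fraction_essential"] * 100,
        bins=np.arange(0, 101, 10),
        right=True,
        include_lowest=False,
    )
    decile_counts = bins.value_counts().sort_index()
    return {
        "genes": summaries,
        "per_line_counts": per_line,
        "median_essential_per_line": float(per_line.median()),
        "decile_bins": decile_counts,
        "excluded_genes": skipped,
    }
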