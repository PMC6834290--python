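"""Brute-force reference implementations used only by the tests.

Each oracle restates the definition being tested in the most literal way
possible (enumeration, exhaustive scanning, hand-rolled step-up) and shares
no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def scan_guide(protospacer: str, genome: dict[str, str], max_mm: int = 2):
    """All <=max_mm-mismatch, NGG-PAM occurrences, by literal sliding window.

    Returns a list of (chrom, strand, start, n_mismatches,
    frozenset(mismatch positions 1..20 from the PAM-distal end)).
    """
    hits = []
    for chrom, seq in genome.items():
        L = len(seq)
        for start in range(L - 19):
            window = seq[start:start + 20]
            # forward strand: PAM right of the window
            mm = 0
            positions = []
            for i, (a, b) in enumerate(zip(window, protospacer)):
                if a != b:
                    mm += 1
                    positions.append(i + 1)
                    if mm > max_mm:
                        break
            if mm <= max_mm and start + 23 <= L and seq[start + 21:start + 23] == "GG":
                hits.append((chrom, "+", start, mm, frozenset(positions)))
            # reverse strand: protospacer reads as revcomp of the window
            rc = revcomp(window)
            mm = 0
            positions = []
            for i, (a, b) in enumerate(zip(rc, protospacer)):
                if a != b:
                    mm += 1
                    positions.append(i + 1)
                    if mm > max_mm:
                        break
            if mm <= max_mm and start - 3 >= 0:
                pam = revcomp(seq[start - 3:start])
                if pam[1:3] == "GG":
                    hits.append((chrom, "-", start, mm, frozenset(positions)))
    return hits


def is_multi_target(hits) -> bool:
    """The three drop rules, applied literally to scan_guide output."""
    perfect = [h for h in hits if h[3] == 0]
    if len(perfect) >= 2:
        return True
    if perfect and any(h[3] == 1 for h in hits):
        return True
    if perfect and any(h[3] == 2 and h[4] <= {1, 2} for h in hits):
        return True
    return False


def bh_stepup(pvalues):
    """Benjamini-Hochberg q-values by the textbook step-up recursion."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * n / rank)
        q[i] = running_min
    return q


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def fisher_twosided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    N = a + b + c + d
    K = a + b       # row-1 margin
    n = a + c       # col-1 margin
    p_obs = hypergeom_pmf(a, N, K, n)
    total = 0.0
    for k in range(max(0, n + K - N), min(n, K) + 1):
        p = hypergeom_pmf(k, N, K, n)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by upper-tail enumeration."""
    N = a + b + c + d
    K = a + b
    n = a + c
    return min(
        sum(hypergeom_pmf(k, N, K, n) for k in range(a, min(n, K) + 1)), 1.0
    )


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(sample_x, sample_y):
        u = 0.0
        for xi in sample_x:
            for yj in sample_y:
                u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
        return u

    u_obs = u_of(x, y)
    mean_u = n1 * len(y) / 2
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if abs(u_of(xs, ys) - mean_u) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total


def average_precision(ranked_labels) -> float:
    """AP over a ranked boolean label list (True = positive)."""
    hits = 0
    precisions = []
    for rank, is_pos in enumerate(ranked_labels, start=1):
        if is_pos:
            hits += 1
            precisions.append(hits / rank)
    return sum(precisions) / len(precisions) if precisions else math.nan


def student_t_sf(t: float, df: int, n_steps: int = 200_000) -> float:
    """P(T > t) by trapezoidal integration of the t density."""
    from math import gamma, pi, sqrt

    norm_const = gamma((df + 1) / 2) / (sqrt(df * pi) * gamma(df / 2))

    def pdf(u: float) -> float:
        return norm_const * (1 + u * u / df) ** (-(df + 1) / 2)

    # integrate from t out to a far bound (heavy tails need a wide window)
    hi = max(abs(t) * 1000.0, 5000.0)
    lo = t
    h = (hi - lo) / n_steps
    total = 0.5 * (pdf(lo) + pdf(hi))
    for i in range(1, n_steps):
        total += pdf(lo + i * h)
    return total * h
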