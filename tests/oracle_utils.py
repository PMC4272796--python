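"""Independent brute-force oracles used across the test suite.

Everything here works on explicit per-base sets, hand-written
order-statistic formulas, or normal equations — deliberately naive and
independent of the package's implementations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from panelcov.intervals import GenomicInterval, IntervalSet


def base_set(intervals) -> set[tuple[str, int]]:
    """Explicit set of (chrom, base) pairs covered by intervals."""
    out: set[tuple[str, int]] = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            out.add((iv.chrom, pos))
    return out


def set_to_tuples(bases: set[tuple[str, int]]) -> list[tuple[str, int, int]]:
    """Canonical (chrom, start, end) runs from a per-base set."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _ in bases}):
        positions = sorted(p for c, p in bases if c == chrom)
        start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                out.append((chrom, start, prev + 1))
                start = p
            prev = p
        out.append((chrom, start, prev + 1))
    return out


def iset_to_tuples(s: IntervalSet) -> list[tuple[str, int, int]]:
    return [(iv.chrom, iv.start, iv.end) for iv in s]


def random_intervals(rng: np.random.Generator, n_max: int = 200, n_chroms: int = 5,
                     coord_max: int = 10_000, len_max: int = 80) -> list[GenomicInterval]:
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, coord_max - 1))
        length = int(rng.integers(1, len_max + 1))
        out.append(GenomicInterval(chrom, start, min(start + length, coord_max)))
    return out


def quantile_sorted(values, p: float) -> float:
    """Linear interpolation between order statistics (R type 7)."""
    v = sorted(values)
    n = len(v)
    if n == 1:
        return float(v[0])
    h = (n - 1) * p
    lo = math.floor(h)
    frac = h - lo
    if lo + 1 >= n:
        return float(v[-1])
    return float(v[lo] + frac * (v[lo + 1] - v[lo]))


def ols_normal_equations(x, y) -> dict:
    """Simple OLS via explicit normal equations + t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    sxx = float(((x - x.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if ss_res > 0:
        se = math.sqrt(ss_res / (n - 2) / sxx)
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), df=n - 2)
    else:
        p = 0.0
    return {"intercept": beta[0], "slope": beta[1], "r_squared": r2, "p_value": p, "n": n}
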