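"""Independent brute-force oracles used to cross-check the estimators.

Everything here is written with plain loops and first-principles formulas,
deliberately avoiding the code paths (numpy.quantile, statsmodels WLS,
vectorized statistics) used by the package itself.
"""

from __future__ import annotations

import math


def quantile_linear(sorted_values: list[float], q: float) -> float:
    """Linear interpolation between order statistics (the documented rule)."""
    n = len(sorted_values)
    if n == 1:
        return sorted_values[0]
    h = (n - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return sorted_values[lo] * (1 - frac) + sorted_values[hi] * frac


def boxplot_brute(values: list[float]) -> dict:
    """Boxplot summary with 1.5*IQR fences, computed by exhaustive loops."""
    xs = sorted(values)
    q1 = quantile_linear(xs, 0.25)
    med = quantile_linear(xs, 0.5)
    q3 = quantile_linear(xs, 0.75)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = [x for x in xs if lo_fence <= x <= hi_fence]
    outliers = [x for x in xs if x < lo_fence or x > hi_fence]
    return {
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_low": min(inside),
        "whisker_high": max(inside),
        "outliers": outliers,
    }


def weighted_stats_brute(values: list[float], weights: list[float]) -> dict:
    """Duration-weighted mean, SD (frequency normalization) and median."""
    total = sum(weights)
    mean = sum(w * v for v, w in zip(values, weights)) / total
    n = len(values)
    if n > 1 and total - total / n > 0:
        var = sum(w * (v - mean) ** 2 for v, w in zip(values, weights)) / (
            total - total / n
        )
        sd = math.sqrt(var)
    else:
        sd = 0.0
    pairs = sorted(zip(values, weights))
    half = 0.5 * total
    cum = 0.0
    median = pairs[-1][0]
    for v, w in pairs:
        cum += w
        if cum >= half:
            median = v
            break
    return {"mean": mean, "sd": sd, "median": median}


def wls_line_grid(
    velocities: list[float],
    forces: list[float],
    weights: list[float],
    rounds: int = 16,
    grid: int = 21,
) -> tuple[float, float]:
    """Weighted-loss line fit by iterative grid refinement.

    Minimizes sum(w * (F - a - b*v)^2) over (a, b) on a shrinking grid,
    independent of any closed-form normal-equation solution.
    """

    def loss(a: float, b: float) -> float:
        return sum(
            w * (f - a - b * v) ** 2 for v, f, w in zip(velocities, forces, weights)
        )

    a_lo, a_hi = -50.0, 50.0
    b_lo, b_hi = -1.0, 1.0
    best = (0.0, 0.0)
    for _ in range(rounds):
        best_loss = float("inf")
        a_step = (a_hi - a_lo) / (grid - 1)
        b_step = (b_hi - b_lo) / (grid - 1)
        for i in range(grid):
            a = a_lo + i * a_step
            for j in range(grid):
                b = b_lo + j * b_step
                l = loss(a, b)
                if l < best_loss:
                    best_loss = l
                    best = (a, b)
        a_lo, a_hi = best[0] - 2 * a_step, best[0] + 2 * a_step
        b_lo, b_hi = best[1] - 2 * b_step, best[1] + 2 * b_step
    return best
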