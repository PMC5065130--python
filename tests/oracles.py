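"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and scipy's
distribution machinery): small-sample p-values come from exhaustive
enumeration, and the epistasis categories from a literal decision table.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def average_ranks(values) -> np.ndarray:
    """Average ranks computed by hand (no scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_enum_two_sided(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    if len(d) == 0:
        return 1.0
    ranks = average_ranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((1, -1), repeat=len(d)):
        ws.append(ranks[np.array(signs) > 0].sum())
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _ks_stat(x, y) -> float:
    pts = np.sort(np.unique(np.concatenate([x, y])))
    fx = np.searchsorted(np.sort(x), pts, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), pts, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


def ks_enum_two_sample(a, b) -> tuple[float, float]:
    """Exact two-sample KS (D, p) by enumerating all label assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = len(a)
    d_obs = _ks_stat(a, b)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        if _ks_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            count += 1
        total += 1
    return d_obs, count / total


def epistasis_decision_table(
    class_a: str,
    class_b: str,
    delta_sign: int,
    p_diff,
    alpha: float = 0.05,
    band_exceeded: bool = True,
) -> str:
    """Literal decision table for the epistasis category.

    ``delta_sign`` is the sign of log10(fold_b) - log10(fold_a);
    ``band_exceeded`` states whether |delta| is beyond the neutrality band
    (only consulted when no between-background p-value exists).
    """
    if "untested" in (class_a, class_b):
        return "indeterminate"
    if p_diff is not None and p_diff >= alpha:
        return "no_epistasis"
    if p_diff is None and not band_exceeded:
        return "no_epistasis"
    table = {
        ("neutral", "neutral"): "no_epistasis",
        ("neutral", "deleterious"): "neutral_shift",
        ("neutral", "favorable"): "neutral_shift",
        ("deleterious", "neutral"): "neutral_shift",
        ("favorable", "neutral"): "neutral_shift",
        ("deleterious", "favorable"): "sign_negative_to_positive",
        ("favorable", "deleterious"): "sign_positive_to_negative",
    }
    if (class_a, class_b) in table:
        return table[(class_a, class_b)]
    if delta_sign == 0:
        return "no_epistasis"
    if class_a == "deleterious":  # both deleterious
        return "magnitude_antagonistic" if delta_sign > 0 else "magnitude_synergistic"
    # both favorable
    return "magnitude_antagonistic" if delta_sign < 0 else "magnitude_synergistic"


def t_test_two_sided_equal_var(x, y) -> float:
    """Closed-form pooled-variance two-sample t-test (oracle)."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    tstat = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2.0 * float(tdist.sf(abs(tstat), nx + ny - 2))


def wilson_interval(count: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Closed-form Wilson score interval (oracle)."""
    p = count / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half
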