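"""Distribution of fitness effects (DFE) for a random mutant library.

Variants carrying single random mutations are measured on two activities
relative to a common reference, binned into four effect classes —

* strongly deleterious: fold < 1/strong_fold (default >2-fold decrease),
* weakly deleterious:   1/strong_fold <= fold < 1/neutral_fold,
* neutral:              1/neutral_fold <= fold <= neutral_fold,
* positive:             fold > neutral_fold,

— with binomial confidence intervals on bin frequencies.  Paired per-variant
log differences between the two activities are compared by a Wilcoxon
signed-rank test; the two log-fold distributions by a two-sample
Kolmogorov–Smirnov test.  The conditional DFE slices the native-activity DFE
by the variant's bin on the promiscuous activity (e.g. the native-activity
effects of adaptive mutations only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .config import DEFAULT_CONFIG, RunConfig

DFE_BINS = ("strongly_deleterious", "weakly_deleterious", "neutral", "positive")


class DFEError(ValueError):
    pass


@dataclass
class DFESummary:
    substrate: str
    n: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    #: below-censored variants whose bound cannot place them in a bin
    n_indeterminate: int = 0
    condition: str = ""


@dataclass
class PairedEffectSet:
    """Per-variant fold-changes on the two activities, aligned by variant."""

    variant_ids: tuple[str, ...]
    fold_native: np.ndarray
    fold_promiscuous: np.ndarray

    def __post_init__(self) -> None:
        self.fold_native = np.asarray(self.fold_native, dtype=float)
        self.fold_promiscuous = np.asarray(self.fold_promiscuous, dtype=float)
        if not (len(self.variant_ids) == len(self.fold_native) == len(self.fold_promiscuous)):
            raise DFEError("paired effect vectors differ in length")
        if np.any(self.fold_native <= 0) or np.any(self.fold_promiscuous <= 0):
            raise DFEError("fold-changes must be positive")

    @property
    def log10_diff(self) -> np.ndarray:
        """log10(fold_native) - log10(fold_promiscuous) per variant."""
        return np.log10(self.fold_native) - np.log10(self.fold_promiscuous)

    def __len__(self) -> int:
        return len(self.variant_ids)


def bin_fold(fold: float, strong_fold: float = 2.0, neutral_fold: float = 1.3) -> str:
    """Assign one fold-change to its DFE bin (boundary convention as listed
    in the module docstring)."""
    if fold <= 0:
        raise DFEError(f"fold-change must be positive, got {fold}")
    if fold < 1.0 / strong_fold:
        return "strongly_deleterious"
    if fold < 1.0 / neutral_fold:
        return "weakly_deleterious"
    if fold <= neutral_fold:
        return "neutral"
    return "positive"


def binomial_ci(
    count: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Binomial confidence interval for a bin frequency.

    Wilson score interval by default (good coverage at moderate frequencies);
    Clopper–Pearson available as ``method="clopper-pearson"``.
    """
    if n < 1:
        raise DFEError("n must be >= 1")
    if not 0 <= count <= n:
        raise DFEError(f"count {count} outside [0, {n}]")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    low, high = proportion_confint(count, n, alpha=1.0 - level, method=sm_method)
    return float(low), float(high)


def bin_dfe(
    folds: Sequence[float],
    strong_fold: float = 2.0,
    neutral_fold: float = 1.3,
    substrate: str = "",
    censored_bounds: Sequence[float] = (),
    ci_level: float = 0.95,
    ci_method: str = "wilson",
    condition: str = "",
) -> DFESummary:
    """Bin a collection of fold-changes into the four-bin DFE.

    Below-censored variants enter as upper bounds: a bound below the
    strongly-deleterious boundary proves its bin; anything else is counted as
    indeterminate, outside the four bins.
    """
    counts = {b: 0 for b in DFE_BINS}
    for f in folds:
        counts[bin_fold(f, strong_fold, neutral_fold)] += 1
    n_indet = 0
    for bound in censored_bounds:
        if bound < 1.0 / strong_fold:
            counts["strongly_deleterious"] += 1
        else:
            n_indet += 1
    n = sum(counts.values())
    if n == 0:
        return DFESummary(
            substrate=substrate,
            n=0,
            counts=counts,
            frequencies={b: math.nan for b in DFE_BINS},
            ci95={b: (math.nan, math.nan) for b in DFE_BINS},
            n_indeterminate=n_indet,
            condition=condition,
        )
    freqs = {b: counts[b] / n for b in DFE_BINS}
    cis = {b: binomial_ci(counts[b], n, ci_level, ci_method) for b in DFE_BINS}
    return DFESummary(
        substrate=substrate,
        n=n,
        counts=counts,
        frequencies=freqs,
        ci95=cis,
        n_indeterminate=n_indet,
        condition=condition,
    )


def _signed_rank_exact_p(d: np.ndarray, alternative: str) -> float:
    """Exact signed-rank p-value under the average-rank tie convention.

    The null distribution of W+ (sum of ranks of positive differences) over
    all 2^n equiprobable sign assignments is built by dynamic programming on
    doubled ranks (average ranks of integers doubled are integers), so ties
    in |d| are handled exactly.
    """
    ranks2 = np.round(2.0 * stats.rankdata(np.abs(d))).astype(int)
    w_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = float(counts[: w_obs + 1].sum())
    p_ge = float(counts[w_obs:].sum())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_difference_test(
    pairs: PairedEffectSet, alternative: str = "two-sided"
) -> float:
    """Wilcoxon signed-rank test of the per-variant log10 differences
    against a symmetric distribution around zero.

    Zero differences are dropped (Wilcoxon's original treatment); ties use
    the average-rank convention.  P-values are exact (full sign-assignment
    distribution) for n <= 25, normal approximation with continuity
    correction above.  All-zero differences give p = 1.
    """
    d = pairs.log10_diff
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    n = len(d)
    if n <= 25:
        return _signed_rank_exact_p(d, alternative)
    res = stats.wilcoxon(
        d, zero_method="wilcox", alternative=alternative, method="approx", correction=True
    )
    return float(res.pvalue)


def distribution_comparison_test(
    folds_a: Sequence[float], folds_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on the log10 fold distributions.

    Returns ``(D, p)``; exact p-values for small samples.
    """
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DFEError("both samples must be non-empty")
    if np.any(a <= 0) or np.any(b <= 0):
        raise DFEError("fold-changes must be positive")
    method = "exact" if max(len(a), len(b)) <= 30 else "auto"
    res = stats.ks_2samp(np.log10(a), np.log10(b), method=method)
    return float(res.statistic), float(res.pvalue)


def conditional_dfe(
    pairs: PairedEffectSet,
    condition: str,
    strong_fold: float = 2.0,
    neutral_fold: float = 1.3,
    ci_level: float = 0.95,
    ci_method: str = "wilson",
) -> DFESummary:
    """Native-activity DFE restricted to variants whose promiscuous-activity
    fold falls in ``condition`` (one of the four bins).

    Summing the conditional counts over all four conditions reproduces the
    unconditional native DFE exactly (partition property).
    """
    if condition not in DFE_BINS:
        raise DFEError(f"condition must be one of {DFE_BINS}, got {condition!r}")
    mask = np.array(
        [bin_fold(f, strong_fold, neutral_fold) == condition for f in pairs.fold_promiscuous]
    )
    selected = pairs.fold_native[mask]
    return bin_dfe(
        selected,
        strong_fold,
        neutral_fold,
        substrate="native",
        ci_level=ci_level,
        ci_method=ci_method,
        condition=condition,
    )


def paired_effects_from_table(
    table, reference_id: str, config: RunConfig = DEFAULT_CONFIG
) -> PairedEffectSet:
    """Build per-variant paired fold-changes (both substrates vs a common
    reference) from an activity table.  Censored variants are excluded."""
    from .effects import estimate_effect

    roles = table.substrate_roles
    if not roles:
        raise DFEError("activity table has no substrate role metadata")
    native, promiscuous = roles["native"], roles["new"]
    ids, fn, fp = [], [], []
    for vid in table.variants():
        if vid == reference_id:
            continue
        rec_n = table.records(vid, native)
        rec_p = table.records(vid, promiscuous)
        if not rec_n or not rec_p:
            continue
        en = estimate_effect(rec_n, table.records(reference_id, native), config, background_id=reference_id)
        ep = estimate_effect(rec_p, table.records(reference_id, promiscuous), config, background_id=reference_id)
        if en.is_censored or ep.is_censored or en.fold_change in (None, 0) or ep.fold_change in (None, 0):
            continue
        ids.append(vid)
        fn.append(en.fold_change)
        fp.append(ep.fold_change)
    return PairedEffectSet(tuple(ids), np.array(fn), np.array(fp))


def dfe_to_frame(summary: DFESummary):
    import pandas as pd

    rows = []
    for b in DFE_BINS:
        low, high = summary.ci95[b]
        rows.append(
            {
                "bin": b,
                "count": summary.counts[b],
                "frequency": summary.frequencies[b],
                "ci_low": low,
                "ci_high": high,
            }
        )
    return pd.DataFrame(rows)
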