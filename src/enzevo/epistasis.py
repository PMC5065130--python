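"""Background-dependence of single-mutation effects (epistasis classes).

Epistasis here means that the same mutation has a different effect in two
genetic backgrounds — e.g. in the wild-type enzyme versus at its point of
occurrence along an evolutionary trajectory.  Categories:

* ``no_epistasis`` — effects statistically indistinguishable (or within the
  neutrality band when no between-background test is available);
* ``magnitude_antagonistic`` — same direction, milder in background B;
* ``magnitude_synergistic`` — same direction, stronger in background B;
* ``sign_negative_to_positive`` / ``sign_positive_to_negative`` — the effect
  flips direction between backgrounds, both sides significant;
* ``neutral_shift`` — neutral in one background, non-neutral in the other;
* ``indeterminate`` — untested or censored effects that the bounds cannot
  order.

This is distinct from pairwise interaction coefficients between two named
mutations (the simulator's interaction terms); background dependence is the
measurable quantity for trajectory data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, RunConfig
from .effects import EFFECT_CLASSES, RelativeEffect

CATEGORIES = (
    "no_epistasis",
    "magnitude_antagonistic",
    "magnitude_synergistic",
    "sign_positive_to_negative",
    "sign_negative_to_positive",
    "neutral_shift",
    "indeterminate",
)


class EpistasisError(ValueError):
    pass


@dataclass
class EpistasisRecord:
    mutation: str
    substrate: str
    background_a: str
    background_b: str
    effect_a: RelativeEffect
    effect_b: RelativeEffect
    delta_log10: float  # log10 fold_b - log10 fold_a; NaN when censored
    p_diff: float | None
    category: str


def classify_epistasis(
    class_a: str,
    class_b: str,
    delta_log10: float,
    p_diff: float | None,
    config: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Decision table mapping two effect classes and their log-difference to
    an epistasis category.

    When a between-background p-value is available it gates every call
    (p >= alpha -> no_epistasis); otherwise magnitude calls require the
    difference to exceed the neutrality band on the log scale.
    """
    if class_a not in EFFECT_CLASSES or class_b not in EFFECT_CLASSES:
        raise EpistasisError(f"unknown effect class: {class_a!r}, {class_b!r}")
    if class_a == "untested" or class_b == "untested":
        return "indeterminate"
    if p_diff is not None:
        if p_diff >= config.alpha:
            return "no_epistasis"
    elif not math.isnan(delta_log10) and abs(delta_log10) <= math.log10(config.neutral_fold):
        return "no_epistasis"
    if class_a == "neutral" and class_b == "neutral":
        return "no_epistasis"
    if class_a == "deleterious" and class_b == "favorable":
        return "sign_negative_to_positive"
    if class_a == "favorable" and class_b == "deleterious":
        return "sign_positive_to_negative"
    if "neutral" in (class_a, class_b):
        return "neutral_shift"
    # same non-neutral direction on both sides
    if math.isnan(delta_log10) or delta_log10 == 0:
        return "no_epistasis"
    if class_a == "deleterious":  # both deleterious: milder in b <=> delta > 0
        return "magnitude_antagonistic" if delta_log10 > 0 else "magnitude_synergistic"
    # both favorable: milder in b <=> delta < 0
    return "magnitude_antagonistic" if delta_log10 < 0 else "magnitude_synergistic"


def _censored_comparison(
    effect_a: RelativeEffect, effect_b: RelativeEffect, config: RunConfig
) -> str:
    """Resolve censored-vs-point comparisons when the bound orders the effects.

    Example: an at-most 1e-4 bound in background A against a point fold of
    0.125 in background B proves the effect is deleterious in both and far
    milder in B (magnitude antagonism); anything the bound cannot order is
    indeterminate.
    """
    a, b = effect_a, effect_b
    band = 1.0 / config.neutral_fold
    if a.is_censored and b.is_censored:
        return "indeterminate"
    if a.is_censored:
        if a.censor_bound != "at_most" or a.bound is None:
            return "indeterminate"
        if b.fold_change is None:
            return "indeterminate"
        # A is deleterious at most `bound`; orderable when B's point estimate
        # clearly exceeds the bound.
        if a.bound < band and b.fold_change > a.bound:
            if b.effect_class == "deleterious":
                return "magnitude_antagonistic"
            if b.effect_class == "favorable":
                return "sign_negative_to_positive"
            if b.effect_class == "neutral":
                return "neutral_shift"
        return "indeterminate"
    # mirror case: B censored
    if b.censor_bound != "at_most" or b.bound is None or a.fold_change is None:
        return "indeterminate"
    if b.bound < band and a.fold_change > b.bound:
        if a.effect_class == "deleterious":
            return "magnitude_synergistic"
        if a.effect_class == "favorable":
            return "sign_positive_to_negative"
        if a.effect_class == "neutral":
            return "neutral_shift"
    return "indeterminate"


def compare_backgrounds(
    effect_a: RelativeEffect,
    effect_b: RelativeEffect,
    config: RunConfig = DEFAULT_CONFIG,
) -> EpistasisRecord:
    """Compare one mutation's effect between two backgrounds.

    The between-background p-value is a two-sample t-test on the per-batch
    log10 ratios retained inside each effect (absent when either side has
    fewer than two batches).
    """
    if effect_a.mutation != effect_b.mutation:
        raise EpistasisError(
            f"mutation mismatch: {effect_a.mutation!r} vs {effect_b.mutation!r}"
        )
    if effect_a.substrate != effect_b.substrate:
        raise EpistasisError(
            f"substrate mismatch: {effect_a.substrate!r} vs {effect_b.substrate!r}"
        )
    if effect_a.background_id == effect_b.background_id:
        raise EpistasisError("effects come from the same background")
    delta, p_diff, category = _compare_effects(effect_a, effect_b, config)
    return EpistasisRecord(
        mutation=effect_a.mutation,
        substrate=effect_a.substrate,
        background_a=effect_a.background_id,
        background_b=effect_b.background_id,
        effect_a=effect_a,
        effect_b=effect_b,
        delta_log10=delta,
        p_diff=p_diff,
        category=category,
    )


def _compare_effects(
    effect_a: RelativeEffect, effect_b: RelativeEffect, config: RunConfig
) -> tuple[float, float | None, str]:
    if effect_a.is_censored or effect_b.is_censored:
        category = _censored_comparison(effect_a, effect_b, config)
        delta = math.nan
        p_diff = None
    else:
        la = effect_a.log10_effect
        lb = effect_b.log10_effect
        if la is None or lb is None or not math.isfinite(la) or not math.isfinite(lb):
            delta, p_diff, category = math.nan, None, "indeterminate"
        else:
            delta = lb - la
            p_diff = None
            ra, rb = effect_a.batch_log10_ratios, effect_b.batch_log10_ratios
            if len(ra) >= 2 and len(rb) >= 2:
                if max(ra) == min(ra) and max(rb) == min(rb):
                    p_diff = 1.0 if ra[0] == rb[0] else 0.0
                else:
                    p_diff = float(
                        stats.ttest_ind(ra, rb, equal_var=(config.t_test == "student")).pvalue
                    )
            category = classify_epistasis(
                effect_a.effect_class, effect_b.effect_class, delta, p_diff, config
            )
    return delta, p_diff, category


@dataclass
class TransitionTable:
    """Contingency of effect-class transitions between two backgrounds."""

    counts: pd.DataFrame  # index: class in A; columns: class in B
    unmatched_a: list[str]
    unmatched_b: list[str]
    category_counts: dict[str, int]

    @property
    def marginal_a(self) -> dict[str, int]:
        return self.counts.sum(axis=1).to_dict()

    @property
    def marginal_b(self) -> dict[str, int]:
        return self.counts.sum(axis=0).to_dict()


def epistasis_transition_table(
    effects_a: list[RelativeEffect],
    effects_b: list[RelativeEffect],
    config: RunConfig = DEFAULT_CONFIG,
) -> TransitionTable:
    """Full class-transition contingency plus per-category epistasis counts.

    Effects are matched by (mutation, substrate); mutations present in only
    one collection are listed as unmatched and excluded from the counts.
    """
    import logging

    index_a = {(e.mutation, e.substrate): e for e in effects_a}
    index_b = {(e.mutation, e.substrate): e for e in effects_b}
    shared = sorted(set(index_a) & set(index_b))
    unmatched_a = sorted(f"{m}/{s}" for m, s in set(index_a) - set(index_b))
    unmatched_b = sorted(f"{m}/{s}" for m, s in set(index_b) - set(index_a))
    counts = pd.DataFrame(
        0, index=list(EFFECT_CLASSES), columns=list(EFFECT_CLASSES), dtype=int
    )
    category_counts = {c: 0 for c in CATEGORIES}
    for key in shared:
        ea, eb = index_a[key], index_b[key]
        counts.loc[ea.effect_class, eb.effect_class] += 1
        _, _, category = _compare_effects(ea, eb, config)
        category_counts[category] += 1
    if not shared:
        logging.getLogger(__name__).warning("no mutations shared between the two backgrounds")
    return TransitionTable(counts, unmatched_a, unmatched_b, category_counts)


def epistasis_to_frame(records: list[EpistasisRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "mutation": r.mutation,
                "substrate": r.substrate,
                "background_a": r.background_a,
                "background_b": r.background_b,
                "fold_a": r.effect_a.fold_change if r.effect_a.fold_change is not None else math.nan,
                "fold_b": r.effect_b.fold_change if r.effect_b.fold_change is not None else math.nan,
                "delta_log10": r.delta_log10,
                "p_diff": r.p_diff if r.p_diff is not None else math.nan,
                "category": r.category,
            }
        )
    return pd.DataFrame(rows)
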