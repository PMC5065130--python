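"""Per-mutation relative effects, effect classes, and the additive null model.

A mutation's *relative effect* on one activity is the fold-change of the
variant's normalized activity over its parent's, aggregated across paired
measurement batches as a geometric mean of per-batch ratios.  Effects are
classified against a symmetric neutrality band (default 1.3-fold) gated by a
two-sided Student t-test on log10 activities: a call of deleterious or
favorable requires both a >1.3-fold mean change *and* p < alpha.

The additive null model states that mutational effects combine by summing on
the log scale: the expected total change of a set of mutations is the product
of their individual fold-changes, equivalently ``geomean ** n``.  Comparing
that expectation with the observed end-to-start change of an evolutionary
trajectory quantifies aggregate epistasis.

Censored measurements (below the assay's detection limit) never contribute
point values to means or medians; they turn products into bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .config import DEFAULT_CONFIG, RunConfig
from .variant_io import (
    ActivityRecord,
    ActivityTable,
    normalize_activity,
    normalized_detection_limit,
    parse_genotype,
)

EFFECT_CLASSES = ("deleterious", "neutral", "favorable", "untested")

LOG10 = math.log(10.0)


class EffectError(ValueError):
    pass


class UndefinedRatioError(EffectError):
    """Parent activity is zero or below detection: no finite ratio exists."""


class StatisticalPreconditionError(EffectError):
    """Too few replicates or batches for the requested statistic."""


@dataclass(frozen=True)
class BoundedValue:
    """A positive quantity that may only be known as a one-sided bound."""

    value: float
    kind: str = "exact"  # exact | at_most | at_least | indeterminate

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "at_most", "at_least", "indeterminate"):
            raise ValueError(f"bad bound kind {self.kind!r}")


@dataclass
class RelativeEffect:
    """One mutation's fold-change effect on one activity in one background."""

    mutation: str
    background_id: str
    substrate: str
    fold_change: float | None
    log10_effect: float | None
    se_log10: float | None = None
    p_value: float | None = None
    n_batches: int = 0
    censor_bound: str = "none"  # none | at_most | at_least
    bound: float | None = None
    effect_class: str = "untested"
    paired: bool = True
    #: per-batch log10 ratios, retained for between-background comparisons
    batch_log10_ratios: tuple[float, ...] = field(default_factory=tuple)

    @property
    def is_censored(self) -> bool:
        return self.censor_bound != "none"


def _batch_means(records: Sequence[ActivityRecord]) -> dict[str, float]:
    sums: dict[str, list[float]] = {}
    for r in records:
        sums.setdefault(r.batch, []).append(normalize_activity(r))
    return {b: float(np.mean(v)) for b, v in sums.items()}


def relative_effect(
    variant_records: Sequence[ActivityRecord],
    parent_records: Sequence[ActivityRecord],
    config: RunConfig = DEFAULT_CONFIG,
    mutation: str = "",
    background_id: str | None = None,
) -> RelativeEffect:
    """Fold-change of variant over parent from paired batch measurements.

    Batches shared between the two collections are compared pairwise (ratio of
    mean normalized activities per batch); the fold-change is the geometric
    mean of the batch ratios and ``se_log10`` their dispersion.  When no batch
    key is shared the comparison falls back to the unpaired ratio of grand
    means and is flagged (``paired=False``).

    A variant entirely below the detection limit yields an ``at_most`` bound
    (detection limit over parent activity) instead of a point estimate.
    A parent that is zero or below detection raises
    :class:`UndefinedRatioError`; callers typically record the effect as
    untested.
    """
    if not variant_records or not parent_records:
        raise StatisticalPreconditionError("need at least one record on each side")
    substrates = {r.substrate for r in variant_records} | {r.substrate for r in parent_records}
    if len(substrates) != 1:
        raise EffectError(f"records mix substrates: {sorted(substrates)}")
    substrate = substrates.pop()
    if background_id is None:
        background_id = parent_records[0].variant_id

    parent_censored = all(r.censor == "below" for r in parent_records)
    parent_means = _batch_means(parent_records)
    if parent_censored or all(v == 0 for v in parent_means.values()):
        raise UndefinedRatioError(
            f"parent {background_id!r} has no measurable activity on {substrate!r}"
        )

    variant_censored = all(r.censor == "below" for r in variant_records)
    any_censored = any(r.censor == "below" for r in variant_records)

    variant_means = _batch_means(variant_records)
    shared = sorted(set(variant_means) & set(parent_means))
    shared = [b for b in shared if parent_means[b] > 0]

    if variant_censored or any_censored:
        # Censored replicates contribute their detection limit, making the
        # resulting ratio an upper bound on the true fold-change.
        limits = [
            normalized_detection_limit(r) if r.censor == "below" else normalize_activity(r)
            for r in variant_records
        ]
        if any(l is None for l in limits):
            raise EffectError("censored record without detection limit")
        by_batch: dict[str, list[float]] = {}
        for r, l in zip(variant_records, limits):
            by_batch.setdefault(r.batch, []).append(float(l))
        bound_batches = [b for b in sorted(set(by_batch) & set(parent_means)) if parent_means[b] > 0]
        if bound_batches:
            ratios = [np.mean(by_batch[b]) / parent_means[b] for b in bound_batches]
        else:
            pm = float(np.mean([v for v in parent_means.values() if v > 0]))
            ratios = [float(np.mean([x for v in by_batch.values() for x in v])) / pm]
        bound = float(np.exp(np.mean(np.log(ratios)))) if all(r > 0 for r in ratios) else float(np.mean(ratios))
        return RelativeEffect(
            mutation=mutation,
            background_id=background_id,
            substrate=substrate,
            fold_change=None,
            log10_effect=None,
            n_batches=len(bound_batches) or 1,
            censor_bound="at_most",
            bound=bound,
            effect_class="untested",
            paired=bool(bound_batches),
        )

    if shared:
        ratios = np.array([variant_means[b] / parent_means[b] for b in shared], dtype=float)
        paired = True
        n_batches = len(shared)
    else:
        v = float(np.mean(list(variant_means.values())))
        p = float(np.mean([x for x in parent_means.values() if x > 0]))
        ratios = np.array([v / p], dtype=float)
        paired = False
        n_batches = 1

    if np.any(ratios <= 0):
        # zero-activity (uncensored) variant batches: fold-change is 0
        fold = 0.0
        return RelativeEffect(
            mutation=mutation,
            background_id=background_id,
            substrate=substrate,
            fold_change=fold,
            log10_effect=-math.inf,
            n_batches=n_batches,
            effect_class="untested",
            paired=paired,
        )

    logs = np.log10(ratios)
    if config.batch_agg == "geometric":
        log10_effect = float(np.mean(logs))
        fold = float(10.0 ** log10_effect)
    else:
        fold = float(np.mean(ratios))
        log10_effect = math.log10(fold)
    se = float(np.std(logs, ddof=1) / math.sqrt(len(logs))) if len(logs) >= 2 else None
    return RelativeEffect(
        mutation=mutation,
        background_id=background_id,
        substrate=substrate,
        fold_change=fold,
        log10_effect=log10_effect,
        se_log10=se,
        n_batches=n_batches,
        paired=paired,
        batch_log10_ratios=tuple(float(x) for x in logs),
    )


def significance_test(
    variant_records: Sequence[ActivityRecord],
    parent_records: Sequence[ActivityRecord],
    config: RunConfig = DEFAULT_CONFIG,
) -> float | None:
    """Two-sided two-sample t-test of variant vs parent activities.

    By default a Student (equal-variance) test on log10 normalized activities;
    Welch and raw-scale variants are available through the configuration.
    Returns ``None`` when either side has fewer than two usable replicates.
    """
    x = [normalize_activity(r) for r in variant_records if r.censor == "none"]
    y = [normalize_activity(r) for r in parent_records if r.censor == "none"]
    if config.log_scale:
        x = [math.log10(v) for v in x if v > 0]
        y = [math.log10(v) for v in y if v > 0]
    if len(x) < 2 or len(y) < 2:
        return None
    if max(x) == min(x) and max(y) == min(y):
        # degenerate noise-free samples: identical -> no evidence, else certain
        return 1.0 if x[0] == y[0] else 0.0
    res = stats.ttest_ind(x, y, equal_var=(config.t_test == "student"))
    return float(res.pvalue)


def classify_effect(
    fold_change: float | None,
    p_value: float | None,
    neutral_fold: float = 1.3,
    alpha: float = 0.05,
) -> str:
    """Classify a fold-change as deleterious / neutral / favorable / untested.

    A non-neutral call requires both a mean change beyond the neutrality band
    and p < alpha; a beyond-band change without a p-value is untested.
    """
    if fold_change is None or (isinstance(fold_change, float) and math.isnan(fold_change)):
        return "untested"
    if fold_change <= 0:
        return "untested"
    beyond = fold_change > neutral_fold or fold_change < 1.0 / neutral_fold
    if not beyond:
        return "neutral"
    if p_value is None:
        return "untested"
    if p_value < alpha:
        return "deleterious" if fold_change < 1.0 else "favorable"
    return "neutral"


def estimate_effect(
    variant_records: Sequence[ActivityRecord],
    parent_records: Sequence[ActivityRecord],
    config: RunConfig = DEFAULT_CONFIG,
    mutation: str = "",
    background_id: str | None = None,
) -> RelativeEffect:
    """Full pipeline for one mutation: fold-change, p-value and class.

    An undefined ratio (unmeasurable parent) yields an untested effect rather
    than an exception.  Censored effects carry a bound and are classified
    deleterious only when the bound itself proves a beyond-band reduction.
    """
    try:
        eff = relative_effect(variant_records, parent_records, config, mutation, background_id)
    except UndefinedRatioError:
        return RelativeEffect(
            mutation=mutation,
            background_id=background_id or (parent_records[0].variant_id if parent_records else ""),
            substrate=variant_records[0].substrate if variant_records else "",
            fold_change=None,
            log10_effect=None,
            effect_class="untested",
        )
    if eff.is_censored:
        if eff.bound is not None and eff.bound < 1.0 / config.neutral_fold:
            eff.effect_class = "deleterious"
        else:
            eff.effect_class = "untested"
        return eff
    eff.p_value = significance_test(variant_records, parent_records, config)
    eff.effect_class = classify_effect(
        eff.fold_change, eff.p_value, config.neutral_fold, config.alpha
    )
    return eff


# ---------------------------------------------------------------------------
# Summaries and the additive null model
# ---------------------------------------------------------------------------


@dataclass
class EffectSummary:
    """Aggregate of relative effects for one background and substrate."""

    background_id: str
    substrate: str
    n_effects: int
    counts: dict[str, int]
    geometric_mean: float | None
    ci95: tuple[float, float] | None
    median: float | None
    expected_total: BoundedValue | None
    n_in_product: int
    observed_total: float | None = None
    note: str = ""


def expected_total_change(effects: Iterable[RelativeEffect | float]) -> BoundedValue:
    """Null-model expected total change: the product of all fold-changes.

    Computed as ``10 ** sum(log10 folds)``.  Plain floats are accepted as bare
    fold-changes.  Any censored effect turns the product into a bound of the
    corresponding kind (mixed bound directions are indeterminate).  The empty
    product is 1.
    """
    total_log = 0.0
    kinds = set()
    for e in effects:
        if isinstance(e, (int, float)):
            if e <= 0:
                raise EffectError(f"fold-change must be positive, got {e}")
            total_log += math.log10(e)
            continue
        if e.is_censored:
            if e.bound is None or e.bound <= 0:
                raise EffectError("censored effect without a positive bound")
            total_log += math.log10(e.bound)
            kinds.add(e.censor_bound)
        elif e.fold_change is not None and e.fold_change > 0:
            total_log += math.log10(e.fold_change)
        else:
            raise EffectError(f"effect {e.mutation!r} has no usable fold-change")
    if not kinds:
        kind = "exact"
    elif kinds == {"at_most"}:
        kind = "at_most"
    elif kinds == {"at_least"}:
        kind = "at_least"
    else:
        kind = "indeterminate"
    return BoundedValue(10.0 ** total_log, kind)


def observed_total_change(start_activity: float, end_activity: float) -> float:
    """Observed end-to-start fold-change of a trajectory."""
    if start_activity <= 0:
        raise EffectError(f"start activity must be positive, got {start_activity}")
    if end_activity <= 0:
        raise EffectError(f"end activity must be positive, got {end_activity}")
    return end_activity / start_activity


def summarize_effects(
    effects: Sequence[RelativeEffect],
    config: RunConfig = DEFAULT_CONFIG,
    observed_total: float | None = None,
) -> EffectSummary:
    """Table-style summary: class counts, geometric mean with a t-based 95% CI
    on the log scale, median, and the null-model expected total change.

    Censored effects are counted in the class tally but excluded from the
    geometric mean, median, and the expected-total product (so that
    ``geometric_mean ** n_in_product == expected_total`` holds exactly).
    """
    if not effects:
        raise StatisticalPreconditionError("no effects to summarize")
    background = effects[0].background_id
    substrate = effects[0].substrate
    counts = {c: 0 for c in EFFECT_CLASSES}
    for e in effects:
        counts[e.effect_class] += 1
    usable = [
        e for e in effects
        if not e.is_censored and e.fold_change is not None and e.fold_change > 0
    ]
    if not usable:
        return EffectSummary(
            background_id=background,
            substrate=substrate,
            n_effects=len(effects),
            counts=counts,
            geometric_mean=None,
            ci95=None,
            median=None,
            expected_total=None,
            n_in_product=0,
            observed_total=observed_total,
            note="all effects censored or untested; summary statistics undefined",
        )
    logs = np.array([math.log10(e.fold_change) for e in usable])
    n = len(logs)
    mean_log = float(np.mean(logs))
    geomean = 10.0 ** mean_log
    if n >= 2:
        se = float(np.std(logs, ddof=1) / math.sqrt(n))
        tq = float(stats.t.ppf(0.5 + config.ci_level / 2.0, df=n - 1))
        ci = (10.0 ** (mean_log - tq * se), 10.0 ** (mean_log + tq * se))
    else:
        ci = None
    median = float(np.median([e.fold_change for e in usable]))
    expected = expected_total_change(usable)
    return EffectSummary(
        background_id=background,
        substrate=substrate,
        n_effects=len(effects),
        counts=counts,
        geometric_mean=geomean,
        ci95=ci,
        median=median,
        expected_total=expected,
        n_in_product=n,
        observed_total=observed_total,
    )


# ---------------------------------------------------------------------------
# Table-level estimation helpers
# ---------------------------------------------------------------------------


def _mutation_label(child_genotype: str, parent_genotype: str) -> str:
    """Identify the mutation separating two genotypes.

    Uses the symmetric difference of token sets, so a reverted mutation in an
    evolved background maps to the same token as the forward mutation in the
    ancestral background — which is what lets effects of "the same mutation"
    be matched across backgrounds.
    """
    child = {m.label for m in parse_genotype(child_genotype)}
    parent = {m.label for m in parse_genotype(parent_genotype)}
    diff = sorted(child ^ parent)
    return ";".join(diff)


def effects_vs_background(
    table: ActivityTable,
    background_id: str,
    config: RunConfig = DEFAULT_CONFIG,
    substrate: str | None = None,
) -> list[RelativeEffect]:
    """Relative effects of every variant whose parent is ``background_id``."""
    from .variant_io import _row_to_record

    df = table.frame
    children = df.loc[df["parent_id"] == background_id, "variant_id"].unique()
    if len(children) == 0:
        available = sorted(set(df["parent_id"]) - {""})
        raise EffectError(
            f"no variants have parent {background_id!r}; available backgrounds: {available}"
        )
    substrates = [substrate] if substrate else table.substrates
    parent_geno = ""
    pg = df.loc[df["variant_id"] == background_id, "genotype"]
    if not pg.empty:
        parent_geno = pg.iloc[0]
    # one grouped pass instead of a frame scan per variant
    grouped: dict[tuple[str, str], list[ActivityRecord]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault((row.variant_id, row.substrate), []).append(_row_to_record(row))
    out: list[RelativeEffect] = []
    for sub in substrates:
        parent_records = grouped.get((background_id, sub))
        if not parent_records:
            raise EffectError(f"background {background_id!r} has no records on {sub!r}")
        parent_by_batch: dict[str, list[ActivityRecord]] = {}
        for r in parent_records:
            parent_by_batch.setdefault(r.batch, []).append(r)
        for child in children:
            child_records = grouped.get((child, sub))
            if not child_records:
                continue
            # restrict the parent side to the child's batches when the table
            # re-measures the parent alongside every variant (large libraries)
            child_batches = {r.batch for r in child_records}
            paired_parent = [r for b in child_batches for r in parent_by_batch.get(b, [])]
            use_parent = paired_parent if paired_parent else parent_records
            label = _mutation_label(child_records[0].genotype, parent_geno) or child
            eff = estimate_effect(child_records, use_parent, config, label, background_id)
            out.append(eff)
    if config.multiple_testing == "bh":
        _apply_bh(out, config)
    return out


def occurrence_effects(
    table: ActivityTable,
    trajectory,
    config: RunConfig = DEFAULT_CONFIG,
    substrate: str | None = None,
) -> list[RelativeEffect]:
    """Effects of each mutation at its point of occurrence in a trajectory.

    Each round's variant is compared against its immediate trajectory parent.
    """
    substrates = [substrate] if substrate else table.substrates
    out: list[RelativeEffect] = []
    rows = list(trajectory.itertuples(index=False))
    for sub in substrates:
        for row in rows:
            if not row.parent_id:
                continue
            child_records = table.records(row.variant_id, sub)
            parent_records = table.records(row.parent_id, sub)
            if not child_records or not parent_records:
                continue
            label = _mutation_label(child_records[0].genotype, parent_records[0].genotype)
            out.append(
                estimate_effect(child_records, parent_records, config, label or row.variant_id)
            )
    if config.multiple_testing == "bh":
        _apply_bh(out, config)
    return out


def _apply_bh(effects: list[RelativeEffect], config: RunConfig) -> None:
    """Benjamini-Hochberg adjust p-values in place and re-classify."""
    from statsmodels.stats.multitest import multipletests

    idx = [i for i, e in enumerate(effects) if e.p_value is not None]
    if not idx:
        return
    pvals = [effects[i].p_value for i in idx]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    for i, p in zip(idx, adj):
        effects[i].p_value = float(p)
        effects[i].effect_class = classify_effect(
            effects[i].fold_change, effects[i].p_value, config.neutral_fold, config.alpha
        )


def effects_to_frame(effects: Sequence[RelativeEffect]):
    """Flatten effects into the output TSV schema."""
    import pandas as pd

    rows = []
    for e in effects:
        rows.append(
            {
                "mutation": e.mutation,
                "background_id": e.background_id,
                "substrate": e.substrate,
                "fold_change": e.fold_change if e.fold_change is not None else math.nan,
                "log10_effect": e.log10_effect if e.log10_effect is not None else math.nan,
                "se_log10": e.se_log10 if e.se_log10 is not None else math.nan,
                "p_value": e.p_value if e.p_value is not None else math.nan,
                "n_batches": e.n_batches,
                "censor": e.censor_bound,
                "bound": e.bound if e.bound is not None else math.nan,
                "effect_class": e.effect_class,
            }
        )
    return pd.DataFrame(rows)
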