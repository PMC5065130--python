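"""Trajectory-level trade-off quantification.

An evolutionary trajectory carries two activities per round, both relative to
the starting variant.  The *trade-off curve* renormalizes the walk onto the
unit square: x is the cumulative fraction of the total log10 gain in the new
activity, y the fraction of the old activity's total log10 loss not yet
incurred.  A concave curve (area under it > 0.5) is a weak trade-off — large
gains in the new function come early, at little initial cost to the old one —
while a convex curve (area < 0.5) is a strong trade-off.  The *weakness
index* is that normalized area.

Transient increases of either activity would push the curve outside the unit
square, so the normalized curve uses each axis's running envelope (raw values
are retained alongside for inspection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .variant_io import ActivityTable


class TrajectoryError(ValueError):
    pass


class DegenerateCurveError(TrajectoryError):
    """No net gain in the new activity or no net loss in the old one."""


@dataclass
class Trajectory:
    """Ordered rounds with native/new activity levels relative to round 0."""

    rounds: pd.DataFrame  # columns: round, variant_id, activity_native, activity_new
    provenance: str = "measured"

    def __post_init__(self) -> None:
        req = ["round", "variant_id", "activity_native", "activity_new"]
        missing = [c for c in req if c not in self.rounds.columns]
        if missing:
            raise TrajectoryError(f"trajectory frame missing columns: {missing}")
        self.rounds = self.rounds.sort_values("round", kind="mergesort").reset_index(drop=True)
        r = self.rounds["round"].to_numpy()
        if len(r) and not np.all(np.diff(r) > 0):
            raise TrajectoryError("round indices must be strictly increasing")
        acts = self.rounds[["activity_native", "activity_new"]].to_numpy()
        if np.any(acts <= 0):
            raise TrajectoryError("activities must be positive")

    @property
    def log10_native(self) -> np.ndarray:
        return np.log10(self.rounds["activity_native"].to_numpy())

    @property
    def log10_new(self) -> np.ndarray:
        return np.log10(self.rounds["activity_new"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        df = self.rounds.copy()
        df["log10_native"] = self.log10_native
        df["log10_new"] = self.log10_new
        return df.rename(
            columns={"activity_native": "rel_activity_native", "activity_new": "rel_activity_new"}
        )


@dataclass
class TradeoffCurve:
    points: np.ndarray  # (k, 2) normalized, monotone
    raw_points: np.ndarray  # same normalization without the envelope
    auc: float


def trajectory_from_tables(
    activity_table: ActivityTable,
    trajectory_table: pd.DataFrame,
    config: RunConfig = DEFAULT_CONFIG,
) -> Trajectory:
    """Chain per-round fold-changes into activities relative to round 0.

    Each round's variant is compared to its immediate parent via paired-batch
    relative effects on both substrates; the chained products give per-round
    activities relative to the starting variant.
    """
    from .effects import relative_effect

    roles = activity_table.substrate_roles
    if not roles:
        raise TrajectoryError("activity table lacks substrate role metadata")
    native, new = roles["native"], roles["new"]

    rows = trajectory_table.sort_values("round", kind="mergesort").itertuples(index=False)
    rows = list(rows)
    if not rows:
        raise TrajectoryError("empty trajectory table")
    seen: set[str] = set()
    prev_variant: str | None = None
    act_native, act_new = 1.0, 1.0
    out = []
    for i, row in enumerate(rows):
        if row.variant_id in seen:
            raise TrajectoryError(f"cyclic parent links: {row.variant_id!r} revisited")
        seen.add(row.variant_id)
        if i == 0:
            out.append((row.round, row.variant_id, 1.0, 1.0))
            prev_variant = row.variant_id
            continue
        if row.parent_id != prev_variant:
            raise TrajectoryError(
                f"broken parent chain at round {row.round}: parent {row.parent_id!r} "
                f"but previous round's variant is {prev_variant!r}"
            )
        for substrate in (native, new):
            child_rec = activity_table.records(row.variant_id, substrate)
            parent_rec = activity_table.records(row.parent_id, substrate)
            if not child_rec or not parent_rec:
                raise TrajectoryError(
                    f"round {row.round}: missing records for {row.variant_id!r} or "
                    f"{row.parent_id!r} on {substrate!r}"
                )
            eff = relative_effect(child_rec, parent_rec, config)
            if eff.is_censored or eff.fold_change is None or eff.fold_change <= 0:
                raise TrajectoryError(
                    f"round {row.round}: no finite fold-change for {row.variant_id!r} on {substrate!r}"
                )
            if substrate == native:
                act_native *= eff.fold_change
            else:
                act_new *= eff.fold_change
        out.append((row.round, row.variant_id, act_native, act_new))
        prev_variant = row.variant_id
    frame = pd.DataFrame(out, columns=["round", "variant_id", "activity_native", "activity_new"])
    return Trajectory(frame, provenance="measured")


def tradeoff_curve(trajectory: Trajectory) -> TradeoffCurve:
    """Normalized gain-vs-retained-activity curve with trapezoid AUC."""
    gain = trajectory.log10_new  # cumulative log10 gain in the new activity
    loss = -trajectory.log10_native  # cumulative log10 loss of the old activity
    genv = np.maximum.accumulate(gain)
    lenv = np.maximum.accumulate(loss)
    if genv[-1] <= 0:
        raise DegenerateCurveError(
            f"no net gain in the new activity (total log10 gain {gain[-1]:.3g})"
        )
    if lenv[-1] <= 0:
        raise DegenerateCurveError(
            f"no loss of the old activity (total log10 loss {loss[-1]:.3g})"
        )
    x = genv / genv[-1]
    y = 1.0 - lenv / lenv[-1]
    points = np.column_stack([x, y])
    raw = np.column_stack([gain / genv[-1], 1.0 - loss / lenv[-1]])
    auc = float(np.trapezoid(y, x))
    return TradeoffCurve(points=points, raw_points=raw, auc=auc)


def weakness_index(curve: TradeoffCurve) -> float:
    """Normalized area under the trade-off curve, in [0, 1].

    Values above 0.5 indicate a weak (concave) trade-off, below 0.5 a strong
    (convex) one; 0.5 is proportional loss per unit gain.
    """
    return curve.auc


def tradeoff_label(index: float, tol: float = 1e-9) -> str:
    if index > 0.5 + tol:
        return "weak"
    if index < 0.5 - tol:
        return "strong"
    return "proportional"


def trajectory_weakness(trajectory: Trajectory) -> float:
    """Weakness index with degenerate trajectories mapped to the limits.

    A walk whose old activity never net-declines incurs no trade-off at all
    (index 1.0); one that never gains new activity while losing the old is
    maximally strong (0.0).  Used by simulation studies where individual
    replicate walks may be degenerate.
    """
    try:
        return weakness_index(tradeoff_curve(trajectory))
    except DegenerateCurveError:
        loss_total = float(np.max(np.concatenate([[0.0], -trajectory.log10_native])))
        if loss_total <= 0:
            return 1.0
        return 0.0


def generalist_window(trajectory: Trajectory, retention_fold: float = 10.0) -> list[int]:
    """Rounds where the variant is an efficient generalist.

    A round qualifies when *both* activities are within ``retention_fold`` of
    their trajectory-wide maxima.  The threshold is an analysis choice, not a
    measured constant.
    """
    if retention_fold < 1:
        raise TrajectoryError("retention_fold must be >= 1")
    a_n = trajectory.rounds["activity_native"].to_numpy()
    a_w = trajectory.rounds["activity_new"].to_numpy()
    if math.isinf(retention_fold):
        return [int(r) for r in trajectory.rounds["round"]]
    keep = (a_n >= a_n.max() / retention_fold) & (a_w >= a_w.max() / retention_fold)
    return [int(r) for r, k in zip(trajectory.rounds["round"], keep) if k]


def curve_to_frame(curve: TradeoffCurve) -> pd.DataFrame:
    return pd.DataFrame(curve.points, columns=["x", "y"])
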