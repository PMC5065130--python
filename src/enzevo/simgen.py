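"""Synthetic two-activity genotype–phenotype landscapes and adaptive walks.

The generator models directed evolution of an enzyme toward a new activity:

* each candidate mutation carries a pair of true log10 effects (on the old,
  native activity and on the new, promiscuous one) drawn from a bivariate
  normal with configurable means, spreads and correlation ``rho``;
* genotype phenotypes are log-additive, optionally perturbed by sparse
  pairwise interaction terms (epistasis);
* measurements add multiplicative log-normal replicate noise with a given
  coefficient of variation and are censored below a detection limit;
* the adaptive walk screens ``m_per_round`` not-yet-accepted candidates from
  a *finite* pool each round and accepts either the candidate with the
  highest measured new activity (greedy regime: selection on the new function
  only, none on the old) or a uniformly chosen one (random regime).

The finite pool is central: greedy selection consumes the best available
mutations first, so gains in the new activity are front-loaded while — with
``rho = 0`` — the concomitant changes in the old activity remain a selection-
blind random walk.  That asymmetry alone produces initially weak trade-offs,
without any intrinsic robustness of the old activity.

All randomness derives deterministically from a single integer seed via
independent sub-streams (effect draws / candidate draws / screening noise /
random-regime acceptance / measurement noise), so greedy and random regimes
share candidate sequences for the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    AA_ALPHABET,
    ActivityRecord,
    ActivityTable,
    Mutation,
    format_genotype,
    parse_genotype,
    table_from_records,
)

SUBSTRATE_OLD = "native"
SUBSTRATE_NEW = "new"
SUBSTRATE_ROLES = {"native": SUBSTRATE_OLD, "new": SUBSTRATE_NEW}

REGIMES = ("greedy_new_activity", "random_accept")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the landscape, the assay, and the selection regime.

    Defaults describe a directed-evolution campaign whose accessible pool of
    point mutations is sized to the campaign itself
    (``m_per_round + n_rounds - 1``): each round screens most of the
    remaining pool, so the campaign gradually exhausts the accessible
    mutational neighborhood — which is what makes greedy gains front-loaded.
    Replicate noise is ~15% multiplicative; per-mutation effects are mildly
    deleterious on average for both activities and uncorrelated between them.
    """

    n_candidate_pool: int = 59
    m_per_round: int = 50
    n_rounds: int = 10
    mu_old: float = -0.2
    mu_new: float = -0.2
    sigma_old: float = 0.5
    sigma_new: float = 0.5
    rho: float = 0.0
    epistasis_density: float = 0.0
    epistasis_sigma: float = 0.0
    noise_cv: float = 0.15
    n_batches: int = 3
    n_replicates: int = 2
    detection_limit: float = 0.0
    seed: int = 0
    regime: str = "greedy_new_activity"

    def __post_init__(self) -> None:
        if self.n_candidate_pool < 1 or self.m_per_round < 1 or self.n_rounds < 0:
            raise SimulationError("pool, per-round, and round counts must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise SimulationError(f"rho must be in [-1, 1], got {self.rho}")
        if self.sigma_old < 0 or self.sigma_new < 0:
            raise SimulationError("effect spreads must be nonnegative")
        if not 0.0 <= self.epistasis_density <= 1.0:
            raise SimulationError("epistasis_density must be in [0, 1]")
        if self.epistasis_sigma < 0 or self.noise_cv < 0 or self.detection_limit < 0:
            raise SimulationError("noise and detection parameters must be nonnegative")
        if self.n_batches < 1 or self.n_replicates < 1:
            raise SimulationError("need at least one batch and one replicate")
        if self.regime not in REGIMES:
            raise SimulationError(f"regime must be one of {REGIMES}")
        if self.m_per_round + self.n_rounds - 1 > self.n_candidate_pool:
            raise SimulationError(
                f"pool of {self.n_candidate_pool} cannot supply {self.m_per_round} "
                f"unused candidates for {self.n_rounds} rounds"
            )


def _stream(config: SimConfig, key: int) -> np.random.Generator:
    """Deterministic sub-stream ``key`` of the run's root seed."""
    return np.random.default_rng([config.seed, key])


def _mutation_labels(n: int) -> list[str]:
    """Deterministic synthetic mutation tokens at positions 1..n."""
    labels = []
    for i in range(n):
        frm = AA_ALPHABET[i % 20]
        to = AA_ALPHABET[(i + 1 + (i // 20) % 19) % 20]
        if to == frm:  # pragma: no cover - arithmetic guarantees inequality
            to = AA_ALPHABET[(i + 2) % 20]
        labels.append(f"{frm}{i + 1}{to}")
    return labels


def sample_effects(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the pool's true per-mutation effects and pairwise interactions.

    Effects are bivariate normal on the log10 scale with correlation ``rho``.
    A fraction ``epistasis_density`` of mutation pairs receives independent
    normal(0, epistasis_sigma) interaction terms for each activity.
    """
    if rng is None:
        rng = _stream(config, 1)
    n = config.n_candidate_pool
    # explicit construction of the bivariate normal: robust to degenerate
    # spreads (sigma = 0) and perfect correlation (|rho| = 1)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    log_old = config.mu_old + config.sigma_old * z1
    log_new = config.mu_new + config.sigma_new * (
        config.rho * z1 + math.sqrt(max(0.0, 1.0 - config.rho**2)) * z2
    )
    labels = _mutation_labels(n)
    effects = pd.DataFrame(
        {
            "mutation": labels,
            "true_log10_old": log_old,
            "true_log10_new": log_new,
        }
    )
    rows = []
    n_pairs = n * (n - 1) // 2
    k = int(round(config.epistasis_density * n_pairs))
    if k > 0 and config.epistasis_sigma > 0:
        pair_idx = rng.choice(n_pairs, size=k, replace=False)
        # unrank the pair index into (i, j), i < j
        ii, jj = np.triu_indices(n, k=1)
        for p in np.sort(pair_idx):
            a, b = labels[ii[p]], labels[jj[p]]
            for activity in (SUBSTRATE_OLD, SUBSTRATE_NEW):
                rows.append(
                    {
                        "mut_a": a,
                        "mut_b": b,
                        "activity": activity,
                        "term": float(rng.normal(0.0, config.epistasis_sigma)),
                    }
                )
    interactions = pd.DataFrame(rows, columns=["mut_a", "mut_b", "activity", "term"])
    return effects, interactions


def _interaction_lookup(interactions: pd.DataFrame) -> dict[tuple[str, str, str], float]:
    return {
        (r.mut_a, r.mut_b, r.activity): r.term for r in interactions.itertuples(index=False)
    }


def genotype_phenotype(
    mutations: Sequence[str],
    effects: pd.DataFrame,
    interactions: pd.DataFrame | dict | None = None,
) -> tuple[float, float]:
    """True (old, new) activity of a genotype: 10^(sum of base effects plus
    the interaction terms of all present pairs), per activity."""
    table = effects.set_index("mutation") if "mutation" in effects.columns else effects
    unknown = [m for m in mutations if m not in table.index]
    if unknown:
        raise SimulationError(f"unknown mutations: {unknown}")
    log_old = float(table.loc[list(mutations), "true_log10_old"].sum()) if mutations else 0.0
    log_new = float(table.loc[list(mutations), "true_log10_new"].sum()) if mutations else 0.0
    if interactions is not None:
        lookup = (
            interactions
            if isinstance(interactions, dict)
            else _interaction_lookup(interactions)
        )
        if lookup:
            present = sorted(mutations)
            for i, a in enumerate(present):
                for b in present[i + 1 :]:
                    for key in ((a, b), (b, a)):
                        log_old += lookup.get((*key, SUBSTRATE_OLD), 0.0)
                        log_new += lookup.get((*key, SUBSTRATE_NEW), 0.0)
    return 10.0**log_old, 10.0**log_new


def _lognormal_sigma(cv: float) -> float:
    """Natural-log sigma giving a log-normal with the requested CV."""
    return math.sqrt(math.log1p(cv**2))


def measure(
    true_activity: float,
    config: SimConfig,
    rng: np.random.Generator,
    variant_id: str,
    parent_id: str = "",
    genotype: str = "",
    substrate: str = SUBSTRATE_NEW,
    batch_prefix: str = "b",
    dataset: str = "",
) -> list[ActivityRecord]:
    """Noisy replicate measurements of one variant on one substrate.

    ``n_batches x n_replicates`` log-normal draws with median equal to the
    true activity and coefficient of variation ``noise_cv``; draws below the
    detection limit are emitted as below-censored records.
    """
    sigma = _lognormal_sigma(config.noise_cv)
    records = []
    for b in range(config.n_batches):
        for r in range(config.n_replicates):
            value = true_activity
            if sigma > 0:
                value = true_activity * math.exp(rng.normal(0.0, sigma))
            censor = "none"
            limit = None
            if config.detection_limit > 0 and value < config.detection_limit:
                censor = "below"
                limit = config.detection_limit
            elif config.detection_limit > 0:
                limit = config.detection_limit
            records.append(
                ActivityRecord(
                    variant_id=variant_id,
                    parent_id=parent_id,
                    substrate=substrate,
                    batch=f"{batch_prefix}{b + 1}",
                    replicate=r + 1,
                    rate=value,
                    od600=None,
                    detection_limit=limit,
                    censor=censor,
                    genotype=genotype,
                    dataset=dataset,
                )
            )
    return records


@dataclass
class SimTruth:
    """Generating ground truth of a simulated walk."""

    effects: pd.DataFrame
    interactions: pd.DataFrame
    genotypes: list[tuple[str, ...]]  # per round, accepted mutation labels
    true_old: np.ndarray  # per round, incl. round 0
    true_new: np.ndarray
    #: mutation labels screened in each round (for auditing the selection)
    screened: list[tuple[str, ...]] = field(default_factory=list)


@dataclass
class WalkResult:
    table: ActivityTable | None
    trajectory: pd.DataFrame  # round, variant_id, parent_id
    truth: SimTruth

    def true_trajectory(self):
        """The walk's ground-truth activity trajectory (no assay noise)."""
        from .tradeoff import Trajectory

        frame = pd.DataFrame(
            {
                "round": np.arange(len(self.truth.true_old)),
                "variant_id": self.trajectory["variant_id"],
                "activity_native": self.truth.true_old,
                "activity_new": self.truth.true_new,
            }
        )
        return Trajectory(frame, provenance="simulated")


def run_walk(config: SimConfig, emit_tables: bool = True) -> WalkResult:
    """Simulate one adaptive walk and emit measurement tables plus truth.

    Starting from the empty genotype, each round screens ``m_per_round``
    not-yet-accepted candidates on the new activity (one noisy assay each) and
    accepts the best (greedy regime; ties break to the lowest mutation index)
    or a uniform choice (random regime).  The accepted variant and its parent
    are then measured on both substrates in shared batches, giving the paired
    records the effects pipeline expects.

    ``emit_tables=False`` skips all measurement emission (``table`` is None);
    the realized trajectory and truth are identical either way because
    measurement noise draws come from their own random sub-stream.
    """
    eff_rng = _stream(config, 1)
    cand_rng = _stream(config, 2)
    screen_rng = _stream(config, 3)
    accept_rng = _stream(config, 4)
    meas_rng = _stream(config, 5)

    effects, interactions = sample_effects(config, eff_rng)
    lookup = _interaction_lookup(interactions)
    labels = list(effects["mutation"])
    screened_rounds: list[tuple[str, ...]] = []
    # fast internal phenotype path: base effects as arrays, interactions
    # keyed by pool indices (genotype_phenotype is the reference semantics)
    base_old = effects["true_log10_old"].to_numpy()
    base_new = effects["true_log10_new"].to_numpy()
    pos = {m: i for i, m in enumerate(labels)}
    inter_old: dict[tuple[int, int], float] = {}
    inter_new: dict[tuple[int, int], float] = {}
    for r in interactions.itertuples(index=False):
        key = (pos[r.mut_a], pos[r.mut_b])
        (inter_old if r.activity == SUBSTRATE_OLD else inter_new)[key] = r.term

    def _pair_sum(terms: dict[tuple[int, int], float], members: Sequence[int], cand: int) -> float:
        if not terms:
            return 0.0
        return sum(
            terms.get((min(i, cand), max(i, cand)), 0.0) for i in members
        )
    dataset = f"walk_seed{config.seed}"
    sigma_screen = _lognormal_sigma(config.noise_cv)
    genotype_idx: list[int] = []
    available = np.ones(config.n_candidate_pool, dtype=bool)
    records: list[ActivityRecord] = []
    traj_rows = [{"round": 0, "variant_id": "R0", "parent_id": ""}]
    genotypes: list[tuple[str, ...]] = [()]
    true_old = [1.0]
    true_new = [1.0]

    def geno_string(idx: Sequence[int]) -> str:
        return format_genotype([parse_genotype(labels[i])[0] for i in idx])

    if emit_tables:
        for substrate, act in ((SUBSTRATE_OLD, 1.0), (SUBSTRATE_NEW, 1.0)):
            records += measure(
                act, config, meas_rng, "R0", "", "", substrate, batch_prefix="r0b",
                dataset=dataset,
            )

    current_old, current_new = 1.0, 1.0
    for rnd in range(1, config.n_rounds + 1):
        remaining = np.flatnonzero(available)
        if config.m_per_round > len(remaining):
            raise SimulationError(
                f"round {rnd}: {config.m_per_round} candidates requested, "
                f"{len(remaining)} remain in the pool"
            )
        cand = cand_rng.choice(remaining, size=config.m_per_round, replace=False)
        cand = np.sort(cand)
        screened_rounds.append(tuple(labels[int(c)] for c in cand))
        log_new_now = math.log10(current_new)
        truths = np.array(
            [
                10.0 ** (log_new_now + base_new[c] + _pair_sum(inter_new, genotype_idx, int(c)))
                for c in cand
            ]
        )
        if config.regime == "greedy_new_activity":
            screened = truths.copy()
            if sigma_screen > 0:
                screened = truths * np.exp(screen_rng.normal(0.0, sigma_screen, size=len(cand)))
            best = screened.max()
            chosen = int(cand[np.flatnonzero(screened == best)[0]])  # cand sorted: lowest index wins
        else:
            chosen = int(accept_rng.choice(cand))
        new_old = current_old * 10.0 ** (
            base_old[chosen] + _pair_sum(inter_old, genotype_idx, chosen)
        )
        new_new = current_new * 10.0 ** (
            base_new[chosen] + _pair_sum(inter_new, genotype_idx, chosen)
        )
        genotype_idx.append(chosen)
        available[chosen] = False
        muts = [labels[i] for i in sorted(genotype_idx)]
        child = f"R{rnd}"
        parent = f"R{rnd - 1}"
        geno = geno_string(sorted(genotype_idx))
        parent_geno = geno_string(sorted(genotype_idx[:-1]))
        if emit_tables:
            for substrate, child_act, parent_act in (
                (SUBSTRATE_OLD, new_old, current_old),
                (SUBSTRATE_NEW, new_new, current_new),
            ):
                records += measure(
                    child_act, config, meas_rng, child, parent, geno, substrate,
                    batch_prefix=f"r{rnd}b", dataset=dataset,
                )
                records += measure(
                    parent_act, config, meas_rng, parent,
                    traj_rows[rnd - 1]["parent_id"], parent_geno, substrate,
                    batch_prefix=f"r{rnd}b", dataset=dataset,
                )
        current_old, current_new = new_old, new_new
        traj_rows.append({"round": rnd, "variant_id": child, "parent_id": parent})
        genotypes.append(tuple(muts))
        true_old.append(new_old)
        true_new.append(new_new)

    table = (
        table_from_records(records, SUBSTRATE_ROLES, dataset=dataset)
        if emit_tables
        else None
    )
    trajectory = pd.DataFrame(traj_rows, columns=["round", "variant_id", "parent_id"])
    truth = SimTruth(
        effects=effects,
        interactions=interactions,
        genotypes=genotypes,
        true_old=np.array(true_old),
        true_new=np.array(true_new),
        screened=screened_rounds,
    )
    return WalkResult(table=table, trajectory=trajectory, truth=truth)


def simulate_library(
    config: SimConfig,
    n_variants: int = 435,
    reference_id: str = "wt",
) -> tuple[ActivityTable, pd.DataFrame]:
    """Simulate a random single-mutant library measured against a reference.

    Each variant carries one mutation with true effects drawn from the
    configured bivariate distribution; the reference is re-measured alongside
    every variant in shared batches (as on a screening plate), so each
    variant/reference comparison is paired and independent of the others.
    Returns the activity table and the per-variant truth frame.
    """
    # the walk-regime fields are irrelevant for a one-mutant-per-variant
    # library; neutralize them so any library size is feasible
    lib_config = replace(config, n_candidate_pool=n_variants, m_per_round=1, n_rounds=0)
    eff_rng = _stream(config, 11)
    meas_rng = _stream(config, 12)
    effects, _ = sample_effects(lib_config, eff_rng)
    dataset = f"library_seed{config.seed}"
    records: list[ActivityRecord] = []
    width = len(str(n_variants))
    ids = []
    for i, row in enumerate(effects.itertuples(index=False)):
        vid = f"v{i + 1:0{width}d}"
        ids.append(vid)
        prefix = f"{vid}.b"
        for substrate, true_act in (
            (SUBSTRATE_OLD, 10.0**row.true_log10_old),
            (SUBSTRATE_NEW, 10.0**row.true_log10_new),
        ):
            records += measure(
                true_act, config, meas_rng, vid, reference_id, row.mutation,
                substrate, batch_prefix=prefix, dataset=dataset,
            )
            records += measure(
                1.0, config, meas_rng, reference_id, "", "", substrate,
                batch_prefix=prefix, dataset=dataset,
            )
    table = table_from_records(records, SUBSTRATE_ROLES, dataset=dataset)
    truth = effects.copy()
    truth.insert(0, "variant_id", ids)
    return table, truth


def write_truth(truth: SimTruth, out_dir: str | Path) -> None:
    """Serialize ground truth as the TSV dialect (effects + interactions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.effects.to_csv(out / "truth_effects.tsv", sep="\t", index=False)
    truth.interactions.to_csv(out / "truth_interactions.tsv", sep="\t", index=False)
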