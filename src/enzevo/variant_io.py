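"""Data model and I/O for variant activity measurements.

The central objects are amino-acid :class:`Mutation`\\ s, :class:`Genotype`\\ s
(sets of mutations relative to a reference protein), and per-replicate
:class:`ActivityRecord`\\ s.  Measurements arrive as tab-delimited tables with
one row per (variant, substrate, batch, replicate); initial rates are
normalized to cell density (OD600) and may be censored at a detection limit.

Censoring is encoded as an explicit flag plus bound rather than a sentinel
value, because bounds must propagate through downstream fold-change products.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

CENSOR_STATES = ("none", "below", "above")

#: Canonical column order of the activity-table dialect.
ACTIVITY_COLUMNS = (
    "dataset",
    "variant_id",
    "parent_id",
    "genotype",
    "substrate",
    "batch",
    "replicate",
    "rate",
    "od600",
    "detection_limit",
    "censor",
)

TRAJECTORY_COLUMNS = ("round", "variant_id", "parent_id")

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class VariantIOError(ValueError):
    """Malformed input: bad mutation token, table row, or genotype."""


class MutationParseError(VariantIOError):
    pass


@dataclass(frozen=True, order=True)
class Mutation:
    """A single amino-acid substitution, 1-based over the mature protein.

    ``from_aa`` is the residue being replaced and ``to_aa`` the residue
    introduced; direction is stored explicitly (the typographic convention of
    marking one side by case does not survive plain text).
    """

    position: int
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")
        for aa in (self.from_aa, self.to_aa):
            if aa not in _AA_SET:
                raise MutationParseError(f"{aa!r} is not one of the 20 amino acids")
        if self.from_aa == self.to_aa:
            raise MutationParseError(
                f"identity substitution {self.from_aa}{self.position}{self.to_aa}"
            )

    @property
    def label(self) -> str:
        """Canonical token, e.g. ``A80V``."""
        return f"{self.from_aa}{self.position}{self.to_aa}"

    def reversed(self) -> "Mutation":
        """The reverting substitution at the same site."""
        return Mutation(self.position, self.to_aa, self.from_aa)


def parse_mutation(token: str, direction_convention: str = "forward") -> Mutation:
    """Parse a mutation token such as ``a80V`` (case-insensitive).

    ``direction_convention`` records which side of the token is the parental
    residue: under ``forward`` the first letter is the parent (e.g. wild-type)
    residue; under ``revertant`` the first letter is the evolved residue being
    reverted and the last the ancestral one.  Either way the first letter maps
    to ``from_aa`` and the last to ``to_aa`` — the convention documents the
    reading, it does not change the stored direction.
    """
    if direction_convention not in ("forward", "revertant"):
        raise ValueError(f"unknown direction convention {direction_convention!r}")
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise MutationParseError(f"malformed mutation token {token!r}")
    from_aa, pos, to_aa = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    try:
        return Mutation(pos, from_aa, to_aa)
    except MutationParseError as exc:
        raise MutationParseError(f"invalid mutation token {token!r}: {exc}") from None


def format_mutation(mutation: Mutation) -> str:
    return mutation.label


def parse_genotype(text: str, direction_convention: str = "forward") -> tuple[Mutation, ...]:
    """Parse a semicolon-joined genotype string into sorted mutations."""
    text = text.strip()
    if not text:
        return ()
    muts = tuple(
        sorted(parse_mutation(tok, direction_convention) for tok in text.split(";") if tok.strip())
    )
    positions = [m.position for m in muts]
    if len(set(positions)) != len(positions):
        raise VariantIOError(f"genotype {text!r} has multiple mutations at one position")
    return muts


def format_genotype(mutations: Sequence[Mutation]) -> str:
    return ";".join(m.label for m in sorted(mutations))


@dataclass(frozen=True)
class Genotype:
    """A variant's mutations relative to a named reference protein."""

    reference_id: str
    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations))
        object.__setattr__(self, "mutations", muts)
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            raise VariantIOError("two mutations share a position")

    @classmethod
    def from_string(cls, text: str, reference_id: str = "") -> "Genotype":
        return cls(reference_id, parse_genotype(text))

    def __len__(self) -> int:
        return len(self.mutations)


def validate_genotype(genotype: Genotype, reference: str) -> list[str]:
    """Check each mutation's parental residue against a reference sequence.

    Returns a list of human-readable violations (empty when consistent);
    out-of-range positions are reported as violations, not exceptions.
    """
    violations: list[str] = []
    n = len(reference)
    for m in genotype.mutations:
        if m.position > n:
            violations.append(
                f"{m.label}: position {m.position} beyond reference length {n}"
            )
        elif reference[m.position - 1].upper() != m.from_aa:
            violations.append(
                f"{m.label}: reference has {reference[m.position - 1].upper()} "
                f"at position {m.position}, not {m.from_aa}"
            )
    return violations


def read_reference_fasta(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file as ``(id, sequence)``."""
    from Bio import SeqIO

    for record in SeqIO.parse(str(path), "fasta"):
        return record.id, str(record.seq).upper()
    raise VariantIOError(f"no FASTA records in {path}")


# ---------------------------------------------------------------------------
# Activity records and tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityRecord:
    """One replicate activity measurement.

    ``rate`` is an initial rate in arbitrary units; when ``od600`` is present
    the normalized activity is ``rate / od600``.  ``batch`` is the pairing key
    that links a variant's replicates with its parent's replicates measured in
    the same growth/expression/assay set.
    """

    variant_id: str
    parent_id: str
    substrate: str
    batch: str
    replicate: int
    rate: float
    od600: float | None = None
    detection_limit: float | None = None
    censor: str = "none"
    genotype: str = ""
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise VariantIOError(f"negative rate {self.rate} for {self.variant_id}")
        if self.censor not in CENSOR_STATES:
            raise VariantIOError(f"censor must be one of {CENSOR_STATES}, got {self.censor!r}")
        if self.censor != "none" and self.detection_limit is None:
            raise VariantIOError(
                f"{self.variant_id}: censor flag {self.censor!r} without a detection limit"
            )
        if self.censor == "below" and self.detection_limit is not None:
            if self.rate > self.detection_limit:
                raise VariantIOError(
                    f"{self.variant_id}: below-censored rate {self.rate} exceeds "
                    f"detection limit {self.detection_limit}"
                )
        if self.od600 is not None and self.od600 <= 0:
            raise VariantIOError(f"{self.variant_id}: OD600 must be positive, got {self.od600}")


def normalize_activity(record: ActivityRecord) -> float:
    """Cell-density-normalized activity: ``rate / od600``.

    A missing OD600 means the rate is treated as already normalized.  Censor
    semantics are preserved by the caller: for a below-censored record the
    returned value is an upper bound on the true activity.
    """
    if record.od600 is None:
        return record.rate
    if record.od600 <= 0:
        raise VariantIOError(f"OD600 must be positive, got {record.od600}")
    return record.rate / record.od600


def normalized_detection_limit(record: ActivityRecord) -> float | None:
    if record.detection_limit is None:
        return None
    if record.od600 is None:
        return record.detection_limit
    return record.detection_limit / record.od600


@dataclass
class ActivityTable:
    """A validated collection of activity records plus substrate-role metadata.

    ``substrate_roles`` maps the roles ``"native"`` and ``"new"`` onto the two
    substrate labels occurring in the table.  ``external_anchors`` lists
    parent ids that are legitimately absent from the table (e.g. a reference
    enzyme measured elsewhere).
    """

    frame: pd.DataFrame
    substrate_roles: dict[str, str] = field(default_factory=dict)
    dataset: str = ""
    external_anchors: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = [c for c in ACTIVITY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise VariantIOError(f"activity table missing columns: {missing}")
        self.frame = self.frame.loc[:, list(ACTIVITY_COLUMNS)].reset_index(drop=True)
        substrates = sorted(self.frame["substrate"].unique())
        if not self.substrate_roles:
            # Fall back to order of first appearance: first substrate = native.
            seen = list(dict.fromkeys(self.frame["substrate"]))
            if len(seen) == 2:
                self.substrate_roles = {"native": seen[0], "new": seen[1]}
                logger.info(
                    "substrate roles not given; assuming native=%r, new=%r",
                    seen[0], seen[1],
                )
        if self.substrate_roles:
            if set(self.substrate_roles) != {"native", "new"}:
                raise VariantIOError("substrate_roles must map exactly 'native' and 'new'")
            unknown = set(self.substrate_roles.values()) - set(substrates)
            if unknown:
                raise VariantIOError(f"substrate roles name unknown substrates: {sorted(unknown)}")
        known = set(self.frame["variant_id"]) | set(self.external_anchors)
        orphans = sorted(
            set(self.frame["parent_id"]) - known - {""}
        )
        if orphans:
            raise VariantIOError(
                f"parent ids never measured and not declared as anchors: {orphans}"
            )
        if (self.frame["od600"].isna()).any() and not self.frame["od600"].isna().all():
            logger.warning("table %s: some rows lack OD600; their rates are used as-is", self.dataset)

    @property
    def substrates(self) -> list[str]:
        return sorted(self.frame["substrate"].unique())

    def records(self, variant_id: str | None = None, substrate: str | None = None) -> list[ActivityRecord]:
        """Materialize (a slice of) the table as ActivityRecord objects."""
        df = self.frame
        if variant_id is not None:
            df = df[df["variant_id"] == variant_id]
        if substrate is not None:
            df = df[df["substrate"] == substrate]
        return [_row_to_record(row) for row in df.itertuples(index=False)]

    def variants(self) -> list[str]:
        return list(dict.fromkeys(self.frame["variant_id"]))

    def genotype_of(self, variant_id: str) -> tuple[Mutation, ...]:
        sub = self.frame.loc[self.frame["variant_id"] == variant_id, "genotype"]
        if sub.empty:
            raise VariantIOError(f"unknown variant {variant_id!r}")
        return parse_genotype(sub.iloc[0])


def _row_to_record(row) -> ActivityRecord:
    def _opt(x):
        return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)

    return ActivityRecord(
        variant_id=row.variant_id,
        parent_id=row.parent_id,
        substrate=row.substrate,
        batch=row.batch,
        replicate=int(row.replicate),
        rate=float(row.rate),
        od600=_opt(row.od600),
        detection_limit=_opt(row.detection_limit),
        censor=row.censor,
        genotype=row.genotype,
        dataset=row.dataset,
    )


def table_from_records(
    records: Iterable[ActivityRecord],
    substrate_roles: Mapping[str, str] | None = None,
    dataset: str = "",
    external_anchors: Iterable[str] = (),
) -> ActivityTable:
    rows = []
    for r in records:
        rows.append(
            {
                "dataset": r.dataset or dataset,
                "variant_id": r.variant_id,
                "parent_id": r.parent_id,
                "genotype": r.genotype,
                "substrate": r.substrate,
                "batch": r.batch,
                "replicate": r.replicate,
                "rate": r.rate,
                "od600": math.nan if r.od600 is None else r.od600,
                "detection_limit": math.nan if r.detection_limit is None else r.detection_limit,
                "censor": r.censor,
            }
        )
    frame = pd.DataFrame(rows, columns=list(ACTIVITY_COLUMNS))
    return ActivityTable(
        frame,
        dict(substrate_roles) if substrate_roles else {},
        dataset=dataset,
        external_anchors=frozenset(external_anchors),
    )


_STRING_COLS = ["dataset", "variant_id", "parent_id", "genotype", "substrate", "batch", "censor"]


def read_activity_table(
    path: str | Path | io.TextIOBase,
    substrate_roles: Mapping[str, str] | None = None,
    external_anchors: Iterable[str] = (),
) -> ActivityTable:
    """Read the tab-delimited activity dialect, validating every row.

    Raises :class:`VariantIOError` naming the first offending row (1-based,
    counting the header as row 0).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in _STRING_COLS},
        na_values=["NA"],
        keep_default_na=False,
    )
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise VariantIOError(f"activity table missing mandatory columns: {missing}")
    for col in _STRING_COLS:
        df[col] = df[col].fillna("")
    df["censor"] = df["censor"].replace("", "none")
    for col in ("rate", "od600", "detection_limit"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            _row_to_record(row)
        except (VariantIOError, ValueError) as exc:
            raise VariantIOError(f"row {i}: {exc}") from None
    dataset = df["dataset"].iloc[0] if len(df) else ""
    return ActivityTable(
        df,
        dict(substrate_roles) if substrate_roles else {},
        dataset=dataset,
        external_anchors=frozenset(external_anchors),
    )


def _fmt_num(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.12g}"


def write_activity_table(table: ActivityTable, path: str | Path | io.TextIOBase) -> None:
    """Write the canonical (sorted, NA-encoded) TSV form of a table."""
    df = table.frame.sort_values(
        ["dataset", "variant_id", "substrate", "batch", "replicate"], kind="mergesort"
    )
    lines = ["\t".join(ACTIVITY_COLUMNS)]
    for row in df.itertuples(index=False):
        lines.append(
            "\t".join(
                [
                    row.dataset,
                    row.variant_id,
                    row.parent_id,
                    row.genotype,
                    row.substrate,
                    row.batch,
                    str(int(row.replicate)),
                    _fmt_num(row.rate),
                    _fmt_num(row.od600),
                    _fmt_num(row.detection_limit),
                    row.censor,
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text, encoding="utf-8")
    else:
        path.write(text)


def read_trajectory_table(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a ``round, variant_id, parent_id`` TSV, sorted by round."""
    df = pd.read_csv(
        path, sep="\t", dtype={"variant_id": str, "parent_id": str},
        na_values=["NA"], keep_default_na=False,
    )
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise VariantIOError(f"trajectory table missing columns: {missing}")
    df["parent_id"] = df["parent_id"].fillna("")
    df["round"] = pd.to_numeric(df["round"], errors="raise").astype(int)
    df = df.sort_values("round", kind="mergesort").reset_index(drop=True)
    if df["round"].duplicated().any():
        raise VariantIOError("trajectory table has duplicate round indices")
    return df.loc[:, list(TRAJECTORY_COLUMNS)]


def write_trajectory_table(trajectory: pd.DataFrame, path: str | Path | io.TextIOBase) -> None:
    df = trajectory.loc[:, list(TRAJECTORY_COLUMNS)].sort_values("round", kind="mergesort")
    text = "\n".join(
        ["\t".join(TRAJECTORY_COLUMNS)]
        + ["\t".join([str(int(r.round)), r.variant_id, r.parent_id]) for r in df.itertuples(index=False)]
    ) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text, encoding="utf-8")
    else:
        path.write(text)
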