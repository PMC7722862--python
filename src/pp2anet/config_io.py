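"""Data model, readers/writers, and validation for the analysis inputs.

The pipeline consumes three kinds of input:

* per-subunit co-expression tables — one row per observed
  (gene, subunit member, stress) triple with a Pearson correlation score;
* promoter sequences (FASTA), nominally 1 kb upstream of the TSS;
* motif tables mapping a motif name to an IUPAC nucleotide pattern.

All gene identifiers are treated as opaque strings: no probe-id to locus-id
mapping is attempted, since that requires an external annotation resource.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "IUPAC_TO_BASES",
    "IUPAC_COMPLEMENT",
    "StressSet",
    "SubunitConfig",
    "CoexpressionRecord",
    "CoexpressionTable",
    "PromoterSet",
    "Motif",
    "RunConfig",
    "TableFormatError",
    "ValidationError",
    "DEFAULT_STRESSES",
    "default_subunits",
    "load_coexpression_table",
    "write_coexpression_table",
    "load_promoters",
    "load_motif_table",
    "write_motif_table",
    "load_run_config",
]

#: The 15 IUPAC nucleotide ambiguity codes and the concrete bases each allows.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Complement map over the full IUPAC alphabet (W, S and N are self-complementary).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


class TableFormatError(ValueError):
    """A file cannot be parsed under the expected tabular dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class StressSet:
    """Ordered set of stress condition labels with fixed 1-based integer codes.

    The integer codes are what the clustering stage uses as the first feature
    axis, so the ordering is part of the data model, not a display choice.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("stress labels must be unique")
        if not self.names:
            raise ValidationError("stress set cannot be empty")

    @property
    def codes(self) -> dict[str, int]:
        return {name: i + 1 for i, name in enumerate(self.names)}

    def code(self, name: str) -> int:
        try:
            return self.codes[name]
        except KeyError:
            raise ValidationError(f"unknown stress label {name!r}") from None

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)


#: The seven stresses in the fixed code order 1..7 used throughout.
DEFAULT_STRESSES = StressSet(
    ("Cold", "Heat", "Genotoxic", "Drought", "Salt", "Osmotic", "Wounding")
)


@dataclass(frozen=True)
class SubunitConfig:
    """Subunit name -> ordered member labels (e.g. the PP2A scaffold subunit A
    has five member genes A_1..A_5)."""

    subunits: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for subunit, members in self.subunits.items():
            if len(set(members)) != len(members):
                raise ValidationError(
                    f"member labels within subunit {subunit!r} must be unique"
                )

    def members(self, subunit: str) -> tuple[str, ...]:
        try:
            return tuple(self.subunits[subunit])
        except KeyError:
            raise ValidationError(f"unknown subunit {subunit!r}") from None

    def names(self) -> tuple[str, ...]:
        return tuple(self.subunits)


def default_subunits() -> SubunitConfig:
    """The PP2A trimer layout: scaffold A (5 members), regulatory B (10),
    catalytic C (2)."""
    return SubunitConfig(
        {
            "A": tuple(f"A_{i}" for i in range(1, 6)),
            "B": tuple(f"B_{i}" for i in range(1, 11)),
            "C": tuple(f"C_{i}" for i in range(1, 3)),
        }
    )


class CoexpressionRecord(NamedTuple):
    """One (gene, subunit member, stress) observation with its Pearson score."""

    gene_id: str
    subunit: str
    member: str
    stress: str
    score: float


@dataclass
class CoexpressionTable:
    """A validated collection of co-expression records.

    The key (gene_id, subunit, member, stress) is unique within a table; the
    score is a Pearson correlation in [-1, 1].
    """

    records: list[CoexpressionRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CoexpressionRecord]:
        return iter(self.records)

    def for_subunit(self, subunit: str) -> "CoexpressionTable":
        return CoexpressionTable(
            [r for r in self.records if r.subunit == subunit],
            provenance=self.provenance,
        )

    def gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.records}

    def scores(self) -> list[float]:
        return [r.score for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["gene_id", "subunit", "member", "stress", "score"]
        )

    def validate(self, stresses: StressSet, config: SubunitConfig) -> None:
        seen: Counter = Counter()
        for r in self.records:
            if not (-1.0 <= r.score <= 1.0) or math.isnan(r.score):
                raise ValidationError(
                    f"score {r.score} out of [-1, 1] for record {r[:4]}"
                )
            if r.stress not in stresses:
                raise ValidationError(f"unknown stress {r.stress!r} in record {r[:4]}")
            if r.member not in config.members(r.subunit):
                raise ValidationError(
                    f"member {r.member!r} not part of subunit {r.subunit!r}"
                )
            seen[r[:4]] += 1
        dupes = [k for k, n in seen.items() if n > 1]
        if dupes:
            raise ValidationError(f"duplicate record keys: {dupes[:5]}")


_TABLE_COLUMNS = ("gene_id", "subunit", "member", "stress", "score")


def load_coexpression_table(
    path: str | Path, stresses: StressSet, config: SubunitConfig
) -> CoexpressionTable:
    """Read and validate a TSV co-expression table.

    The dialect is fixed: tab-separated with the mandatory header
    ``gene_id\\tsubunit\\tmember\\tstress\\tscore``. Every row is checked
    against the stress set and subunit membership; duplicate keys and
    out-of-range scores are rejected. Errors name the offending line.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != _TABLE_COLUMNS:
            expected = "\t".join(_TABLE_COLUMNS)
            raise TableFormatError(
                f"{path}: expected header {expected!r}, got {header!r}"
            )
        records: list[CoexpressionRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise TableFormatError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            gene_id, subunit, member, stress, score_text = parts
            try:
                score = float(score_text)
            except ValueError:
                raise TableFormatError(
                    f"{path}:{lineno}: score {score_text!r} is not a number"
                ) from None
            if not (-1.0 <= score <= 1.0):
                raise ValidationError(
                    f"{path}:{lineno}: score {score_text} outside [-1, 1]"
                )
            records.append(CoexpressionRecord(gene_id, subunit, member, stress, score))
    table = CoexpressionTable(records, provenance=str(path))
    table.validate(stresses, config)
    return table


def write_coexpression_table(table: CoexpressionTable, path: str | Path) -> None:
    """Write a TSV that :func:`load_coexpression_table` reads back identically.

    Scores are serialised with ``repr`` so the float round-trips bit-for-bit.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for r in table.records:
            fh.write(f"{r.gene_id}\t{r.subunit}\t{r.member}\t{r.stress}\t{r.score!r}\n")


@dataclass
class PromoterSet:
    """Uppercased promoter sequences keyed by gene id.

    ``short`` lists genes whose sequence is shorter than ``target_length``
    (default 1 kb). Short promoters are accepted and flagged rather than
    rejected: the fixed upstream window is an extraction convention, not a
    validity constraint.
    """

    sequences: dict[str, str]
    target_length: int = 1000
    short: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.short = frozenset(
            g for g, s in self.sequences.items() if len(s) < self.target_length
        )

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def items(self):
        return self.sequences.items()


_PROMOTER_ALPHABET = frozenset("ACGTN")


def load_promoters(path: str | Path, target_length: int = 1000) -> PromoterSet:
    """Load a FASTA promoter file.

    The gene id is the first whitespace-delimited token of each header;
    sequences are uppercased. Duplicate ids and empty sequences are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in sequences:
            raise ValidationError(f"{path}: duplicate gene id {record.id!r}")
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {record.id!r}")
        bad = set(seq) - _PROMOTER_ALPHABET
        if bad:
            raise ValidationError(
                f"{path}: sequence for {record.id!r} has non-ACGTN characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    return PromoterSet(sequences, target_length=target_length)


@dataclass(frozen=True)
class Motif:
    """A named cis-regulatory element expressed as an IUPAC nucleotide pattern."""

    name: str
    pattern: str
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError(f"motif {self.name!r}: empty pattern")
        bad = set(self.pattern) - set(IUPAC_TO_BASES)
        if bad:
            raise ValidationError(
                f"motif {self.name!r}: non-IUPAC characters {sorted(bad)} in pattern"
            )

    def __len__(self) -> int:
        return len(self.pattern)


def load_motif_table(path: str | Path) -> list[Motif]:
    """Read a TSV of (name, pattern[, description]) motif rows.

    A leading header row ``name<TAB>pattern[...]`` is tolerated and skipped.
    Patterns are validated as IUPAC; names must be unique.
    """
    path = Path(path)
    motifs: list[Motif] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "name":
                continue
            if len(parts) < 2:
                raise TableFormatError(
                    f"{path}:{lineno}: expected at least name and pattern fields"
                )
            name, pattern = parts[0].strip(), parts[1].strip().upper()
            description = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
            try:
                motifs.append(Motif(name, pattern, description))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate motif names")
    return motifs


def write_motif_table(motifs: Sequence[Motif], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("name\tpattern\tdescription\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\t{m.description or ''}\n")


@dataclass
class RunConfig:
    """A whole-run configuration loaded from one YAML file."""

    stresses: StressSet = DEFAULT_STRESSES
    subunits: SubunitConfig = field(default_factory=default_subunits)
    threshold_mode: str = "pooled"
    strands: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("pooled", "per_stress"):
            raise ValidationError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.strands not in ("forward", "both"):
            raise ValidationError(f"unknown strand mode {self.strands!r}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration; omitted keys fall back to the defaults."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "stresses" in raw:
        kwargs["stresses"] = StressSet(tuple(raw["stresses"]))
    if "subunits" in raw:
        kwargs["subunits"] = SubunitConfig(
            {k: tuple(v) for k, v in raw["subunits"].items()}
        )
    for key in ("threshold_mode", "strands", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)
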