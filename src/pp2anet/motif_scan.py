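"""IUPAC motif scanning of promoters, hit clubbing, and CRE summaries.

Scanning tests every start position of the supplied sequence against the
IUPAC pattern (overlapping matches all count — the permissive reading that
short 4-mer elements require). An ``N`` in the *sequence* matches only an
``N`` in the pattern: unknown bases never inflate counts. In ``both`` strand
mode the reverse complement of the pattern is additionally tested against
the supplied strand and reported with strand ``-``; a self-complementary
pattern (CACGTG and friends) would match at the same start on both strands,
so those duplicates are reported once with strand ``+``.

"Clubbing" is the deduplication step applied to per-gene hits: hits sharing
(motif name, pattern, strand) collapse into one group whose frequency is its
number of distinct start locations. The per-gene x per-motif frequency
matrix feeds two summaries: the *common* motifs (present at least once in
every gene analysed) and the *unique* ones (grand total exactly 1 across the
whole gene set, tagged with their single gene).

Coordinates are 1-based on the supplied upstream sequence; when a full 1-kb
promoter is given, position 1 is -1000 relative to the TSS, and the reported
``tss_offset`` is ``start - len(seq) - 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .config_io import (
    IUPAC_COMPLEMENT,
    IUPAC_TO_BASES,
    Motif,
    PromoterSet,
    ValidationError,
)

__all__ = [
    "MotifLibrary",
    "MotifHit",
    "ClubbedHits",
    "MotifFrequencyMatrix",
    "MotifSummary",
    "builtin_motif_library",
    "reverse_complement_pattern",
    "scan_sequence",
    "club_hits",
    "scan_promoters",
    "summarize_common_unique",
    "write_hits_tsv",
]

# The 16 stress-associated cis-regulatory elements recurrent in the promoters
# of the hub genes, with their PLACE IUPAC patterns. Two pairs intentionally
# share a pattern under different names (EBOXBNNAPA/MYCCONSENSUSAT and
# NODCON2GM/OSE2ROOTNODULE).
_BUILTIN = (
    ("ARR1AT", "NGATT", "cytokinin response regulator ARR1 binding element"),
    ("CAATBOX1", "CAAT", "CAAT promoter consensus"),
    ("CACTFTPPCA1", "CACGTG", "mesophyll expression module / G-box core"),
    ("DOFCOREZM", "AAAG", "Dof transcription factor core site"),
    ("EBOXBNNAPA", "CANNTG", "E-box, ABA responsive"),
    ("GATABOX", "GATA", "light regulation / tissue-specific GATA box"),
    ("GT1CONSENSUS", "GRWAAW", "GT-1 binding site of light-regulated genes"),
    ("GT1GMSCAM4", "GAAAAA", "GT-1 site, pathogen/salt induced"),
    ("GTGANTG10", "GTGA", "late pollen gene g10 GTGA motif"),
    ("IBOXCORE", "GATAA", "I-box core of light-regulated promoters"),
    ("MYCCONSENSUSAT", "CANNTG", "MYC recognition site, dehydration/cold"),
    ("NODCON2GM", "CTCTT", "nodulin consensus sequence 2"),
    ("OSE2ROOTNODULE", "CTCTT", "organ-specific element of root nodules"),
    ("POLLEN1LELAT52", "AGAAA", "pollen-specific activation element"),
    ("TAAAGSTKST1", "TAAAG", "guard cell-specific Dof target"),
    ("WRKY71OS", "TGAC", "WRKY W-box core"),
)


@dataclass
class MotifLibrary:
    """An ordered, name-unique collection of motifs."""

    motifs: tuple[Motif, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValidationError("motif names must be unique within a library")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, name: str) -> Motif:
        for m in self.motifs:
            if m.name == name:
                return m
        raise KeyError(name)

    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.motifs)


def builtin_motif_library() -> MotifLibrary:
    """The 16 built-in cis-regulatory elements."""
    return MotifLibrary(tuple(Motif(n, p, d) for n, p, d in _BUILTIN))


def reverse_complement_pattern(pattern: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern))


class MotifHit(NamedTuple):
    """One match of a motif in one promoter.

    ``start`` is 1-based on the supplied sequence. For strand ``-`` the
    reverse complement of ``matched`` fits the motif's pattern.
    """

    gene_id: str
    motif: str
    start: int
    strand: str
    matched: str


def _window_matches(window: str, pattern: str) -> bool:
    return all(
        (p == "N") if (s == "N") else (s in IUPAC_TO_BASES[p])
        for s, p in zip(window, pattern)
    )


def scan_sequence(
    seq: str, motif: Motif, strands: str = "both", gene_id: str = ""
) -> list[MotifHit]:
    """All matches of one motif in one sequence.

    Every start position is tested, so overlapping occurrences are all
    reported. A pattern longer than the sequence yields no hits.
    """
    if strands not in ("forward", "both"):
        raise ValidationError(f"unknown strand mode {strands!r}")
    pattern = motif.pattern
    m = len(pattern)
    hits: list[MotifHit] = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if _window_matches(window, pattern):
            hits.append(MotifHit(gene_id, motif.name, i + 1, "+", window))
    if strands == "both":
        rc = reverse_complement_pattern(pattern)
        if rc != pattern:  # self-complementary: minus-strand hits duplicate plus
            for i in range(len(seq) - m + 1):
                window = seq[i : i + m]
                if _window_matches(window, rc):
                    hits.append(MotifHit(gene_id, motif.name, i + 1, "-", window))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass(frozen=True)
class ClubbedHits:
    """Hits of one gene collapsed over (motif name, pattern, strand)."""

    gene_id: str
    motif: str
    pattern: str
    strand: str
    starts: tuple[int, ...]

    @property
    def frequency(self) -> int:
        return len(self.starts)


def club_hits(hits: Sequence[MotifHit], pattern_of: dict[str, str]) -> list[ClubbedHits]:
    """Deduplicate one gene's hits into (motif, pattern, strand) groups.

    The group frequency is the number of distinct start locations; the
    distinct starts themselves are kept on the group record.
    """
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise ValidationError("club_hits expects hits from a single gene")
    groups: dict[tuple[str, str, str], set[int]] = {}
    for h in hits:
        key = (h.motif, pattern_of[h.motif], h.strand)
        groups.setdefault(key, set()).add(h.start)
    gene = genes.pop() if genes else ""
    return [
        ClubbedHits(gene, motif, pattern, strand, tuple(sorted(starts)))
        for (motif, pattern, strand), starts in sorted(groups.items())
    ]


@dataclass
class MotifFrequencyMatrix:
    """Per-gene x per-motif deduplicated occurrence counts."""

    genes: tuple[str, ...]
    motifs: tuple[str, ...]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def count(self, gene: str, motif: str) -> int:
        return self.counts.get((gene, motif), 0)

    def motif_total(self, motif: str) -> int:
        return sum(self.count(g, motif) for g in self.genes)

    def grand_total(self) -> int:
        return sum(self.counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(0, index=list(self.genes), columns=list(self.motifs))
        for (g, m), c in self.counts.items():
            df.loc[g, m] = c
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")


def scan_promoters(
    promoters: PromoterSet, library: MotifLibrary, strands: str = "both"
) -> tuple[list[MotifHit], MotifFrequencyMatrix]:
    """Scan every promoter against every library motif.

    Returns the concatenated hit list and the frequency matrix built from
    the clubbed (deduplicated) hits; since scanning already emits each
    (motif, strand, start) site once, the matrix equals the per-(gene,
    motif) hit counts.
    """
    if len(promoters) == 0:
        return [], MotifFrequencyMatrix(genes=(), motifs=library.names())
    pattern_of = {m.name: m.pattern for m in library}
    all_hits: list[MotifHit] = []
    matrix = MotifFrequencyMatrix(
        genes=tuple(promoters.sequences), motifs=library.names()
    )
    for gene, seq in promoters.items():
        gene_hits: list[MotifHit] = []
        for motif in library:
            gene_hits.extend(scan_sequence(seq, motif, strands=strands, gene_id=gene))
        for group in club_hits(gene_hits, pattern_of):
            key = (gene, group.motif)
            matrix.counts[key] = matrix.counts.get(key, 0) + group.frequency
        all_hits.extend(gene_hits)
    return all_hits, matrix


@dataclass
class MotifSummary:
    """Common (present in every gene) and unique (grand total 1) motifs."""

    common: frozenset[str]
    unique: dict[str, str]  # motif -> its single gene

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"common": sorted(self.common), "unique": dict(sorted(self.unique.items()))},
                indent=1,
            )
        )


def summarize_common_unique(matrix: MotifFrequencyMatrix) -> MotifSummary:
    """Classify motifs as common across all genes or unique to one site."""
    if not matrix.genes:
        raise ValidationError("frequency matrix covers no genes")
    common = frozenset(
        m for m in matrix.motifs if all(matrix.count(g, m) >= 1 for g in matrix.genes)
    )
    unique: dict[str, str] = {}
    for m in matrix.motifs:
        if matrix.motif_total(m) == 1:
            gene = next(g for g in matrix.genes if matrix.count(g, m) == 1)
            unique[m] = gene
    return MotifSummary(common=common, unique=unique)


def write_hits_tsv(
    hits: Sequence[MotifHit],
    library: MotifLibrary,
    promoters: PromoterSet,
    path: str | Path,
) -> None:
    """Hit table with TSS-relative offsets (position 1 = -len(seq) upstream)."""
    pattern_of = {m.name: m.pattern for m in library}
    with Path(path).open("w") as fh:
        fh.write("gene_id\tmotif\tpattern\tstart\tstrand\tmatched\ttss_offset\n")
        for h in hits:
            offset = h.start - len(promoters[h.gene_id]) - 1
            fh.write(
                f"{h.gene_id}\t{h.motif}\t{pattern_of[h.motif]}\t{h.start}\t"
                f"{h.strand}\t{h.matched}\t{offset}\n"
            )
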