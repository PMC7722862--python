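"""Synthetic co-expression tables and promoters with planted ground truth.

Real inputs to this pipeline are Pearson co-expression scores of thousands of
Arabidopsis genes against PP2A subunit members under seven stresses, plus 1-kb
upstream promoter sequences. Neither can ship with the package, so this module
generates stand-ins whose structure is known exactly:

* background scores are drawn from a truncated normal on [-1, 1], one
  location/scale pair per (subunit, stress) — emulating the per-stress
  box-plot structure of real per-subunit score distributions;
* "hub" genes are planted with a deterministic above-location score in every
  (subunit, member, stress) slot, so the downstream centrality/intersection
  machinery has an exact expected answer;
* promoters are i.i.d. background at a chosen GC content with motif instances
  written at known positions; with ``avoid_background`` the background is
  resampled until no stray match of any planted pattern remains, making the
  planted counts exact on both strands.

One integer seed drives each generator; the contract is same-seed,
same-version reproducibility, not cross-platform bit stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .config_io import (
    DEFAULT_STRESSES,
    IUPAC_COMPLEMENT,
    IUPAC_TO_BASES,
    CoexpressionRecord,
    CoexpressionTable,
    Motif,
    PromoterSet,
    StressSet,
    SubunitConfig,
    ValidationError,
    default_subunits,
)

__all__ = [
    "SyntheticSpec",
    "MotifPlanting",
    "GroundTruth",
    "generate_coexpression",
    "generate_promoters",
]

# Default per-subunit score locations: C sits above B above A, mirroring the
# ordering seen in real per-subunit distributions; one shared spread.
_DEFAULT_LOCATIONS = {"A": 0.15, "B": 0.25, "C": 0.35}
_DEFAULT_SCALE = 0.2


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic co-expression table.

    ``score_distributions`` maps (subunit, stress) to a (location, scale)
    pair of the truncated normal; missing pairs fall back to a per-subunit
    default location and common scale. ``coverage`` is the probability that a
    background (gene, member, stress) record exists at all; planted hubs are
    always fully covered and receive the deterministic score
    ``location + hub_offset`` clipped to 1.
    """

    n_genes: int
    stresses: StressSet = DEFAULT_STRESSES
    config: SubunitConfig = field(default_factory=default_subunits)
    score_distributions: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    coverage: float = 0.8
    planted_hubs: tuple[str, ...] = ()
    hub_offset: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValidationError("n_genes must be non-negative")
        if self.n_genes < len(self.planted_hubs):
            raise ValidationError(
                f"n_genes={self.n_genes} is smaller than the "
                f"{len(self.planted_hubs)} planted hubs"
            )
        if not (0.0 < self.coverage <= 1.0):
            raise ValidationError("coverage must lie in (0, 1]")
        if self.hub_offset <= 0:
            raise ValidationError("hub_offset must be positive")
        for (subunit, stress), (loc, scale) in self.score_distributions.items():
            if not (-1.0 < loc < 1.0):
                raise ValidationError(
                    f"location {loc} for ({subunit}, {stress}) outside (-1, 1)"
                )
            if scale <= 0:
                raise ValidationError("scales must be positive")

    def distribution(self, subunit: str, stress: str) -> tuple[float, float]:
        if (subunit, stress) in self.score_distributions:
            return self.score_distributions[(subunit, stress)]
        return (_DEFAULT_LOCATIONS.get(subunit, 0.2), _DEFAULT_SCALE)


@dataclass(frozen=True)
class MotifPlanting:
    """Request to write ``count`` instances of ``motif`` into one promoter.

    ``positions`` gives explicit 1-based starts; when None, non-overlapping
    positions are chosen at random.
    """

    gene_id: str
    motif: Motif
    count: int = 1
    positions: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError("planting count must be non-negative")
        if self.positions is not None and len(self.positions) != self.count:
            raise ValidationError("positions length must equal count")


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream checks."""

    planted_hubs: frozenset[str] = frozenset()
    hub_records: dict[str, int] = field(default_factory=dict)
    planted_motif_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    planted_positions: dict[tuple[str, str], tuple[int, ...]] = field(
        default_factory=dict
    )


def _gene_universe(spec: SyntheticSpec) -> list[str]:
    n_background = spec.n_genes - len(spec.planted_hubs)
    background = [f"G{i:04d}" for i in range(n_background)]
    return list(spec.planted_hubs) + background


def generate_coexpression(spec: SyntheticSpec) -> tuple[CoexpressionTable, GroundTruth]:
    """Sample a co-expression table with planted hub genes.

    Iteration order (subunit, member, stress, gene) is fixed, so the same
    seed yields a byte-identical table when written to TSV.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_universe(spec)
    hubs = set(spec.planted_hubs)
    records: list[CoexpressionRecord] = []
    hub_records: dict[str, int] = {h: 0 for h in hubs}
    for subunit in spec.config.names():
        for member in spec.config.members(subunit):
            for stress in spec.stresses.names:
                loc, scale = spec.distribution(subunit, stress)
                a, b = (-1.0 - loc) / scale, (1.0 - loc) / scale
                for gene in genes:
                    if gene in hubs:
                        score = min(1.0, loc + spec.hub_offset)
                        hub_records[gene] += 1
                    else:
                        if rng.random() >= spec.coverage:
                            continue
                        score = float(
                            truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng)
                        )
                    records.append(
                        CoexpressionRecord(gene, subunit, member, stress, score)
                    )
    table = CoexpressionTable(records, provenance=f"synthetic(seed={spec.seed})")
    truth = GroundTruth(planted_hubs=frozenset(hubs), hub_records=hub_records)
    return table, truth


def _realise_pattern(pattern: str, rng: np.random.Generator) -> str:
    """Resolve each IUPAC code uniformly among its allowed bases."""
    out = []
    for ch in pattern:
        allowed = sorted(IUPAC_TO_BASES[ch])
        out.append(allowed[rng.integers(len(allowed))] if len(allowed) > 1 else allowed[0])
    return "".join(out)


def _revcomp(pattern: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def _window_matches(window: str, pattern: str) -> bool:
    # sequence N matches only pattern position N
    return all(
        (p == "N") if (s == "N") else (s in IUPAC_TO_BASES[p])
        for s, p in zip(window, pattern)
    )


def _match_starts(seq: str, pattern: str) -> list[int]:
    m = len(pattern)
    return [i for i in range(len(seq) - m + 1) if _window_matches(seq[i : i + m], pattern)]


def _choose_positions(
    length: int, sizes: list[int], occupied: list[tuple[int, int]], rng: np.random.Generator
) -> list[int]:
    """Random non-overlapping 0-based starts for instances of given sizes."""
    placed = list(occupied)
    starts: list[int] = []
    for size in sizes:
        for _ in range(1000):
            s = int(rng.integers(0, length - size + 1))
            if all(s + size <= a or s >= a + b_size for a, b_size in placed):
                placed.append((s, size))
                starts.append(s)
                break
        else:
            raise ValidationError(
                "could not place motif instances without overlap; "
                "use a longer sequence or fewer plantings"
            )
    return starts


def generate_promoters(
    gene_ids: Sequence[str],
    length: int = 1000,
    gc: float = 0.36,
    plantings: Sequence[MotifPlanting] = (),
    avoid_background: bool = False,
    seed: int = 0,
) -> tuple[PromoterSet, GroundTruth]:
    """Generate promoters with planted motif occurrences.

    Background bases are i.i.d. at the requested GC content (the 0.36 default
    is typical of plant upstream regions). With ``avoid_background`` the
    background is rejection-sampled, with a per-window repair fallback, until
    no match of any planted motif (either strand) exists outside the planted
    sites — so ground-truth counts are exact for a both-strand scanner.
    """
    if not (0.0 < gc < 1.0):
        raise ValidationError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    by_gene: dict[str, list[MotifPlanting]] = {g: [] for g in gene_ids}
    for p in plantings:
        if p.gene_id not in by_gene:
            raise ValidationError(f"planting targets unknown gene {p.gene_id!r}")
        if len(p.motif) > length:
            raise ValidationError(
                f"motif {p.motif.name!r} does not fit in length {length}"
            )
        by_gene[p.gene_id].append(p)

    # Exactness is a property of the whole promoter set: planted patterns are
    # scrubbed from every gene, so unplanted genes count zero.
    global_patterns = sorted({p.motif.pattern for p in plantings})

    sequences: dict[str, str] = {}
    truth = GroundTruth()
    for gene in gene_ids:
        gene_plants = by_gene[gene]
        # decide positions first (explicit ones checked for overlap)
        layout: list[tuple[MotifPlanting, list[int]]] = []
        occupied: list[tuple[int, int]] = []
        for p in gene_plants:
            if p.positions is not None:
                starts0 = [pos - 1 for pos in p.positions]
                for s in starts0:
                    if s < 0 or s + len(p.motif) > length:
                        raise ValidationError(
                            f"planting of {p.motif.name!r} at {s + 1} exceeds length {length}"
                        )
                    if any(s + len(p.motif) > a and s < a + b for a, b in occupied):
                        raise ValidationError(
                            f"plantings overlap in promoter of {gene!r}"
                        )
                    occupied.append((s, len(p.motif)))
            else:
                starts0 = _choose_positions(
                    length, [len(p.motif)] * p.count, occupied, rng
                )
                occupied.extend((s, len(p.motif)) for s in starts0)
            layout.append((p, sorted(starts0)))

        seq = _build_sequence(
            length, layout, occupied, global_patterns, base_probs, bases,
            avoid_background, rng,
        )
        sequences[gene] = seq
        for p, starts0 in layout:
            key = (gene, p.motif.name)
            truth.planted_motif_counts[key] = (
                truth.planted_motif_counts.get(key, 0) + len(starts0)
            )
            truth.planted_positions[key] = truth.planted_positions.get(key, ()) + tuple(
                s + 1 for s in starts0
            )
    return PromoterSet(sequences, target_length=length), truth


def _build_sequence(
    length: int,
    layout: list[tuple[MotifPlanting, list[int]]],
    occupied: list[tuple[int, int]],
    global_patterns: list[str],
    base_probs: np.ndarray,
    bases: np.ndarray,
    avoid_background: bool,
    rng: np.random.Generator,
) -> str:
    def fresh_background() -> list[str]:
        return list(rng.choice(bases, size=length, p=base_probs))

    def plant(seq: list[str]) -> None:
        for p, starts0 in layout:
            for s in starts0:
                inst = _realise_pattern(p.motif.pattern, rng)
                seq[s : s + len(inst)] = list(inst)

    # allowed forward starts per pattern on this gene
    allowed: dict[str, set[int]] = {pat: set() for pat in global_patterns}
    for p, starts0 in layout:
        allowed[p.motif.pattern].update(starts0)

    def stray_windows(seq_str: str) -> list[tuple[int, int]]:
        """(start, length) of matches a both-strand scanner would report
        beyond the planted forward-strand sites."""
        strays = []
        for pat in global_patterns:
            for s in _match_starts(seq_str, pat):
                if s not in allowed[pat]:
                    strays.append((s, len(pat)))
            rc = _revcomp(pat)
            if rc != pat:  # palindromic patterns dedup to the forward hit
                strays.extend((s, len(pat)) for s in _match_starts(seq_str, rc))
        return strays

    is_planted = np.zeros(length, dtype=bool)
    for a, b in occupied:
        is_planted[a : a + b] = True

    seq = fresh_background()
    plant(seq)
    if not avoid_background or not global_patterns:
        return "".join(seq)

    # whole-sequence rejection first, then per-window repair
    for _ in range(3):
        if not stray_windows("".join(seq)):
            return "".join(seq)
        seq = fresh_background()
        plant(seq)

    for _ in range(500):
        strays = stray_windows("".join(seq))
        if not strays:
            return "".join(seq)
        for s, m in strays:
            free = [i for i in range(s, s + m) if not is_planted[i]]
            if not free:
                raise ValidationError(
                    "a stray motif match lies entirely within planted sites; "
                    "use a longer sequence or sparser plantings"
                )
            i = free[int(rng.integers(len(free)))]
            seq[i] = str(rng.choice(bases, p=base_probs))
    raise ValidationError(
        "could not remove background motif matches within the iteration cap; "
        "use a longer sequence or fewer/shorter plantings"
    )
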