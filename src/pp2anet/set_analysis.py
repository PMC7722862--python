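"""n-set membership-signature (Venn) analysis for up to 7 named gene sets.

Every gene in the union of the input sets belongs to exactly one region: the
region of its exact membership signature (the subset of input sets that
contain it and no others). For n sets there are 2^n - 1 possible signatures,
all of which are enumerated in the report, empty or not. Intersection counts
in the at-least sense (|A ∩ B| regardless of other sets) are recovered by
summing the regions whose signature includes the required sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .config_io import ValidationError

__all__ = ["MembershipSignature", "VennReport", "venn_regions"]

MAX_SETS = 7


@dataclass(frozen=True)
class MembershipSignature:
    """Inclusion flag per named set, in the report's set order."""

    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not any(self.bits):
            raise ValidationError("a signature must include at least one set")

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    def label(self, set_names: Sequence[str]) -> str:
        return "".join("+" if b else "-" for b in self.bits)

    def member_names(self, set_names: Sequence[str]) -> tuple[str, ...]:
        return tuple(n for n, b in zip(set_names, self.bits) if b)


def _signature_order_key(sig: MembershipSignature):
    # popcount first, then earlier sets before later ones
    return (sig.popcount, tuple(0 if b else 1 for b in sig.bits))


@dataclass
class VennReport:
    """All 2^n - 1 regions of an n-set Venn decomposition."""

    set_names: tuple[str, ...]
    regions: dict[MembershipSignature, tuple[str, ...]]

    def counts(self) -> dict[MembershipSignature, int]:
        return {sig: len(genes) for sig, genes in self.regions.items()}

    def nonempty(self) -> dict[MembershipSignature, tuple[str, ...]]:
        return {sig: genes for sig, genes in self.regions.items() if genes}

    def region(self, *names: str) -> tuple[str, ...]:
        """Genes exactly in the named sets and no others."""
        bits = tuple(n in names for n in self.set_names)
        return self.regions[MembershipSignature(bits)]

    def at_least(self, *names: str) -> set[str]:
        """Genes in all the named sets, regardless of other memberships."""
        required = tuple(self.set_names.index(n) for n in names)
        out: set[str] = set()
        for sig, genes in self.regions.items():
            if all(sig.bits[i] for i in required):
                out.update(genes)
        return out

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("signature\tsets\tcount\tgenes\n")
            for sig, genes in self.regions.items():
                fh.write(
                    f"{sig.label(self.set_names)}\t"
                    f"{','.join(sig.member_names(self.set_names))}\t"
                    f"{len(genes)}\t{','.join(genes)}\n"
                )

    def write_json(self, path: str | Path) -> None:
        payload = {
            "set_names": list(self.set_names),
            "regions": [
                {
                    "signature": sig.label(self.set_names),
                    "sets": list(sig.member_names(self.set_names)),
                    "count": len(genes),
                    "genes": list(genes),
                }
                for sig, genes in self.regions.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def venn_regions(sets: Mapping[str, set[str]]) -> VennReport:
    """Decompose up to 7 named gene sets into exact-membership regions.

    The computation is general in n, but the report is capped at 7 sets —
    the readability bound of nested Venn rendering downstream.
    """
    names = tuple(sets)
    n = len(names)
    if n < 1:
        raise ValidationError("need at least one set")
    if n > MAX_SETS:
        raise ValidationError(f"at most {MAX_SETS} sets supported, got {n}")

    regions: dict[MembershipSignature, list[str]] = {}
    for mask in range(1, 2**n):
        bits = tuple(bool(mask & (1 << i)) for i in range(n))
        regions[MembershipSignature(bits)] = []

    union = set().union(*sets.values())
    for gene in sorted(union):
        bits = tuple(gene in sets[name] for name in names)
        regions[MembershipSignature(bits)].append(gene)

    ordered = {
        sig: tuple(regions[sig])
        for sig in sorted(regions, key=_signature_order_key)
    }
    return VennReport(set_names=names, regions=ordered)
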