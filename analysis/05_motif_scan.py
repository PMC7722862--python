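#!/usr/bin/env python
"""Scan the hub-gene promoters for the 16 built-in cis-regulatory elements,
club duplicate hits, and summarise common and unique CREs.

Reads results/promoters.fa; writes motif_hits.tsv, motif_matrix.tsv and
motif_summary.json under results/.
"""

import argparse
from pathlib import Path

from pp2anet import (
    builtin_motif_library,
    load_promoters,
    scan_promoters,
    summarize_common_unique,
)
from pp2anet.motif_scan import write_hits_tsv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--strands", choices=("forward", "both"), default="both")
    args = parser.parse_args()

    promoters = load_promoters(args.outdir / "promoters.fa")
    library = builtin_motif_library()
    hits, matrix = scan_promoters(promoters, library, strands=args.strands)
    write_hits_tsv(hits, library, promoters, args.outdir / "motif_hits.tsv")
    matrix.write_tsv(args.outdir / "motif_matrix.tsv")
    summary = summarize_common_unique(matrix)
    summary.write_json(args.outdir / "motif_summary.json")

    print(f"{len(hits)} motif sites across {len(promoters)} promoters")
    totals = sorted(
        ((matrix.motif_total(m), m) for m in matrix.motifs), reverse=True
    )
    for total, name in totals[:5]:
        print(f"  {name}: {total}")
    print(f"common to every gene: {sorted(summary.common)}")
    print(f"unique single-site CREs: {dict(sorted(summary.unique.items()))}")


if __name__ == "__main__":
    main()
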