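#!/usr/bin/env python
"""Generate the synthetic study inputs: a full-coverage co-expression table
with three planted hub genes, and 1-kb promoters for those hubs with known
planted cis-element occurrences.

Writes results/coexpression.tsv, results/promoters.fa and
results/ground_truth.json.
"""

import argparse
import json
from pathlib import Path

from pp2anet import (
    builtin_motif_library,
    generate_coexpression,
    generate_promoters,
    write_coexpression_table,
)
from pp2anet.synthetic_data import MotifPlanting, SyntheticSpec

HUBS = ("HUB1", "HUB2", "HUB3")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = SyntheticSpec(
        n_genes=40, coverage=1.0, planted_hubs=HUBS, hub_offset=0.6, seed=args.seed
    )
    table, truth = generate_coexpression(spec)
    write_coexpression_table(table, args.outdir / "coexpression.tsv")
    print(f"co-expression table: {len(table)} records, hubs {', '.join(HUBS)}")

    lib = builtin_motif_library()
    plantings = [
        MotifPlanting("HUB1", lib["CAATBOX1"], 4),
        MotifPlanting("HUB1", lib["WRKY71OS"], 2),
        MotifPlanting("HUB2", lib["ARR1AT"], 3),
        MotifPlanting("HUB3", lib["TAAAGSTKST1"], 1),
    ]
    promoters, prom_truth = generate_promoters(
        list(HUBS), length=1000, plantings=plantings,
        avoid_background=True, seed=args.seed,
    )
    with (args.outdir / "promoters.fa").open("w") as fh:
        for gene, seq in promoters.items():
            fh.write(f">{gene}\n{seq}\n")
    print(f"promoters: {len(promoters)} x 1000 nt, "
          f"{sum(prom_truth.planted_motif_counts.values())} planted motif sites")

    truth_payload = {
        "planted_hubs": sorted(truth.planted_hubs),
        "planted_motif_counts": {
            f"{g}:{m}": c for (g, m), c in prom_truth.planted_motif_counts.items()
        },
    }
    (args.outdir / "ground_truth.json").write_text(
        json.dumps(truth_payload, indent=1)
    )


if __name__ == "__main__":
    main()
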