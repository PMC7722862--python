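#!/usr/bin/env python
"""Score genes by closeness centrality, select the high-CCS set per subunit
at the largest gap, intersect across A, B, C to call hubs, and report the
7-set stress Venn decomposition per subunit.

Reads the networks and filtered tables of step 02; writes centrality TSVs,
hubs.json and per-subunit venn_<S>.tsv under results/.
"""

import argparse
import json
from pathlib import Path

from pp2anet import (
    DEFAULT_STRESSES,
    closeness_centrality,
    default_subunits,
    intersect_hubs,
    load_coexpression_table,
    load_gexf,
    select_high_ccs,
    venn_regions,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    config = default_subunits()

    selections = []
    for subunit in config.names():
        net = load_gexf(args.outdir / f"network_{subunit}.gexf", subunit=subunit)
        scores = closeness_centrality(net)
        with (args.outdir / f"centrality_{subunit}.tsv").open("w") as fh:
            fh.write("node\ttype\tscore\n")
            for node, s in sorted(scores.scores.items(), key=lambda kv: str(kv[0])):
                kind = "gene" if node in net.gene_nodes else "stress_unit"
                name = node if isinstance(node, str) else f"{node.stress}|{node.member}"
                fh.write(f"{name}\t{kind}\t{s:.6f}\n")
        selection = select_high_ccs(scores.gene_scores(net), subunit=subunit)
        selections.append(selection)
        print(
            f"subunit {subunit}: {len(selection.selected)} high-CCS genes "
            f"(cutoff {selection.cutoff:.4f})"
        )

        filtered = load_coexpression_table(
            args.outdir / f"filtered_{subunit}.tsv", DEFAULT_STRESSES, config
        )
        per_stress = {
            stress: {r.gene_id for r in filtered if r.stress == stress}
            for stress in DEFAULT_STRESSES.names
        }
        report = venn_regions(per_stress)
        report.write_tsv(args.outdir / f"venn_{subunit}.tsv")
        print(
            f"  7-set stress Venn: {len(report.nonempty())} of "
            f"{len(report.regions)} regions occupied"
        )

    hubs = intersect_hubs(selections)
    (args.outdir / "hubs.json").write_text(
        json.dumps(
            {
                "hubs": sorted(hubs.hubs),
                "per_subunit": {
                    sel.subunit: sorted(sel.selected) for sel in hubs.per_subunit
                },
            },
            indent=1,
        )
    )
    print(f"hub genes (high-CCS in A, B and C): {sorted(hubs.hubs)}")


if __name__ == "__main__":
    main()
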