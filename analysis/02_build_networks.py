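#!/usr/bin/env python
"""Threshold each subunit's co-expression records at the pooled mean and
build the bipartite gene ↔ stress-unit networks.

Reads results/coexpression.tsv; writes per-subunit GEXF networks, filtered
tables, and threshold reports under results/.
"""

import argparse
import json
from pathlib import Path

from pp2anet import (
    DEFAULT_STRESSES,
    apply_threshold,
    build_bipartite_network,
    compute_threshold,
    default_subunits,
    export_gexf,
    load_coexpression_table,
    write_coexpression_table,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    config = default_subunits()
    table = load_coexpression_table(
        args.outdir / "coexpression.tsv", DEFAULT_STRESSES, config
    )

    for subunit in config.names():
        report = compute_threshold(table, subunit, mode="pooled")
        filtered = apply_threshold(table, report)
        net = build_bipartite_network(filtered, subunit, DEFAULT_STRESSES, config)
        export_gexf(net, args.outdir / f"network_{subunit}.gexf")
        write_coexpression_table(filtered, args.outdir / f"filtered_{subunit}.tsv")
        (args.outdir / f"threshold_{subunit}.json").write_text(
            json.dumps(
                {
                    "subunit": subunit,
                    "mode": report.mode,
                    "mean_score": report.mean_score,
                    "n_before": report.n_before,
                    "n_after": report.n_after,
                },
                indent=1,
            )
        )
        print(
            f"subunit {subunit}: mean {report.mean_score:+.4f}, "
            f"{report.n_after}/{report.n_before} records kept -> "
            f"{len(net.su_nodes)} stress-unit nodes, {len(net.gene_nodes)} genes, "
            f"{len(net.edges)} edges"
        )


if __name__ == "__main__":
    main()
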