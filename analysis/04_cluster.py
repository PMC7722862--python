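#!/usr/bin/env python
"""Cluster each subunit's surviving gene occurrences in the
⟨stress code, closeness, co-expression⟩ space with silhouette-selected
K-means, and summarise cluster occupancy.

Reads step 02/03 outputs; writes silhouette_<S>.tsv, assignments_<S>.tsv
and clusters_<S>.json under results/.
"""

import argparse
import json
from pathlib import Path

from pp2anet import (
    DEFAULT_STRESSES,
    build_feature_table,
    closeness_centrality,
    default_subunits,
    fit_kmeans,
    load_coexpression_table,
    load_gexf,
    select_k,
    summarize_clusters,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    config = default_subunits()

    for subunit in config.names():
        net = load_gexf(args.outdir / f"network_{subunit}.gexf", subunit=subunit)
        filtered = load_coexpression_table(
            args.outdir / f"filtered_{subunit}.tsv", DEFAULT_STRESSES, config
        )
        centrality = closeness_centrality(net).gene_scores(net)
        points = build_feature_table(filtered, centrality, DEFAULT_STRESSES)
        curve = select_k(points, seed=args.seed)
        curve.write_tsv(args.outdir / f"silhouette_{subunit}.tsv")
        model = fit_kmeans(points, curve.chosen_k, seed=args.seed)
        with (args.outdir / f"assignments_{subunit}.tsv").open("w") as fh:
            fh.write("gene_id\tstress_code\tccs\tscore\tcluster\n")
            for p, label in zip(points, model.assignments):
                fh.write(
                    f"{p.gene_id}\t{p.stress_code}\t{p.ccs:.6f}\t"
                    f"{p.score:.6f}\t{label}\n"
                )
        summaries = summarize_clusters(model, points)
        (args.outdir / f"clusters_{subunit}.json").write_text(
            json.dumps(
                [
                    {
                        "cluster": s.cluster_id,
                        "size": s.size,
                        "dominant_stress_codes": list(s.dominant_stress_codes),
                        "n_genes": len(s.gene_multiplicity),
                        "n_singletons": len(s.singleton_genes),
                    }
                    for s in summaries
                ],
                indent=1,
            )
        )
        sil = curve.mean_silhouette[curve.chosen_k]
        print(
            f"subunit {subunit}: {len(points)} points, chose K={curve.chosen_k} "
            f"(silhouette {sil:.3f}); cluster sizes "
            f"{[s.size for s in summaries]}"
        )


if __name__ == "__main__":
    main()
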