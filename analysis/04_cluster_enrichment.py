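#!/usr/bin/env python
"""Annotate the three major branches with planted gene sets.

Builds "essential-like" (lethal) and "lipodystrophy-like" (lipo) gene
sets from the generator's ground truth and tests each branch for
enrichment: 2x2 odds ratio plus hypergeometric upper-tail p, mirroring
how screen clusters are annotated against known gene lists.
"""

from pathlib import Path

import pandas as pd

from morphoscreen import enrichment as en
from morphoscreen import synthetic_data as sd

RESULTS = Path("results")


def main() -> None:
    clusters_path = RESULTS / "clusters.tsv"
    truth_path = RESULTS / "screen_ground_truth.json"
    if not clusters_path.exists() or not truth_path.exists():
        raise SystemExit("run 01-03 first (clusters.tsv / ground truth missing)")
    cut = pd.read_csv(clusters_path, sep="\t").set_index("gene")["cluster"].to_dict()
    truth = sd.GroundTruth.from_json(truth_path.read_text())

    sets = [
        en.GeneSet("essential_like", frozenset(
            g for g, grp in truth.true_group.items() if grp == "lethal")),
        en.GeneSet("lipodystrophy_like", frozenset(
            g for g, grp in truth.true_group.items() if grp == "lipo")),
    ]
    results = en.cluster_enrichment(cut, sets)
    frame = en.enrichment_frame(results)
    frame.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)

    print("cluster enrichment (odds ratio, hypergeometric p):")
    for r in results:
        if r.a == 0:
            continue
        print(f"  cluster {r.cluster} x {r.gene_set}: "
              f"a={r.a}/{r.a + r.b} in-cluster, OR={r.odds_ratio:.1f}, p={r.p:.2e}")
    print(f"full table -> {RESULTS / 'enrichment.tsv'}")


if __name__ == "__main__":
    main()
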