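#!/usr/bin/env python
"""Disruptive-indel odds ratios for sorted-bin amplicon experiments.

Simulates three FACS-sorted amplicon sequencing experiments -- two
regulatory binding sites with a strong true disruption odds ratio (2.7)
and a weaker control locus (1.7) -- then recovers each odds ratio with
its 95% Wald interval from the read tables alone, classifying alleles
as disruptive when any indel exceeds 3 bp.
"""

from pathlib import Path

import pandas as pd

from morphoscreen import indel_analysis as ia
from morphoscreen import synthetic_data as sd

RESULTS = Path("results")

SITES = {
    "S1": dict(true_or=2.7, seed=101),
    "S2": dict(true_or=2.7, seed=102),
    "Int1Control": dict(true_or=1.7, seed=103),
}


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    print("sorted-bin disruptive-indel odds ratios (true OR in parentheses):")
    for site, params in SITES.items():
        cfg = sd.SortConfig(total_reads_per_bin=50_000, **params)
        table = sd.generate_sorted_alleles(cfg)
        flags, cells = ia.classify_alleles(table, min_indel=3)
        res = ia.disruption_or(cells)
        rows.append(
            (site, params["true_or"], int(flags.sum()), *[int(c) for c in cells],
             res.or_estimate, res.ci_low, res.ci_high)
        )
        print(f"  {site}: OR={res.or_estimate:.2f} "
              f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f})  (true {params['true_or']})")
    frame = pd.DataFrame(
        rows,
        columns=["site", "true_or", "disruptive_alleles", "disruptive_low",
                 "nondisruptive_low", "disruptive_high", "nondisruptive_high",
                 "or_estimate", "ci_low", "ci_high"],
    )
    frame.to_csv(RESULTS / "indel_odds_ratios.tsv", sep="\t", index=False)
    print(f"table -> {RESULTS / 'indel_odds_ratios.tsv'}")


if __name__ == "__main__":
    main()
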