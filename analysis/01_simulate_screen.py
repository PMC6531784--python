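#!/usr/bin/env python
"""Generate the synthetic arrayed knockout screen used by the analyses.

Emulates the study design: 133 genes x 3 guides + 25 non-targeting
controls, four biological replicates at each of two seeding densities,
425 well-level morphometric features (28 planted noise, 249 planted
near-duplicates, 148 reproducible base features), with lethal and
lipodystrophy-like gene groups planted on the cell-number and
lipid-droplet feature blocks.

Writes the (large) well table under scratch/ and the ground truth under
results/.
"""

from pathlib import Path

from morphoscreen import synthetic_data as sd

SEED = 1
SCRATCH = Path("scratch/screen")
RESULTS = Path("results")


def main() -> None:
    cfg = sd.ScreenConfig(seed=SEED)
    table, truth = sd.generate_screen(cfg)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    sd.write_well_table(table, SCRATCH / "wells.csv")
    sd.write_ground_truth(truth, RESULTS / "screen_ground_truth.json")

    groups = {}
    for g in truth.true_group.values():
        groups[g] = groups.get(g, 0) + 1
    print(f"simulated screen (seed {SEED}):")
    print(f"  {cfg.n_constructs} constructs ({cfg.n_genes} genes x {cfg.guides_per_gene} guides"
          f" + {cfg.n_nontargeting} non-targeting)")
    print(f"  {table.shape[0]} wells ({cfg.replicates} replicates x {cfg.densities} densities)")
    print(f"  {cfg.n_features} features: {cfg.n_base_features} base, "
          f"{cfg.n_redundant_features} redundant, {cfg.n_noise_features} noise")
    print(f"  planted gene groups: {dict(sorted(groups.items()))}")
    print(f"  well table -> {SCRATCH / 'wells.csv'}")
    print(f"  ground truth -> {RESULTS / 'screen_ground_truth.json'}")


if __name__ == "__main__":
    main()
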