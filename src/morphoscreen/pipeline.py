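"""End-to-end screen analysis: QC -> profiles -> clustering -> enrichment.

Stage order is fixed: reproducibility filter, Z-normalization,
redundancy pruning, median aggregation to gene profiles, Ward.D2
clustering, multiscale bootstrap, branch cut, gene-set enrichment.
Every stage writes a self-describing plain-text artifact, and a JSON
manifest records parameters, seeds, and per-stage counts so a rerun
with the same config reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, clustering, enrichment, feature_qc, profiling, synthetic_data


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run.

    Exactly one of ``input_table`` (path to a well-table CSV) or
    ``simulate`` (ScreenConfig field overrides) must be given.
    Defaults mirror the published analysis: alpha 0.05, redundancy
    cutoff 0.9, Ward.D2, k = 3 major branches, 10 bootstrap scales.
    """

    out_dir: str = "results/pipeline"
    input_table: str | None = None
    simulate: dict | None = None
    alpha: float = 0.05
    redundancy_cutoff: float = 0.9
    reproducibility_rule: str = "any"
    k: int = 3
    include_controls: bool = True
    bootstrap_scales: tuple[float, ...] = clustering.BootstrapConfig().scales
    bootstrap_replications: int = 1000
    run_bootstrap: bool = True
    gene_sets: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        if "bootstrap_scales" in data:
            data["bootstrap_scales"] = tuple(data["bootstrap_scales"])
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "morphoscreen",
        "version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "redundancy_cutoff": config.redundancy_cutoff,
            "reproducibility_rule": config.reproducibility_rule,
            "k": config.k,
            "include_controls": config.include_controls,
            "bootstrap_scales": list(config.bootstrap_scales),
            "bootstrap_replications": config.bootstrap_replications,
        },
        "stages": {},
    }

    # -- input ------------------------------------------------------------
    if (config.input_table is None) == (config.simulate is None):
        raise PipelineError("give exactly one of input_table or simulate")
    if config.simulate is not None:
        screen_cfg = synthetic_data.ScreenConfig(**{"seed": config.seed, **config.simulate})
        table, truth = _stage("simulate")(synthetic_data.generate_screen)(screen_cfg)
        synthetic_data.write_well_table(table, out / "wells.csv")
        synthetic_data.write_ground_truth(truth, out / "ground_truth.json")
        manifest["stages"]["simulate"] = {
            "rows": int(table.shape[0]),
            "features": len(feature_qc.feature_columns(table)),
        }
    else:
        table = _stage("load")(synthetic_data.read_well_table)(config.input_table)
        manifest["stages"]["load"] = {"rows": int(table.shape[0])}

    # -- feature QC --------------------------------------------------------
    report, z = _stage("feature_qc")(feature_qc.run_feature_qc)(
        table,
        alpha=config.alpha,
        cutoff=config.redundancy_cutoff,
        rule=config.reproducibility_rule,
    )
    report.write(out / "qc_report.tsv", out / "qc_summary.json")
    z.values.to_csv(out / "zmatrix.csv")
    manifest["stages"]["feature_qc"] = report.counts

    # -- gene profiles -----------------------------------------------------
    profiles = _stage("profiles")(profiling.gene_profiles)(z)
    profiles.write(out / "profiles.csv")
    manifest["stages"]["profiles"] = {
        "genes": int((profiles.row_class == "gene").sum()),
        "pseudo_rows": int((profiles.row_class != "gene").sum()),
        "features": int(profiles.values.shape[1]),
    }

    clustered = profiles if config.include_controls else profiles.genes_only()

    # -- clustering + bootstrap -------------------------------------------
    if config.run_bootstrap:
        bs_cfg = clustering.BootstrapConfig(
            scales=config.bootstrap_scales,
            replications_per_scale=config.bootstrap_replications,
            seed=config.seed,
        )
        tree, support = _stage("bootstrap")(clustering.multiscale_bootstrap)(
            clustered, bs_cfg
        )
        clustering.write_support(support, out / "support.json")
        manifest["stages"]["bootstrap"] = {
            "nodes": len(support),
            "replications": config.bootstrap_replications * len(config.bootstrap_scales),
        }
    else:
        tree = _stage("cluster")(clustering.ward_cluster)(
            clustering.distance_matrix(clustered)
        )
    (out / "tree.newick").write_text(clustering.tree_to_newick(tree) + "\n")

    assignments = _stage("cut")(clustering.cut_tree)(tree, config.k)
    pd.DataFrame(sorted(assignments.items()), columns=["gene", "cluster"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    sizes: dict[int, int] = {}
    for cl in assignments.values():
        sizes[cl] = sizes.get(cl, 0) + 1
    manifest["stages"]["cut"] = {"k": config.k, "cluster_sizes": dict(sorted(sizes.items()))}

    # -- enrichment --------------------------------------------------------
    if config.gene_sets is not None:
        sets = _stage("enrich")(enrichment.read_gene_sets)(config.gene_sets)
        results = _stage("enrich")(enrichment.cluster_enrichment)(assignments, sets)
        enrichment.enrichment_frame(results).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        manifest["stages"]["enrich"] = {"tests": len(results)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
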