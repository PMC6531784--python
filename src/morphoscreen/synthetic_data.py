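"""Synthetic screen, sorted-bin amplicon, and AFM particle generators.

The generators emulate the statistical structure of an arrayed CRISPR
knockout screen read out by high-content imaging: ~133 genes x 3 guides
plus 25 non-targeting controls, four biological replicates (optionally
at two seeding densities), and 425 well-level summarized morphometric
features.  Planted structure mirrors what the downstream QC and
clustering stages are designed to detect:

* gene groups ("control_like", "lethal", "lipo") shift designated
  feature blocks (cell-number, lipid-droplet) by a stated number of
  within-feature standard deviations, scaled per guide by a random
  modification efficiency;
* a block of pure-noise features with no inter-replicate concordance
  (fodder for the reproducibility filter);
* a block of redundant features that are near-duplicates (population
  r = ``redundancy_level``) of reproducible base features (fodder for
  correlation pruning).

All randomness flows from the single integer ``seed`` of each config
through one ``numpy.random.Generator`` stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = [
    "construct_id",
    "gene",
    "guide_index",
    "well_class",
    "replicate",
    "density",
    "plate",
    "well",
]

BLOCKS = ("cell_number", "lipid_droplet", "texture", "other")

#: Default per-group mean shifts, in units of the within-feature
#: construct-level SD, applied to whole feature blocks.  Lethal
#: knockouts lose cells and lipid; lipodystrophy-like knockouts lose
#: lipid with near-normal cell number; control-like genes are null.
DEFAULT_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "control_like": {},
    "lethal": {"cell_number": -4.0, "lipid_droplet": -2.0},
    "lipo": {"cell_number": -0.3, "lipid_droplet": -3.0},
}


class ConfigurationError(ValueError):
    """Raised when a generator config violates its invariants."""


@dataclass
class ScreenConfig:
    """Design of a synthetic arrayed screen.

    ``n_noise_features + n_redundant_features`` must stay below
    ``n_features``; the remainder are reproducible "base" features
    partitioned into correlated blocks (cell_number, lipid_droplet,
    texture, other).
    """

    n_genes: int = 133
    guides_per_gene: int = 3
    n_nontargeting: int = 25
    replicates: int = 4
    densities: int = 2
    n_features: int = 425
    n_noise_features: int = 28
    n_redundant_features: int = 249
    redundancy_level: float = 0.95
    group_assignment: Mapping[str, str] | None = None
    n_lethal: int = 13
    n_lipo: int = 14
    effect_sizes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_EFFECT_SIZES
    )
    construct_sd: float = 1.0
    replicate_noise_sd: float = 0.5
    block_correlation: float = 0.2
    guide_efficiency_range: tuple[float, float] = (0.7, 1.0)
    plate_effect_sd: float = 0.0
    wells_per_plate: int = 96
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ConfigurationError("need at least one gene and one guide per gene")
        if self.replicates < 1 or self.densities < 1:
            raise ConfigurationError("replicates and densities must be >= 1")
        if self.n_noise_features + self.n_redundant_features >= self.n_features:
            raise ConfigurationError(
                "n_noise_features + n_redundant_features must be < n_features"
            )
        if not 0.0 < self.redundancy_level < 1.0:
            raise ConfigurationError("redundancy_level must be in (0, 1)")
        lo, hi = self.guide_efficiency_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigurationError("guide_efficiency_range must be within [0, 1]")
        if self.group_assignment is not None:
            missing = set(self.genes()) - set(self.group_assignment)
            if missing:
                raise ConfigurationError(f"genes without a group: {sorted(missing)[:5]}")
            bad = set(self.group_assignment.values()) - set(self.effect_sizes)
            if bad:
                raise ConfigurationError(f"groups without effect sizes: {sorted(bad)}")
        elif self.n_lethal + self.n_lipo > self.n_genes:
            raise ConfigurationError("n_lethal + n_lipo exceeds n_genes")

    def genes(self) -> list[str]:
        width = max(3, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def groups(self) -> dict[str, str]:
        """Gene -> group map (explicit assignment wins over counts)."""
        if self.group_assignment is not None:
            return dict(self.group_assignment)
        genes = self.genes()
        out = {g: "control_like" for g in genes}
        for g in genes[: self.n_lethal]:
            out[g] = "lethal"
        for g in genes[self.n_lethal : self.n_lethal + self.n_lipo]:
            out[g] = "lipo"
        return out

    @property
    def n_base_features(self) -> int:
        return self.n_features - self.n_noise_features - self.n_redundant_features

    @property
    def n_constructs(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_nontargeting

    @property
    def n_rows(self) -> int:
        return self.n_constructs * self.replicates * self.densities


@dataclass
class GroundTruth:
    """Planted structure of a generated screen table."""

    true_group: dict[str, str]
    noise_features: list[str]
    redundant_parent: dict[str, str]
    guide_efficiency: dict[str, float]
    feature_block: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def feature_names(n_features: int) -> list[str]:
    """Header names in the well-table dialect: f0001_mean, f0001_sd, ..."""
    names = []
    for i in range(n_features):
        stem = i // 2 + 1
        suffix = "mean" if i % 2 == 0 else "sd"
        names.append(f"f{stem:04d}_{suffix}")
    return names


def _block_sizes(n_base: int) -> dict[str, int]:
    # fixed proportions; cell_number kept small like a real count block
    cell = max(2, round(0.08 * n_base))
    lipid = max(2, round(0.27 * n_base))
    texture = max(1, round(0.32 * n_base))
    other = n_base - cell - lipid - texture
    if other < 1:
        raise ConfigurationError("too few base features to form blocks")
    return {"cell_number": cell, "lipid_droplet": lipid, "texture": texture, "other": other}


def generate_screen(config: ScreenConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a well-level feature table plus its ground truth.

    Rows: every (construct, replicate, density) combination.  Base
    features are block-correlated Gaussians with a construct-level
    component (shared across a construct's wells, which is what makes
    them reproducible) plus per-well noise; group effects shift blocks
    in proportion to the guide's modification efficiency.  Noise
    features are independent per well.  Redundant features copy a base
    feature's well values plus noise calibrated so the population
    correlation with the parent equals ``redundancy_level``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = config.genes()
    groups = config.groups()
    constructs: list[tuple[str, str, int, str]] = []  # id, gene, guide_index, class
    for gene in genes:
        for g in range(1, config.guides_per_gene + 1):
            constructs.append((f"{gene}_g{g}", gene, g, "targeting"))
    for j in range(1, config.n_nontargeting + 1):
        constructs.append((f"NT_{j:03d}", "non_targeting", j, "non_targeting"))
    n_con = len(constructs)

    n_base = config.n_base_features
    sizes = _block_sizes(n_base)
    block_of = np.concatenate(
        [np.full(sizes[b], i) for i, b in enumerate(BLOCKS)]
    )  # base feature index -> block index

    lo, hi = config.guide_efficiency_range
    efficiency = rng.uniform(lo, hi, size=n_con)
    # effect per construct per base feature (SD units)
    effect = np.zeros((n_con, n_base))
    for ci, (_, gene, _, wclass) in enumerate(constructs):
        if wclass != "targeting":
            continue
        shifts = config.effect_sizes.get(groups[gene], {})
        for bi, bname in enumerate(BLOCKS):
            s = shifts.get(bname, 0.0)
            if s:
                effect[ci, block_of == bi] = s * efficiency[ci]

    # construct-level component: block factor + independent part
    rho = config.block_correlation
    g_block = rng.standard_normal((n_con, len(BLOCKS)))
    u_ind = rng.standard_normal((n_con, n_base))
    u = config.construct_sd * (
        np.sqrt(rho) * g_block[:, block_of] + np.sqrt(1.0 - rho) * u_ind
    )
    construct_level = effect * config.construct_sd + u  # (n_con, n_base)

    n_wells_per_con = config.replicates * config.densities
    n_rows = n_con * n_wells_per_con
    base_wells = np.repeat(construct_level, n_wells_per_con, axis=0)
    base_wells = base_wells + rng.normal(
        0.0, config.replicate_noise_sd, size=(n_rows, n_base)
    )

    # redundant features: parent well values + calibrated noise
    r = config.redundancy_level
    total_sd = np.sqrt(config.construct_sd**2 + config.replicate_noise_sd**2)
    dup_sd = total_sd * np.sqrt(1.0 / r**2 - 1.0)
    parents = np.arange(config.n_redundant_features) % n_base
    dup_wells = base_wells[:, parents] + rng.normal(
        0.0, dup_sd, size=(n_rows, config.n_redundant_features)
    )

    noise_wells = rng.standard_normal((n_rows, config.n_noise_features))

    values = np.concatenate([base_wells, dup_wells, noise_wells], axis=1)
    names = feature_names(config.n_features)
    base_names = names[:n_base]
    dup_names = names[n_base : n_base + config.n_redundant_features]
    noise_names = names[n_base + config.n_redundant_features :]

    meta_rows = []
    row = 0
    for ci, (cid, gene, gi, wclass) in enumerate(constructs):
        for d in range(1, config.densities + 1):
            for rep in range(1, config.replicates + 1):
                plate = row // config.wells_per_plate + 1
                meta_rows.append(
                    (cid, gene, gi, wclass, rep, d, plate, f"W{row % config.wells_per_plate + 1:03d}")
                )
                row += 1
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)

    if config.plate_effect_sd > 0:
        n_plates = int(meta["plate"].max())
        plate_shift = rng.normal(0.0, config.plate_effect_sd, size=(n_plates, config.n_features))
        values = values + plate_shift[meta["plate"].to_numpy() - 1, :]

    table = pd.concat([meta, pd.DataFrame(values, columns=names)], axis=1)

    truth = GroundTruth(
        true_group={g: groups[g] for g in genes},
        noise_features=list(noise_names),
        redundant_parent={d: base_names[p] for d, p in zip(dup_names, parents)},
        guide_efficiency={constructs[i][0]: float(efficiency[i]) for i in range(n_con)},
        feature_block={base_names[i]: BLOCKS[block_of[i]] for i in range(n_base)},
    )
    return table, truth


def qc_fixture_config(seed: int = 7) -> ScreenConfig:
    """Screen config reproducing the study's feature-QC bookkeeping.

    150 constructs (125 single-guide genes + 25 non-targeting) x 4
    replicates, 425 features of which 28 are planted pure-noise and 249
    are planted near-duplicates of the 148 reproducible base features.
    """
    return ScreenConfig(
        n_genes=125,
        guides_per_gene=1,
        n_nontargeting=25,
        replicates=4,
        densities=1,
        n_features=425,
        n_noise_features=28,
        n_redundant_features=249,
        n_lethal=0,
        n_lipo=0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sorted-bin amplicon alleles


@dataclass
class SortConfig:
    """Design of a synthetic sorted-bin amplicon experiment.

    Each read is assigned to the low-expression bin by a Bernoulli draw
    whose odds depend on whether its allele is disruptive; the
    disruptive/non-disruptive odds ratio of landing low equals
    ``true_or`` at the population level.
    """

    n_alleles: int = 40
    disruptive_fraction: float = 0.4
    total_reads_per_bin: int = 50_000
    true_or: float = 2.7
    disruptive_lengths: tuple[int, int] = (4, 32)
    nondisruptive_lengths: tuple[int, int] = (0, 3)
    seed: int = 0

    def validate(self) -> None:
        if self.true_or <= 0:
            raise ConfigurationError("true_or must be positive")
        if self.n_alleles < 2 or not 0 < self.disruptive_fraction < 1:
            raise ConfigurationError("need >= 2 alleles and fraction in (0, 1)")
        if self.total_reads_per_bin < 1:
            raise ConfigurationError("read counts must be positive")
        if self.disruptive_lengths[0] <= 3:
            raise ConfigurationError("disruptive indel lengths must exceed 3 bp")


def generate_sorted_alleles(config: SortConfig) -> pd.DataFrame:
    """Generate an allele read table with columns
    ``allele_id, ops, max_indel_len, reads_low, reads_high``.

    Allele frequencies are Dirichlet(1); total reads are
    ``2 * total_reads_per_bin`` split by per-read Bernoulli bin draws
    with P(low | disruptive) = true_or / (1 + true_or) and
    P(low | non-disruptive) = 1/2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_alleles
    n_dis = max(1, round(n * config.disruptive_fraction))
    disruptive = np.zeros(n, dtype=bool)
    disruptive[:n_dis] = True

    ops, max_len = [], []
    for i in range(n):
        if disruptive[i]:
            lo, hi = config.disruptive_lengths
            length = int(rng.integers(lo, hi + 1))
        else:
            lo, hi = config.nondisruptive_lengths
            length = int(rng.integers(lo, hi + 1))
        if length == 0:
            ops.append("SNV" if rng.random() < 0.5 else "WT")
            max_len.append(0)
        else:
            offset = int(rng.integers(-20, 21))
            kind = "D" if rng.random() < 0.7 else "I"
            ops.append(f"{offset}:{length}{kind}")
            max_len.append(length)

    freqs = rng.dirichlet(np.ones(n))
    total = 2 * config.total_reads_per_bin
    reads = rng.multinomial(total, freqs)
    p_low = np.where(disruptive, config.true_or / (1.0 + config.true_or), 0.5)
    reads_low = rng.binomial(reads, p_low)
    reads_high = reads - reads_low

    return pd.DataFrame(
        {
            "allele_id": [f"A{i + 1:04d}" for i in range(n)],
            "ops": ops,
            "max_indel_len": max_len,
            "reads_low": reads_low,
            "reads_high": reads_high,
        }
    )


# ---------------------------------------------------------------------------
# AFM particles


@dataclass(frozen=True)
class AFMParticle:
    """A particle measured by AFM: height and radius in nm."""

    h: float
    r: float


def generate_afm_particles(
    n: int,
    height_dist=("lognorm", 0.788, 0.2),
    radius_dist=("lognorm", 3.25, 0.15),
    seed: int = 0,
) -> list[AFMParticle]:
    """Draw ``n`` particles with positive heights and radii (nm).

    Distributions are given either as ``("lognorm", mu, sigma)`` tuples
    (parameters of the underlying normal), as ``("constant", value)``,
    or as any object with an ``rvs(size, random_state)`` method over
    positive support.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def draw(dist):
        if hasattr(dist, "rvs"):
            return np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)
        kind = dist[0]
        if kind == "lognorm":
            return rng.lognormal(dist[1], dist[2], size=n)
        if kind == "constant":
            return np.full(n, float(dist[1]))
        raise ConfigurationError(f"unknown distribution spec: {dist!r}")

    h = draw(height_dist)
    r = draw(radius_dist)
    if np.any(h <= 0) or np.any(r <= 0):
        raise ConfigurationError("particle heights and radii must be positive")
    return [AFMParticle(float(a), float(b)) for a, b in zip(h, r)]


# ---------------------------------------------------------------------------
# profile-level scaffolds for cluster-support benchmarks


def planted_blocks_profiles(
    n_per_block: int = 6,
    n_features: int = 60,
    separation: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two well-separated groups of gene profiles (rows x features).

    Group A gets ``+separation`` and group B ``-separation`` on the
    first half of the features; used to benchmark cluster support.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_block
    x = rng.normal(0.0, noise_sd, size=(n, n_features))
    half = n_features // 2
    x[:n_per_block, :half] += separation
    x[n_per_block:, :half] -= separation
    idx = [f"A{i + 1}" for i in range(n_per_block)] + [
        f"B{i + 1}" for i in range(n_per_block)
    ]
    return pd.DataFrame(x, index=idx, columns=[f"f{j + 1}" for j in range(n_features)])


def planted_pair_profiles(
    n_genes: int = 12,
    n_features: int = 60,
    pair_effect: float = 4.0,
    pair_noise_sd: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[str, str]]:
    """Profiles where two genes share a strong distinctive profile.

    The pair ("P1", "P2") shares one latent extreme profile on the
    first third of the features plus small independent noise, so they
    should co-cluster in essentially every feature resample; the other
    genes are unstructured.  Returns (profiles, pair labels).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, size=(n_genes, n_features))
    third = max(2, n_features // 3)
    shared = pair_effect * np.sign(rng.standard_normal(third))
    for row in (0, 1):
        x[row, :third] = shared + rng.normal(0.0, pair_noise_sd, size=third)
    idx = ["P1", "P2"] + [f"G{i + 1}" for i in range(n_genes - 2)]
    return (
        pd.DataFrame(x, index=idx, columns=[f"f{j + 1}" for j in range(n_features)]),
        ("P1", "P2"),
    )


# ---------------------------------------------------------------------------
# I/O in the package's plain-text dialects


def write_well_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_well_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def write_allele_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_allele_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_afm_particles(particles: Sequence[AFMParticle], path: str | Path) -> None:
    pd.DataFrame({"h": [p.h for p in particles], "r": [p.r for p in particles]}).to_csv(
        path, index=False
    )


def read_afm_particles(path: str | Path) -> list[AFMParticle]:
    df = pd.read_csv(path)
    return [AFMParticle(float(h), float(r)) for h, r in zip(df["h"], df["r"])]
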