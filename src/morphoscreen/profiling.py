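"""Gene-level morphologic profiles and profile statistics.

A gene's profile is the per-feature median of its guides' Z-scores;
non-targeting guides collapse into a single pseudo-row.  Profiles
support gene-gene Pearson correlation across features and ranking of
"extreme" features (|Z| above a threshold, e.g. the top-percentile 2.5
convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .feature_qc import CorrelationResult, ZMatrix, pearson_r_p

CONTROL_CLASSES = ("non_targeting", "empty")


class ProfilingError(ValueError):
    pass


@dataclass
class GeneProfileMatrix:
    """Genes (plus control pseudo-rows) x retained core features."""

    values: pd.DataFrame  # index = gene / pseudo-gene, columns = features
    row_class: pd.Series  # "gene" | "non_targeting" | "empty"

    def genes_only(self) -> "GeneProfileMatrix":
        keep = self.row_class == "gene"
        return GeneProfileMatrix(self.values[keep.to_numpy()], self.row_class[keep])

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "row_class", self.row_class)
        out.to_csv(path, index=True, index_label="gene")

    @classmethod
    def read(cls, path: str | Path) -> "GeneProfileMatrix":
        df = pd.read_csv(path, index_col="gene")
        df.index.name = None
        row_class = df.pop("row_class")
        return cls(values=df, row_class=row_class)


@dataclass(frozen=True)
class ExtremeFeature:
    """A (gene, feature) profile value exceeding the extremeness cutoff."""

    gene: str
    feature: str
    z: float
    rank: int  # within-feature rank by |z| (1 = most extreme)


def gene_profiles(
    z: ZMatrix,
    guide_to_gene: Mapping[str, str] | None = None,
) -> GeneProfileMatrix:
    """Median-aggregate guide Z-scores into gene profiles.

    ``guide_to_gene`` maps construct_id -> gene symbol or a control
    class name; when omitted it is taken from the Z-matrix's construct
    metadata.  Controls aggregate into one pseudo-row per class.
    """
    if guide_to_gene is None:
        if z.construct_meta is None:
            raise ProfilingError("no guide-to-gene map and no construct metadata")
        guide_to_gene = z.construct_meta["gene"].to_dict()
    unmapped = [c for c in z.values.index if c not in guide_to_gene]
    if unmapped:
        raise ProfilingError(f"unmapped guides: {unmapped[:5]}")

    genes = pd.Series({c: guide_to_gene[c] for c in z.values.index}, name="gene")
    med = z.values.groupby(genes).median()
    med.index.name = None
    row_class = pd.Series(
        ["non_targeting" if g == "non_targeting" else "empty" if g == "empty" else "gene"
         for g in med.index],
        index=med.index,
    )
    return GeneProfileMatrix(values=med, row_class=row_class)


def profile_correlation(a: pd.Series, b: pd.Series) -> CorrelationResult:
    """Pearson correlation between two gene profiles across features."""
    if not a.index.equals(b.index):
        raise ProfilingError("profiles must share the same feature set")
    return pearson_r_p(a.to_numpy(), b.to_numpy())


def extreme_features(
    profiles: GeneProfileMatrix,
    z_threshold: float = 2.5,
    signed: bool = False,
) -> list[ExtremeFeature]:
    """All (gene, feature) pairs with |profile Z| > threshold.

    Ranks are within-feature by |Z| (rank 1 = most extreme; under
    ``signed=True`` by signed Z, rank 1 = largest).  The returned list
    is sorted by |Z| (or Z) descending.
    """
    vals = profiles.values
    if vals.empty:
        raise ProfilingError("empty profile matrix")
    key = vals if signed else vals.abs()
    ranks = key.rank(axis=0, ascending=False, method="min").astype(int)
    mask = key > z_threshold
    out = []
    for i, j in zip(*np.nonzero(mask.to_numpy())):
        out.append(
            ExtremeFeature(
                gene=str(vals.index[i]),
                feature=str(vals.columns[j]),
                z=float(vals.iat[i, j]),
                rank=int(ranks.iat[i, j]),
            )
        )
    out.sort(key=lambda e: (e.z if signed else abs(e.z)), reverse=True)
    return out
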