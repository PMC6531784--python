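"""Feature quality control for well-level morphometric tables.

Three stages, applied in order:

1. **Reproducibility filter** — for each feature and each seeding
   density, form one vector per biological replicate (entries indexed
   by construct) and compute all C(R, 2) pairwise Pearson correlations;
   a feature is flagged ``non_reproducible`` if any pair has r < 0 or a
   two-sided p above ``alpha`` (default 0.05).
2. **Z-normalization** — reduce wells to one value per construct
   (mean over its replicate wells, densities pooled) and normalize each
   feature to mean 0 / sample SD 1 across all guides, targeting and
   non-targeting alike.
3. **Redundancy pruning** — greedily prune features until no retained
   pair exceeds an absolute Pearson correlation cutoff (default 0.9),
   always removing the member of the worst pair with the larger mean
   absolute correlation to everything still retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import META_COLUMNS


class FeatureQCError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson coefficient with its two-sided p-value and sample size."""

    r: float
    p: float
    n: int


@dataclass
class FeatureQCReport:
    """Per-feature QC outcome.

    ``status`` maps every feature to one of ``retained``,
    ``non_reproducible`` or ``correlated``; ``reason`` holds the
    offending replicate pair (and its r, p) or the redundant partner.
    """

    status: dict[str, str]
    reason: dict[str, str] = field(default_factory=dict)
    partner: dict[str, str] = field(default_factory=dict)
    detail: dict[str, CorrelationResult] = field(default_factory=dict)

    def features_with_status(self, status: str) -> list[str]:
        return [f for f, s in self.status.items() if s == status]

    @property
    def counts(self) -> dict[str, int]:
        out = {"retained": 0, "non_reproducible": 0, "correlated": 0}
        for s in self.status.values():
            out[s] += 1
        return out

    def merge(self, other: "FeatureQCReport") -> "FeatureQCReport":
        """Combine two stages' reports; later statuses override 'retained'."""
        status = dict(self.status)
        for f, s in other.status.items():
            if status.get(f, "retained") == "retained":
                status[f] = s
        return FeatureQCReport(
            status=status,
            reason={**self.reason, **other.reason},
            partner={**self.partner, **other.partner},
            detail={**self.detail, **other.detail},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, s in self.status.items():
            d = self.detail.get(f)
            rows.append(
                (
                    f,
                    s,
                    self.reason.get(f, ""),
                    self.partner.get(f, ""),
                    d.r if d else np.nan,
                    d.p if d else np.nan,
                )
            )
        return pd.DataFrame(rows, columns=["feature", "status", "reason", "partner", "r", "p"])

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.counts, indent=2) + "\n")


@dataclass
class ZMatrix:
    """Guides x features matrix of Z-scores plus the stored transform."""

    values: pd.DataFrame  # index = construct_id, columns = features
    means: pd.Series
    sds: pd.Series
    construct_meta: pd.DataFrame | None = None  # gene / well_class per construct

    def inverse(self) -> pd.DataFrame:
        return self.values * self.sds + self.means

    def select(self, features: list[str]) -> "ZMatrix":
        return ZMatrix(
            values=self.values[features],
            means=self.means[features],
            sds=self.sds[features],
            construct_meta=self.construct_meta,
        )


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# Pearson correlation


def pearson_r_p(x, y) -> CorrelationResult:
    """Sample Pearson r with the two-sided p from the exact t-transform
    ``t = r sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FeatureQCError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise FeatureQCError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FeatureQCError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def _pairwise_columnwise(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r and two-sided p for two (n, f) matrices."""
    n = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = np.sqrt((ac**2).sum(axis=0))
    sb = np.sqrt((bc**2).sum(axis=0))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    r[denom == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[np.isnan(r)] = np.nan
    return r, p


# ---------------------------------------------------------------------------
# reproducibility filter


def reproducibility_filter(
    table: pd.DataFrame,
    alpha: float = 0.05,
    rule: str = "any",
    include_nontargeting: bool = True,
) -> FeatureQCReport:
    """Flag features whose replicate-vs-replicate correlations fail.

    For every density present, one vector per replicate index is formed
    (entries = that replicate's well value per construct) and all
    replicate pairs are tested.  Under ``rule="any"`` a single pair with
    r < 0 or p > alpha marks the feature ``non_reproducible``; under
    ``rule="mean"`` the mean r over pairs must be non-negative with all
    per-pair evidence pooled via the mean p.  Features with undefined
    correlations (constant replicate vectors) are non-reproducible.
    """
    if rule not in ("any", "mean"):
        raise FeatureQCError(f"unknown rule: {rule!r}")
    feats = feature_columns(table)
    if not feats:
        raise FeatureQCError("table has no feature columns")
    df = table
    if not include_nontargeting:
        df = df[df["well_class"] == "targeting"]
    df = df[df["well_class"] != "empty"]

    reps = sorted(df["replicate"].unique())
    if len(reps) < 2:
        raise FeatureQCError("need at least 2 replicates")

    status = {f: "retained" for f in feats}
    reason: dict[str, str] = {}
    detail: dict[str, CorrelationResult] = {}
    # per feature, collect (r, p) over pairs for the "mean" rule
    acc_r = {f: [] for f in feats}
    acc_p = {f: [] for f in feats}

    for density, sub in df.groupby("density"):
        pivots = {}
        for rep in reps:
            block = sub[sub["replicate"] == rep]
            piv = block.set_index("construct_id")[feats]
            if piv.index.duplicated().any():
                dupes = piv.index[piv.index.duplicated()][:3].tolist()
                raise FeatureQCError(
                    f"duplicate wells for constructs {dupes} (replicate {rep}, density {density})"
                )
            pivots[rep] = piv
        idx = pivots[reps[0]].index
        for rep in reps[1:]:
            if not pivots[rep].index.equals(idx):
                missing = sorted(set(idx) ^ set(pivots[rep].index))[:3]
                raise FeatureQCError(
                    f"missing replicate {rep} wells for constructs {missing} at density {density}"
                )
        if len(idx) < 3:
            raise FeatureQCError("need at least 3 constructs")
        mats = {rep: pivots[rep].to_numpy(dtype=float) for rep in reps}
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1 :]:
                r, p = _pairwise_columnwise(mats[r1], mats[r2])
                for j, f in enumerate(feats):
                    acc_r[f].append(r[j])
                    acc_p[f].append(p[j])
                    if rule == "any" and status[f] == "retained":
                        if np.isnan(r[j]):
                            status[f] = "non_reproducible"
                            reason[f] = f"undefined correlation (rep {r1} vs {r2}, density {density})"
                        elif r[j] < 0 or p[j] > alpha:
                            status[f] = "non_reproducible"
                            reason[f] = f"rep {r1} vs {r2}, density {density}"
                            detail[f] = CorrelationResult(float(r[j]), float(p[j]), len(idx))

    if rule == "mean":
        for f in feats:
            rs = np.array(acc_r[f])
            ps = np.array(acc_p[f])
            if np.isnan(rs).any() or rs.mean() < 0 or ps.mean() > alpha:
                status[f] = "non_reproducible"
                reason[f] = "mean over replicate pairs"
    return FeatureQCReport(status=status, reason=reason, detail=detail)


# ---------------------------------------------------------------------------
# guide-level reduction and Z-normalization


def guide_values(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Reduce wells to one row per construct: mean over its replicate
    wells with densities pooled.  Metadata (gene, well_class) is kept as
    a MultiIndex-free frame via ``attrs['meta']``."""
    feats = features if features is not None else feature_columns(table)
    df = table[table["well_class"] != "empty"]
    grouped = df.groupby("construct_id", sort=True)
    vals = grouped[feats].mean()
    meta = grouped[["gene", "well_class"]].first()
    vals.attrs["meta"] = meta
    return vals


def znormalize(guide_matrix: pd.DataFrame) -> ZMatrix:
    """Column-wise (x - mean) / sample SD across all guide rows."""
    if guide_matrix.shape[0] < 2:
        raise FeatureQCError("need at least 2 guide rows")
    if guide_matrix.isna().any().any():
        bad = guide_matrix.columns[guide_matrix.isna().any()][:3].tolist()
        raise FeatureQCError(f"missing values in features {bad}; reject or filter upstream")
    means = guide_matrix.mean(axis=0)
    sds = guide_matrix.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][:3].tolist()
        raise FeatureQCError(f"constant features {bad}: remove upstream before Z-normalization")
    z = (guide_matrix - means) / sds
    meta = guide_matrix.attrs.get("meta")
    return ZMatrix(values=z, means=means, sds=sds, construct_meta=meta)


# ---------------------------------------------------------------------------
# correlation-redundancy pruning


def prune_correlated(z: ZMatrix | pd.DataFrame, cutoff: float = 0.9) -> FeatureQCReport:
    """Greedy pruning of the absolute correlation matrix.

    Repeatedly locate the remaining pair with the largest |r| above
    ``cutoff`` and drop the member with the larger mean absolute
    correlation to all remaining features (ties: drop the later column
    in header order).  Terminates with no retained pair above cutoff.
    """
    if not 0.0 < cutoff <= 1.0:
        raise FeatureQCError("cutoff must be in (0, 1]")
    values = z.values if isinstance(z, ZMatrix) else z
    feats = list(values.columns)
    if len(feats) < 2:
        return FeatureQCReport(status={f: "retained" for f in feats})
    corr = np.abs(np.corrcoef(values.to_numpy(dtype=float), rowvar=False))
    np.fill_diagonal(corr, 0.0)

    active = np.ones(len(feats), dtype=bool)
    status = {f: "retained" for f in feats}
    partner: dict[str, str] = {}
    while True:
        sub = corr[np.ix_(active, active)]
        if sub.size == 0 or sub.max() <= cutoff:
            break
        act_idx = np.flatnonzero(active)
        i_s, j_s = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = act_idx[i_s], act_idx[j_s]
        # mean |r| to all other remaining features
        mean_i = sub[i_s].sum() / (sub.shape[0] - 1)
        mean_j = sub[j_s].sum() / (sub.shape[0] - 1)
        if mean_i > mean_j:
            drop, keep = i, j
        elif mean_j > mean_i:
            drop, keep = j, i
        else:  # deterministic tie-break: larger column index goes
            drop, keep = max(i, j), min(i, j)
        active[drop] = False
        status[feats[drop]] = "correlated"
        partner[feats[drop]] = feats[keep]

    report = FeatureQCReport(status=status, partner=partner)
    # invariant: no retained pair above cutoff
    rest = corr[np.ix_(active, active)]
    assert rest.size == 0 or rest.max() <= cutoff
    return report


# ---------------------------------------------------------------------------
# one-call QC


def run_feature_qc(
    table: pd.DataFrame,
    alpha: float = 0.05,
    cutoff: float = 0.9,
    rule: str = "any",
) -> tuple[FeatureQCReport, ZMatrix]:
    """Apply the full QC chain and return the combined report plus the
    Z-matrix restricted to retained core features."""
    rep_report = reproducibility_filter(table, alpha=alpha, rule=rule)
    kept = rep_report.features_with_status("retained")
    if not kept:
        raise FeatureQCError("no reproducible features")
    z = znormalize(guide_values(table, kept))
    prune_report = prune_correlated(z, cutoff=cutoff)
    report = rep_report.merge(prune_report)
    core = report.features_with_status("retained")
    return report, z.select(core)
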