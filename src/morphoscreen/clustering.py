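"""Hierarchical clustering of gene profiles with bootstrap support.

Clustering follows the screen's published recipe: pairwise Euclidean
distances between gene profiles, agglomerated under the Ward.D2
convention (the Lance-Williams update runs on squared dissimilarities;
merge heights are reported on the original scale).  Cluster confidence
comes from multiscale bootstrap resampling of the feature columns: the
bootstrap probability BP of each full-data cluster is measured at
several resample-size scales r = n'/n and extrapolated through the
probit model

    Phi^-1(1 - BP(r)) = v * sqrt(r) + c / sqrt(r)

(n' = resampled feature count; v = signed distance, c = curvature) to
the approximately-unbiased p-value AU = 1 - Phi(v - c).  Small 1 - AU ("resampling p") indicates robust
co-clustering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .profiling import GeneProfileMatrix


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterTree:
    """Agglomerative merge history.

    ``merges`` is an (n-1, 4) array in scipy linkage layout: child ids
    (leaves are 0..n-1, internal nodes n..2n-2 in merge order), merge
    height on the original distance scale, and cluster size.
    """

    labels: list[str]
    merges: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Leaf-index set of every internal node, keyed by node id."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for step, (a, b, _, _) in enumerate(self.merges):
            sets[n + step] = sets[int(a)] | sets[int(b)]
        return {k: v for k, v in sets.items() if k >= n}


def distance_matrix(profiles: GeneProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance over feature columns."""
    values = profiles.values if isinstance(profiles, GeneProfileMatrix) else profiles
    if values.shape[0] < 2:
        raise ClusteringError("need at least 2 rows")
    if values.isna().any().any():
        raise ClusteringError("profile matrix contains missing values")
    d = squareform(pdist(values.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=values.index, columns=values.index)


def _ward_merges(d: np.ndarray) -> np.ndarray:
    """Ward.D2 agglomeration on a square distance matrix.

    Ties on the minimal Ward distance are broken toward the pair whose
    smallest contained original leaf index is least (then the other
    member's smallest leaf index), making the merge order deterministic.
    """
    n = d.shape[0]
    m = d.astype(float) ** 2  # squared dissimilarities, Lance-Williams scale
    size = np.ones(n)
    min_leaf = np.arange(n)
    cluster_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    np.fill_diagonal(m, np.inf)
    m[:, ~active] = np.inf  # no-op, shape keeper

    merges = np.empty((n - 1, 4))
    last_h = 0.0
    for step in range(n - 1):
        sub = np.where(active[:, None] & active[None, :], m, np.inf)
        best = sub.min()
        ti, tj = np.nonzero(sub == best)
        # candidate pairs (i < j); pick by smallest-leaf key
        key = None
        for a, b in zip(ti, tj):
            if a >= b:
                continue
            k = (min(min_leaf[a], min_leaf[b]), max(min_leaf[a], min_leaf[b]))
            if key is None or k < key:
                key, i, j = k, a, b
        h = float(np.sqrt(best))
        if h < last_h - 1e-9:
            raise AssertionError("Ward merge heights must be non-decreasing")
        last_h = max(last_h, h)

        left, right = (i, j) if min_leaf[i] <= min_leaf[j] else (j, i)
        merges[step] = (cluster_id[left], cluster_id[right], h, size[i] + size[j])

        # Lance-Williams update for Ward on squared dissimilarities
        others = active.copy()
        others[[i, j]] = False
        k_idx = np.nonzero(others)[0]
        if k_idx.size:
            nk = size[k_idx]
            ni, nj = size[i], size[j]
            new = ((ni + nk) * m[i, k_idx] + (nj + nk) * m[j, k_idx] - nk * best) / (
                ni + nj + nk
            )
            m[i, k_idx] = new
            m[k_idx, i] = new
        size[i] += size[j]
        min_leaf[i] = min(min_leaf[i], min_leaf[j])
        cluster_id[i] = n + step
        active[j] = False
        m[j, :] = np.inf
        m[:, j] = np.inf
    return merges


def ward_cluster(d: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> ClusterTree:
    """Cluster a distance matrix under Ward.D2."""
    if isinstance(d, pd.DataFrame):
        labels = [str(x) for x in d.index]
        arr = d.to_numpy(dtype=float)
    else:
        arr = np.asarray(d, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(arr.shape[0])]
        labels = list(labels)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ClusteringError("distance matrix must be square")
    if arr.shape[0] < 2:
        raise ClusteringError("need at least 2 leaves")
    if np.any(arr < 0) or not np.allclose(arr, arr.T, atol=1e-10):
        raise ClusteringError("distance matrix must be symmetric and non-negative")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ClusteringError("distance matrix must have a zero diagonal")
    return ClusterTree(labels=labels, merges=_ward_merges(arr))


def cut_tree(tree: ClusterTree, k: int) -> dict[str, int]:
    """Assign leaves to k clusters by undoing the last k-1 merges.

    Cluster ids are 1..k, ordered by the smallest leaf index each
    cluster contains.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ClusteringError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = tree.merges[step]
        node = n + step
        parent[find(int(a))] = node
        parent[find(int(b))] = node

    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(roots.values(), key=min)
    out: dict[str, int] = {}
    for cid, leaves in enumerate(ordered, start=1):
        for leaf in leaves:
            out[tree.labels[leaf]] = cid
    return out


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick rendering with leaves at height 0 and each node plotted at
    half its merge height (so a two-leaf tree of height d reads
    ``(A:{d/2},B:{d/2});``)."""
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    text = {i: _escape(tree.labels[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        node = n + step
        height[node] = h / 2.0
        la = height[node] - height[a]
        lb = height[node] - height[b]
        text[node] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
    return text[2 * n - 2] + ";"


def _escape(label: str) -> str:
    if any(ch in label for ch in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# multiscale bootstrap


@dataclass
class BootstrapConfig:
    """Multiscale bootstrap settings.

    ``scales`` are resample-size fractions n'/n; the default ten scales
    at 1,000 replications each give 10,000 bootstrap trees in total.
    """

    scales: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)
    replications_per_scale: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if len(self.scales) < 3:
            raise ClusteringError("need at least 3 scales for the curve fit")
        if any(s <= 0 for s in self.scales):
            raise ClusteringError("scales must be strictly positive")
        if self.replications_per_scale < 1:
            raise ClusteringError("replications_per_scale must be >= 1")


@dataclass
class ClusterSupport:
    """Bootstrap support for one internal node of the full-data tree."""

    node_id: int
    leaves: tuple[str, ...]
    bp_by_scale: dict[float, float]
    au: float
    bp: float
    v: float
    c: float
    fit_ok: bool
    residual: float = float("nan")
    df: int = 0
    note: str = ""

    @property
    def resampling_p(self) -> float:
        return 1.0 - self.au


def _fit_au(
    counts: np.ndarray, sigma2: np.ndarray, b: int
) -> tuple[float, float, float, bool, float, int, str]:
    """Fit the probit multiscale model; returns (au, v, c, ok, resid, df, note)."""
    usable = (counts > 0) & (counts < b)
    if usable.sum() < 3:
        # Degenerate fit: (nearly) every scale sits at a BP boundary, so
        # the probit curve is unidentifiable.  Fall back to the aggregate
        # bootstrap probability over all replications -- for a cluster
        # present in every bootstrap tree this is exactly 1.
        au = float(counts.sum() / (b * len(counts)))
        note = "degenerate fit (<3 informative scales): AU = pooled BP"
        if np.all(counts == b):
            note = "all scales at BP=1"
        elif np.all(counts == 0):
            note = "all scales at BP=0"
        return au, float("nan"), float("nan"), False, float("nan"), 0, note
    bp = np.clip(counts / b, 1.0 / (b + 1), 1.0 - 1.0 / (b + 1))
    z = norm.isf(bp)  # Phi^-1(1 - BP)
    w = b * norm.pdf(z) ** 2 / (bp * (1.0 - bp))  # binomial-variance weights
    # z(sigma) = v/sigma + c*sigma: the signed distance v scales with the
    # resample fraction sqrt(r) = 1/sigma, the curvature c with sigma
    sigma = np.sqrt(sigma2)
    design = np.column_stack([1.0 / sigma, sigma])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    resid = float(np.sum(w * (z - design @ coef) ** 2))
    au = float(1.0 - norm.cdf(v - c))
    return au, v, c, True, resid, len(z) - 2, ""


def multiscale_bootstrap(
    profiles: GeneProfileMatrix | pd.DataFrame,
    cfg: BootstrapConfig | None = None,
) -> tuple[ClusterTree, dict[int, ClusterSupport]]:
    """Multiscale bootstrap support for every node of the full-data tree.

    Features (columns) are the resampled observations: at each scale r,
    ``round(r * n_features)`` columns are drawn with replacement, the
    rows are re-clustered, and each full-data node scores a hit when
    some bootstrap node has exactly its leaf set.
    """
    cfg = cfg or BootstrapConfig()
    cfg.validate()
    values = profiles.values if isinstance(profiles, GeneProfileMatrix) else profiles
    x = values.to_numpy(dtype=float)
    labels = [str(i) for i in values.index]
    n_feat = x.shape[1]
    if n_feat < 4:
        raise ClusteringError("need at least 4 feature columns to resample")

    tree = ward_cluster(distance_matrix(values))
    node_sets = tree.leaf_sets()
    set_to_node = {s: nid for nid, s in node_sets.items()}

    rng = np.random.default_rng(cfg.seed)
    b = cfg.replications_per_scale
    counts = {nid: np.zeros(len(cfg.scales), dtype=int) for nid in node_sets}
    sigma2 = np.empty(len(cfg.scales))
    n_rows = x.shape[0]

    for si, scale in enumerate(cfg.scales):
        m = max(2, round(scale * n_feat))
        sigma2[si] = n_feat / m
        for _ in range(b):
            cols = rng.integers(0, n_feat, size=m)
            xb = x[:, cols]
            d = squareform(pdist(xb, metric="euclidean"))
            merges = _ward_merges(d)
            sets: list[frozenset[int]] = [frozenset([i]) for i in range(n_rows)]
            for a, bb, _, _ in merges:
                s = sets[int(a)] | sets[int(bb)]
                sets.append(s)
                nid = set_to_node.get(s)
                if nid is not None:
                    counts[nid][si] += 1

    support: dict[int, ClusterSupport] = {}
    one_idx = int(np.argmin(np.abs(np.asarray(cfg.scales) - 1.0)))
    for nid, leaf_set in node_sets.items():
        au, v, c, ok, resid, dof, note = _fit_au(counts[nid], sigma2, b)
        support[nid] = ClusterSupport(
            node_id=nid,
            leaves=tuple(tree.labels[i] for i in sorted(leaf_set)),
            bp_by_scale={float(s): counts[nid][i] / b for i, s in enumerate(cfg.scales)},
            au=au,
            bp=counts[nid][one_idx] / b,
            v=v,
            c=c,
            fit_ok=ok,
            residual=resid,
            df=dof,
            note=note,
        )
    return tree, support


def pair_support(
    support: dict[int, ClusterSupport], pair: tuple[str, str]
) -> ClusterSupport | None:
    """Support record of the smallest node containing both labels."""
    best = None
    for s in support.values():
        if pair[0] in s.leaves and pair[1] in s.leaves:
            if best is None or len(s.leaves) < len(best.leaves):
                best = s
    return best


def write_support(support: dict[int, ClusterSupport], path: str | Path) -> None:
    rows = [
        {
            "node_id": s.node_id,
            "leaves": list(s.leaves),
            "au": None if np.isnan(s.au) else s.au,
            "bp": s.bp,
            "v": None if np.isnan(s.v) else s.v,
            "c": None if np.isnan(s.c) else s.c,
            "fit_ok": s.fit_ok,
            "note": s.note,
            "bp_by_scale": s.bp_by_scale,
        }
        for s in sorted(support.values(), key=lambda s: s.node_id)
    ]
    Path(path).write_text(json.dumps(rows, indent=2) + "\n")
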