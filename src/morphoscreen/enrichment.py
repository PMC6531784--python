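"""Gene-set enrichment of clusters via 2x2 tables.

Each (cluster, gene set) pair is summarized by the contingency table

    a = in cluster & in set        b = in cluster & not in set
    c = not in cluster & in set    d = neither

with the sample cross-product odds ratio ad/bc (Haldane-Anscombe +0.5
correction when any cell is empty) and the hypergeometric upper-tail
p-value P(X >= a).  p-values are raw; a Benjamini-Hochberg column is
emitted for convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise EnrichmentError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    cluster: int
    gene_set: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    haldane_applied: bool
    bh_q: float = float("nan")


def hypergeom_tail(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), summed in
    log space for numerical stability deep in the tail."""
    if not (0 <= big_k <= big_n and 0 <= n <= big_n):
        raise EnrichmentError("need K, n <= N and all counts non-negative")
    if not 0 <= k <= min(big_k, n):
        raise EnrichmentError("k must satisfy 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(big_k, n) + 1)
    return float(min(1.0, np.exp(logsumexp(hypergeom.logpmf(ks, big_n, big_k, n)))))


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Sample cross-product odds ratio; returns (OR, haldane_applied)."""
    if min(a, b, c, d) < 0:
        raise EnrichmentError("counts must be non-negative")
    if a + b + c + d == 0:
        raise EnrichmentError("all-zero table")
    if 0 in (a, b, c, d):
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (aa * dd) / (bb * cc), True
    return (a * d) / (b * c), False


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Two-column tab-separated file: set name, gene symbol."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"], comment="#")
    return [
        GeneSet(name=str(name), members=frozenset(map(str, sub["gene"])))
        for name, sub in df.groupby("set", sort=True)
    ]


def cluster_enrichment(
    assignments: Mapping[str, int],
    sets: Iterable[GeneSet],
    universe: Iterable[str] | None = None,
    control_classes: Iterable[str] = ("non_targeting", "empty"),
) -> list[EnrichmentResult]:
    """Enrichment of every gene set in every cluster.

    ``assignments`` maps leaf label -> cluster id (control pseudo-rows
    are excluded from the universe); ``universe`` defaults to all
    assigned genes.  Set members outside the universe are dropped.
    """
    controls = set(control_classes)
    assigned = {g: cl for g, cl in assignments.items() if g not in controls}
    uni = set(universe) if universe is not None else set(assigned)
    uni -= controls
    if not uni:
        raise EnrichmentError("empty gene universe")
    missing = uni - set(assigned)
    if missing:
        raise EnrichmentError(f"universe genes without a cluster: {sorted(missing)[:5]}")

    big_n = len(uni)
    results: list[EnrichmentResult] = []
    for cl in sorted(set(assigned.values())):
        in_cluster = {g for g, c in assigned.items() if c == cl and g in uni}
        n = len(in_cluster)
        for gs in sets:
            members = gs.members & uni
            if not members:
                continue
            big_k = len(members)
            a = len(in_cluster & members)
            b = n - a
            c = big_k - a
            d = big_n - a - b - c
            oratio, haldane = odds_ratio_2x2(a, b, c, d)
            p = hypergeom_tail(a, big_k, n, big_n)
            results.append(
                EnrichmentResult(cl, gs.name, a, b, c, d, oratio, p, haldane)
            )

    # BH q-values across all tests (informational only)
    if results:
        ps = np.array([r.p for r in results])
        order = np.argsort(ps)
        m = len(ps)
        q = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            q[i] = running
        for r, qi in zip(results, q):
            r.bh_q = float(qi)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.cluster, r.gene_set, r.a, r.b, r.c, r.d, r.odds_ratio, r.p, r.bh_q, r.haldane_applied)
            for r in results
        ],
        columns=["cluster", "set", "a", "b", "c", "d", "odds_ratio", "p", "bh_q", "haldane"],
    )
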