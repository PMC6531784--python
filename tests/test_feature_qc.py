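"""Reproducibility filtering, Z-normalization, and redundancy pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoscreen import feature_qc as fq
from morphoscreen import synthetic_data as sd

# ---------------------------------------------------------------------------
# pearson_r_p


def test_pearson_identity_and_reversal():
    assert fq.pearson_r_p([1, 2, 3, 4], [1, 2, 3, 4]).r == pytest.approx(1.0)
    assert fq.pearson_r_p([1, 2, 3, 4], [4, 3, 2, 1]).r == pytest.approx(-1.0)


def test_pearson_p_matches_permutation_oracle():
    rng = np.random.default_rng(42)
    x = rng.standard_normal(20)
    y = 0.5 * x + rng.standard_normal(20)
    res = fq.pearson_r_p(x, y)

    n_perm = 100_000
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])
    xc = x - x.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_perm = (pc @ xc) / (np.linalg.norm(xc) * np.linalg.norm(pc, axis=1))
    p_perm = (np.sum(np.abs(r_perm) >= abs(res.r) - 1e-12) + 1) / (n_perm + 1)
    se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert abs(res.p - p_perm) < 4 * se + 1e-3


def test_pearson_rejects_bad_input():
    with pytest.raises(fq.FeatureQCError):
        fq.pearson_r_p([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(fq.FeatureQCError):
        fq.pearson_r_p([1, 2], [3, 4])


# ---------------------------------------------------------------------------
# reproducibility filter


def _toy_table(vectors_by_rep, feature="f0001_mean"):
    """Build a minimal well table with one feature and R replicates."""
    rows = []
    n_con = len(next(iter(vectors_by_rep.values())))
    for rep, vec in vectors_by_rep.items():
        for ci in range(n_con):
            rows.append((f"C{ci:03d}", f"G{ci:03d}", 1, "targeting", rep, 1, 1, "W001", vec[ci]))
    return pd.DataFrame(rows, columns=sd.META_COLUMNS + [feature])


def test_identical_replicates_retained():
    vec = list(np.linspace(0, 5, 50))
    table = _toy_table({r: vec for r in (1, 2, 3, 4)})
    report = fq.reproducibility_filter(table)
    assert report.status["f0001_mean"] == "retained"


def test_anticorrelated_replicate_flagged():
    vec = list(np.linspace(0, 5, 50))
    table = _toy_table({1: vec, 2: [-v for v in vec], 3: vec, 4: vec})
    report = fq.reproducibility_filter(table)
    assert report.status["f0001_mean"] == "non_reproducible"


def test_missing_replicate_names_construct():
    table = _toy_table({1: list(range(10)), 2: list(range(10))})
    table = table[~((table.construct_id == "C004") & (table.replicate == 2))]
    with pytest.raises(fq.FeatureQCError, match="C004"):
        fq.reproducibility_filter(table)


def test_filter_statuses_match_bruteforce_oracle(small_screen):
    """All six replicate-pair correlations per feature, recomputed one
    scipy.pearsonr call at a time, must give the same status set."""
    table, _ = small_screen
    report = fq.reproducibility_filter(table)
    pivots = {
        rep: table[table.replicate == rep].set_index("construct_id")
        for rep in sorted(table.replicate.unique())
    }
    idx = pivots[1].index
    for feat in fq.feature_columns(table):
        failed = False
        reps = sorted(pivots)
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1 :]:
                x = pivots[r1].loc[idx, feat]
                y = pivots[r2].loc[idx, feat]
                r, p = stats.pearsonr(x, y)
                if r < 0 or p > 0.05:
                    failed = True
        expected = "non_reproducible" if failed else "retained"
        assert report.status[feat] == expected, feat


def test_planted_noise_flagged_redundant_pruned_over_seeds():
    """Across 20 seeds, every planted noise feature is non-reproducible
    and at least 95% of planted duplicates are pruned as correlated."""
    n_dup_total = n_dup_flagged = 0
    for seed in range(20):
        cfg = sd.ScreenConfig(
            n_genes=15, guides_per_gene=3, n_nontargeting=8, replicates=4,
            densities=1, n_features=60, n_noise_features=6,
            n_redundant_features=12, n_lethal=4, n_lipo=4, seed=seed,
        )
        table, truth = sd.generate_screen(cfg)
        report, _ = fq.run_feature_qc(table)
        for f in truth.noise_features:
            assert report.status[f] == "non_reproducible"
        dup_flags = [
            report.status[f] == "correlated" or report.status[truth.redundant_parent[f]] == "correlated"
            for f in truth.redundant_parent
        ]
        n_dup_total += len(dup_flags)
        n_dup_flagged += sum(dup_flags)
    assert n_dup_flagged / n_dup_total >= 0.95


def test_bookkeeping_partitions_features(small_qc):
    report, _ = small_qc
    counts = report.counts
    assert sum(counts.values()) == len(report.status) == 60
    assert set(counts) == {"retained", "non_reproducible", "correlated"}


# ---------------------------------------------------------------------------
# Z-normalization


def test_znormalize_column_and_roundtrip():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 1.0, 0.0]})
    z = fq.znormalize(df)
    np.testing.assert_allclose(z.values["a"], [-1, 0, 1])
    assert abs(z.values.mean(axis=0)).max() < 1e-9
    assert abs(z.values.std(axis=0, ddof=1) - 1).max() < 1e-9
    np.testing.assert_allclose(z.inverse().to_numpy(), df.to_numpy(), atol=1e-9)


def test_znormalize_rejects_constant_column():
    with pytest.raises(fq.FeatureQCError, match="constant"):
        fq.znormalize(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}))


# ---------------------------------------------------------------------------
# redundancy pruning


def _exact_corr_pair(n, r, rng):
    """Two n-vectors whose sample correlation is exactly r."""
    x = rng.standard_normal(n)
    w = rng.standard_normal(n)
    xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
    wc = w - w.mean() - ((w - w.mean()) @ xc) * xc
    wc /= np.linalg.norm(wc)
    return x, r * xc + np.sqrt(1 - r**2) * wc


def test_duplicate_column_pruned_once():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
    df["dup"] = df["c"]
    report = fq.prune_correlated(df, cutoff=0.9)
    assert report.counts["correlated"] == 1
    assert {report.status["c"], report.status["dup"]} == {"retained", "correlated"}


def test_pair_just_below_cutoff_survives():
    rng = np.random.default_rng(2)
    x, y = _exact_corr_pair(40, 0.89, rng)
    df = pd.DataFrame({"x": x, "y": y, "z": rng.standard_normal(40)})
    report = fq.prune_correlated(df, cutoff=0.9)
    assert all(s == "retained" for s in report.status.values())


def _naive_greedy_prune(values: pd.DataFrame, cutoff: float) -> set:
    """Independent re-implementation of the greedy rule, recomputed from
    scratch each iteration."""
    remaining = list(values.columns)
    while True:
        corr = values[remaining].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() <= cutoff:
            return set(remaining)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        mean_i = corr.values[i].sum() / (len(remaining) - 1)
        mean_j = corr.values[j].sum() / (len(remaining) - 1)
        if mean_i > mean_j:
            drop = remaining[i]
        elif mean_j > mean_i:
            drop = remaining[j]
        else:
            drop = remaining[max(i, j)]
        remaining.remove(drop)


def test_prune_matches_naive_oracle():
    rng = np.random.default_rng(3)
    base = rng.standard_normal((30, 6))
    extra = base[:, :4] + 0.1 * rng.standard_normal((30, 4))
    df = pd.DataFrame(np.hstack([base, extra]), columns=[f"v{i}" for i in range(10)])
    report = fq.prune_correlated(df, cutoff=0.9)
    retained = set(report.features_with_status("retained"))
    assert retained == _naive_greedy_prune(df, 0.9)
    # no retained pair above cutoff
    corr = df[sorted(retained)].corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    assert corr.values.max() <= 0.9


def test_prune_invalid_cutoff():
    with pytest.raises(fq.FeatureQCError):
        fq.prune_correlated(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}), cutoff=1.5)
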