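"""Ward.D2 agglomeration, tree cutting, Newick export, bootstrap AU."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from morphoscreen import clustering as cl
from morphoscreen import synthetic_data as sd

# ---------------------------------------------------------------------------
# distances


def test_distance_trivial_cases():
    df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]], index=list("abc"))
    d = cl.distance_matrix(df)
    assert d.at["a", "b"] == pytest.approx(5.0)
    assert d.at["a", "c"] == 0.0
    assert np.allclose(d.values, d.values.T)


def test_distance_matches_direct_formula():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.standard_normal((6, 4)))
    d = cl.distance_matrix(df).to_numpy()
    for i in range(6):
        for j in range(6):
            expected = np.sqrt(((df.iloc[i] - df.iloc[j]) ** 2).sum())
            assert d[i, j] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Ward.D2


def _naive_ward(d: np.ndarray):
    """Brute-force Lance-Williams re-agglomeration on squared
    dissimilarities, re-scanning the full matrix each step."""
    n = d.shape[0]
    clusters = {i: {"leaves": {i}, "id": i} for i in range(n)}
    m = {(i, j): d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            m[tuple(sorted((a, b)))] for a in keys for b in keys if a < b
        )
        candidates = [
            (min(min(clusters[a]["leaves"]), min(clusters[b]["leaves"])),
             max(min(clusters[a]["leaves"]), min(clusters[b]["leaves"])), a, b)
            for a in keys for b in keys
            if a < b and m[tuple(sorted((a, b)))] == best
        ]
        _, _, i, j = min(candidates)
        ni, nj = len(clusters[i]["leaves"]), len(clusters[j]["leaves"])
        li, lj = min(clusters[i]["leaves"]), min(clusters[j]["leaves"])
        ids = (clusters[i]["id"], clusters[j]["id"])
        left, right = ids if li <= lj else ids[::-1]
        merges.append((left, right, np.sqrt(best), ni + nj))
        for k in clusters:
            if k in (i, j):
                continue
            nk = len(clusters[k]["leaves"])
            dik = m[tuple(sorted((i, k)))]
            djk = m[tuple(sorted((j, k)))]
            m[tuple(sorted((i, k)))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * best
            ) / (ni + nj + nk)
        clusters[i] = {"leaves": clusters[i]["leaves"] | clusters[j]["leaves"], "id": next_id}
        del clusters[j]
        next_id += 1
    return np.array(merges)


def test_two_leaves_single_merge():
    tree = cl.ward_cluster(np.array([[0.0, 2.5], [2.5, 0.0]]), labels=["A", "B"])
    assert tree.merges.shape == (1, 4)
    assert tree.merges[0, 2] == pytest.approx(2.5)


def test_one_dimensional_points_merge_order():
    pts = np.array([[0.0], [1.0], [10.0]])
    d = squareform(pdist(pts))
    tree = cl.ward_cluster(d, labels=["p0", "p1", "p10"])
    assert tree.leaf_sets()[3] == frozenset({0, 1})
    expected = _naive_ward(d)
    np.testing.assert_allclose(tree.merges, expected)


@pytest.mark.parametrize("n", range(3, 13))
def test_ward_equals_naive_oracle_small_n(n):
    rng = np.random.default_rng(100 + n)
    d = squareform(pdist(rng.standard_normal((n, 4))))
    tree = cl.ward_cluster(d)
    np.testing.assert_allclose(tree.merges, _naive_ward(d), rtol=1e-10, atol=1e-10)


def test_ward_heights_match_scipy_and_are_monotone():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((25, 6))
    tree = cl.ward_cluster(squareform(pdist(x)))
    ref = linkage(pdist(x), method="ward")
    np.testing.assert_allclose(tree.merges[:, 2], ref[:, 2], atol=1e-9)
    heights = tree.merges[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)


def test_ward_invariant_to_row_order():
    rng = np.random.default_rng(9)
    x = rng.standard_normal((10, 5))
    labels = [f"L{i}" for i in range(10)]
    d1 = cl.distance_matrix(pd.DataFrame(x, index=labels))
    perm = rng.permutation(10)
    d2 = cl.distance_matrix(pd.DataFrame(x[perm], index=[labels[i] for i in perm]))
    t1, t2 = cl.ward_cluster(d1), cl.ward_cluster(d2)
    np.testing.assert_allclose(t1.merges[:, 2], t2.merges[:, 2], atol=1e-9)
    sets1 = {frozenset(t1.labels[i] for i in s) for s in t1.leaf_sets().values()}
    sets2 = {frozenset(t2.labels[i] for i in s) for s in t2.leaf_sets().values()}
    assert sets1 == sets2


def test_ward_rejects_bad_matrices():
    with pytest.raises(cl.ClusteringError):
        cl.ward_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(cl.ClusteringError):
        cl.ward_cluster(np.array([[0.0, -1.0], [-1.0, 0.0]]))


# ---------------------------------------------------------------------------
# cutting


def test_cut_tree_boundary_ks():
    rng = np.random.default_rng(1)
    d = squareform(pdist(rng.standard_normal((6, 3))))
    tree = cl.ward_cluster(d, labels=list("abcdef"))
    assert set(cl.cut_tree(tree, 1).values()) == {1}
    assert sorted(cl.cut_tree(tree, 6).values()) == [1, 2, 3, 4, 5, 6]
    with pytest.raises(cl.ClusteringError):
        cl.cut_tree(tree, 0)


def test_cut_recovers_planted_groups(small_screen, small_qc):
    from sklearn.metrics import adjusted_rand_score

    from morphoscreen import profiling as pr

    _, truth = small_screen
    _, z = small_qc
    prof = pr.gene_profiles(z)
    tree = cl.ward_cluster(cl.distance_matrix(prof))
    cut = cl.cut_tree(tree, 3)
    genes = [g for g in cut if g in truth.true_group]
    ari = adjusted_rand_score([truth.true_group[g] for g in genes], [cut[g] for g in genes])
    assert ari >= 0.9


# ---------------------------------------------------------------------------
# Newick


def test_newick_two_leaves_symmetric_split():
    tree = cl.ward_cluster(np.array([[0.0, 1.0], [1.0, 0.0]]), labels=["A", "B"])
    assert cl.tree_to_newick(tree) == "(A:0.5,B:0.5);"


def test_newick_roundtrip_topology_and_heights():
    from Bio import Phylo

    rng = np.random.default_rng(4)
    x = rng.standard_normal((5, 3))
    labels = [f"L{i}" for i in range(5)]
    tree = cl.ward_cluster(cl.distance_matrix(pd.DataFrame(x, index=labels)))
    newick = cl.tree_to_newick(tree)
    parsed = Phylo.read(io.StringIO(newick), "newick")
    assert {t.name for t in parsed.get_terminals()} == set(labels)
    # root-to-leaf depth equals half the final merge height for every leaf
    depths = parsed.depths()
    root_height = tree.merges[-1, 2] / 2
    for term in parsed.get_terminals():
        assert depths[term] == pytest.approx(root_height, abs=1e-8)
    # topology invariant under leaf permutation of the input
    perm = rng.permutation(5)
    tree2 = cl.ward_cluster(
        cl.distance_matrix(pd.DataFrame(x[perm], index=[labels[i] for i in perm]))
    )
    parsed2 = Phylo.read(io.StringIO(cl.tree_to_newick(tree2)), "newick")
    clades1 = {frozenset(t.name for t in c.get_terminals()) for c in parsed.get_nonterminals()}
    clades2 = {frozenset(t.name for t in c.get_terminals()) for c in parsed2.get_nonterminals()}
    assert clades1 == clades2


# ---------------------------------------------------------------------------
# multiscale bootstrap


def test_bootstrap_deterministic_and_probabilities_valid():
    prof = sd.planted_blocks_profiles(n_per_block=4, n_features=24, seed=3)
    cfg = cl.BootstrapConfig(replications_per_scale=50, seed=12)
    _, s1 = cl.multiscale_bootstrap(prof, cfg)
    _, s2 = cl.multiscale_bootstrap(prof, cfg)
    for nid in s1:
        assert s1[nid].bp == s2[nid].bp
        assert (np.isnan(s1[nid].au) and np.isnan(s2[nid].au)) or s1[nid].au == s2[nid].au
        assert 0 <= s1[nid].bp <= 1
        assert np.isnan(s1[nid].au) or 0 <= s1[nid].au <= 1
        for bp in s1[nid].bp_by_scale.values():
            assert 0 <= bp <= 1


def test_wls_fit_matches_normal_equations_oracle():
    b = 1000
    # BP rising with the resample fraction, as for a genuine cluster
    counts = np.array([700, 730, 750, 770, 800, 820, 850, 880, 900, 920])
    scales = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4])
    sigma2 = 1.0 / scales
    au, v, c, ok, _, dof, _ = cl._fit_au(counts, sigma2, b)
    assert ok and dof == 8
    # independent closed-form weighted normal equations
    bp = counts / b
    z = norm.isf(bp)
    w = b * norm.pdf(z) ** 2 / (bp * (1 - bp))
    design = np.column_stack([np.sqrt(scales), 1 / np.sqrt(scales)])
    a_mat = design.T @ (design * w[:, None])
    rhs = design.T @ (w * z)
    v_ref, c_ref = np.linalg.solve(a_mat, rhs)
    assert v == pytest.approx(v_ref, abs=1e-10)
    assert c == pytest.approx(c_ref, abs=1e-10)
    assert au == pytest.approx(1 - norm.cdf(v_ref - c_ref), abs=1e-12)
    # BP rising with the resample fraction implies positive curvature,
    # so the AU correction lifts support above the plain bootstrap BP
    assert c > 0
    assert au >= bp[5]


def test_perfectly_stable_cluster_gets_au_one():
    counts = np.full(10, 200)
    au, *_ , note = cl._fit_au(counts, 1.0 / np.linspace(0.5, 1.4, 10), 200)
    assert au == 1.0 and "BP=1" in note
    # near-boundary degenerate fits fall back to the pooled BP
    counts2 = np.full(10, 200)
    counts2[3] = 199
    au2, *_, note2 = cl._fit_au(counts2, 1.0 / np.linspace(0.5, 1.4, 10), 200)
    assert au2 == pytest.approx(1999 / 2000)
    assert "degenerate" in note2


def test_planted_blocks_have_high_support():
    prof = sd.planted_blocks_profiles(n_per_block=5, n_features=40, seed=6)
    _, support = cl.multiscale_bootstrap(prof, cl.BootstrapConfig(replications_per_scale=100, seed=6))
    a_set = frozenset(f"A{i+1}" for i in range(5))
    b_set = frozenset(f"B{i+1}" for i in range(5))
    found = {frozenset(s.leaves): s.au for s in support.values()}
    assert found[a_set] > 0.95
    assert found[b_set] > 0.95


def test_planted_pair_coclusters_with_low_resampling_p():
    prof, pair = sd.planted_pair_profiles(seed=5)
    _, support = cl.multiscale_bootstrap(prof, cl.BootstrapConfig(replications_per_scale=100, seed=5))
    node = cl.pair_support(support, pair)
    assert set(node.leaves) == set(pair)
    assert node.resampling_p <= 0.05
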