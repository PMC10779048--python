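"""Uncentered-Pearson average-linkage clustering of z-score profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from toxpod.clustering import (
    Dendrogram, average_linkage, build_zscore_matrix, cluster_samples,
    cut_dendrogram, pairwise_uncentered_distance, uncentered_pearson,
)
from toxpod.enrichment import EnrichmentResult


def brute_force_upgma(d):
    """Independent average-linkage enumeration: clusters merge at the mean
    of all between-cluster leaf distances; returns the partition after each
    merge together with its height."""
    d = np.asarray(d, dtype=float)
    clusters = [frozenset([i]) for i in range(len(d))]
    steps = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dist < best[0] - 1e-12:
                    best = (dist, i, j)
        dist, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        steps.append((dist, frozenset(clusters)))
    return steps


def linkage_steps(dendro: Dendrogram):
    """Partition after each merge of a SciPy linkage, with merge heights."""
    n = len(dendro.labels)
    members = {i: frozenset([i]) for i in range(n)}
    clusters = set(members.values())
    steps = []
    for row_idx, (a, b, h, _) in enumerate(dendro.linkage):
        ca, cb = members[int(a)], members[int(b)]
        merged = ca | cb
        clusters -= {ca, cb}
        clusters.add(merged)
        members[n + row_idx] = merged
        steps.append((h, frozenset(clusters)))
    return steps


def _zres(sample, pathway, z, significant=True):
    return EnrichmentResult(
        sample=sample, pathway=pathway, n_deg=4, p=0.01, z=z,
        coverage=0.1, significant=significant,
        state=EnrichmentResult.classify(z),
    )


def test_zscore_matrix_fill_rules():
    results = [
        _zres("s1", "P", 2.7),                     # significant with z
        _zres("s1", "Q", 3.0, significant=False),  # non-significant -> 0
        _zres("s2", "P", None),                    # significant, no z -> 0
        _zres("s2", "Q", -2.1),
    ]
    zmat = build_zscore_matrix(results)
    assert zmat.values.loc["s1", "P"] == 2.7
    assert zmat.values.loc["s1", "Q"] == 0.0
    assert zmat.values.loc["s2", "P"] == 0.0
    assert zmat.values.loc["s2", "Q"] == -2.1
    assert not zmat.values.isna().any().any()


def test_zscore_matrix_duplicate_entries_raise():
    results = [_zres("s1", "P", 1.0), _zres("s1", "P", 2.0)]
    with pytest.raises(ValueError, match="duplicate"):
        build_zscore_matrix(results)


def test_uncentered_pearson_closed_forms():
    x = np.array([1.0, 2.0, -1.0])
    assert uncentered_pearson(x, x) == pytest.approx(1.0)
    assert uncentered_pearson(x, -x) == pytest.approx(-1.0)
    assert uncentered_pearson([1, 0], [1, 1]) == pytest.approx(1 / math.sqrt(2))
    with pytest.raises(ValueError, match="zero vector"):
        uncentered_pearson([0, 0], [1, 1])


@settings(deadline=None, max_examples=40)
@given(
    x=st.lists(st.floats(min_value=-5, max_value=5), min_size=2, max_size=8),
    y=st.lists(st.floats(min_value=-5, max_value=5), min_size=2, max_size=8),
)
def test_uncentered_pearson_symmetric_and_bounded(x, y):
    n = min(len(x), len(y))
    x, y = np.array(x[:n]), np.array(y[:n])
    if np.linalg.norm(x) == 0 or np.linalg.norm(y) == 0:
        return
    s = uncentered_pearson(x, y)
    assert -1.0 <= s <= 1.0
    assert s == pytest.approx(uncentered_pearson(y, x))


def test_identical_rows_merge_at_zero():
    rows = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, -1.0]])
    d = pairwise_uncentered_distance(rows)
    tree = average_linkage(d)
    assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_average_linkage_matches_brute_force_enumeration():
    rng = np.random.default_rng(0)
    for trial in range(30):
        n = int(rng.integers(4, 7))
        x = rng.normal(size=(n, 5))
        d = pairwise_uncentered_distance(pd.DataFrame(x))
        tree = average_linkage(d)
        expected = brute_force_upgma(d)
        got = linkage_steps(tree)
        for (h_exp, part_exp), (h_got, part_got) in zip(expected, got):
            assert h_got == pytest.approx(h_exp, rel=1e-9, abs=1e-12)
            assert part_exp == part_got


def test_leaf_permutation_gives_isomorphic_tree():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(6, 4))
    d = pairwise_uncentered_distance(pd.DataFrame(x))
    perm = rng.permutation(6)
    d_perm = d[np.ix_(perm, perm)]
    steps_a = brute_force_upgma(d)
    tree_b = average_linkage(d_perm, labels=[str(p) for p in perm])
    # map permuted leaf ids back to original ids and compare partitions
    n = 6
    members = {i: frozenset([int(perm[i])]) for i in range(n)}
    clusters = set(members.values())
    steps_b = []
    for row_idx, (a, b, h, _) in enumerate(tree_b.linkage):
        merged = members[int(a)] | members[int(b)]
        clusters -= {members[int(a)], members[int(b)]}
        clusters.add(merged)
        members[n + row_idx] = merged
        steps_b.append((h, frozenset(clusters)))
    for (h_exp, part_exp), (h_got, part_got) in zip(steps_a, steps_b):
        assert h_got == pytest.approx(h_exp, rel=1e-9, abs=1e-12)
        assert part_exp == part_got


def test_asymmetric_input_rejected():
    d = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        average_linkage(d)


def test_cut_dendrogram_extremes_and_planted_blocks():
    rng = np.random.default_rng(5)
    # 4 well-separated blocks of 3 samples in profile space
    base = rng.normal(size=(4, 6)) * 5
    rows = np.vstack([base[i] + rng.normal(0, 0.05, size=(3, 6))
                      for i in range(4)])
    d = pairwise_uncentered_distance(pd.DataFrame(rows))
    tree = average_linkage(d)
    assert cut_dendrogram(tree, 1).nunique() == 1
    assert cut_dendrogram(tree, 12).nunique() == 12
    labels = cut_dendrogram(tree, 4)
    blocks = [labels.iloc[3 * i: 3 * i + 3] for i in range(4)]
    assert all(b.nunique() == 1 for b in blocks)
    assert labels.nunique() == 4
    with pytest.raises(ValueError, match="k must lie"):
        cut_dendrogram(tree, 0)


def test_all_zero_rows_excluded_deterministically():
    results = [
        _zres("s1", "P", 2.5), _zres("s1", "Q", -2.5),
        _zres("s2", "P", 2.4), _zres("s2", "Q", -2.6),
        _zres("s3", "P", None), _zres("s3", "Q", None),  # all-zero row
    ]
    zmat = build_zscore_matrix(results)
    tree, labels, excluded = cluster_samples(zmat, k=2)
    assert excluded == ["s3"]
    assert set(labels.index) == {"s1", "s2"}
    tree2, labels2, excluded2 = cluster_samples(zmat, k=2)
    assert excluded2 == excluded
    pd.testing.assert_series_equal(labels, labels2)


def test_newick_roundtrip_leaf_names():
    rng = np.random.default_rng(1)
    d = pairwise_uncentered_distance(pd.DataFrame(rng.normal(size=(4, 3))))
    tree = average_linkage(d, labels=["a", "b", "c", "d"])
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for label in "abcd":
        assert label in nwk
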