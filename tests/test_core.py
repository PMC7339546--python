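"""Methylome model, window statistics and cross-sample comparisons."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bovmeth.core import (build_sample_matrix, conserved_variable_regions,
                          feature_enrichment, global_levels,
                          hierarchical_cluster, make_window_track, mask_snps,
                          pairwise_correlation, pca, weighted_level)
from bovmeth.types import GenomicInterval, HetSNP
from conftest import methylome_from_arrays


# ---------------------------------------------------------------- masking

def test_mask_snps_removes_c_and_g_positions():
    m = methylome_from_arrays("s", "chr1", [100, 250], [8, 8], [2, 2])
    snps = [HetSNP("chr1", 100, "C", "T", True)]
    out = mask_snps(m, snps)
    assert list(out.chroms["chr1"].pos) == [250]
    # SNP on the G of the symmetric site also removes the CpG
    snps_g = [HetSNP("chr1", 101, "G", "A", True)]
    out = mask_snps(m, snps_g)
    assert list(out.chroms["chr1"].pos) == [250]
    # distant SNP leaves it alone; empty set is identity
    out = mask_snps(m, [HetSNP("chr1", 400, "C", "T", True)])
    assert len(out.chroms["chr1"]) == 2
    assert len(mask_snps(m, []).chroms["chr1"]) == 2


# ---------------------------------------------------------- weighted level

def test_weighted_level_examples():
    assert weighted_level(np.array([8, 0]), np.array([2, 10])) == \
        pytest.approx(0.40)
    assert np.isnan(weighted_level(np.array([1]), np.array([1]), min_cov=5))
    assert weighted_level(np.array([16]), np.array([0])) == 1.0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)),
                min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_weighted_level_order_and_split_invariant(counts, rnd):
    meth = np.array([c[0] for c in counts])
    unmeth = np.array([c[1] for c in counts])
    ref = weighted_level(meth, unmeth)
    idx = list(range(len(counts)))
    rnd.shuffle(idx)
    shuffled = weighted_level(meth[idx], unmeth[idx])
    if np.isnan(ref):
        assert np.isnan(shuffled)
        return
    assert shuffled == pytest.approx(ref)
    # arbitrary split then pooled recombination gives the same level
    k = len(counts) // 2
    tot = meth.sum() + unmeth.sum()
    if tot:
        pooled = (meth[:k].sum() + meth[k:].sum()) / tot
        assert pooled == pytest.approx(ref)


# ----------------------------------------------------------------- windows

def test_window_track_tiling_and_levels():
    pos = np.arange(10) * 40 + 10      # all inside the first 500-bp window
    m = methylome_from_arrays("s", "chr1", pos, [3] * 10, [1] * 10)
    tr = make_window_track(m, 500, chrom_lengths={"chr1": 1050})
    assert len(tr.start) == 3           # 1050 bp -> 3 windows, last partial
    assert tr.level[0] == pytest.approx(0.75)
    assert np.isnan(tr.level[1]) and np.isnan(tr.level[2])
    assert tr.end[2] == 1050


def test_global_levels():
    m = methylome_from_arrays("s", "chr1", [10, 50], [5, 7], [0, 0])
    cg, noncg = global_levels(m)
    assert cg == 1.0 and np.isnan(noncg)


def test_global_level_tracks_binomial_truth():
    """At 16x over 1e4 CpGs the estimate sits within 3 s.e. of truth."""
    rng = np.random.default_rng(8)
    n, pi, cov = 10_000, 0.75, 16
    totals = rng.poisson(cov, size=n)
    meth = rng.binomial(totals, pi)
    m = methylome_from_arrays("s", "chr1", np.arange(n) * 50, meth,
                              totals - meth)
    cg, _ = global_levels(m)
    se = np.sqrt(pi * (1 - pi) / totals.sum())
    assert abs(cg - pi) < 3 * se


# ------------------------------------------------------------ correlations

def _matrix():
    rng = np.random.default_rng(1)
    base = rng.uniform(0, 1, size=200)
    return pd.DataFrame({
        "a": base, "b": base.copy(), "c": 1 - base,
        "d": rng.uniform(0, 1, size=200)})


def test_pairwise_correlation_identities():
    corr = pairwise_correlation(_matrix())
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert np.allclose(np.diag(corr.values), 1.0)
    assert np.allclose(corr.values, corr.values.T)


def test_pairwise_correlation_requires_complete_rows():
    mat = pd.DataFrame({"a": [1.0, np.nan], "b": [0.5, 0.2]})
    with pytest.raises(ValueError):
        pairwise_correlation(mat)


def test_correlation_row_shuffle_invariance():
    mat = _matrix()
    perm = np.random.default_rng(2).permutation(len(mat))
    assert np.allclose(pairwise_correlation(mat).values,
                       pairwise_correlation(mat.iloc[perm]).values)


def test_replicates_correlate_on_windows(small_ds):
    tracks = [make_window_track(small_ds.methylomes[s], 10_000,
                                chrom_lengths=small_ds.annotation.chrom_lengths)
              for s in ("liver_1", "liver_2")]
    mat = build_sample_matrix(tracks)
    r = pairwise_correlation(mat).iloc[0, 1]
    assert r >= 0.9


# -------------------------------------------------------------- clustering

def test_cluster_copies_merge_first():
    Z = hierarchical_cluster(_matrix()[["a", "b", "d"]])
    assert sorted(Z[0, :2]) == [0, 1]
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_cluster_constant_column_errors():
    mat = _matrix()
    mat["e"] = 0.5
    with pytest.raises(ValueError, match="e"):
        hierarchical_cluster(mat)


def test_cluster_groups_recover_sample_classes(small_ds):
    from scipy.cluster.hierarchy import fcluster

    tracks = [make_window_track(m, 10_000,
                                chrom_lengths=small_ds.annotation.chrom_lengths)
              for m in small_ds.methylomes.values()]
    mat = build_sample_matrix(tracks)
    Z = hierarchical_cluster(mat)
    labels = fcluster(Z, t=3, criterion="maxclust")
    by_group = {}
    for sid, lab in zip(mat.columns, labels):
        grp = small_ds.sheet.by_id(sid).cluster_group
        by_group.setdefault(grp, set()).add(lab)
    # sperm, placenta and the somatic block separate cleanly
    assert all(len(v) == 1 for v in by_group.values())
    assert len(set().union(*by_group.values())) == 3


# --------------------------------------------------------------------- PCA

def test_pca_variance_fractions_and_rank_guard():
    mat = _matrix()
    scores, frac = pca(mat, 2)
    assert np.all(np.diff(frac) <= 1e-12)
    assert frac.sum() <= 1 + 1e-9
    with pytest.raises(ValueError):
        pca(mat[["a", "b"]], 2)  # b duplicates a -> rank 1 after centering


def test_pca_separates_planted_groups(small_ds):
    tracks = [make_window_track(m, 10_000,
                                chrom_lengths=small_ds.annotation.chrom_lengths)
              for m in small_ds.methylomes.values()]
    mat = build_sample_matrix(tracks)
    scores, _ = pca(mat, 2)
    grp = {sid: small_ds.sheet.by_id(sid).cluster_group
           for sid in scores.index}
    placenta = scores.loc[[s for s in scores.index
                           if grp[s] == "placenta"]].values
    somatic = scores.loc[[s for s in scores.index
                          if grp[s] == "somatic"]].values
    # placenta is the methylation outlier on PC1
    assert np.min(np.abs(placenta[:, 0])) > np.max(np.abs(somatic[:, 0]))


# --------------------------------------------- conserved/variable regions

def build_cv_fixture():
    """1000 complete windows with designed SD structure."""
    rng = np.random.default_rng(4)
    n = 1000
    idx = [f"chr1:{i * 10_000}-{(i + 1) * 10_000}" for i in range(n)]
    base = rng.uniform(0.35, 0.65, size=n)
    data = {s: base + rng.normal(0, 0.05, size=n)
            for s in ("sperm", "s2", "s3", "s4")}
    mat = pd.DataFrame(data, index=idx)
    # conserved: 5 windows all-equal high, 5 all-equal low
    for i in range(5):
        mat.iloc[i] = 0.8
    for i in range(5, 10):
        mat.iloc[i] = 0.2
    # variable: sperm-hypo, sperm-hyper, and middling-sperm windows
    for i in range(10, 14):
        mat.iloc[i] = [0.05, 0.8, 0.85, 0.8]
    for i in range(14, 18):
        mat.iloc[i] = [0.95, 0.2, 0.15, 0.2]
    for i in range(18, 20):
        mat.iloc[i] = [0.5, 0.05, 0.95, 0.05]
    return mat


def test_conserved_variable_tail_counts_and_classes():
    mat = build_cv_fixture()
    calls = conserved_variable_regions(mat, ["sperm"])
    n = len(mat)
    k = int(np.floor(0.01 * n))
    by_class = {}
    for c in calls:
        by_class.setdefault(c.klass, []).append(c)
    n_cons = len(by_class.get("conserved_hyper", [])) + \
        len(by_class.get("conserved_hypo", []))
    n_var = sum(len(v) for k_, v in by_class.items()
                if k_.startswith("variable"))
    assert n_cons == k and n_var == k
    assert len(by_class["conserved_hyper"]) == 5
    assert len(by_class["conserved_hypo"]) == 5
    assert {c.klass for c in calls[10:14]} == {"variable_sperm_hypo"}
    assert {c.klass for c in calls[14:18]} == {"variable_sperm_hyper"}
    assert {c.klass for c in calls[18:20]} == {"variable_other"}


def test_conserved_variable_without_sperm_warns():
    mat = build_cv_fixture().rename(columns={"sperm": "x"})
    with pytest.warns(UserWarning):
        calls = conserved_variable_regions(mat, ["sperm"])
    assert all(c.klass in ("variable_other", "background",
                           "conserved_hyper", "conserved_hypo")
               for c in calls)


# -------------------------------------------------------------- enrichment

def test_feature_enrichment_bounds():
    genome = {"chr1": 100_000}
    regions = [GenomicInterval("chr1", 0, 10_000)]
    whole = [GenomicInterval("chr1", 0, 100_000)]
    fold, _ = feature_enrichment(regions, whole, genome, n_permutations=10,
                                 seed=0)
    assert fold == pytest.approx(1.0)
    disjoint = [GenomicInterval("chr1", 50_000, 60_000)]
    fold, _ = feature_enrichment(regions, disjoint, genome,
                                 n_permutations=10, seed=0)
    assert fold == 0.0


def test_feature_enrichment_detects_planted_overlap():
    rng = np.random.default_rng(9)
    genome = {"chr1": 1_000_000}
    features = [GenomicInterval("chr1", int(s), int(s) + 1000)
                for s in rng.integers(0, 990_000, size=50)]
    regions = [GenomicInterval("chr1", f.start, f.end)
               for f in features[:20]]
    fold, p = feature_enrichment(regions, features, genome,
                                 n_permutations=200, seed=1)
    assert fold > 5
    assert p < 0.05
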