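"""Segment callers: HMRs, PMDs, drops and profile summaries."""
import numpy as np
import pytest

from bovmeth.segmentation import (HMRParams, PMDParams, call_hmrs, call_pmds,
                                  detect_drops, pmd_genome_fraction,
                                  segment_methylation_profile, union_bp)
from bovmeth.types import SampleInfo, SampleSheet, Segment
from conftest import base_jaccard, iv_triples, methylome_from_arrays, seg_triples


def synth_methylome(segments_levels, background=0.8, spacing=100,
                    length=200_000, cov=16, seed=0, sample_id="s"):
    """A single-chromosome methylome with painted level intervals."""
    rng = np.random.default_rng(seed)
    pos = np.arange(0, length, spacing)
    pi = np.full(len(pos), background)
    for s, e, lv in segments_levels:
        pi[(pos >= s) & (pos < e)] = lv
    totals = rng.poisson(cov, size=len(pos))
    meth = rng.binomial(totals, pi)
    return methylome_from_arrays(sample_id, "chr1", pos, meth, totals - meth)


def test_uniform_background_yields_no_hmrs():
    m = synth_methylome([], seed=1)
    segs, fit = call_hmrs(m)
    assert segs == []
    assert fit.degenerate


def test_planted_hmr_recovered_with_high_overlap():
    truth = [(50_000, 51_500, 0.08), (120_000, 121_500, 0.08)]
    m = synth_methylome(truth, spacing=60, seed=2)
    segs, _ = call_hmrs(m)
    J = base_jaccard([("chr1", s, e) for s, e, _ in truth],
                     seg_triples(segs))
    assert J >= 0.8


def test_hmrs_never_merge_across_deserts():
    """Two hypo runs separated by a CpG desert stay two segments."""
    pos = np.concatenate([np.arange(0, 3000, 100),
                          np.arange(20_000, 23_000, 100)])
    rng = np.random.default_rng(3)
    totals = rng.poisson(16, len(pos))
    meth = rng.binomial(totals, 0.08)
    # surround with background so the fit sees two states
    bg_pos = np.concatenate([np.arange(5000, 15_000, 100),
                             np.arange(25_000, 40_000, 100)])
    bg_tot = rng.poisson(16, len(bg_pos))
    bg_meth = rng.binomial(bg_tot, 0.8)
    allpos = np.concatenate([pos, bg_pos])
    order = np.argsort(allpos)
    m = methylome_from_arrays("s", "chr1", allpos[order],
                              np.concatenate([meth, bg_meth])[order],
                              np.concatenate([totals - meth,
                                              bg_tot - bg_meth])[order])
    segs, _ = call_hmrs(m)
    hypo = [s for s in segs if s.mean_level < 0.3]
    assert len(hypo) == 2
    assert all(s.end <= 20_000 or s.start >= 19_000 for s in hypo)
    # boundary extension capped at desert_gap / 2
    assert max(s.end for s in hypo) <= 23_000 + 2500


def test_hmr_calls_mirror_under_coordinate_reversal():
    truth = [(50_000, 51_500, 0.08)]
    m = synth_methylome(truth, spacing=60, seed=4, length=100_000)
    segs, _ = call_hmrs(m)
    L = 100_000
    cc = m.chroms["chr1"]
    rev = methylome_from_arrays("s", "chr1", (L - cc.pos - 2)[::-1],
                                cc.meth[::-1], cc.unmeth[::-1])
    rsegs, _ = call_hmrs(rev)
    mirrored = sorted((L - s.end, L - s.start) for s in rsegs)
    direct = sorted((s.start - 2, s.end - 2) for s in segs)
    # identical site sets decoded identically; allow the 2-bp CpG width shift
    assert len(mirrored) == len(direct)
    for (a, b), (c, d) in zip(mirrored, direct):
        assert abs(a - c) <= 2 and abs(b - d) <= 2


def test_pmd_refuses_sparse_genomes():
    m = synth_methylome([], length=100_000, spacing=1000, seed=5)
    with pytest.raises(ValueError, match="informative windows"):
        call_pmds(m, PMDParams())


def test_pmd_recovery_and_min_length(small_ds):
    ds = small_ds
    segs, _ = call_pmds(ds.methylomes["liver_1"],
                        chrom_lengths=ds.annotation.chrom_lengths)
    truth = iv_triples(ds.truth.pmds_by_sample["liver_1"])
    assert base_jaccard(truth, seg_triples(segs)) >= 0.8
    # sub-100-kb decoys are fully removed by the length filter
    for d in ds.truth.decoys:
        assert not any(s.chrom == d.chrom and s.start < d.end
                       and d.start < s.end for s in segs)


def test_pmd_window_size_stability(small_ds):
    ds = small_ds
    lengths = ds.annotation.chrom_lengths
    segs10, _ = call_pmds(ds.methylomes["liver_1"], chrom_lengths=lengths)
    segs5, _ = call_pmds(ds.methylomes["liver_1"],
                         PMDParams(window_size=5000), chrom_lengths=lengths)
    assert base_jaccard(seg_triples(segs10), seg_triples(segs5)) >= 0.7


def test_hmd_reporting(default_ds):
    ds = default_ds
    segs, _ = call_pmds(ds.methylomes["placenta"],
                        chrom_lengths=ds.annotation.chrom_lengths,
                        report_hmds=True)
    labels = {s.state_label for s in segs}
    assert labels == {"PMD", "HMD"}
    hmd_levels = [s.mean_level for s in segs if s.state_label == "HMD"]
    pmd_levels = [s.mean_level for s in segs if s.state_label == "PMD"]
    assert min(hmd_levels) > max(pmd_levels)


def test_placenta_pmd_fraction(default_ds):
    """On the default study the placenta PMD share lands within 5 points."""
    ds = default_ds
    segs, _ = call_pmds(ds.methylomes["placenta"],
                        chrom_lengths=ds.annotation.chrom_lengths)
    truth_frac = sum(len(iv) for iv in ds.truth.pmds_by_sample["placenta"]) \
        / sum(ds.annotation.chrom_lengths.values())
    called = pmd_genome_fraction(segs, ds.annotation.chrom_lengths)
    assert abs(called - truth_frac) <= 0.05


# ----------------------------------------------------------------- drops

def _sheet():
    rows = [SampleInfo("blood", "blood", "somatic", True)]
    for i in range(5):
        rows.append(SampleInfo(f"t{i}", f"tis{i}", "somatic"))
    return SampleSheet(rows)


def seg(chrom, s, e):
    return Segment(chrom, s, e, 10, 0.5, 1.0, "PMD")


def test_drop_requires_blood_absence_and_support():
    sheet = _sheet()
    pmds = {f"t{i}": [seg("chr1", 1_000_000, 1_500_000)] for i in range(5)}
    pmds["blood"] = []
    drops = detect_drops(pmds, sheet)
    assert len(drops) == 1
    assert (drops[0].start, drops[0].end) == (1_000_000, 1_500_000)
    assert "pericentromeric" in drops[0].flags
    # present in blood too -> no drop
    pmds["blood"] = [seg("chr1", 1_000_000, 1_500_000)]
    assert detect_drops(pmds, sheet) == []
    # support below 80% of somatic samples -> no drop
    pmds["blood"] = []
    pmds["t4"] = []
    pmds["t3"] = []
    assert detect_drops(pmds, sheet) == []


def test_drop_flags():
    sheet = _sheet()
    pmds = {f"t{i}": [seg("chr1", 4_000_000, 4_200_000),
                      seg("chr2", 100_000, 2_100_000)] for i in range(5)}
    pmds["blood"] = []
    drops = {(d.chrom): d for d in detect_drops(pmds, sheet)}
    assert "pericentromeric" not in drops["chr1"].flags
    assert "out_of_range" in drops["chr1"].flags       # 200 kb < 300 kb
    assert "out_of_range" in drops["chr2"].flags       # 2 Mb > 1.8 Mb
    assert "pericentromeric" in drops["chr2"].flags


def test_drop_no_blood_warns():
    sheet = SampleSheet([SampleInfo(f"t{i}", f"tis{i}", "somatic")
                         for i in range(4)])
    pmds = {f"t{i}": [seg("chr1", 1_000_000, 1_400_000)] for i in range(4)}
    import logging
    drops = detect_drops(pmds, sheet)
    assert len(drops) == 1


# ---------------------------------------------------------------- profile

def test_segment_profile_u_shape():
    truth = [(50_000, 52_000, 0.05), (100_000, 102_000, 0.05)]
    m = synth_methylome(truth, spacing=50, seed=6)
    segs = [Segment("chr1", s, e, 10, 0.05, 1.0, "HMR") for s, e, _ in truth]
    prof = segment_methylation_profile(segs, m, flank_bp=2000, n_bins=10)
    inner = prof[5:15]
    flanks = np.concatenate([prof[:5], prof[15:]])
    assert np.nanmean(inner) < 0.2
    assert np.nanmean(flanks) > 0.6


def test_segment_profile_zero_flank_and_single_segment():
    m = synth_methylome([(10_000, 12_000, 0.1)], spacing=50, seed=7,
                        length=20_000)
    segs = [Segment("chr1", 10_000, 12_000, 10, 0.1, 1.0, "HMR")]
    prof = segment_methylation_profile(segs, m, flank_bp=0, n_bins=8)
    assert len(prof) == 8
    assert np.nanmax(prof) < 0.3


def test_union_bp():
    segs = [seg("chr1", 0, 100), seg("chr1", 50, 150), seg("chr2", 0, 10)]
    assert union_bp(segs) == 160
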