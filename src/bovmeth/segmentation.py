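"""HMR / PMD / HMD segment calling and the multi-tissue drop detector.

HMRs are decoded from per-CpG counts with a two-state beta-binomial HMM
(hypo mean ~0.1 vs background ~0.8); PMDs use the same machinery on 10-kb
window sums with a partially methylated state near 0.5.  Methylation
"drops" are 0.3-1.8 Mb regions recurrently partially methylated across
non-blood somatic tissues but absent from blood-lineage samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import Methylome, make_window_track
from .hmm import (FitResult, HMMModel, decode_state_runs, fit_two_state_hmm,
                  posterior_decode)
from .types import SampleSheet, Segment

log = logging.getLogger(__name__)


@dataclass(slots=True)
class HMRParams:
    min_cov: int = 1
    min_sites: int = 5
    score_min: float = 0.0
    desert_gap: int = 5000
    init_mean_hypo: float = 0.1
    init_mean_bg: float = 0.8
    init_icc: float = 0.1
    tol: float = 1e-4
    max_iter: int = 100
    seed: int = 17


@dataclass(slots=True)
class PMDParams:
    window_size: int = 10_000
    min_window_reads: int = 10
    min_length: int = 100_000
    merge_gap_windows: int = 1
    min_informative_windows: int = 50
    init_mean_pmd: float = 0.5
    init_mean_bg: float = 0.8
    init_icc: float = 0.1
    tol: float = 1e-4
    max_iter: int = 100
    seed: int = 17


def _split_chains(pos: np.ndarray, desert_gap: int) -> list[tuple[int, int]]:
    """Half-open index spans between gaps exceeding ``desert_gap`` bp."""
    if len(pos) == 0:
        return []
    breaks = np.where(np.diff(pos) > desert_gap)[0] + 1
    bounds = [0, *breaks.tolist(), len(pos)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def call_hmrs(methylome: Methylome, params: HMRParams | None = None,
              model: Optional[HMMModel] = None
              ) -> tuple[list[Segment], FitResult]:
    """Call hypomethylated regions for one sample.

    Chains are broken at CpG deserts (> ``desert_gap`` bp without covered
    CpGs); segment boundaries extend from the first/last CpG of a hypo run
    by half the gap to the flanking CpG, capped at ``desert_gap/2``.
    """
    params = params or HMRParams()
    chain_meta = []  # (chrom, pos slice, meth, total)
    chains = []
    for chrom in sorted(methylome.chroms):
        cc = methylome.chroms[chrom]
        cov = cc.coverage
        ok = cov >= params.min_cov
        pos, meth, tot = cc.pos[ok], cc.meth[ok], cov[ok]
        if len(pos) < params.min_sites:
            if len(pos):
                log.warning("chromosome %s has < %d covered CpGs: no calls",
                            chrom, params.min_sites)
            continue
        for lo, hi in _split_chains(pos, params.desert_gap):
            chains.append((meth[lo:hi], tot[lo:hi]))
            chain_meta.append((chrom, pos[lo:hi], meth[lo:hi], tot[lo:hi]))

    init = (model or HMMModel.default(params.init_mean_hypo, params.init_mean_bg,
                                      params.init_icc))
    fit = fit_two_state_hmm(chains, init=init, tol=params.tol,
                            max_iter=params.max_iter, seed=params.seed)

    half_cap = params.desert_gap // 2
    segments: list[Segment] = []
    for chrom, pos, meth, tot in chain_meta:
        states, logodds = posterior_decode(fit.model, meth, tot)
        for lo, hi in decode_state_runs(states, 0):
            n_sites = hi - lo
            if n_sites < params.min_sites:
                continue
            score = float(logodds[lo:hi].sum())
            if score < params.score_min:
                continue
            left_ext = ((pos[lo] - pos[lo - 1]) // 2) if lo > 0 else 0
            right_ext = ((pos[hi] - pos[hi - 1]) // 2) if hi < len(pos) else 0
            start = int(pos[lo] - min(left_ext, half_cap))
            end = int(pos[hi - 1] + 2 + min(right_ext, half_cap))
            level = float(meth[lo:hi].sum() / tot[lo:hi].sum())
            segments.append(Segment(chrom, start, end, int(n_sites), level,
                                    score, "HMR"))
    return segments, fit


def call_pmds(methylome: Methylome, params: PMDParams | None = None,
              chrom_lengths: Optional[Mapping[str, int]] = None,
              report_hmds: bool = False
              ) -> tuple[list[Segment], FitResult]:
    """Call partially methylated domains from 10-kb window counts.

    Windows with fewer than ``min_window_reads`` total reads are treated as
    missing and break the observation chain.  Runs of the partial state
    separated by <= ``merge_gap_windows`` windows are merged; merged runs
    shorter than ``min_length`` bp are discarded.  With ``report_hmds`` the
    complementary background-state runs are returned as HMD segments too.
    """
    params = params or PMDParams()
    track = make_window_track(methylome, params.window_size,
                              chrom_lengths=chrom_lengths)
    informative = track.total_sum >= params.min_window_reads
    if int(informative.sum()) < params.min_informative_windows:
        raise ValueError(
            f"only {int(informative.sum())} informative windows "
            f"(< {params.min_informative_windows}): refusing to fit")

    # build chains of consecutive informative windows per chromosome
    chains = []
    chain_meta = []
    for chrom in np.unique(track.chrom):
        sel = track.chrom == chrom
        idx = np.where(sel & informative)[0]
        if len(idx) == 0:
            continue
        brk = np.where(np.diff(idx) > 1)[0] + 1
        for piece in np.split(idx, brk):
            chains.append((track.meth_sum[piece], track.total_sum[piece]))
            chain_meta.append((chrom, piece))

    init = HMMModel.default(params.init_mean_pmd, params.init_mean_bg,
                            params.init_icc)
    fit = fit_two_state_hmm(chains, init=init, tol=params.tol,
                            max_iter=params.max_iter, seed=params.seed)

    raw: dict[str, list[tuple[int, int, int, float, float]]] = {}
    hmds: list[Segment] = []
    for (chrom, piece), (meth, tot) in zip(
            chain_meta, ((track.meth_sum[p], track.total_sum[p])
                         for _, p in chain_meta)):
        states, logodds = posterior_decode(fit.model, meth, tot)
        for lo, hi in decode_state_runs(states, 0):
            w = piece[lo:hi]
            start = int(track.start[w[0]])
            end = int(track.end[w[-1]])
            level = float(meth[lo:hi].sum() / tot[lo:hi].sum())
            raw.setdefault(str(chrom), []).append(
                (start, end, hi - lo, level, float(logodds[lo:hi].sum())))
        if report_hmds:
            for lo, hi in decode_state_runs(states, 1):
                w = piece[lo:hi]
                level = float(meth[lo:hi].sum() / tot[lo:hi].sum())
                hmds.append(Segment(str(chrom), int(track.start[w[0]]),
                                    int(track.end[w[-1]]), hi - lo, level,
                                    float(-logodds[lo:hi].sum()), "HMD"))

    merge_gap_bp = params.merge_gap_windows * params.window_size
    segments: list[Segment] = []
    for chrom, runs in sorted(raw.items()):
        runs.sort()
        merged: list[list] = []
        for start, end, n, level, score in runs:
            if merged and start - merged[-1][1] <= merge_gap_bp:
                prev = merged[-1]
                w_prev = prev[2]
                prev[1] = max(prev[1], end)
                prev[2] += n
                prev[3] = (prev[3] * w_prev + level * n) / (w_prev + n)
                prev[4] += score
            else:
                merged.append([start, end, n, level, score])
        for start, end, n, level, score in merged:
            if end - start < params.min_length:
                continue
            segments.append(Segment(chrom, start, end, n, level, score, "PMD"))
    if report_hmds:
        segments.extend(hmds)
    return segments, fit


def pmd_genome_fraction(pmds: Sequence[Segment],
                        genome_lengths: Mapping[str, int]) -> float:
    bp = sum(len(s) for s in pmds if s.state_label == "PMD")
    return bp / sum(genome_lengths.values())


def detect_drops(pmd_sets_by_sample: Mapping[str, Sequence[Segment]],
                 sample_sheet: SampleSheet,
                 min_support_fraction: float = 0.8,
                 min_len: int = 300_000, max_len: int = 1_800_000,
                 merge_gap: int = 100_000,
                 pericentromere_bp: int = 3_000_000) -> list[Segment]:
    """PMD-cluster detection of multi-tissue methylation drops.

    A drop is a run of genome positions inside PMDs of at least
    ``min_support_fraction`` of the non-blood somatic samples and of zero
    blood-related samples, merged across gaps <= ``merge_gap``.  Drops
    outside [min_len, max_len] are kept but flagged; a drop starting within
    the first ``pericentromere_bp`` of its chromosome is flagged
    pericentromeric (bovine autosomes are acrocentric).
    """
    somatic = [s for s in sample_sheet
               if s.cluster_group == "somatic" and not s.blood_related
               and s.sample_id in pmd_sets_by_sample]
    blood = [s for s in sample_sheet
             if s.blood_related and s.sample_id in pmd_sets_by_sample]
    if len(somatic) < 3:
        raise ValueError("need PMD calls for >= 3 non-blood somatic samples")
    if not blood:
        log.warning("no blood-related samples: blood-exclusion criterion "
                    "is vacuous")
    need = int(np.ceil(min_support_fraction * len(somatic)))

    events: dict[str, list[tuple[int, int, int]]] = {}

    def add(samples, weight):
        for s in samples:
            for seg in pmd_sets_by_sample[s.sample_id]:
                if seg.state_label != "PMD":
                    continue
                events.setdefault(seg.chrom, []).append((seg.start, weight, +1))
                events.setdefault(seg.chrom, []).append((seg.end, weight, -1))

    add(somatic, 0)   # weight channel 0 = somatic support
    add(blood, 1)     # weight channel 1 = blood support

    drops: list[Segment] = []
    for chrom, evs in sorted(events.items()):
        evs.sort()
        support = [0, 0]
        cur_start = None
        candidates: list[tuple[int, int]] = []
        prev_pos = None
        for pos, channel, delta in evs:
            if prev_pos is not None and pos > prev_pos:
                ok = support[0] >= need and support[1] == 0
                if ok and cur_start is None:
                    cur_start = prev_pos
                elif not ok and cur_start is not None:
                    candidates.append((cur_start, prev_pos))
                    cur_start = None
            support[channel] += delta
            prev_pos = pos
        if cur_start is not None and prev_pos is not None:
            candidates.append((cur_start, prev_pos))
        # merge across small gaps
        merged: list[list[int]] = []
        for s, e in candidates:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            flags = []
            if not (min_len <= e - s <= max_len):
                flags.append("out_of_range")
            if s < pericentromere_bp:
                flags.append("pericentromeric")
            drops.append(Segment(chrom, s, e, 1, 0.5, float(e - s), "DROP",
                                 tuple(flags)))
    return drops


def segment_methylation_profile(segments: Sequence[Segment],
                                methylome: Methylome,
                                flank_bp: int = 2000,
                                n_bins: int = 20) -> np.ndarray:
    """Mean weighted level in ``n_bins`` across segments plus flanks.

    Each segment body is scaled to ``n_bins`` bins; flanks contribute
    ``n_bins // 2`` extra bins on each side (zero when flank_bp == 0).
    Returns the across-segment average profile (NaN where no data).
    """
    if not segments:
        raise ValueError("no segments supplied")
    flank_bins = n_bins // 2 if flank_bp > 0 else 0
    total_bins = n_bins + 2 * flank_bins
    meth_acc = np.zeros(total_bins)
    tot_acc = np.zeros(total_bins)
    for seg in segments:
        cc = methylome.chroms.get(seg.chrom)
        if cc is None:
            continue
        lo = np.searchsorted(cc.pos, seg.start - flank_bp)
        hi = np.searchsorted(cc.pos, seg.end + flank_bp)
        for i in range(lo, hi):
            p = int(cc.pos[i])
            if p < seg.start:
                if not flank_bins:
                    continue
                b = int((p - (seg.start - flank_bp)) / flank_bp * flank_bins)
                b = min(max(b, 0), flank_bins - 1)
            elif p >= seg.end:
                if not flank_bins:
                    continue
                b = flank_bins + n_bins + int(
                    (p - seg.end) / flank_bp * flank_bins)
                b = min(b, total_bins - 1)
            else:
                b = flank_bins + int((p - seg.start) / len(seg) * n_bins)
                b = min(b, flank_bins + n_bins - 1)
            meth_acc[b] += cc.meth[i]
            tot_acc[b] += cc.meth[i] + cc.unmeth[i]
    with np.errstate(invalid="ignore"):
        return np.where(tot_acc > 0, meth_acc / np.maximum(tot_acc, 1), np.nan)


def union_bp(segments: Sequence[Segment]) -> int:
    """Total bp covered by the plain interval union of segments."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total
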