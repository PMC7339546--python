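"""Per-sample methylome model and cross-sample comparison statistics.

A :class:`Methylome` stores one sample's strand-merged CpG read counts as
per-chromosome numpy arrays (position, methylated, unmethylated).  All
summary levels are *weighted* methylation levels: summed methylated reads
over summed total reads, the convention that is robust to uneven coverage.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .types import CpGSiteRecord, GenomicInterval, HetSNP

log = logging.getLogger(__name__)


@dataclass(slots=True)
class ChromCounts:
    """Ordered CpG counts on one chromosome."""

    pos: np.ndarray    # int64, strictly increasing
    meth: np.ndarray   # int64
    unmeth: np.ndarray  # int64

    def __post_init__(self) -> None:
        if len(self.pos) > 1 and not np.all(np.diff(self.pos) > 0):
            raise ValueError("CpG positions must be strictly increasing")

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def __len__(self) -> int:
        return len(self.pos)


@dataclass(slots=True)
class Methylome:
    sample_id: str
    chroms: dict[str, ChromCounts] = field(default_factory=dict)
    # optional per-strand non-CG cytosines: chrom -> (pos, strand, meth, unmeth)
    noncg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    lambda_conversion_rate: Optional[float] = None

    @classmethod
    def from_records(cls, sample_id: str,
                     records: Iterable[CpGSiteRecord]) -> "Methylome":
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(
                (r.pos, r.meth_count, r.unmeth_count))
        m = cls(sample_id=sample_id)
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
            m.chroms[chrom] = ChromCounts(arr[:, 0], arr[:, 1], arr[:, 2])
        return m

    def records(self) -> Iterable[CpGSiteRecord]:
        for chrom in sorted(self.chroms):
            cc = self.chroms[chrom]
            for p, mm, uu in zip(cc.pos, cc.meth, cc.unmeth):
                yield CpGSiteRecord(chrom, int(p), int(mm), int(uu))

    @property
    def n_sites(self) -> int:
        return sum(len(cc) for cc in self.chroms.values())


def mask_snps(methylome: Methylome, het_snps: Sequence[HetSNP]) -> Methylome:
    """Drop any CpG whose C (pos) or G (pos+1) coincides with a het SNP.

    Bisulfite conversion cannot distinguish an unmethylated C from a C>T
    variant, so heterozygous positions are removed outright.
    """
    snp_pos: dict[str, set[int]] = {}
    for s in het_snps:
        if s.is_het:
            snp_pos.setdefault(s.chrom, set()).add(s.pos)
    out = Methylome(sample_id=methylome.sample_id,
                    lambda_conversion_rate=methylome.lambda_conversion_rate,
                    noncg=methylome.noncg)
    n_removed = 0
    for chrom, cc in methylome.chroms.items():
        hits = snp_pos.get(chrom)
        if not hits:
            out.chroms[chrom] = cc
            continue
        snp_arr = np.fromiter(hits, dtype=np.int64)
        bad = np.isin(cc.pos, snp_arr) | np.isin(cc.pos + 1, snp_arr)
        n_removed += int(bad.sum())
        out.chroms[chrom] = ChromCounts(cc.pos[~bad], cc.meth[~bad], cc.unmeth[~bad])
    if n_removed:
        log.info("mask_snps: removed %d CpGs overlapping het SNPs (%s)",
                 n_removed, methylome.sample_id)
    return out


def weighted_level(meth: np.ndarray, unmeth: np.ndarray,
                   min_cov: int = 1) -> float:
    """Weighted methylation level over CpGs with coverage >= ``min_cov``."""
    meth = np.asarray(meth, dtype=np.int64)
    unmeth = np.asarray(unmeth, dtype=np.int64)
    cov = meth + unmeth
    keep = cov >= min_cov
    total = int(cov[keep].sum())
    if total == 0:
        return float("nan")
    return float(meth[keep].sum() / total)


@dataclass(slots=True)
class WindowTrack:
    """Tiled (optionally sliding) window summary of one methylome."""

    sample_id: str
    window_size: int
    step: int
    chrom: np.ndarray      # object array of chromosome names
    start: np.ndarray
    end: np.ndarray
    meth_sum: np.ndarray
    total_sum: np.ndarray
    n_cpgs: np.ndarray
    level: np.ndarray      # NaN where no qualifying CpG

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "meth_sum": self.meth_sum, "total_sum": self.total_sum,
            "n_cpgs": self.n_cpgs, "level": self.level,
        })


def make_window_track(methylome: Methylome, window_size: int,
                      step: Optional[int] = None, min_cov: int = 1,
                      chrom_lengths: Optional[Mapping[str, int]] = None
                      ) -> WindowTrack:
    """Per-window weighted levels, windows tiling each chromosome from 0.

    Only CpGs with coverage >= ``min_cov`` contribute to a window's sums;
    a window with no qualifying CpG is present with level NaN.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    step = step or window_size
    if step > window_size:
        raise ValueError("step must not exceed window_size")
    chroms, starts, ends = [], [], []
    msums, tsums, ncpgs = [], [], []
    for chrom in sorted(methylome.chroms):
        cc = methylome.chroms[chrom]
        cov = cc.coverage
        ok = cov >= min_cov
        pos, meth, tot = cc.pos[ok], cc.meth[ok], cov[ok]
        length = (chrom_lengths or {}).get(chrom) or (int(cc.pos[-1]) + 2 if len(cc) else 0)
        if length == 0:
            continue
        n_win = max(1, -(-max(length - window_size, 0) // step) + 1) if length > 0 else 0
        for i in range(n_win):
            ws = i * step
            we = min(ws + window_size, length)
            if ws >= length:
                break
            lo, hi = np.searchsorted(pos, [ws, we])
            chroms.append(chrom)
            starts.append(ws)
            ends.append(we)
            msums.append(int(meth[lo:hi].sum()))
            tsums.append(int(tot[lo:hi].sum()))
            ncpgs.append(int(hi - lo))
    msums = np.asarray(msums, dtype=np.int64)
    tsums = np.asarray(tsums, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(tsums > 0, msums / np.maximum(tsums, 1), np.nan)
    return WindowTrack(methylome.sample_id, window_size, step,
                       np.asarray(chroms, dtype=object),
                       np.asarray(starts, dtype=np.int64),
                       np.asarray(ends, dtype=np.int64),
                       msums, tsums,
                       np.asarray(ncpgs, dtype=np.int64), level)


def global_levels(methylome: Methylome, min_cov: int = 1
                  ) -> tuple[float, float]:
    """Genome-wide weighted CG level and (if per-strand data exist) non-CG level."""
    meth = np.concatenate([cc.meth for cc in methylome.chroms.values()]) \
        if methylome.chroms else np.zeros(0, dtype=np.int64)
    unmeth = np.concatenate([cc.unmeth for cc in methylome.chroms.values()]) \
        if methylome.chroms else np.zeros(0, dtype=np.int64)
    cg = weighted_level(meth, unmeth, min_cov)
    if not methylome.noncg:
        return cg, float("nan")
    nm = np.concatenate([v[2] for v in methylome.noncg.values()])
    nu = np.concatenate([v[3] for v in methylome.noncg.values()])
    return cg, weighted_level(nm, nu, min_cov)


def build_sample_matrix(tracks: Sequence[WindowTrack]) -> pd.DataFrame:
    """Windows x samples matrix of levels; index ``chrom:start-end``.

    All tracks must share the same window grid (same window_size/step and
    chromosome tiling).
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    ref = tracks[0]
    idx = [f"{c}:{s}-{e}" for c, s, e in zip(ref.chrom, ref.start, ref.end)]
    data = {}
    for tr in tracks:
        if len(tr.level) != len(idx):
            raise ValueError("window grids differ between tracks")
        data[tr.sample_id] = tr.level
    return pd.DataFrame(data, index=idx)


def complete_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix.dropna(axis=0, how="any")


def pairwise_correlation(matrix: pd.DataFrame, method: str = "pearson"
                         ) -> pd.DataFrame:
    """Sample x sample correlation on complete (no-missing) rows only."""
    comp = complete_rows(matrix)
    if len(comp) < 2:
        raise ValueError("need >= 2 complete rows for correlations")
    corr = comp.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def hierarchical_cluster(matrix: pd.DataFrame) -> np.ndarray:
    """Average-linkage tree on distance 1 - Pearson over complete rows.

    Returns a scipy linkage matrix; leaf order is the matrix column order,
    which makes ties deterministic.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples to cluster")
    comp = complete_rows(matrix)
    stds = comp.std(axis=0)
    const = stds.index[stds.values == 0].tolist()
    if const:
        raise ValueError(
            f"constant methylation column(s) {const}: correlation undefined")
    dist = 1.0 - comp.corr().values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return linkage(squareform(dist, checks=False), method="average")


def pca(matrix: pd.DataFrame, n_components: int = 2
        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores from column-centred SVD of the complete-row matrix.

    Sign convention: within each component the largest-|loading| sample
    score is made positive.  Returns (scores, explained variance fractions).
    """
    comp = complete_rows(matrix)
    n_samples = matrix.shape[1]
    if len(comp) < n_components:
        raise ValueError("fewer complete rows than components")
    # center each window (feature) across samples
    X = comp.values - comp.values.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank {rank}")
    # samples are columns: decompose X^T (samples x windows)
    U, S, _ = np.linalg.svd(X.T, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    for j in range(n_components):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] = -scores[:, j]
    frac = (S ** 2) / (S ** 2).sum()
    scores_df = pd.DataFrame(
        scores, index=matrix.columns[:n_samples],
        columns=[f"PC{i+1}" for i in range(n_components)])
    return scores_df, frac[:n_components]


@dataclass(frozen=True, slots=True)
class RegionVariabilityCall:
    chrom: str
    start: int
    end: int
    sd_across_samples: float
    mean_level: float
    klass: str  # conserved_hyper/.._hypo/variable_sperm_hypo/.._hyper/variable_other/background


def conserved_variable_regions(matrix: pd.DataFrame,
                               sperm_sample_ids: Sequence[str],
                               tail_fraction: float = 0.01,
                               hyper_split: float = 0.5,
                               sperm_hypo_max: float = 0.3,
                               sperm_hyper_min: float = 0.7
                               ) -> list[RegionVariabilityCall]:
    """Classify 10-kb windows into methylation-conserved and -variable tails.

    The lowest ``tail_fraction`` of across-sample SDs (complete windows
    only) are conserved regions, split into hyper/hypo at mean 0.5; the
    highest tail are variable regions, split by the mean sperm level.
    Exactly ``floor(tail_fraction * n_complete)`` windows enter each tail;
    SD ties break by window order.
    """
    comp = complete_rows(matrix)
    n = len(comp)
    k = int(np.floor(tail_fraction * n))
    sd = comp.values.std(axis=1, ddof=1) if comp.shape[1] > 1 else np.zeros(n)
    mean = comp.values.mean(axis=1)
    sperm_ids = [s for s in sperm_sample_ids if s in comp.columns]
    if sperm_sample_ids and not sperm_ids:
        warnings.warn("no sperm sample present: variable windows fall back "
                      "to variable_other")
    sperm_mean = (comp[sperm_ids].values.mean(axis=1)
                  if sperm_ids else np.full(n, np.nan))
    order = np.argsort(sd, kind="stable")
    conserved_idx = set(order[:k].tolist())
    variable_idx = set(order[n - k:].tolist()) if k else set()
    out = []
    for i, widx in enumerate(comp.index):
        chrom, rest = widx.split(":")
        start, end = (int(x) for x in rest.split("-"))
        if i in conserved_idx:
            klass = "conserved_hyper" if mean[i] >= hyper_split else "conserved_hypo"
        elif i in variable_idx:
            if np.isnan(sperm_mean[i]):
                klass = "variable_other"
            elif sperm_mean[i] <= sperm_hypo_max:
                klass = "variable_sperm_hypo"
            elif sperm_mean[i] >= sperm_hyper_min:
                klass = "variable_sperm_hyper"
            else:
                klass = "variable_other"
        else:
            klass = "background"
        out.append(RegionVariabilityCall(chrom, start, end, float(sd[i]),
                                         float(mean[i]), klass))
    return out


def feature_enrichment(regions: Sequence[GenomicInterval],
                       features: Sequence[GenomicInterval],
                       genome_lengths: Mapping[str, int],
                       n_permutations: int = 200,
                       seed: int = 0) -> tuple[float, float]:
    """Fold enrichment of feature bp within regions + permutation p-value.

    fold = (overlap bp / region bp) / (feature bp / genome bp).  The null
    redistributes each region uniformly on its own chromosome, preserving
    lengths.
    """
    genome_bp = sum(genome_lengths.values())
    feat_bp = sum(len(f) for f in features)
    if feat_bp == 0:
        return float("nan"), float("nan")
    region_bp = sum(len(r) for r in regions)
    if region_bp == 0:
        return float("nan"), float("nan")

    feat_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        feat_by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    feat_arr = {c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
                for c, v in ((c, sorted(v)) for c, v in feat_by_chrom.items())}

    def overlap_bp(ivs: Sequence[tuple[str, int, int]]) -> int:
        total = 0
        for chrom, s, e in ivs:
            if chrom not in feat_arr:
                continue
            fs, fe = feat_arr[chrom]
            total += int(np.sum(np.clip(np.minimum(fe, e) - np.maximum(fs, s),
                                        0, None)))
        return total

    obs = overlap_bp([(r.chrom, r.start, r.end) for r in regions])
    expected_frac = feat_bp / genome_bp
    fold = (obs / region_bp) / expected_frac

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = []
        for r in regions:
            L = genome_lengths[r.chrom]
            width = min(len(r), L)
            s = int(rng.integers(0, L - width + 1))
            perm.append((r.chrom, s, s + width))
        if overlap_bp(perm) >= obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return float(fold), float(p)
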