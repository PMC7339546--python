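"""Distance-based CpG island prediction and experimental validation.

Islands are maximal runs of genomic CpG dinucleotides whose neighbour
gaps all stay below a chromosome-specific distance threshold (the median
consecutive-CpG gap by default), significant against a null of uniform
CpG placement.  Validation against a panel of methylomes labels each
island eCGI (hypomethylated, < 30%, in at least one evaluable sample) or
neCGI.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .core import Methylome, weighted_level
from .types import GeneModel, GenomicInterval, HetSNP


@dataclass(frozen=True, slots=True)
class CpGCluster:
    chrom: str
    start: int
    end: int
    n_cpgs: int
    max_gap_used: float
    p_value: float
    q_value: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, "CGI")


@dataclass(frozen=True, slots=True)
class CGIAnnotation:
    cluster: CpGCluster
    levels: dict  # sample_id -> level (evaluable samples only)
    n_evaluable_samples: int
    verdict: str  # eCGI | neCGI | unevaluable


def predict_cgis(cpg_positions_by_chrom: Mapping[str, np.ndarray],
                 genome_lengths: Mapping[str, int],
                 percentile: float = 0.5, min_cpgs: int = 5,
                 q_max: float = 0.05) -> list[CpGCluster]:
    """Single-base CpG island prediction from genomic CpG positions.

    Per chromosome the distance threshold tau is the ``percentile``
    quantile of consecutive-CpG gaps; clusters are maximal runs with all
    gaps <= tau and >= ``min_cpgs`` sites.  Significance uses the run
    length: under uniform (Poisson) CpG placement a maximal run of small
    gaps has geometric length, so conditional on reaching ``min_cpgs``
    sites the survival beyond that is p = q0^(n_cpgs - min_cpgs), with q0
    the empirical fraction of gaps <= tau.  Conditioning on candidacy
    keeps the p-value valid for the BH correction across the tested
    clusters (a span-conditional binomial is biased here, because maximal
    runs are selected for density).
    """
    candidates = []
    pvals = []
    for chrom in sorted(cpg_positions_by_chrom):
        pos = np.sort(np.asarray(cpg_positions_by_chrom[chrom], dtype=np.int64))
        if len(pos) < min_cpgs:
            continue
        gaps = np.diff(pos)
        tau = float(np.quantile(gaps, percentile))
        ok = gaps <= tau
        q0 = float(ok.mean())
        # runs of consecutive small gaps
        brk = np.where(~ok)[0]
        starts = [0] + (brk + 1).tolist()
        ends = (brk).tolist() + [len(pos) - 1]
        for i0, i1 in zip(starts, ends):
            n = i1 - i0 + 1
            if n < min_cpgs:
                continue
            p = float(q0 ** (n - min_cpgs))
            candidates.append((chrom, int(pos[i0]), int(pos[i1]) + 2, n, tau, p))
            pvals.append(p)
    if not candidates:
        return []
    q = multipletests(pvals, method="fdr_bh")[1]
    out = []
    for (chrom, start, end, n, tau, p), qi in zip(candidates, q):
        if qi < q_max:
            out.append(CpGCluster(chrom, start, end, n, tau, p, float(qi)))
    return out


def validate_ecgi(clusters: Sequence[CpGCluster],
                  methylomes: Sequence[Methylome],
                  level_max: float = 0.30, min_cpgs_cov: int = 5,
                  min_cov: int = 5, require_all_samples: bool = False
                  ) -> list[CGIAnnotation]:
    """Assign each predicted island an eCGI/neCGI/unevaluable verdict.

    A sample is evaluable for an island when at least ``min_cpgs_cov``
    CpGs have coverage strictly greater than ``min_cov`` inside it; its
    level is the weighted level over those CpGs.  eCGI: level <
    ``level_max`` in at least one evaluable sample.  With
    ``require_all_samples`` an island must be evaluable in every supplied
    methylome to receive a verdict.  Placenta-group samples should be
    excluded by the caller (they are genome-wide hypomethylated).
    """
    out = []
    for cl in clusters:
        levels: dict[str, float] = {}
        for m in methylomes:
            cc = m.chroms.get(cl.chrom)
            if cc is None:
                continue
            lo, hi = np.searchsorted(cc.pos, [cl.start, cl.end])
            cov = cc.coverage[lo:hi]
            det = cov > min_cov
            if int(det.sum()) < min_cpgs_cov:
                continue
            levels[m.sample_id] = weighted_level(
                cc.meth[lo:hi][det], cc.unmeth[lo:hi][det])
        n_eval = len(levels)
        if n_eval == 0 or (require_all_samples and n_eval < len(methylomes)):
            verdict = "unevaluable"
        elif any(lv < level_max for lv in levels.values()):
            verdict = "eCGI"
        else:
            verdict = "neCGI"
        out.append(CGIAnnotation(cl, levels, n_eval, verdict))
    return out


def ct_het_rate(regions: Sequence[GenomicInterval],
                het_snps: Sequence[HetSNP]) -> float:
    """C/T (incl. G/A) heterozygote count per kb of region."""
    if not regions:
        raise ValueError("empty region set")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for v in by_chrom.values():
        v.sort()
    total_kb = sum(len(r) for r in regions) / 1000.0
    count = 0
    for s in het_snps:
        if not (s.is_het and s.is_ct_type):
            continue
        ivs = by_chrom.get(s.chrom)
        if not ivs:
            continue
        starts = np.array([a for a, _ in ivs])
        idx = np.searchsorted(starts, s.pos, side="right") - 1
        if idx >= 0 and ivs[idx][0] <= s.pos < ivs[idx][1]:
            count += 1
    return count / total_kb


def cgi_distribution_stats(annotations: Sequence[CGIAnnotation],
                           gene_models: Sequence[GeneModel],
                           genome_lengths: Mapping[str, int]
                           ) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome eCGI/neCGI/gene counts and their length correlations."""
    chroms = sorted(genome_lengths)
    if len(chroms) < 3:
        raise ValueError("need >= 3 chromosomes")
    rows = []
    for chrom in chroms:
        e = sum(1 for a in annotations
                if a.cluster.chrom == chrom and a.verdict == "eCGI")
        ne = sum(1 for a in annotations
                 if a.cluster.chrom == chrom and a.verdict == "neCGI")
        g = sum(1 for gm in gene_models if gm.chrom == chrom)
        rows.append((chrom, e, ne, g, genome_lengths[chrom]))
    table = pd.DataFrame(rows, columns=["chrom", "n_ecgi", "n_necgi",
                                        "n_genes", "length"])
    stats: dict[str, float] = {}
    for key, col in (("r_ecgi_genes", "n_genes"), ("r_ecgi_length", "length")):
        x = table["n_ecgi"].values.astype(float)
        y = table[col].values.astype(float)
        if np.std(x) == 0 or np.std(y) == 0:
            stats[key] = float("nan")
        else:
            stats[key] = float(pearsonr(x, y)[0])
    return table, stats


def tss_profile(regions: Sequence[GenomicInterval],
                gene_models: Sequence[GeneModel],
                flank_bp: int = 5000, bin_bp: int = 100) -> np.ndarray:
    """Strand-oriented density of region midpoints around TSSs.

    Bin 0 covers [-flank_bp, -flank_bp + bin_bp) relative to the TSS in
    the gene's reading direction; the profile is normalised by the number
    of regions so an everything-at-TSS input gives a single unit peak.
    """
    if not regions:
        raise ValueError("no regions supplied")
    n_bins = 2 * flank_bp // bin_bp
    prof = np.zeros(n_bins)
    mids_by_chrom: dict[str, np.ndarray] = {}
    for r in regions:
        mids_by_chrom.setdefault(r.chrom, []).append((r.start + r.end) // 2)
    mids_by_chrom = {c: np.sort(np.array(v)) for c, v in mids_by_chrom.items()}
    for g in gene_models:
        mids = mids_by_chrom.get(g.chrom)
        if mids is None:
            continue
        for t in g.transcripts:
            lo, hi = np.searchsorted(mids, [t.tss_pos - flank_bp,
                                            t.tss_pos + flank_bp])
            for mid in mids[lo:hi]:
                d = int(mid) - t.tss_pos
                if g.strand == "-":
                    d = -d
                b = (d + flank_bp) // bin_bp
                if 0 <= b < n_bins:
                    prof[b] += 1
    return prof / len(regions)
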