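"""TSS-HMR gene classification and expression-linked promoter analyses.

Genes are placed into five mutually exclusive classes by how their
transcription start sites relate to hypomethylated regions across samples:

``TOTAL_IN_HMR``  the whole gene lies inside one HMR in >= 1 sample;
``T3``            >= 2 transcripts have TSSs in different HMRs;
``T2``            an opposite-strand partner gene's TSS shares the HMR
                  (a bidirectional, "twin-gene" promoter);
``T1``            some TSS falls in an HMR;
``NO_TSS_HMR``    no TSS ever falls in an HMR.

Precedence is TOTAL_IN_HMR > T3 > T2 > T1 > NO_TSS_HMR, which forces
exclusivity; both members of a T2 pair receive T2 (unless a higher class
applies to one of them).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, spearmanr

from .core import Methylome
from .differential import DMRRecord, element_methylation
from .types import GeneModel, GenomicInterval, SampleSheet, Segment

log = logging.getLogger(__name__)

CLASSES = ("NO_TSS_HMR", "TOTAL_IN_HMR", "T1", "T2", "T3")


@dataclass(slots=True)
class GeneHMRAssignment:
    gene_id: str
    klass: str
    partner_gene_id: Optional[str] = None          # T2 only
    distinct_hmr_count: int = 0                    # T3 only
    # sample_id -> {tx_id: (hmr_start, hmr_end)} for TSSs inside an HMR
    evidence: dict = field(default_factory=dict)


class _HMRIndex:
    """Sorted-array interval lookup for one sample's HMRs."""

    def __init__(self, segments: Sequence[Segment]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for s in segments:
            tmp.setdefault(s.chrom, []).append((s.start, s.end))
        for chrom, ivs in tmp.items():
            ivs.sort()
            self.by_chrom[chrom] = (np.array([a for a, _ in ivs]),
                                    np.array([b for _, b in ivs]))

    def containing(self, chrom: str, pos: int) -> Optional[tuple[int, int]]:
        """The HMR containing pos, if any (HMRs do not overlap per sample)."""
        arr = self.by_chrom.get(chrom)
        if arr is None:
            return None
        starts, ends = arr
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return int(starts[i]), int(ends[i])
        return None

    def covering(self, chrom: str, start: int, end: int
                 ) -> Optional[tuple[int, int]]:
        """An HMR fully containing [start, end), if any."""
        hit = self.containing(chrom, start)
        if hit and hit[1] >= end:
            return hit
        return None


def classify_genes(gene_models: Sequence[GeneModel],
                   hmr_sets_by_sample: Mapping[str, Sequence[Segment]],
                   t3_within_sample_only: bool = False
                   ) -> list[GeneHMRAssignment]:
    """Assign each gene one of the five TSS-HMR classes."""
    indexes = {sid: _HMRIndex(segs)
               for sid, segs in hmr_sets_by_sample.items()}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    known_chroms = set()
    for idx in indexes.values():
        known_chroms |= set(idx.by_chrom)

    # pass 1: collect evidence per gene
    evidence: dict[str, dict] = {}
    total_in: set[str] = set()
    t3: dict[str, int] = {}
    any_tss: set[str] = set()
    for g in gene_models:
        ev: dict[str, dict] = {}
        if g.chrom not in known_chroms:
            log.warning("gene %s on chromosome %s with no HMR data",
                        g.gene_id, g.chrom)
        hmr_ids = set()  # distinct (sample-agnostic) HMR intervals hit
        per_sample_hits: dict[str, dict[str, tuple[int, int]]] = {}
        for sid, idx in indexes.items():
            hits = {}
            for t in g.transcripts:
                hit = idx.containing(g.chrom, t.tss_pos)
                if hit:
                    hits[t.tx_id] = hit
            if hits:
                ev[sid] = hits
                per_sample_hits[sid] = hits
                any_tss.add(g.gene_id)
            if idx.covering(g.chrom, g.gene_start, g.gene_end):
                total_in.add(g.gene_id)
        evidence[g.gene_id] = ev
        # T3: >= 2 transcripts in non-identical HMRs, within one sample or
        # (optionally) across samples where the HMRs do not overlap
        if len(g.transcripts) >= 2:
            found = 0
            for sid, hits in per_sample_hits.items():
                distinct = set(hits.values())
                found = max(found, len(distinct))
            if not t3_within_sample_only and found < 2:
                all_hits = [(h, sid) for sid, hits in per_sample_hits.items()
                            for h in set(hits.values())]
                disjoint = set()
                for (s1, e1), _ in all_hits:
                    merged = False
                    for (s2, e2) in list(disjoint):
                        if s1 < e2 and s2 < e1:
                            merged = True
                            break
                    if not merged:
                        disjoint.add((s1, e1))
                found = max(found, len(disjoint))
            if found >= 2:
                t3[g.gene_id] = found

    # pass 2: T2 pairs — opposite-strand genes sharing one HMR in a sample
    t2_partner: dict[str, str] = {}
    for chrom, genes in genes_by_chrom.items():
        for i, ga in enumerate(genes):
            for gb in genes[i + 1:]:
                if ga.strand == gb.strand:
                    continue
                for sid, idx in indexes.items():
                    ha = {evidence[ga.gene_id].get(sid, {}).get(t.tx_id)
                          for t in ga.transcripts} - {None}
                    hb = {evidence[gb.gene_id].get(sid, {}).get(t.tx_id)
                          for t in gb.transcripts} - {None}
                    if ha & hb:
                        t2_partner.setdefault(ga.gene_id, gb.gene_id)
                        t2_partner.setdefault(gb.gene_id, ga.gene_id)
                        break

    out = []
    for g in gene_models:
        if g.gene_id in total_in:
            klass: str = "TOTAL_IN_HMR"
        elif g.gene_id in t3:
            klass = "T3"
        elif g.gene_id in t2_partner:
            klass = "T2"
        elif g.gene_id in any_tss:
            klass = "T1"
        else:
            klass = "NO_TSS_HMR"
        out.append(GeneHMRAssignment(
            g.gene_id, klass,
            partner_gene_id=t2_partner.get(g.gene_id) if klass == "T2" else None,
            distinct_hmr_count=t3.get(g.gene_id, 0) if klass == "T3" else 0,
            evidence=evidence[g.gene_id]))
    return out


@dataclass(frozen=True, slots=True)
class CoreFlank:
    gene_id: str
    core: Optional[GenomicInterval]
    upstream_flank: Optional[GenomicInterval]
    downstream_flank: Optional[GenomicInterval]


def compute_core_flank(gene: GeneModel,
                       assignment: GeneHMRAssignment) -> Optional[CoreFlank]:
    """Core = intersection of the gene's TSS-HMRs over contributing samples.

    Flanks are the union minus the core, split at the core boundaries and
    oriented by strand.  Returns None when fewer than two samples have a
    TSS-HMR or the intersection is empty.
    """
    hmrs = []
    for sid, hits in assignment.evidence.items():
        for iv in set(hits.values()):
            hmrs.append(iv)
    if len(assignment.evidence) < 2:
        return None
    core_s = max(s for s, _ in hmrs)
    core_e = min(e for _, e in hmrs)
    if core_s >= core_e:
        return None
    union_s = min(s for s, _ in hmrs)
    union_e = max(e for _, e in hmrs)
    chrom = gene.chrom
    left = (GenomicInterval(chrom, union_s, core_s)
            if union_s < core_s else None)
    right = (GenomicInterval(chrom, core_e, union_e)
             if core_e < union_e else None)
    if gene.strand == "-":
        left, right = right, left
    return CoreFlank(gene.gene_id, GenomicInterval(chrom, core_s, core_e),
                     left, right)


def correlation_decay(methylomes: Sequence[Methylome],
                      region_sets: Mapping[str, Sequence[GenomicInterval]],
                      max_dist: int = 2000, bin_bp: int = 200,
                      min_samples: int = 10, min_cov: int = 5,
                      min_pairs: int = 20,
                      max_pairs_per_region: int = 2000
                      ) -> pd.DataFrame:
    """Across-sample correlation of CpG pairs vs their genomic distance.

    For every CpG pair inside one region of a class, separated by at most
    ``max_dist`` bp and each covered >= ``min_cov`` in >= ``min_samples``
    shared samples, the Pearson correlation of methylation levels across
    those samples is averaged per distance bin per class.
    """
    if len(methylomes) < min_samples:
        raise ValueError(f"need >= {min_samples} methylomes")
    n_bins = max_dist // bin_bp
    rows = []
    for klass, regions in region_sets.items():
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=np.int64)
        for iv in regions:
            levels = []  # per sample: (pos, level) arrays restricted to iv
            for m in methylomes:
                cc = m.chroms.get(iv.chrom)
                if cc is None:
                    levels.append(None)
                    continue
                lo, hi = np.searchsorted(cc.pos, [iv.start, iv.end])
                cov = cc.coverage[lo:hi]
                ok = cov >= min_cov
                levels.append((cc.pos[lo:hi][ok],
                               cc.meth[lo:hi][ok] / cov[ok]))
            all_pos = sorted({int(p) for lv in levels if lv
                              for p in lv[0]})
            mat = np.full((len(all_pos), len(methylomes)), np.nan)
            pidx = {p: i for i, p in enumerate(all_pos)}
            for j, lv in enumerate(levels):
                if lv is None:
                    continue
                for p, val in zip(lv[0], lv[1]):
                    mat[pidx[int(p)], j] = val
            n_pairs = 0
            for i in range(len(all_pos)):
                for k in range(i + 1, len(all_pos)):
                    d = all_pos[k] - all_pos[i]
                    if d > max_dist:
                        break
                    shared = ~np.isnan(mat[i]) & ~np.isnan(mat[k])
                    if int(shared.sum()) < min_samples:
                        continue
                    x, y = mat[i, shared], mat[k, shared]
                    if np.std(x) == 0 or np.std(y) == 0:
                        continue
                    r = float(np.corrcoef(x, y)[0, 1])
                    b = min(d // bin_bp, n_bins - 1)
                    sums[b] += r
                    counts[b] += 1
                    n_pairs += 1
                if n_pairs >= max_pairs_per_region:
                    break
        for b in range(n_bins):
            rows.append((klass, b * bin_bp, (b + 1) * bin_bp,
                         sums[b] / counts[b] if counts[b] >= min_pairs
                         else np.nan, int(counts[b])))
    return pd.DataFrame(rows, columns=["region_class", "dist_lo", "dist_hi",
                                       "mean_r", "n_pairs"])


def boundary_tss_distances(hmr_set: Sequence[Segment],
                           gene_models: Sequence[GeneModel]) -> pd.DataFrame:
    """Strand-oriented offsets of TSS-HMR boundaries/centers from the TSS.

    Positive offsets point downstream of transcription.  Returns one row
    per (gene, transcript, HMR) with upstream/center/downstream offsets;
    the median center offset summarises where HMRs sit relative to TSSs.
    """
    idx = _HMRIndex(hmr_set)
    rows = []
    for g in gene_models:
        sign = -1 if g.strand == "-" else 1
        for t in g.transcripts:
            hit = idx.containing(g.chrom, t.tss_pos)
            if not hit:
                continue
            s, e = hit
            center = (s + e) / 2
            up, down = s, e
            if sign < 0:
                up, down = e, s
            rows.append((g.gene_id, t.tx_id,
                         sign * (up - t.tss_pos),
                         sign * (center - t.tss_pos),
                         sign * (down - t.tss_pos)))
    return pd.DataFrame(rows, columns=["gene_id", "tx_id", "upstream_offset",
                                       "center_offset", "downstream_offset"])


def dmr_expression_correlation(dmrs: Sequence[DMRRecord],
                               methylomes: Sequence[Methylome],
                               expression: pd.DataFrame,
                               gene_models: Sequence[GeneModel],
                               bins_from: int = -2000, bins_to: int = 10_000,
                               bin_bp: int = 500,
                               min_cov: int = 5) -> pd.DataFrame:
    """Per-positional-bin Spearman correlation of DMR level vs expression.

    Each DMR is assigned to its closest gene (by TSS) and a strand-oriented
    bin relative to that TSS; within a bin the Spearman correlation between
    the DMR's across-sample methylation and log2(TPM+1) of the gene is
    averaged over DMRs, stratified by CpG density (split at the median
    CpGs-per-bp of the assigned DMRs).
    """
    sample_ids = [m.sample_id for m in methylomes
                  if m.sample_id in expression.columns]
    if len(sample_ids) < 3:
        raise ValueError("need >= 3 matched methylome/expression samples")
    meth_by_id = {m.sample_id: m for m in methylomes}
    tss_list = []
    for g in gene_models:
        tss_list.append((g.chrom, g.primary_tss, g.strand, g.gene_id))
    tss_by_chrom: dict[str, list] = {}
    for row in tss_list:
        tss_by_chrom.setdefault(row[0], []).append(row)
    for v in tss_by_chrom.values():
        v.sort(key=lambda r: r[1])

    n_bins = (bins_to - bins_from) // bin_bp
    assigned = []  # (bin, density, correlation)
    for d in dmrs:
        cands = tss_by_chrom.get(d.chrom)
        if not cands:
            continue
        mid = (d.start + d.end) // 2
        gene = min(cands, key=lambda r: abs(r[1] - mid))
        _, tss, strand, gene_id = gene
        if gene_id not in expression.index:
            continue
        offset = (mid - tss) if strand != "-" else (tss - mid)
        b = (offset - bins_from) // bin_bp
        if not (0 <= b < n_bins):
            continue
        iv = GenomicInterval(d.chrom, d.start, d.end)
        lv = []
        for sid in sample_ids:
            tab = element_methylation([iv], meth_by_id[sid], min_cov=min_cov)
            lv.append(tab["level"].iloc[0])
        lv = np.array(lv, dtype=float)
        expr = np.log2(expression.loc[gene_id, sample_ids].values.astype(float)
                       + 1.0)
        ok = ~np.isnan(lv)
        if ok.sum() < 3 or np.std(lv[ok]) == 0 or np.std(expr[ok]) == 0:
            continue
        r = float(spearmanr(lv[ok], expr[ok])[0])
        n_cpg_per_bp = _dmr_cpg_density(d, meth_by_id[sample_ids[0]])
        assigned.append((int(b), n_cpg_per_bp, r))
    if not assigned:
        return pd.DataFrame(columns=["bin_start", "bin_end", "density_class",
                                     "mean_r", "n_dmrs"])
    dens = np.array([a[1] for a in assigned])
    median_density = float(np.median(dens))
    rows = []
    for density_class in ("high", "low", "all"):
        for b in range(n_bins):
            rs = [r for (bb, dd, r) in assigned if bb == b and (
                density_class == "all"
                or (density_class == "high" and dd >= median_density)
                or (density_class == "low" and dd < median_density))]
            rows.append((bins_from + b * bin_bp, bins_from + (b + 1) * bin_bp,
                         density_class,
                         float(np.mean(rs)) if rs else np.nan, len(rs)))
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "density_class",
                                       "mean_r", "n_dmrs"])


def _dmr_cpg_density(d: DMRRecord, methylome: Methylome) -> float:
    cc = methylome.chroms.get(d.chrom)
    if cc is None:
        return 0.0
    lo, hi = np.searchsorted(cc.pos, [d.start, d.end])
    return (hi - lo) / (d.end - d.start)


def tissue_specific_tss_hmrs(gene_models: Sequence[GeneModel],
                             hmr_sets_by_sample: Mapping[str, Sequence[Segment]],
                             sample_sheet: SampleSheet
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample TSS-in-HMR presence matrix plus tissue-specific calls.

    A gene's TSS-HMR is tissue-specific when present in every sample of
    exactly one tissue and absent from every sample of all other tissues.
    Also reports genes whose presence varies across samples at all.
    """
    indexes = {sid: _HMRIndex(segs)
               for sid, segs in hmr_sets_by_sample.items()}
    sample_ids = [s.sample_id for s in sample_sheet
                  if s.sample_id in indexes]
    presence = pd.DataFrame(False, index=[g.gene_id for g in gene_models],
                            columns=sample_ids)
    for g in gene_models:
        for sid in sample_ids:
            idx = indexes[sid]
            if any(idx.containing(g.chrom, t.tss_pos) for t in g.transcripts):
                presence.loc[g.gene_id, sid] = True
    tissue_of = {s.sample_id: s.tissue for s in sample_sheet}
    calls = []
    for gene_id, row in presence.iterrows():
        present_tissues = {tissue_of[sid] for sid in sample_ids if row[sid]}
        if len(present_tissues) != 1:
            continue
        tissue = next(iter(present_tissues))
        members = [sid for sid in sample_ids if tissue_of[sid] == tissue]
        if all(row[sid] for sid in members):
            calls.append((gene_id, tissue))
    return presence, pd.DataFrame(calls, columns=["gene_id", "tissue"])


@dataclass(frozen=True, slots=True)
class TwinPair:
    gene_a: str
    gene_b: str
    tss_distance: int
    shared_hmr: bool


def twin_pairs_from_assignments(assignments: Sequence[GeneHMRAssignment],
                                gene_models: Sequence[GeneModel]
                                ) -> list[TwinPair]:
    by_id = {g.gene_id: g for g in gene_models}
    seen = set()
    out = []
    for a in assignments:
        if a.klass != "T2" or not a.partner_gene_id:
            continue
        key = tuple(sorted((a.gene_id, a.partner_gene_id)))
        if key in seen:
            continue
        seen.add(key)
        ga, gb = by_id[key[0]], by_id[key[1]]
        out.append(TwinPair(key[0], key[1],
                            abs(ga.primary_tss - gb.primary_tss), True))
    return out


def twin_gene_coexpression(pairs: Sequence[TwinPair],
                           expression: pd.DataFrame,
                           gene_models: Sequence[GeneModel],
                           n_random: Optional[int] = None,
                           seed: int = 0,
                           distance_tolerance: float = 0.10) -> dict:
    """Co-expression of twin-gene pairs vs random and distance-matched pairs.

    Correlation is Pearson on log2(TPM+1) across samples.  Random pairs
    are drawn uniformly from genes with expression data; control pairs
    match each twin pair's TSS distance within +/- ``distance_tolerance``.
    Returns medians and Mann-Whitney p-values.
    """
    if len(pairs) < 5:
        raise ValueError("need >= 5 twin pairs")
    expr = np.log2(expression + 1.0)
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 expression samples for correlations")
    by_id = {g.gene_id: g for g in gene_models}
    rng = np.random.default_rng(seed)

    def pair_r(a: str, b: str) -> Optional[float]:
        if a not in expr.index or b not in expr.index:
            return None
        x, y = expr.loc[a].values, expr.loc[b].values
        if np.std(x) == 0 or np.std(y) == 0:
            return None
        return float(pearsonr(x, y)[0])

    same = [r for p in pairs if (r := pair_r(p.gene_a, p.gene_b)) is not None]
    genes = [g for g in expr.index if g in by_id]
    n_random = n_random or len(same)
    random_r = []
    attempts = 0
    while len(random_r) < n_random and attempts < n_random * 50:
        attempts += 1
        a, b = rng.choice(len(genes), size=2, replace=False)
        r = pair_r(genes[a], genes[b])
        if r is not None:
            random_r.append(r)

    # distance-matched controls: opposite-strand matches that are not
    # themselves twin (shared-HMR) pairs
    twin_sets = {frozenset((p.gene_a, p.gene_b)) for p in pairs}
    control_r = []
    n_unmatched = 0
    gene_list = sorted(genes, key=lambda gid: (by_id[gid].chrom,
                                               by_id[gid].primary_tss))
    for p in pairs:
        target = p.tss_distance
        found = None
        order = rng.permutation(len(gene_list))
        for i in order:
            ga = by_id[gene_list[i]]
            for gid_b in gene_list:
                if gid_b == gene_list[i]:
                    continue
                gb = by_id[gid_b]
                if gb.chrom != ga.chrom or gb.strand == ga.strand:
                    continue
                d = abs(ga.primary_tss - gb.primary_tss)
                if target == 0:
                    match = d == 0
                else:
                    match = abs(d - target) <= distance_tolerance * target
                if match and frozenset((gene_list[i], gid_b)) not in twin_sets:
                    found = pair_r(gene_list[i], gid_b)
                    break
            if found is not None:
                break
        if found is None:
            n_unmatched += 1
        else:
            control_r.append(found)

    def mwu(x, y):
        if len(x) < 2 or len(y) < 2:
            return float("nan")
        return float(mannwhitneyu(x, y, alternative="greater")[1])

    return {
        "median_same_hmr": float(np.median(same)),
        "median_random": float(np.median(random_r)) if random_r else np.nan,
        "median_control": float(np.median(control_r)) if control_r else np.nan,
        "p_same_vs_random": mwu(same, random_r),
        "p_same_vs_control": mwu(same, control_r),
        "n_pairs": len(same),
        "n_control_unmatched": n_unmatched,
    }


def nearest_opposite_strand_pairs(gene_models: Sequence[GeneModel]
                                  ) -> dict[str, str]:
    """gene_id -> its nearest opposite-strand neighbour (by TSS distance)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    nearest = {}
    for genes in by_chrom.values():
        for g in genes:
            best, best_d = None, None
            for h in genes:
                if h.gene_id == g.gene_id or h.strand == g.strand:
                    continue
                d = abs(h.primary_tss - g.primary_tss)
                if best_d is None or d < best_d:
                    best, best_d = h.gene_id, d
            if best is not None:
                nearest[g.gene_id] = best
    return nearest


def cross_species_consistency(t2_pairs: Sequence[TwinPair],
                              ortholog_table: Mapping[str, str],
                              other_gene_models: Sequence[GeneModel],
                              other_hmrs: Optional[Sequence[Segment]] = None
                              ) -> float:
    """Fraction of twin pairs preserved as twin arrangements in another species.

    A pair is consistent when both orthologs exist, are mutually nearest
    opposite-strand neighbours in the other annotation, and (when HMRs are
    supplied) both TSSs fall inside one shared HMR there.
    """
    if not ortholog_table:
        return float("nan")
    nearest = nearest_opposite_strand_pairs(other_gene_models)
    by_id = {g.gene_id: g for g in other_gene_models}
    idx = _HMRIndex(other_hmrs) if other_hmrs is not None else None
    n_mapped = 0
    n_consistent = 0
    for p in t2_pairs:
        oa, ob = ortholog_table.get(p.gene_a), ortholog_table.get(p.gene_b)
        if oa is None or ob is None or oa not in by_id or ob not in by_id:
            continue
        n_mapped += 1
        if nearest.get(oa) != ob or nearest.get(ob) != oa:
            continue
        if idx is not None:
            ga, gb = by_id[oa], by_id[ob]
            ha = idx.containing(ga.chrom, ga.primary_tss)
            hb = idx.containing(gb.chrom, gb.primary_tss)
            if ha is None or ha != hb or ga.chrom != gb.chrom:
                continue
        n_consistent += 1
    return n_consistent / n_mapped if n_mapped else float("nan")


def hmr_size_distribution(hmr_sets_by_sample: Mapping[str, Sequence[Segment]],
                          gene_models: Sequence[GeneModel],
                          n_bins: int = 30, size_lo: int = 100,
                          size_hi: int = 100_000) -> pd.DataFrame:
    """Log-spaced size histograms of TSS-HMRs vs non-TSS-HMRs per sample.

    An HMR is a TSS-HMR when it contains at least one transcript TSS.
    Reports per (sample, label) the histogram and its modal bin center.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for g in gene_models:
        for t in g.transcripts:
            tmp.setdefault(g.chrom, []).append(t.tss_pos)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tmp.items()}
    edges = np.geomspace(size_lo, size_hi, n_bins + 1)
    rows = []
    for sid, segs in hmr_sets_by_sample.items():
        sizes = {"TSS-HMR": [], "non-TSS-HMR": []}
        for s in segs:
            tss = tss_by_chrom.get(s.chrom)
            has_tss = bool(tss is not None and
                           np.searchsorted(tss, s.start) <
                           np.searchsorted(tss, s.end))
            sizes["TSS-HMR" if has_tss else "non-TSS-HMR"].append(len(s))
        for label, vals in sizes.items():
            hist, _ = np.histogram(vals, bins=edges)
            if hist.sum():
                mode_bin = int(np.argmax(hist))
                mode = float(np.sqrt(edges[mode_bin] * edges[mode_bin + 1]))
            else:
                mode = np.nan
            rows.append((sid, label, len(vals), mode))
    return pd.DataFrame(rows, columns=["sample_id", "label", "n_hmrs",
                                       "modal_size_bp"])
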