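"""Synthetic multi-tissue WGBS study generator with planted ground truth.

The generator lays out a small multi-chromosome genome with the
statistical structure the analysis modules assume: CpG background plus
dense island clusters, genes in five promoter/HMR configurations
(head-to-head twin pairs, multi-promoter genes, genes swallowed by large
HMRs, plain promoter HMRs, fully methylated promoters), tissue-specific
promoter hypomethylation, partially methylated domains and multi-tissue
methylation drops, a repeat catalogue with young sperm-hypomethylated
elements and nested insertions, heterozygous SNPs with elevated C/T rates
at methylated CpGs, and expression negatively coupled to promoter
methylation.  Read counts are Binomial(coverage, pi) with Poisson
coverage and optional per-sample beta jitter on pi (beta-binomial
dispersion); everything is deterministic given the seed.

Chromosome layout (fractions of the chromosome length): a pericentromeric
zone (drops, sub-100-kb PMD decoys), a gene zone tiled into 30-kb slots,
and a tail zone (tissue PMD blocks, non-pericentromeric drops, one
universal PMD present in every sample including blood).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ChromCounts, Methylome
from .repeats import element_key
from .types import (GeneModel, GenomicInterval, HetSNP, RepeatElement,
                    SampleInfo, SampleSheet, Transcript)

SLOT_BP = 30_000


@dataclass(frozen=True, slots=True)
class TissueSpec:
    name: str
    n_replicates: int
    cluster_group: str  # sperm | placenta | somatic
    blood_related: bool = False


DEFAULT_TISSUES: tuple[TissueSpec, ...] = (
    TissueSpec("sperm", 1, "sperm"),
    TissueSpec("placenta", 1, "placenta"),
    TissueSpec("blood", 1, "somatic", blood_related=True),
    TissueSpec("liver", 2, "somatic"),
    TissueSpec("kidney", 2, "somatic"),
    TissueSpec("heart", 2, "somatic"),
    TissueSpec("muscle", 1, "somatic"),
    TissueSpec("brain", 1, "somatic"),
    TissueSpec("rumen", 1, "somatic"),
)


@dataclass(slots=True)
class SimConfig:
    seed: int = 17
    n_chroms: int = 3
    chrom_length_bp: int = 5_000_000
    # chromosomes differ in length and gene density (cycled when n_chroms
    # exceeds the tuples) so per-chromosome count statistics are not
    # degenerate; gene-rich need not mean long, as in real genomes
    chrom_length_factors: tuple[float, ...] = (1.0, 1.3, 0.9)
    gene_density_factors: tuple[float, ...] = (1.0, 0.78, 0.95)
    tissues: tuple[TissueSpec, ...] = DEFAULT_TISSUES
    # CpG placement
    background_cpg_rate: float = 0.008
    cgi_cpg_rate: float = 0.08
    cgi_width: int = 800
    distal_cpg_rate: float = 0.012
    repeat_cpg_rate: float = 0.02        # repeats retain CpGs
    young_repeat_cpg_rate: float = 0.05  # young SINEs are CpG-rich
    young_divergence_max: float = 8.0
    # methylation surface
    background_level: float = 0.80
    hmr_level: float = 0.10
    pmd_level: float = 0.50
    # gene-zone slot plan (per chromosome)
    n_t2_pairs: int = 8
    n_control_pairs: int = 4      # opposite-strand pairs without a shared HMR
    n_t3_genes: int = 5
    n_total_in_hmr: int = 4
    n_no_hmr_genes: int = 12
    tissue_specific_plan: tuple[tuple[str, int], ...] = (
        ("liver", 3), ("kidney", 2), ("heart", 2))
    n_graded_genes: int = 6   # promoter level graded across somatic tissues
    graded_level_lo: float = 0.10
    graded_level_hi: float = 0.80
    n_extra_ecgi: int = 15
    n_necgi: int = 8
    n_distal_hmrs: int = 30
    promoter_hmr_mean: int = 2000
    distal_hmr_mean: int = 500
    placenta_distal_hmr_mean: int = 5000
    # PMDs, drops, decoys
    pmd_block_min: int = 120_000
    pmd_block_max: int = 260_000
    pmds_per_somatic_tissue: int = 2
    placenta_pmd_fraction: float = 0.40
    n_drops: int = 4
    drop_min: int = 300_000
    drop_max: int = 600_000
    n_pmd_decoys: int = 3
    decoy_min: int = 30_000
    decoy_max: int = 60_000
    universal_pmd_len: int = 500_000
    n_sperm_hypo_windows: int = 16   # sperm-specific 10-kb hypo regions
    # read sampling
    coverage_mean: float = 16.0
    beta_jitter_concentration: float = 50.0  # 0 => pure binomial
    # expression
    expression_coupling: float = 6.0
    twin_factor_sd: float = 1.5
    expr_noise_sd: float = 0.5
    expr_base_mean: float = 4.0
    expr_base_sd: float = 1.0
    # repeats
    repeats_per_chrom: int = 300
    n_sperm_hypo_bova2: int = 10
    n_bova2_in_tss_hmr: int = 12
    n_nested_per_chrom: int = 4
    repeat_age_slope: float = -0.008  # level change per % divergence
    # het SNPs
    snp_rate: float = 5e-4
    cpg_ct_het_base: float = 0.002
    ct_het_elevation: float = 5.0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def sample_sheet(self) -> SampleSheet:
        samples = []
        for t in self.tissues:
            for r in range(t.n_replicates):
                sid = f"{t.name}_{r + 1}" if t.n_replicates > 1 else t.name
                samples.append(SampleInfo(sid, t.name, t.cluster_group,
                                          t.blood_related))
        return SampleSheet(samples)


@dataclass(slots=True)
class Annotation:
    chrom_lengths: dict
    cpg_positions: dict          # chrom -> int64 array
    genes: list
    repeats: list
    cgis: list                   # all planted dense clusters


@dataclass(slots=True)
class TruthSet:
    hmrs_by_sample: dict         # sample_id -> [GenomicInterval]
    pmds_by_sample: dict         # sample_id -> [GenomicInterval] (>= 100 kb)
    decoys: list                 # sub-100kb partial blocks (non-blood somatic)
    drops: list                  # [(GenomicInterval, pericentromeric: bool)]
    universal_pmd: Optional[GenomicInterval]
    cgi_truth: list              # [(GenomicInterval, "eCGI"|"neCGI")]
    gene_class: dict             # gene_id -> expected 5-way class
    graded_genes: dict           # gene_id -> {tissue: promoter truth level}
    twin_pairs: list             # [(gene_a, gene_b)]
    control_pairs: list
    tissue_specific_genes: dict  # gene_id -> tissue
    sperm_hypo_repeats: list     # element keys
    nested: list                 # [(outer_up, inner, outer_down)]
    surfaces: dict               # tissue -> {chrom: per-CpG truth level}
    tissue_of: dict              # sample_id -> tissue


@dataclass(slots=True)
class Dataset:
    config: SimConfig
    sheet: SampleSheet
    annotation: Annotation
    truth: TruthSet
    methylomes: dict             # sample_id -> Methylome
    expression: pd.DataFrame
    het_snps: list


# ----------------------------------------------------------------- layout

class _Cursor:
    """Sequential allocator inside one zone, 10-kb aligned with gaps."""

    def __init__(self, start: int, end: int, gap: int = 20_000):
        self.pos = -(-start // 10_000) * 10_000
        self.end = end
        self.gap = gap

    def take(self, length: int) -> Optional[tuple[int, int]]:
        length = -(-length // 10_000) * 10_000
        if self.pos + length > self.end:
            return None
        iv = (self.pos, self.pos + length)
        self.pos += length + self.gap
        return iv


def simulate_annotation(config: SimConfig
                        ) -> tuple[Annotation, TruthSet]:
    """Build the genome annotation and the planted-feature truth."""
    rng = np.random.default_rng(config.seed)
    base_L = config.chrom_length_bp
    chroms = config.chrom_names()
    sheet = config.sample_sheet()
    tissue_of = {s.sample_id: s.tissue for s in sheet}

    lf, gf = config.chrom_length_factors, config.gene_density_factors
    chrom_len = {c: int(round(base_L * lf[i % len(lf)] / 10_000)) * 10_000
                 for i, c in enumerate(chroms)}
    slots_full = int(0.36 * base_L) // SLOT_BP
    slots_by_chrom = {}
    for i, c in enumerate(chroms):
        zone_cap = (int(0.66 * chrom_len[c])
                    - int(0.30 * chrom_len[c])) // SLOT_BP
        slots_by_chrom[c] = min(int(slots_full * gf[i % len(gf)]), zone_cap)
    plan_slots = (config.n_t2_pairs + config.n_control_pairs
                  + config.n_t3_genes + config.n_total_in_hmr
                  + config.n_no_hmr_genes + config.n_graded_genes
                  + sum(n for _, n in config.tissue_specific_plan))
    for c in chroms:
        if plan_slots > slots_by_chrom[c]:
            raise ValueError(
                f"infeasible packing: {plan_slots} gene slots requested, "
                f"{slots_by_chrom[c]} available on {c}")

    genes: list[GeneModel] = []
    cgis: list[GenomicInterval] = []
    cgi_truth: list[tuple[GenomicInterval, str]] = []
    all_sample_hmrs: list[GenomicInterval] = []
    distal_hmrs: list[GenomicInterval] = []
    tissue_hmrs: dict[str, list[GenomicInterval]] = {}
    gene_class: dict[str, str] = {}
    twin_pairs: list[tuple[str, str]] = []
    control_pairs: list[tuple[str, str]] = []
    tissue_specific_genes: dict[str, str] = {}
    graded_genes: dict[str, dict[str, float]] = {}
    graded_hmrs: dict[str, GenomicInterval] = {}  # gene_id -> promoter HMR
    dense_regions: list[GenomicInterval] = []   # CGI-rate CpG placement
    distal_regions: list[GenomicInterval] = []  # intermediate-rate placement
    drops: list[tuple[GenomicInterval, bool]] = []
    decoys: list[GenomicInterval] = []
    tissue_pmds: dict[str, list[GenomicInterval]] = {}
    universal: Optional[GenomicInterval] = None

    def add_cgi(chrom: str, center: int, hypo: bool) -> GenomicInterval:
        half = config.cgi_width // 2
        iv = GenomicInterval(chrom, center - half, center + half, "CGI")
        cgis.append(iv)
        dense_regions.append(iv)
        cgi_truth.append((iv, "eCGI" if hypo else "neCGI"))
        return iv

    def promoter_hmr(chrom: str, tss: int, width: Optional[int] = None
                     ) -> GenomicInterval:
        w = width or int(rng.normal(config.promoter_hmr_mean, 200))
        w = max(1200, w)
        # HMR center sits slightly downstream of the TSS
        return GenomicInterval(chrom, tss - w // 2 + 250, tss + w // 2 + 250)

    gid = 0

    def next_gid() -> str:
        nonlocal gid
        gid += 1
        return f"G{gid:05d}"

    for ci, chrom in enumerate(chroms):
        L = chrom_len[chrom]
        n_slots = slots_by_chrom[chrom]
        density = gf[ci % len(gf)]
        gene_zone = (int(0.30 * L), int(0.30 * L) + n_slots * SLOT_BP)
        slot_types: list[tuple[str, object]] = []
        slot_types += [("t2", None)] * config.n_t2_pairs
        slot_types += [("ctrl", None)] * config.n_control_pairs
        slot_types += [("t3", None)] * config.n_t3_genes
        slot_types += [("total", None)] * config.n_total_in_hmr
        slot_types += [("nohmr", None)] * config.n_no_hmr_genes
        for tissue, n in config.tissue_specific_plan:
            slot_types += [("tissue", tissue)] * n
        slot_types += [("graded", None)] * config.n_graded_genes
        slot_types += [("t1", None)] * (n_slots - len(slot_types))
        # scatter island-dense slots so no run of 10-kb windows becomes
        # partially methylated by promoter islands alone
        slot_types = [slot_types[i] for i in rng.permutation(len(slot_types))]

        no_hmr_promoters: list[int] = []  # TSS positions, for sperm repeats

        for si, (stype, sarg) in enumerate(slot_types):
            s0 = gene_zone[0] + si * SLOT_BP
            if stype == "t2":
                x = s0 + 3000
                ga, gb = next_gid(), next_gid()
                genes.append(GeneModel(ga, chrom, "-", x - 2500, x + 1, (
                    Transcript(f"{ga}.t1", x, x - 2500, x + 1),)))
                genes.append(GeneModel(gb, chrom, "+", x + 800, x + 3800, (
                    Transcript(f"{gb}.t1", x + 800, x + 800, x + 3800),)))
                hmr = GenomicInterval(chrom, x - 800, x + 1600)
                all_sample_hmrs.append(hmr)
                add_cgi(chrom, x + 400, True)
                gene_class[ga] = gene_class[gb] = "T2"
                twin_pairs.append((ga, gb))
            elif stype == "ctrl":
                x = s0 + 3000
                ga, gb = next_gid(), next_gid()
                genes.append(GeneModel(ga, chrom, "-", x - 2500, x + 1, (
                    Transcript(f"{ga}.t1", x, x - 2500, x + 1),)))
                genes.append(GeneModel(gb, chrom, "+", x + 800, x + 3800, (
                    Transcript(f"{gb}.t1", x + 800, x + 800, x + 3800),)))
                gene_class[ga] = gene_class[gb] = "NO_TSS_HMR"
                control_pairs.append((ga, gb))
                no_hmr_promoters.extend((x, x + 800))
            elif stype == "t3":
                g = next_gid()
                t1_tss, t2_tss = s0 + 1000, s0 + 16_000
                genes.append(GeneModel(g, chrom, "+", t1_tss, s0 + 21_000, (
                    Transcript(f"{g}.t1", t1_tss, t1_tss, s0 + 21_000),
                    Transcript(f"{g}.t2", t2_tss, t2_tss, s0 + 21_000))))
                for tss in (t1_tss, t2_tss):
                    all_sample_hmrs.append(promoter_hmr(chrom, tss))
                    add_cgi(chrom, tss + 250, True)
                gene_class[g] = "T3"
            elif stype == "total":
                g = next_gid()
                hmr = GenomicInterval(chrom, s0 + 1000, s0 + 7000)
                all_sample_hmrs.append(hmr)
                add_cgi(chrom, s0 + 3500, True)
                genes.append(GeneModel(g, chrom, "+", s0 + 3000, s0 + 4200, (
                    Transcript(f"{g}.t1", s0 + 3000, s0 + 3000, s0 + 4200),)))
                gene_class[g] = "TOTAL_IN_HMR"
            elif stype == "nohmr":
                g = next_gid()
                tss = s0 + 2000
                genes.append(GeneModel(g, chrom, "+", tss, tss + 4000, (
                    Transcript(f"{g}.t1", tss, tss, tss + 4000),)))
                gene_class[g] = "NO_TSS_HMR"
                no_hmr_promoters.append(tss)
            elif stype == "tissue":
                g = next_gid()
                tss = s0 + 2000
                genes.append(GeneModel(g, chrom, "+", tss, tss + 5000, (
                    Transcript(f"{g}.t1", tss, tss, tss + 5000),)))
                hmr = promoter_hmr(chrom, tss)
                tissue_hmrs.setdefault(str(sarg), []).append(hmr)
                add_cgi(chrom, tss + 250, True)
                gene_class[g] = "T1"
                tissue_specific_genes[g] = str(sarg)
            elif stype == "graded":
                # promoter methylation graded across the somatic tissues:
                # emulates gradual tissue DMRs rather than on/off promoters
                g = next_gid()
                tss = s0 + 2000
                genes.append(GeneModel(g, chrom, "+", tss, tss + 5000, (
                    Transcript(f"{g}.t1", tss, tss, tss + 5000),)))
                hmr = promoter_hmr(chrom, tss)
                graded_hmrs[g] = hmr
                add_cgi(chrom, tss + 250, True)
                grade_tissues = [t.name for t in config.tissues
                                 if t.cluster_group == "somatic"
                                 and not t.blood_related]
                lv = np.linspace(config.graded_level_lo,
                                 config.graded_level_hi, len(grade_tissues))
                order = rng.permutation(len(grade_tissues))
                graded_genes[g] = {grade_tissues[i]: float(lv[j])
                                   for j, i in enumerate(order)}
                gene_class[g] = "T1"
            else:  # t1
                g = next_gid()
                tss = s0 + 2000
                genes.append(GeneModel(g, chrom, "+", tss, tss + 5000, (
                    Transcript(f"{g}.t1", tss, tss, tss + 5000),)))
                all_sample_hmrs.append(promoter_hmr(chrom, tss))
                add_cgi(chrom, tss + 250, True)
                gene_class[g] = "T1"

        # slot-gap extras: distal HMRs, free-standing eCGIs, neCGIs
        def stride(n: int) -> list[int]:
            return [int(i) for i in
                    np.linspace(0, n_slots - 1, num=n).round()] if n else []

        # extras live in the promoter-proximal window of their slot: CpG
        # islands cluster near genes, and keeping each slot's dense
        # features inside one 10-kb window avoids runs of partially
        # methylated windows that only reflect island CpG weight
        for k, si in enumerate(stride(round(config.n_distal_hmrs * density))):
            s0 = gene_zone[0] + si * SLOT_BP
            w = max(300, int(rng.normal(config.distal_hmr_mean, 100)))
            iv = GenomicInterval(chrom, s0 + 8600, s0 + 8600 + w)
            distal_hmrs.append(iv)
            distal_regions.append(iv)
        for si in stride(round(config.n_extra_ecgi * density)):
            s0 = gene_zone[0] + si * SLOT_BP
            iv = add_cgi(chrom, s0 + 5400, True)
            all_sample_hmrs.append(iv)
        for si in stride(round(config.n_necgi * density)):
            s0 = gene_zone[0] + si * SLOT_BP
            add_cgi(chrom, s0 + 7400, False)

        # pericentromeric zone: one drop per chromosome + decoys
        peri = _Cursor(int(0.04 * L) + 200_000, int(0.28 * L))
        if ci < config.n_drops:
            dlen = int(rng.integers(config.drop_min // 10_000,
                                    config.drop_max // 10_000 + 1)) * 10_000
            iv = peri.take(dlen)
            if iv:
                drops.append((GenomicInterval(chrom, *iv, "drop"),
                              iv[0] < 3_000_000))
        if ci < config.n_pmd_decoys:
            dlen = int(rng.integers(config.decoy_min, config.decoy_max))
            iv = peri.take(dlen)
            if iv:
                decoys.append(GenomicInterval(chrom, *iv, "decoy"))

        # tail zone: remaining drops, universal PMD, tissue PMD blocks
        tail = _Cursor(int(0.68 * L), int(0.98 * L))
        extra_drop_idx = config.n_chroms + ci
        if extra_drop_idx < config.n_drops:
            dlen = int(rng.integers(config.drop_min // 10_000,
                                    config.drop_max // 10_000 + 1)) * 10_000
            iv = tail.take(dlen)
            if iv:
                drops.append((GenomicInterval(chrom, *iv, "drop"),
                              iv[0] < 3_000_000))
        if ci == config.n_chroms - 1 and config.universal_pmd_len:
            iv = tail.take(config.universal_pmd_len)
            if iv:
                universal = GenomicInterval(chrom, *iv, "universal")
        somatic_tissues = [t.name for t in config.tissues
                           if t.cluster_group == "somatic"
                           and not t.blood_related]
        blocks = [(t, b) for b in range(config.pmds_per_somatic_tissue)
                  for t in somatic_tissues]
        for bi, (tissue, _) in enumerate(blocks):
            if bi % config.n_chroms != ci:
                continue
            blen = int(rng.integers(config.pmd_block_min // 10_000,
                                    config.pmd_block_max // 10_000 + 1)
                       ) * 10_000
            iv = tail.take(blen)
            if iv:
                tissue_pmds.setdefault(tissue, []).append(
                    GenomicInterval(chrom, *iv, f"pmd_{tissue}"))

    # sperm-specific hypomethylated windows in the inter-zone gaps: the
    # germline's distinct methylome and the source of sperm-hypo variable
    # regions in the 1%-tail analysis
    sperm_windows: list[GenomicInterval] = []
    for chrom in chroms:
        L = chrom_len[chrom]
        gaps = ((int(0.28 * L), int(0.30 * L)),
                (int(0.66 * L), int(0.68 * L)))
        placed = 0
        for glo, ghi in gaps:
            pos_w = -(-glo // 10_000) * 10_000
            while placed < config.n_sperm_hypo_windows and \
                    pos_w + 10_000 <= ghi:
                sperm_windows.append(
                    GenomicInterval(chrom, pos_w, pos_w + 10_000))
                pos_w += 10_000
                placed += 1

    # ---- repeats --------------------------------------------------------
    catalog = (("SINE/Bov-A2", "Bov-A2", 190), ("SINE/Bov-tA2", "Bov-tA2", 190),
               ("LINE/L1", "L1_BT", 6000), ("LINE/RTE-BovB", "BovB", 3000),
               ("LTR/ERVK", "ERVK_LTR", 1000))
    repeats: list[RepeatElement] = []
    nested: list[tuple[RepeatElement, RepeatElement, RepeatElement]] = []
    sperm_hypo: list[RepeatElement] = []

    def young_bova2(chrom: str, start: int) -> RepeatElement:
        div = float(rng.uniform(0.5, 6.0))
        return RepeatElement(chrom, start, start + 185, "+", "Bov-A2",
                             "SINE/Bov-A2", div, 0, 185, 190)

    no_hmr_tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        if gene_class[g.gene_id] == "NO_TSS_HMR":
            no_hmr_tss_by_chrom.setdefault(g.chrom, []).append(g.primary_tss)
    t1_tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        if gene_class[g.gene_id] == "T1" and g.gene_id not in tissue_specific_genes:
            t1_tss_by_chrom.setdefault(g.chrom, []).append(g.primary_tss)

    for ci, chrom in enumerate(chroms):
        L = chrom_len[chrom]
        # random background catalogue
        for _ in range(config.repeats_per_chrom):
            subclass, name, clen = catalog[int(rng.integers(len(catalog)))]
            div = float(rng.uniform(1, 30))
            if clen <= 200:
                # young SINE copies have not fragmented yet
                if div <= config.young_divergence_max:
                    cs, ce = 0, int(rng.integers(clen - 8, clen + 1))
                else:
                    cs = 0
                    ce = int(rng.integers(int(0.5 * clen), clen + 1))
            else:
                cs = int(rng.integers(0, clen // 2))
                ce = cs + int(rng.integers(200, min(1200, clen - cs) + 1))
            length = ce - cs
            start = int(rng.integers(0, L - length))
            strand = "+" if rng.random() < 0.5 else "-"
            repeats.append(RepeatElement(chrom, start, start + length, strand,
                                         name, subclass, div, cs, ce, clen))
        # sperm-hypomethylated young Bov-A2 at methylated promoters
        hosts = no_hmr_tss_by_chrom.get(chrom, [])
        for k in range(min(config.n_sperm_hypo_bova2, len(hosts))):
            e = young_bova2(chrom, hosts[k] + 220)
            repeats.append(e)
            sperm_hypo.append(e)
        # full-length Bov-A2 planted inside TSS-HMRs (O/E signal)
        t1_hosts = t1_tss_by_chrom.get(chrom, [])
        for k in range(min(config.n_bova2_in_tss_hmr, len(t1_hosts))):
            repeats.append(young_bova2(chrom, t1_hosts[k] + 700))
        # nested insertions: young Bov-A2 splitting an old Bov-tA2
        for k in range(config.n_nested_per_chrom):
            x = int(0.985 * L) + k * 1500
            if x + 600 > L:
                break
            up = RepeatElement(chrom, x, x + 80, "+", "Bov-tA2",
                               "SINE/Bov-tA2", 22.0, 0, 80, 190)
            inner = RepeatElement(chrom, x + 90, x + 280, "+", "Bov-A2",
                                  "SINE/Bov-A2", 2.0, 0, 190, 190)
            down = RepeatElement(chrom, x + 300, x + 410, "+", "Bov-tA2",
                                 "SINE/Bov-tA2", 23.0, 80, 190, 190)
            repeats.extend((up, inner, down))
            nested.append((up, inner, down))
    repeats.sort(key=lambda e: (e.chrom, e.start, e.end))

    # young CpG-rich SINE bodies are planted dense CpG clusters too: a
    # distance-based island predictor will (correctly) report them
    sperm_hypo_keys = {element_key(e) for e in sperm_hypo}
    for e in repeats:
        if (e.repeat_subclass.startswith("SINE")
                and e.divergence_pct <= config.young_divergence_max):
            iv = GenomicInterval(e.chrom, e.start, e.end, "repeat_cluster")
            cgi_truth.append(
                (iv, "eCGI" if element_key(e) in sperm_hypo_keys
                 else "neCGI"))

    # ---- CpG positions --------------------------------------------------
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom in chroms:
        L = chrom_len[chrom]
        n_bg = rng.poisson(config.background_cpg_rate * L)
        pos = rng.integers(0, L - 1, size=n_bg)
        extra = []
        for iv in dense_regions:
            if iv.chrom != chrom:
                continue
            n = rng.poisson((config.cgi_cpg_rate - config.background_cpg_rate)
                            * len(iv))
            extra.append(rng.integers(iv.start, iv.end - 1, size=n))
        for iv in distal_regions:
            if iv.chrom != chrom:
                continue
            n = rng.poisson((config.distal_cpg_rate
                             - config.background_cpg_rate) * len(iv))
            extra.append(rng.integers(iv.start, iv.end - 1, size=n))
            # deterministic backbone so every planted feature holds >= 5 CpGs
            extra.append(np.linspace(iv.start, iv.end - 2, num=5,
                                     dtype=np.int64))
        for e in repeats:
            if e.chrom != chrom:
                continue
            rate = (config.young_repeat_cpg_rate
                    if e.repeat_subclass.startswith("SINE")
                    and e.divergence_pct <= config.young_divergence_max
                    else config.repeat_cpg_rate)
            n = rng.poisson((rate - config.background_cpg_rate)
                            * (e.end - e.start))
            if n:
                extra.append(rng.integers(e.start, e.end - 1, size=n))
        allpos = np.concatenate([pos, *extra]) if extra else pos
        allpos = np.unique(allpos)
        keep = np.ones(len(allpos), dtype=bool)
        if len(allpos) > 1:
            keep[1:] = np.diff(allpos) >= 2  # CpGs cannot overlap
        cpg_positions[chrom] = allpos[keep].astype(np.int64)

    # ---- per-tissue truth surfaces --------------------------------------
    tissue_names = [t.name for t in config.tissues]
    surfaces: dict[str, dict[str, np.ndarray]] = {}
    placenta_blocks: list[GenomicInterval] = []
    for chrom in chroms:
        L = chrom_len[chrom]
        period = 1_000_000
        block = int(config.placenta_pmd_fraction * period)
        for s in range(0, L, period):
            placenta_blocks.append(
                GenomicInterval(chrom, s, min(s + block, L)))

    def paint(level_arr: np.ndarray, pos: np.ndarray,
              ivs: Sequence[GenomicInterval], chrom: str, level: float):
        for iv in ivs:
            if iv.chrom != chrom:
                continue
            lo, hi = np.searchsorted(pos, [iv.start, iv.end])
            level_arr[lo:hi] = level

    spec_by_name = {t.name: t for t in config.tissues}
    for tissue in tissue_names:
        spec = spec_by_name[tissue]
        surfaces[tissue] = {}
        for chrom in chroms:
            pos = cpg_positions[chrom]
            lv = np.full(len(pos), config.background_level)
            # repeat-age modulation of the methylated background
            for e in repeats:
                if e.chrom != chrom or np.isnan(e.divergence_pct):
                    continue
                lo, hi = np.searchsorted(pos, [e.start, e.end])
                if hi > lo:
                    lv[lo:hi] = np.clip(
                        config.background_level
                        + config.repeat_age_slope * e.divergence_pct,
                        0.05, 0.95)
            if spec.cluster_group == "placenta":
                paint(lv, pos, placenta_blocks, chrom, config.pmd_level)
            if spec.cluster_group == "somatic" and not spec.blood_related:
                paint(lv, pos, tissue_pmds.get(tissue, []), chrom,
                      config.pmd_level)
                paint(lv, pos, [d for d, _ in drops], chrom, config.pmd_level)
                paint(lv, pos, decoys, chrom, config.pmd_level)
            if universal is not None:
                paint(lv, pos, [universal], chrom, config.pmd_level)
            # hypomethylated features
            hypo = list(all_sample_hmrs)
            if spec.cluster_group == "placenta":
                wide = []
                for iv in distal_hmrs:
                    mid = (iv.start + iv.end) // 2
                    half = config.placenta_distal_hmr_mean // 2
                    wide.append(GenomicInterval(
                        iv.chrom, max(0, mid - half),
                        min(chrom_len[iv.chrom], mid + half)))
                hypo += wide
            else:
                hypo += distal_hmrs
            hypo += tissue_hmrs.get(tissue, [])
            if spec.cluster_group == "sperm":
                hypo += [e.interval for e in sperm_hypo]
                hypo += sperm_windows
            paint(lv, pos, hypo, chrom, config.hmr_level)
            for g, levels in graded_genes.items():
                if tissue in levels:
                    paint(lv, pos, [graded_hmrs[g]], chrom, levels[tissue])
            surfaces[tissue][chrom] = lv

    # ---- truth bookkeeping per sample -----------------------------------
    hmrs_by_sample: dict[str, list[GenomicInterval]] = {}
    pmds_by_sample: dict[str, list[GenomicInterval]] = {}
    for s in sheet:
        spec = spec_by_name[s.tissue]
        hmrs = list(all_sample_hmrs)
        if spec.cluster_group == "placenta":
            for iv in distal_hmrs:
                mid = (iv.start + iv.end) // 2
                half = config.placenta_distal_hmr_mean // 2
                hmrs.append(GenomicInterval(
                    iv.chrom, max(0, mid - half),
                    min(chrom_len[iv.chrom], mid + half)))
        else:
            hmrs += distal_hmrs
        hmrs += tissue_hmrs.get(s.tissue, [])
        if spec.cluster_group == "sperm":
            hmrs += [e.interval for e in sperm_hypo]
            hmrs += sperm_windows
        for g, levels in graded_genes.items():
            if levels.get(s.tissue, 1.0) <= 0.3:
                hmrs.append(graded_hmrs[g])
        hmrs_by_sample[s.sample_id] = sorted(
            hmrs, key=lambda iv: (iv.chrom, iv.start))
        pmds: list[GenomicInterval] = []
        if spec.cluster_group == "placenta":
            pmds += placenta_blocks
        if spec.cluster_group == "somatic" and not spec.blood_related:
            pmds += tissue_pmds.get(s.tissue, [])
            pmds += [d for d, _ in drops]
        if universal is not None:
            pmds.append(universal)
        pmds_by_sample[s.sample_id] = sorted(
            pmds, key=lambda iv: (iv.chrom, iv.start))

    annotation = Annotation(dict(chrom_len), cpg_positions, genes,
                            repeats, cgis)
    truth = TruthSet(hmrs_by_sample, pmds_by_sample, decoys, drops, universal,
                     cgi_truth, gene_class, graded_genes, twin_pairs,
                     control_pairs,
                     tissue_specific_genes,
                     [element_key(e) for e in sperm_hypo], nested,
                     surfaces, tissue_of)
    return annotation, truth


# ------------------------------------------------------------- methylomes

def simulate_methylomes(config: SimConfig, annotation: Annotation,
                        truth: TruthSet, seed: Optional[int] = None
                        ) -> dict[str, Methylome]:
    """Draw per-sample read counts from the tissue truth surfaces.

    coverage ~ Poisson(coverage_mean); pi gets per-sample beta jitter with
    the configured concentration (0 = pure binomial); counts ~
    Binomial(coverage, pi).  Replicates share the tissue surface and
    differ only through sampling noise.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out: dict[str, Methylome] = {}
    for sample_id, tissue in truth.tissue_of.items():
        m = Methylome(sample_id=sample_id)
        for chrom, pos in annotation.cpg_positions.items():
            pi = truth.surfaces[tissue][chrom]
            cov = rng.poisson(config.coverage_mean, size=len(pos))
            c = config.beta_jitter_concentration
            if c > 0:
                p = rng.beta(np.clip(pi * c, 1e-3, None),
                             np.clip((1 - pi) * c, 1e-3, None))
            else:
                p = pi
            meth = rng.binomial(cov, p)
            m.chroms[chrom] = ChromCounts(pos.copy(), meth.astype(np.int64),
                                          (cov - meth).astype(np.int64))
        out[sample_id] = m
    return out


def simulate_null_pair(n_cpgs: int = 100_000, coverage_mean: float = 16.0,
                       level: float = 0.8, seed: int = 0
                       ) -> tuple[Methylome, Methylome]:
    """Two methylomes sampled independently from one shared truth.

    Pure binomial sampling (no biological jitter): the correct null for
    differential-test calibration.
    """
    rng = np.random.default_rng(seed)
    pos = np.arange(n_cpgs, dtype=np.int64) * 50
    out = []
    for name in ("null_a", "null_b"):
        cov = rng.poisson(coverage_mean, size=n_cpgs)
        meth = rng.binomial(cov, level)
        m = Methylome(sample_id=name)
        m.chroms["chr1"] = ChromCounts(pos.copy(), meth.astype(np.int64),
                                       (cov - meth).astype(np.int64))
        out.append(m)
    return out[0], out[1]


# ------------------------------------------------------------- expression

def simulate_expression(config: SimConfig, annotation: Annotation,
                        truth: TruthSet, coupling: Optional[float] = None,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Gene x sample TPM table coupled to promoter truth methylation.

    log2(TPM+1) = base + coupling * (0.4 - promoter_level) + twin factor
    (shared within a twin pair, scaled off when coupling == 0) + noise.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    coupling = config.expression_coupling if coupling is None else coupling
    twin_sd = config.twin_factor_sd if coupling != 0 else 0.0
    sheet = config.sample_sheet()
    sample_ids = [s.sample_id for s in sheet]
    genes = annotation.genes
    base = rng.normal(config.expr_base_mean, config.expr_base_sd,
                      size=len(genes))

    # promoter truth level per gene per tissue
    prom_level = np.zeros((len(genes), len(sample_ids)))
    for gi, g in enumerate(genes):
        pos = annotation.cpg_positions[g.chrom]
        tss = g.primary_tss
        lo, hi = np.searchsorted(pos, [tss - 1000, tss + 1000])
        for sj, s in enumerate(sheet):
            surf = truth.surfaces[s.tissue][g.chrom]
            prom_level[gi, sj] = surf[lo:hi].mean() if hi > lo else 0.8

    logexpr = (base[:, None]
               + coupling * (0.4 - prom_level)
               + rng.normal(0, config.expr_noise_sd,
                            size=(len(genes), len(sample_ids))))
    if twin_sd > 0:
        gidx = {g.gene_id: i for i, g in enumerate(genes)}
        for ga, gb in truth.twin_pairs:
            factor = rng.normal(0, twin_sd, size=len(sample_ids))
            logexpr[gidx[ga]] += factor
            logexpr[gidx[gb]] += factor
    tpm = np.maximum(np.exp2(logexpr) - 1.0, 0.0)
    return pd.DataFrame(tpm, index=[g.gene_id for g in genes],
                        columns=sample_ids)


# ---------------------------------------------------------------- hetSNPs

def simulate_het_snps(config: SimConfig, annotation: Annotation,
                      truth: TruthSet, seed: Optional[int] = None
                      ) -> list[HetSNP]:
    """Baseline het SNPs plus elevated C/T hets at methylated CpGs.

    The C/T (and G/A) heterozygote rate at a CpG scales with the
    configured elevation factor when the CpG's shared truth methylation is
    high — spontaneous deamination of methyl-C — which depletes C/T hets
    inside the planted (hypomethylated) islands.
    """
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    bases = np.array(list("ACGT"))
    out: list[HetSNP] = []
    somatic = [t.name for t in config.tissues
               if t.cluster_group == "somatic" and not t.blood_related]
    ref_tissue = somatic[0] if somatic else config.tissues[0].name
    for chrom, L in annotation.chrom_lengths.items():
        n = rng.poisson(config.snp_rate * L)
        pos = np.sort(rng.integers(0, L, size=n))
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            out.append(HetSNP(chrom, int(p), str(bases[ref]),
                              str(bases[alt]), bool(rng.random() < 0.9)))
        # CpG transition hets, methylation-coupled
        cpgs = annotation.cpg_positions[chrom]
        lvl = truth.surfaces[ref_tissue][chrom]
        prob = np.where(lvl >= 0.5,
                        config.cpg_ct_het_base * config.ct_het_elevation,
                        config.cpg_ct_het_base)
        hit = rng.random(len(cpgs)) < prob
        g_strand = rng.random(len(cpgs)) < 0.5
        for p, on_g in zip(cpgs[hit], g_strand[hit]):
            if on_g:
                out.append(HetSNP(chrom, int(p) + 1, "G", "A", True))
            else:
                out.append(HetSNP(chrom, int(p), "C", "T", True))
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


# ---------------------------------------------------------------- driver

def generate(config: SimConfig) -> Dataset:
    """Full deterministic dataset for one configuration."""
    annotation, truth = simulate_annotation(config)
    methylomes = simulate_methylomes(config, annotation, truth)
    expression = simulate_expression(config, annotation, truth)
    snps = simulate_het_snps(config, annotation, truth)
    return Dataset(config, config.sample_sheet(), annotation, truth,
                   methylomes, expression, snps)


def write_dataset(ds: Dataset, outdir) -> None:
    """Emit the dataset in exactly the formats the readers consume."""
    from . import io as bio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = []
    for s in ds.sheet:
        name = f"{s.sample_id}.CpG_report.txt"
        bio.write_cytosine_report(ds.methylomes[s.sample_id].records(),
                                  outdir / name)
        # paths are stored relative to the sheet for relocatable datasets
        samples.append(SampleInfo(s.sample_id, s.tissue, s.cluster_group,
                                  s.blood_related, name, "expression.tsv"))
    bio.write_sample_sheet(SampleSheet(samples), outdir / "samples.csv")
    bio.write_expression_table(ds.expression, outdir / "expression.tsv")
    _write_gtf(ds.annotation.genes, outdir / "genes.gtf")
    _write_repeatmasker(ds.annotation.repeats, outdir / "repeats.out")
    _write_vcf(ds.het_snps, outdir / "snps.vcf")
    with open(outdir / "chrom_lengths.json", "w") as fh:
        json.dump(ds.annotation.chrom_lengths, fh, indent=0, sort_keys=True)
    # truth files
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    for sid, hmrs in ds.truth.hmrs_by_sample.items():
        bio.write_bed(hmrs, tdir / f"{sid}.hmr.bed")
    for sid, pmds in ds.truth.pmds_by_sample.items():
        bio.write_bed(pmds, tdir / f"{sid}.pmd.bed")
    bio.write_bed([d for d, _ in ds.truth.drops], tdir / "drops.bed")
    bio.write_bed(ds.truth.decoys, tdir / "pmd_decoys.bed")
    bio.write_bed([iv for iv, _ in ds.truth.cgi_truth], tdir / "cgis.bed")
    with open(tdir / "gene_class.json", "w") as fh:
        json.dump(ds.truth.gene_class, fh, indent=0, sort_keys=True)


def _write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tsim\tgene\t{g.gene_start + 1}\t{g.gene_end}"
                     f"\t.\t{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                a = f'gene_id "{g.gene_id}"; transcript_id "{t.tx_id}";'
                fh.write(f"{g.chrom}\tsim\ttranscript\t{t.tx_start + 1}\t"
                         f"{t.tx_end}\t.\t{g.strand}\t.\t{a}\n")
                fh.write(f"{g.chrom}\tsim\texon\t{t.tx_start + 1}\t{t.tx_end}"
                         f"\t.\t{g.strand}\t.\t{a}\n")


def _write_repeatmasker(repeats: Sequence[RepeatElement], path) -> None:
    with open(path, "w") as fh:
        fh.write("   SW  perc perc perc  query     position in query"
                 "              matching repeat\n")
        fh.write("score  div. del. ins.  sequence  begin  end    (left)"
                 "   repeat    class/family  begin end (left)  ID\n\n")
        for i, e in enumerate(repeats, 1):
            if e.consensus_length is None:
                cs, ce, left = 1, 1, "(0)"
            elif e.strand == "+":
                cs = e.consensus_start + 1
                ce = e.consensus_end
                left = f"({e.consensus_length - e.consensus_end})"
            else:
                cs = e.consensus_start + 1
                ce = e.consensus_end
                left = f"({e.consensus_length - e.consensus_end})"
            strand = "+" if e.strand == "+" else "C"
            if e.strand == "+":
                cons = f"{cs} {ce} {left}"
            else:
                cons = f"{left} {ce} {cs}"
            fh.write(f"{1000 + i} {e.divergence_pct:.1f} 0.0 0.0 {e.chrom} "
                     f"{e.start + 1} {e.end} (0) {strand} {e.repeat_name} "
                     f"{e.repeat_subclass} {cons} {i}\n")


def _write_vcf(snps: Sequence[HetSNP], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({s.chrom for s in snps})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 "animal1\n")
        for s in snps:
            gt = "0/1" if s.is_het else "1/1"
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref_allele}\t"
                     f"{s.alt_allele}\t50\tPASS\t.\tGT\t{gt}\n")
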