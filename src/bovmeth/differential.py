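"""DMC / DMR calling between sample pairs and tissue-specific DMR ranking.

Per-site differences are tested with Fisher's exact test on the 2x2 read
count table and corrected with Benjamini-Hochberg FDR.  DMCs require
|difference| > 0.3, q < 0.05 and >= 10x depth in both samples; DMRs are
500-bp windows with the same thresholds on pooled counts, supported by at
least five DMCs in the same direction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import Methylome, weighted_level
from .types import GenomicInterval, SampleSheet

log = logging.getLogger(__name__)

_REL_TOL = 1 + 1e-7  # two-sided rule: sum pmf(k) <= pmf(obs) * (1 + eps)


@lru_cache(maxsize=1_000_000)
def fisher_exact_two_sided(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher's exact p for the table [[m_a, u_a], [m_b, u_b]].

    Computed by direct hypergeometric enumeration: conditioning on the
    margins, p is the sum of probabilities of all tables no more likely
    than the observed one (the convention shared by R and scipy).
    """
    n_a, n_b = m_a + u_a, m_b + u_b
    M, K = n_a + n_b, m_a + m_b
    lo, hi = max(0, K - n_b), min(K, n_a)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, M, K, n_a)
    p_obs = pmf[m_a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * _REL_TOL].sum()))


def dmc_test(m_a: int, u_a: int, m_b: int, u_b: int) -> tuple[float, float]:
    """Methylation difference (A - B) and two-sided Fisher p for one site."""
    n_a, n_b = m_a + u_a, m_b + u_b
    if n_a == 0 or n_b == 0:
        raise ValueError("both sites need coverage")
    diff = m_a / n_a - m_b / n_b
    return diff, fisher_exact_two_sided(m_a, u_a, m_b, u_b)


@dataclass(frozen=True, slots=True)
class DMCRecord:
    chrom: str
    pos: int
    level_a: float
    level_b: float
    diff: float
    p_value: float
    q_value: float
    cov_a: int
    cov_b: int

    @property
    def direction(self) -> str:
        return "hyper" if self.diff > 0 else "hypo"


@dataclass(frozen=True, slots=True)
class DMRRecord:
    chrom: str
    start: int
    end: int
    mean_diff: float
    p_value: float
    q_value: float
    n_dmc_same_direction: int
    direction: str


def _shared_sites(a: Methylome, b: Methylome, min_depth: int
                  ) -> list[tuple[str, np.ndarray, np.ndarray, np.ndarray,
                                  np.ndarray, np.ndarray]]:
    out = []
    for chrom in sorted(set(a.chroms) & set(b.chroms)):
        ca, cb = a.chroms[chrom], b.chroms[chrom]
        common, ia, ib = np.intersect1d(ca.pos, cb.pos, return_indices=True)
        cov_a = ca.coverage[ia]
        cov_b = cb.coverage[ib]
        keep = (cov_a >= min_depth) & (cov_b >= min_depth)
        if keep.any():
            out.append((chrom, common[keep], ca.meth[ia][keep],
                        cov_a[keep], cb.meth[ib][keep], cov_b[keep]))
    return out


def call_dmcs(methylome_a: Methylome, methylome_b: Methylome,
              min_depth: int = 10, diff_min: float = 0.3,
              q_max: float = 0.05, return_all: bool = False
              ) -> list[DMCRecord]:
    """Differentially methylated CpGs between two samples.

    All shared sites at ``min_depth`` in both samples are tested and enter
    the BH correction; only sites with |diff| > ``diff_min`` and
    q < ``q_max`` are reported (all tested sites with ``return_all``).
    """
    shared = _shared_sites(methylome_a, methylome_b, min_depth)
    if not shared:
        log.warning("no shared CpGs at depth >= %d", min_depth)
        return []
    rows = []
    pvals = []
    for chrom, pos, m_a, n_a, m_b, n_b in shared:
        for i in range(len(pos)):
            diff, p = dmc_test(int(m_a[i]), int(n_a[i] - m_a[i]),
                               int(m_b[i]), int(n_b[i] - m_b[i]))
            rows.append((chrom, int(pos[i]), m_a[i] / n_a[i], m_b[i] / n_b[i],
                         diff, p, int(n_a[i]), int(n_b[i])))
            pvals.append(p)
    q = multipletests(pvals, method="fdr_bh")[1]
    out = []
    for (chrom, pos, la, lb, diff, p, ca, cb), qi in zip(rows, q):
        if return_all or (abs(diff) > diff_min and qi < q_max):
            out.append(DMCRecord(chrom, pos, la, lb, diff, p, float(qi),
                                 ca, cb))
    return out


def call_dmrs(methylome_a: Methylome, methylome_b: Methylome,
              dmcs: Sequence[DMCRecord], window: int = 500,
              min_depth: int = 10, diff_min: float = 0.3,
              q_max: float = 0.05, min_dmc: int = 5) -> list[DMRRecord]:
    """500-bp window DMRs from pooled counts, requiring DMC support.

    Each window's difference and Fisher p come from the pooled 2x2 table
    of its shared >= ``min_depth`` CpGs; BH across windows; a window is
    reported when |mean_diff| > ``diff_min``, q < ``q_max`` and at least
    ``min_dmc`` DMCs in it share the window's direction.
    """
    shared = _shared_sites(methylome_a, methylome_b, min_depth)
    dmc_by_window: dict[tuple[str, int], list[int]] = {}
    for d in dmcs:
        dmc_by_window.setdefault((d.chrom, d.pos // window), []).append(
            1 if d.diff > 0 else -1)
    windows = []
    pvals = []
    for chrom, pos, m_a, n_a, m_b, n_b in shared:
        widx = pos // window
        for w in np.unique(widx):
            sel = widx == w
            Ma, Na = int(m_a[sel].sum()), int(n_a[sel].sum())
            Mb, Nb = int(m_b[sel].sum()), int(n_b[sel].sum())
            diff = Ma / Na - Mb / Nb
            p = fisher_exact_two_sided(Ma, Na - Ma, Mb, Nb - Mb)
            windows.append((chrom, int(w), diff, p))
            pvals.append(p)
    if not windows:
        return []
    q = multipletests(pvals, method="fdr_bh")[1]
    out = []
    for (chrom, w, diff, p), qi in zip(windows, q):
        if abs(diff) <= diff_min or qi >= q_max:
            continue
        signs = dmc_by_window.get((chrom, w), [])
        sign = 1 if diff > 0 else -1
        support = sum(1 for s in signs if s == sign)
        if support < min_dmc:
            continue
        out.append(DMRRecord(chrom, w * window, (w + 1) * window,
                             float(diff), float(p), float(qi), support,
                             "hyper" if diff > 0 else "hypo"))
    return out


@dataclass(frozen=True, slots=True)
class TissueSpecificDMR:
    chrom: str
    start: int
    end: int
    tissue: str
    frequency: int
    direction: str
    mean_abs_diff: float


def tissue_specific_dmrs(dmr_sets_by_comparison: Mapping[tuple[str, str],
                                                         Sequence[DMRRecord]],
                         sample_sheet: SampleSheet, focal_tissue: str,
                         top_fraction: float = 0.001
                         ) -> list[TissueSpecificDMR]:
    """Rank windows by how often they are a same-direction DMR for a tissue.

    ``dmr_sets_by_comparison`` maps (focal_sample, other_sample) pairs to
    their DMR calls (direction = focal minus other).  Windows are ranked
    by frequency (ties by |mean_diff| then coordinate), the top fraction
    selected, overlapping windows merged, and each merged region must have
    been a DMR against every other tissue group to survive.
    """
    if not (0.0001 <= top_fraction <= 0.003):
        log.warning("top_fraction %.4f outside the usual 0.01%%-0.3%% range",
                    top_fraction)
    focal_ids = set(sample_sheet.ids(tissue=focal_tissue))
    tissue_of = {s.sample_id: s.tissue for s in sample_sheet}

    stats: dict[tuple[str, int, int, str], dict] = {}
    for (sa, sb), dmrs in dmr_sets_by_comparison.items():
        if sa not in focal_ids:
            continue
        other_tissue = tissue_of.get(sb, sb)
        for d in dmrs:
            key = (d.chrom, d.start, d.end, d.direction)
            st = stats.setdefault(key, {"freq": 0, "diffs": [],
                                        "tissues": set()})
            st["freq"] += 1
            st["diffs"].append(abs(d.mean_diff))
            st["tissues"].add(other_tissue)

    if not stats:
        return []
    other_tissues = {t for t in sample_sheet.tissues if t != focal_tissue}
    ranked = sorted(
        stats.items(),
        key=lambda kv: (-kv[1]["freq"], -float(np.mean(kv[1]["diffs"])),
                        kv[0][0], kv[0][1]))
    k = max(1, int(np.floor(top_fraction * len(ranked))))
    chosen = ranked[:k]

    merged: list[dict] = []
    for (chrom, start, end, direction), st in sorted(
            chosen, key=lambda kv: (kv[0][0], kv[0][1])):
        if (merged and merged[-1]["chrom"] == chrom
                and start <= merged[-1]["end"]
                and merged[-1]["direction"] == direction):
            m = merged[-1]
            m["end"] = max(m["end"], end)
            m["freq"] = max(m["freq"], st["freq"])
            m["diffs"].extend(st["diffs"])
            m["tissues"] |= st["tissues"]
        else:
            merged.append({"chrom": chrom, "start": start, "end": end,
                           "direction": direction, "freq": st["freq"],
                           "diffs": list(st["diffs"]),
                           "tissues": set(st["tissues"])})
    out = []
    for m in merged:
        if other_tissues and not other_tissues <= m["tissues"]:
            continue  # not differential against every other tissue group
        out.append(TissueSpecificDMR(m["chrom"], m["start"], m["end"],
                                     focal_tissue, m["freq"], m["direction"],
                                     float(np.mean(m["diffs"]))))
    return out


def element_methylation(elements: Sequence[GenomicInterval],
                        methylome: Methylome, min_cov: int = 5,
                        detection_rate: float = 0.10,
                        small_element_cgs: int = 5,
                        large_element_threshold: int = 50
                        ) -> pd.DataFrame:
    """Weighted level per element with the size-dependent detection filter.

    An element passes when >= 10% of its CpGs are detected (coverage >=
    ``min_cov``) if it holds more than 50 CpGs, or when at least five CpGs
    are detected otherwise.  Returns a frame indexed like ``elements`` with
    columns (n_cpgs, n_detected, level, passes).
    """
    rows = []
    for iv in elements:
        cc = methylome.chroms.get(iv.chrom)
        if cc is None:
            rows.append((iv.name, iv.chrom, iv.start, iv.end, 0, 0,
                         np.nan, False))
            continue
        lo, hi = np.searchsorted(cc.pos, [iv.start, iv.end])
        n_cpgs = hi - lo
        cov = cc.coverage[lo:hi]
        det = cov >= min_cov
        n_det = int(det.sum())
        if n_cpgs > large_element_threshold:
            passes = n_det >= detection_rate * n_cpgs
        else:
            passes = n_det >= small_element_cgs
        level = (weighted_level(cc.meth[lo:hi][det], cc.unmeth[lo:hi][det])
                 if n_det else np.nan)
        rows.append((iv.name, iv.chrom, iv.start, iv.end, int(n_cpgs),
                     n_det, level, bool(passes)))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end",
                                       "n_cpgs", "n_detected", "level",
                                       "passes"])


def promoter_intervals(gene_models, flank: int = 1000,
                       use_primary_tss: bool = True
                       ) -> list[GenomicInterval]:
    """Promoters as TSS +/- ``flank`` bp (one per gene by default)."""
    out = []
    for g in gene_models:
        tss_list = [g.primary_tss] if use_primary_tss else list(g.tss_positions)
        for i, tss in enumerate(tss_list):
            name = g.gene_id if use_primary_tss else f"{g.gene_id}.{i}"
            out.append(GenomicInterval(g.chrom, max(0, tss - flank),
                                       tss + flank, name, g.strand))
    return out
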