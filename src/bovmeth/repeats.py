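"""Repeat-element methylation analyses.

Covers hypomethylated-repeat detection and TSS-proximity enrichment,
full-length (integrity > 80%) elements inside TSS-HMRs, per-subclass
observed/expected ratios, divergence-vs-methylation trends, and detection
of young elements nested inside split older elements.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .types import GeneModel, GenomicInterval, RepeatElement, Segment


def element_key(e: RepeatElement) -> str:
    """Unique identifier for one genomic repeat copy."""
    return f"{e.repeat_name}|{e.chrom}:{e.start}-{e.end}"


def element_intervals(elements: Sequence[RepeatElement]
                      ) -> list[GenomicInterval]:
    """Intervals named by :func:`element_key`, for element_methylation."""
    return [GenomicInterval(e.chrom, e.start, e.end, element_key(e), e.strand)
            for e in elements]


def hypomethylated_repeats(levels: Mapping[str, pd.DataFrame],
                           level_max: float = 0.3
                           ) -> dict[str, set[str]]:
    """Per-sample sets of element names with filtered level <= ``level_max``.

    ``levels`` maps sample_id to an element_methylation frame (must carry
    ``name``, ``level`` and ``passes`` columns).
    """
    out = {}
    for sid, tab in levels.items():
        ok = tab[tab["passes"] & (tab["level"] <= level_max)]
        out[sid] = set(ok["name"])
    return out


def tss_proximity_enrichment(hypo_names: set[str],
                             elements: Sequence[RepeatElement],
                             gene_models: Sequence[GeneModel],
                             window_bp: int = 2000,
                             n_shuffles: int = 500,
                             seed: int = 0) -> tuple[float, float]:
    """Enrichment of hypomethylated elements near TSSs.

    fold = (fraction of hypomethylated elements with midpoint within
    +/- ``window_bp`` of any TSS) / (same fraction over all elements);
    p by shuffling the hypomethylation labels across elements.
    """
    if not hypo_names:
        return float("nan"), float("nan")
    tss: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for g in gene_models:
        for t in g.transcripts:
            tmp.setdefault(g.chrom, []).append(t.tss_pos)
    tss = {c: np.sort(np.array(v)) for c, v in tmp.items()}

    def near(e: RepeatElement) -> bool:
        arr = tss.get(e.chrom)
        if arr is None:
            return False
        mid = (e.start + e.end) // 2
        i = np.searchsorted(arr, mid)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(int(arr[j]) - mid) <= window_bp:
                return True
        return False

    near_flags = np.array([near(e) for e in elements])
    hypo_flags = np.array([element_key(e) in hypo_names for e in elements])
    base = near_flags.mean()
    n_hypo = int(hypo_flags.sum())
    if base == 0 or n_hypo == 0:
        return float("nan"), float("nan")
    obs = near_flags[hypo_flags].mean()
    fold = obs / base
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        perm = rng.choice(len(elements), size=n_hypo, replace=False)
        if near_flags[perm].mean() >= obs:
            hits += 1
    return float(fold), (hits + 1) / (n_shuffles + 1)


def full_length_in_tss_hmr(elements: Sequence[RepeatElement],
                           tss_hmrs: Sequence[Segment],
                           integrity_min: float = 0.8
                           ) -> tuple[list[RepeatElement], pd.Series, int]:
    """Full-length elements overlapping a TSS-HMR, with per-subclass counts.

    Returns (kept elements, counts per subclass, number skipped for
    missing consensus coordinates).
    """
    hmr_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in tss_hmrs:
        hmr_by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    arrs = {}
    for c, ivs in hmr_by_chrom.items():
        ivs.sort()
        arrs[c] = (np.array([a for a, _ in ivs]), np.array([b for _, b in ivs]))

    kept = []
    n_missing = 0
    for e in elements:
        integ = e.integrity
        if integ is None:
            n_missing += 1
            continue
        if integ <= integrity_min:
            continue
        arr = arrs.get(e.chrom)
        if arr is None:
            continue
        starts, ends = arr
        i = np.searchsorted(starts, e.end)
        if i > 0 and ends[i - 1] > e.start:
            kept.append(e)
        elif i < len(starts) and starts[i] < e.end:
            kept.append(e)
    counts = pd.Series([e.repeat_subclass for e in kept]).value_counts() \
        if kept else pd.Series(dtype=int)
    return kept, counts, n_missing


def subclass_oe_ratio(elements_in_tss_hmr: Sequence[RepeatElement],
                      all_elements: Sequence[RepeatElement],
                      tss_hmr_total_bp: int, genome_bp: int) -> pd.DataFrame:
    """Observed/expected counts per subclass under bp-proportional placement."""
    obs = pd.Series([e.repeat_subclass for e in elements_in_tss_hmr]
                    ).value_counts()
    tot = pd.Series([e.repeat_subclass for e in all_elements]).value_counts()
    frac = tss_hmr_total_bp / genome_bp
    rows = []
    for subclass, n_total in tot.items():
        expected = n_total * frac
        if expected == 0:
            continue
        observed = int(obs.get(subclass, 0))
        rows.append((subclass, observed, float(expected),
                     observed / expected, expected < 1))
    return pd.DataFrame(rows, columns=["subclass", "observed", "expected",
                                       "oe_ratio", "unstable"])


def age_methylation_trend(elements: Sequence[RepeatElement],
                          levels: Mapping[str, pd.DataFrame],
                          min_elements: int = 20) -> pd.DataFrame:
    """Spearman correlation of divergence (age) vs level per subclass/sample."""
    div_by_name = {element_key(e): (e.repeat_subclass, e.divergence_pct)
                   for e in elements}
    rows = []
    for sid, tab in levels.items():
        tab = tab[tab["passes"]]
        sub_groups: dict[str, list[tuple[float, float]]] = {}
        for name, level in zip(tab["name"], tab["level"]):
            info = div_by_name.get(name)
            if info is None or np.isnan(info[1]) or np.isnan(level):
                continue
            sub_groups.setdefault(info[0], []).append((info[1], level))
        for subclass, pts in sub_groups.items():
            if len(pts) < min_elements:
                continue
            div = np.array([p[0] for p in pts])
            lev = np.array([p[1] for p in pts])
            if np.std(div) == 0 or np.std(lev) == 0:
                continue
            r, p = spearmanr(div, lev)
            rows.append((sid, subclass, len(pts), float(r), float(p)))
    return pd.DataFrame(rows, columns=["sample_id", "subclass", "n_elements",
                                       "spearman_r", "p_value"])


@dataclass(frozen=True, slots=True)
class NestedInsertion:
    inner: RepeatElement
    outer_up: RepeatElement
    outer_down: RepeatElement


def detect_nested_insertions(elements: Sequence[RepeatElement],
                             max_gap: int = 50,
                             consensus_slack: int = 30
                             ) -> list[NestedInsertion]:
    """Young elements that split an older element into two flanking parts.

    A nesting is a triple (outer_up, inner, outer_down) where the outer
    fragments share repeat_name and strand, flank the inner within
    ``max_gap`` bp on each side, their consensus coordinates continue
    sequentially within ``consensus_slack`` bp, and the inner's subclass
    differs from the outer's.
    """
    by_chrom: dict[str, list[RepeatElement]] = {}
    for e in elements:
        by_chrom.setdefault(e.chrom, []).append(e)
    out = []
    for chrom, els in sorted(by_chrom.items()):
        els.sort(key=lambda e: (e.start, e.end))
        for i in range(len(els) - 2):
            up, inner, down = els[i], els[i + 1], els[i + 2]
            if up.repeat_name != down.repeat_name or up.strand != down.strand:
                continue
            if inner.repeat_subclass == up.repeat_subclass:
                continue
            if not (up.end <= inner.start <= inner.end <= down.start):
                continue
            if inner.start - up.end > max_gap or down.start - inner.end > max_gap:
                continue
            if (up.consensus_end is None or down.consensus_start is None):
                continue
            a, b = up, down
            if up.strand == "-":
                a, b = down, up
            if not (b.consensus_start - consensus_slack <= a.consensus_end
                    <= b.consensus_start + consensus_slack):
                continue
            out.append(NestedInsertion(inner, up, down))
    return out
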