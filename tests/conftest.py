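"""Shared fixtures: generated datasets and interval helpers."""
from __future__ import annotations

import numpy as np
import pytest

from bovmeth.core import ChromCounts, Methylome
from bovmeth.simulate import DEFAULT_TISSUES, SimConfig, TissueSpec, generate
from bovmeth.types import Segment


@pytest.fixture(scope="session")
def default_ds():
    """The default desk-scale study: 3 x 5 Mb, 12 samples, 16x."""
    return generate(SimConfig(seed=11))


SMALL_TISSUES = (
    TissueSpec("sperm", 1, "sperm"),
    TissueSpec("placenta", 1, "placenta"),
    TissueSpec("blood", 1, "somatic", blood_related=True),
    TissueSpec("liver", 2, "somatic"),
    TissueSpec("kidney", 1, "somatic"),
    TissueSpec("heart", 1, "somatic"),
    TissueSpec("muscle", 1, "somatic"),
)


def small_config(seed: int = 3, **kw) -> SimConfig:
    defaults = dict(
        seed=seed, n_chroms=1, chrom_length_bp=2_000_000,
        tissues=SMALL_TISSUES, n_t2_pairs=3, n_control_pairs=1,
        n_t3_genes=2, n_total_in_hmr=2, n_no_hmr_genes=4, n_graded_genes=2,
        tissue_specific_plan=(("liver", 2),), n_extra_ecgi=5, n_necgi=3,
        n_distal_hmrs=8, n_drops=1, n_pmd_decoys=1, repeats_per_chrom=80,
        n_sperm_hypo_bova2=3, n_nested_per_chrom=2)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_ds():
    """A 1 x 2 Mb, 8-sample study for cheap unit tests."""
    return generate(small_config())


def truth_segments(intervals, label: str = "HMR") -> list[Segment]:
    """Wrap truth intervals as Segment objects for classifier inputs."""
    return [Segment(iv.chrom, iv.start, iv.end, 1, 0.1, 1.0, label)
            for iv in intervals]


def merged_cover(triples):
    """(chrom, start, end) triples -> merged per-chrom interval lists."""
    d: dict[str, list] = {}
    for c, s, e in triples:
        d.setdefault(c, []).append((s, e))
    for c in d:
        d[c].sort()
        merged = []
        for s, e in d[c]:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        d[c] = merged
    return d


def base_jaccard(a, b) -> float:
    """Base-level Jaccard of two (chrom, start, end) interval collections."""
    A, B = merged_cover(a), merged_cover(b)
    inter = 0
    for c in set(A) & set(B):
        for s, e in A[c]:
            for s2, e2 in B[c]:
                inter += max(0, min(e, e2) - max(s, s2))
    tot = (sum(e - s for m in A.values() for s, e in m)
           + sum(e - s for m in B.values() for s, e in m) - inter)
    return inter / tot if tot else float("nan")


def seg_triples(segments):
    return [(s.chrom, s.start, s.end) for s in segments]


def iv_triples(intervals):
    return [(iv.chrom, iv.start, iv.end) for iv in intervals]


def methylome_from_arrays(sample_id: str, chrom: str, pos, meth, unmeth
                          ) -> Methylome:
    m = Methylome(sample_id=sample_id)
    m.chroms[chrom] = ChromCounts(np.asarray(pos, dtype=np.int64),
                                  np.asarray(meth, dtype=np.int64),
                                  np.asarray(unmeth, dtype=np.int64))
    return m
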