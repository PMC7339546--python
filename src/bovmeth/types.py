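"""Core domain types shared across the toolkit.

All coordinates are 0-based, half-open ([start, end)); conversion to and
from 1-based on-disk conventions happens only at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True, slots=True)
class CpGSiteRecord:
    """A strand-merged CpG dinucleotide with bisulfite read counts.

    ``pos`` is the 0-based position of the C on the forward strand; counts
    from the reverse-strand C (at ``pos + 1``) are folded in by the reader.
    """

    chrom: str
    pos: int
    meth_count: int
    unmeth_count: int
    context: str = "CG"

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def level(self) -> float:
        cov = self.coverage
        return self.meth_count / cov if cov else float("nan")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class Transcript:
    tx_id: str
    tss_pos: int
    tx_start: int
    tx_end: int


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with one or more transcripts.

    The TSS follows the strand rule: ``tx_start`` for '+' genes and
    ``tx_end - 1`` for '-' genes (half-open coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    transcripts: tuple[Transcript, ...]

    @property
    def tss_positions(self) -> tuple[int, ...]:
        return tuple(t.tss_pos for t in self.transcripts)

    @property
    def primary_tss(self) -> int:
        """TSS of the longest transcript (deterministic tie-break by id)."""
        best = max(
            self.transcripts, key=lambda t: (t.tx_end - t.tx_start, t.tx_id)
        )
        return best.tss_pos


@dataclass(frozen=True, slots=True)
class RepeatElement:
    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_subclass: str
    divergence_pct: float = float("nan")
    consensus_start: Optional[int] = None
    consensus_end: Optional[int] = None
    consensus_length: Optional[int] = None

    @property
    def integrity(self) -> Optional[float]:
        """Fraction of the consensus covered by this copy; None if unknown."""
        if (
            self.consensus_start is None
            or self.consensus_end is None
            or not self.consensus_length
        ):
            return None
        return (self.consensus_end - self.consensus_start) / self.consensus_length

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.repeat_name, self.strand)


@dataclass(frozen=True, slots=True)
class HetSNP:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    is_het: bool

    @property
    def is_ct_type(self) -> bool:
        """True for C/T or G/A allele pairs (strand-symmetric transition)."""
        pair = frozenset((self.ref_allele.upper(), self.alt_allele.upper()))
        return pair == frozenset("CT") or pair == frozenset("GA")


@dataclass(frozen=True, slots=True)
class SampleInfo:
    sample_id: str
    tissue: str
    cluster_group: str  # sperm | placenta | somatic
    blood_related: bool = False
    methylome_path: Optional[str] = None
    expression_path: Optional[str] = None


@dataclass(slots=True)
class SampleSheet:
    samples: list[SampleInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_id values must be unique")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def by_id(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def ids(self, *, cluster_group: Optional[str] = None,
            blood_related: Optional[bool] = None,
            tissue: Optional[str] = None) -> list[str]:
        out = []
        for s in self.samples:
            if cluster_group is not None and s.cluster_group != cluster_group:
                continue
            if blood_related is not None and s.blood_related != blood_related:
                continue
            if tissue is not None and s.tissue != tissue:
                continue
            out.append(s.sample_id)
        return out

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.tissue, None)
        return list(seen)


@dataclass(frozen=True, slots=True)
class Segment:
    """A decoded genomic state run (HMR, PMD, HMD or methylation drop)."""

    chrom: str
    start: int
    end: int
    n_sites: int
    mean_level: float
    score: float
    state_label: str  # HMR | PMD | HMD | DROP
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.n_sites < 1:
            raise ValueError("segment must contain at least one site")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.state_label)

    def __len__(self) -> int:
        return self.end - self.start


def sort_intervals(intervals: Sequence) -> list:
    """Deterministic (chrom, start, end) ordering for any interval-likes."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(intervals: Sequence[GenomicInterval], gap: int = 0
                    ) -> list[GenomicInterval]:
    """Union of intervals, joining neighbours separated by <= ``gap`` bp."""
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out
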