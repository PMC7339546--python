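"""Readers and writers for every on-disk format the pipeline touches.

Internal coordinates are 0-based half-open; the 1-based conventions of
Bismark cytosine reports, GTF and VCF are converted here and only here.
Symmetric CpG strand pairs (C at p on '+', C at p+1 on '-') are merged
into a single forward-strand record with summed counts by default, since
CpG methylation is strand-symmetric; non-CG cytosines stay per-strand.
"""
from __future__ import annotations

import csv
import gzip
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (CpGSiteRecord, GeneModel, GenomicInterval, HetSNP,
                    RepeatElement, SampleInfo, SampleSheet, Transcript,
                    sort_intervals)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = str(path), lineno


def _open_text(path: PathLike):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_cpg_report(path: PathLike, context_filter: str = "CG",
                    merge_strands: bool = True) -> list[CpGSiteRecord]:
    """Read a Bismark cytosine report or coverage file into CpG records.

    The dialect is auto-detected: a cytosine report carries a strand
    symbol in column 3 (chrom, 1-based pos, strand, meth, unmeth,
    context), a coverage file does not (chrom, start, end, percent, meth,
    unmeth; coverage rows are CpG-merged already).  Records come back
    sorted per chromosome with 0-based forward-strand positions; unsorted
    input is sorted with a warning.
    """
    raw: list[tuple[str, int, str, int, int, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if parts[2] in "+-":  # cytosine report
                    chrom, pos, strand, meth, unmeth = (
                        parts[0], int(parts[1]), parts[2],
                        int(parts[3]), int(parts[4]))
                    context = parts[5] if len(parts) > 5 else "CG"
                    raw.append((chrom, pos - 1, strand, meth, unmeth, context))
                else:  # coverage dialect
                    chrom, start = parts[0], int(parts[1])
                    meth, unmeth = int(parts[4]), int(parts[5])
                    raw.append((chrom, start - 1, "+", meth, unmeth, "CG"))
            except (IndexError, ValueError) as exc:
                raise ParseError(path, lineno, f"malformed line: {exc}")

    if context_filter:
        raw = [r for r in raw if r[5] == context_filter]
    if raw != sorted(raw, key=lambda r: (r[0], r[1])):
        warnings.warn(f"{path}: input not sorted; sorting")
        raw.sort(key=lambda r: (r[0], r[1]))

    if not merge_strands:
        return [CpGSiteRecord(c, p, m, u, ctx)
                for c, p, s, m, u, ctx in raw]

    merged: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for chrom, pos0, strand, meth, unmeth, ctx in raw:
        fwd = pos0 if strand == "+" else pos0 - 1
        key = (chrom, fwd)
        if key not in merged:
            merged[key] = [0, 0]
            order.append(key)
        merged[key][0] += meth
        merged[key][1] += unmeth
    order.sort()
    return [CpGSiteRecord(c, p, merged[(c, p)][0], merged[(c, p)][1], "CG")
            for c, p in order]


def read_noncg_report(path: PathLike) -> list[tuple[str, int, str, int, int, str]]:
    """Per-strand CHG/CHH rows of a cytosine report (no merging)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) >= 6 and parts[5] in ("CHG", "CHH"):
                out.append((parts[0], int(parts[1]) - 1, parts[2],
                            int(parts[3]), int(parts[4]), parts[5]))
    return out


def read_gene_models(path: PathLike,
                     tss_override: Optional[dict[str, int]] = None
                     ) -> list[GeneModel]:
    """Read gene models from GTF/GFF3 or BED12.

    The TSS per transcript follows the strand rule (tx_start for '+',
    tx_end - 1 for '-'); a ``tss_override`` mapping of gene_id -> position
    replaces the TSS of every transcript of that gene (standing in for
    RNA-seq fine-mapped starts).
    """
    path = str(path)
    if path.endswith((".bed", ".bed12", ".bed.gz")):
        genes = _read_bed12_genes(path)
    else:
        genes = _read_gtf_genes(path)
    if tss_override:
        genes = [_apply_tss_override(g, tss_override) for g in genes]
    return genes


def _apply_tss_override(g: GeneModel, override: dict[str, int]) -> GeneModel:
    if g.gene_id not in override:
        return g
    tss = override[g.gene_id]
    txs = tuple(Transcript(t.tx_id, tss, t.tx_start, t.tx_end)
                for t in g.transcripts)
    return GeneModel(g.gene_id, g.chrom, g.strand, g.gene_start, g.gene_end,
                     txs)


def _read_gtf_genes(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True, verbose=False,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes = []
    gene_ids = set()
    for gene in db.features_of_type(("gene",)):
        gene_ids.add(gene.id)
        txs = []
        for tx in db.children(gene, featuretype=("transcript", "mRNA")):
            tss = tx.start - 1 if gene.strand != "-" else tx.end - 1
            txs.append(Transcript(tx.id, tss, tx.start - 1, tx.end))
        if not txs:
            tss = gene.start - 1 if gene.strand != "-" else gene.end - 1
            txs = [Transcript(gene.id + ".t1", tss, gene.start - 1, gene.end)]
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand or ".",
                               gene.start - 1, gene.end, tuple(txs)))
    n_orphans = sum(1 for tx in db.features_of_type(("transcript", "mRNA"))
                    if not any(p.id in gene_ids
                               for p in db.parents(tx, featuretype="gene")))
    if n_orphans:
        log.warning("%s: skipped %d transcripts without a parent gene",
                    path, n_orphans)
    genes.sort(key=lambda g: (g.chrom, g.gene_start))
    return genes


def _read_bed12_genes(path: str) -> list[GeneModel]:
    genes: dict[str, list[Transcript]] = {}
    meta: dict[str, tuple[str, str]] = {}
    spans: dict[str, list[int]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                if line.strip():
                    raise ParseError(path, lineno, "BED12 needs >= 6 columns")
                continue
            chrom, start, end, name, _, strand = parts[:6]
            start, end = int(start), int(end)
            gene_id = name.rsplit(".", 1)[0] if "." in name else name
            tss = start if strand != "-" else end - 1
            genes.setdefault(gene_id, []).append(
                Transcript(name, tss, start, end))
            meta[gene_id] = (chrom, strand)
            spans.setdefault(gene_id, []).extend((start, end))
    out = []
    for gid, txs in genes.items():
        chrom, strand = meta[gid]
        out.append(GeneModel(gid, chrom, strand, min(spans[gid]),
                             max(spans[gid]), tuple(txs)))
    out.sort(key=lambda g: (g.chrom, g.gene_start))
    return out


def read_repeatmasker(path: PathLike) -> list[RepeatElement]:
    """Read RepeatMasker .out (or a BED-with-subclass table).

    For '-' strand .out rows the parenthesised "left" field is converted
    so that consensus_start < consensus_end and consensus_length is the
    full consensus size.  Elements lacking consensus fields are kept with
    integrity undefined.
    """
    # dialect sniff: BED rows are tab-separated with integer columns 2-3
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    try:
                        int(parts[1]), int(parts[2])
                        return _read_repeat_bed(path)
                    except ValueError:
                        pass
                break
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header lines of the .out layout
            if len(parts) < 14:
                raise ParseError(path, lineno, "short RepeatMasker row")
            div = float(parts[1])
            chrom = parts[4]
            start, end = int(parts[5]) - 1, int(parts[6])
            strand = "+" if parts[8] == "+" else "-"
            name, subclass = parts[9], parts[10]

            def val(s: str) -> int:
                return int(s.strip("()"))

            if strand == "+":
                c_start, c_end, left = val(parts[11]), val(parts[12]), val(parts[13])
                c_len = c_end + left
            else:
                left, c_end, c_start = val(parts[11]), val(parts[12]), val(parts[13])
                c_len = c_end + left
            out.append(RepeatElement(chrom, start, end, strand, name,
                                     subclass, div, c_start - 1, c_end, c_len))
    return out


def _read_repeat_bed(path: PathLike) -> list[RepeatElement]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                continue
            chrom, start, end, name, _, strand = parts[:6]
            subclass = parts[6] if len(parts) > 6 else "Unknown"
            div = float(parts[7]) if len(parts) > 7 else float("nan")
            cs = int(parts[8]) if len(parts) > 8 else None
            ce = int(parts[9]) if len(parts) > 9 else None
            cl = int(parts[10]) if len(parts) > 10 else None
            out.append(RepeatElement(chrom, int(start), int(end), strand,
                                     name, subclass, div, cs, ce, cl))
    return out


def read_het_snps(path: PathLike) -> list[HetSNP]:
    """Read heterozygous SNVs from VCF or a 4-column table.

    Only biallelic single-nucleotide variants are kept; indel and
    multi-allelic rows are skipped with a counter.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf_snps(path)
    out = []
    with _open_text(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            chrom, pos, ref, alt = parts[:4]
            if len(ref) != 1 or len(alt) != 1:
                continue
            is_het = parts[4].lower() in ("1", "true", "het") \
                if len(parts) > 4 else True
            out.append(HetSNP(chrom, int(pos), ref, alt, is_het))
    return out


def _read_vcf_snps(path: str) -> list[HetSNP]:
    import pysam

    out = []
    n_skipped = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            is_het = False
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt and None not in gt and len(set(gt)) > 1:
                    is_het = True
            out.append(HetSNP(rec.chrom, rec.pos - 1, ref, alt, is_het))
    if n_skipped:
        log.info("%s: skipped %d indel/multiallelic records", path, n_skipped)
    return out


def write_bed(intervals: Sequence, path: PathLike,
              score_field: Optional[str] = None,
              extra_fields: Sequence[str] = ()) -> None:
    """Write interval-likes as sorted BED (plus optional extra columns)."""
    with open(path, "w") as fh:
        for iv in sort_intervals(list(intervals)):
            name = getattr(iv, "name", None) or getattr(iv, "state_label", ".")
            score = getattr(iv, score_field) if score_field else 0
            strand = getattr(iv, "strand", ".")
            row = [iv.chrom, iv.start, iv.end, name, score, strand]
            for f in extra_fields:
                row.append(getattr(iv, f))
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or parts[0].startswith(("#", "track")):
                continue
            name = parts[3] if len(parts) > 3 else None
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                       name, strand))
    return out


def read_expression_table(path: PathLike) -> pd.DataFrame:
    """Gene x sample TPM matrix (tab-separated, header of sample ids)."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if (tab.values < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return tab


def write_expression_table(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id",
                float_format="%.6g")


def read_sample_sheet(path: PathLike) -> SampleSheet:
    samples = []
    with _open_text(path) as fh:
        for row in csv.DictReader(fh):
            samples.append(SampleInfo(
                sample_id=row["sample_id"], tissue=row["tissue"],
                cluster_group=row["cluster_group"],
                blood_related=row.get("blood_related", "").lower()
                in ("1", "true", "yes"),
                methylome_path=row.get("methylome_path") or None,
                expression_path=row.get("expression_path") or None))
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "tissue", "cluster_group", "blood_related",
                    "methylome_path", "expression_path"])
        for s in sheet:
            w.writerow([s.sample_id, s.tissue, s.cluster_group,
                        str(s.blood_related).lower(),
                        s.methylome_path or "", s.expression_path or ""])


def write_cytosine_report(records: Iterable[CpGSiteRecord],
                          path: PathLike) -> None:
    """Write strand-merged CpGs back out in cytosine-report layout.

    Each merged record becomes a single '+' strand row at the C of the
    forward strand (1-based), which round-trips through read_cpg_report.
    """
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(f"{r.chrom}\t{r.pos + 1}\t+\t{r.meth_count}\t"
                     f"{r.unmeth_count}\t{r.context}\tCGG\n")


def write_segments(segments: Sequence, path: PathLike,
                   header: Optional[dict] = None) -> None:
    """BED6 + n_sites, mean_level, score columns, with a parameter header."""
    with open(path, "w") as fh:
        if header:
            for k, v in header.items():
                fh.write(f"#{k}={v}\n")
        for s in sort_intervals(list(segments)):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state_label}\t"
                     f"{s.score:.4f}\t.\t{s.n_sites}\t{s.mean_level:.4f}"
                     + (f"\t{','.join(s.flags)}" if s.flags else "\t.")
                     + "\n")


def read_segments(path: PathLike) -> list:
    from .types import Segment

    out = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            flags = tuple(parts[8].split(",")) if len(parts) > 8 \
                and parts[8] != "." else ()
            out.append(Segment(parts[0], int(parts[1]), int(parts[2]),
                               int(parts[6]), float(parts[7]),
                               float(parts[4]), parts[3], flags))
    return out


def read_tss_override(path: PathLike) -> dict[str, int]:
    out = {}
    with _open_text(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 2 and not parts[0].startswith("#"):
                out[parts[0]] = int(parts[1])
    return out
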