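#!/usr/bin/env python
"""Methylome segmentation: HMRs, PMDs/HMDs and multi-tissue drops.

Calls per-CpG HMRs for a panel of samples, 10-kb-window PMDs for every
sample, derives the methylation drops shared by non-blood somatic
tissues, and summarises TSS-HMR vs non-TSS-HMR size distributions.
Segment BED files and the drop table land under results/segments/.
"""
import argparse
from pathlib import Path

from bovmeth import io as bio
from bovmeth.segmentation import (call_hmrs, call_pmds, detect_drops,
                                  pmd_genome_fraction)
from bovmeth.simulate import SimConfig, generate
from bovmeth.tss_hmr import hmr_size_distribution

HMR_PANEL = ("blood", "sperm", "liver_1", "placenta")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results/segments"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ds = generate(SimConfig(seed=args.seed))
    lengths = ds.annotation.chrom_lengths

    hmr_sets = {}
    for sid in HMR_PANEL:
        segs, fit = call_hmrs(ds.methylomes[sid])
        hmr_sets[sid] = segs
        bio.write_segments(segs, args.out / f"{sid}.hmr.bed", header={
            "caller": "hmr", "sample": sid,
            "state_means": ",".join(f"{e.mean:.3f}"
                                    for e in fit.model.emissions)})
        bp = sum(len(s) for s in segs)
        print(f"{sid}: {len(segs)} HMRs covering {bp / 1e6:.2f} Mb")

    pmd_sets = {}
    for sid, m in ds.methylomes.items():
        segs, _ = call_pmds(m, chrom_lengths=lengths)
        pmd_sets[sid] = segs
        bio.write_segments(segs, args.out / f"{sid}.pmd.bed",
                           header={"caller": "pmd", "sample": sid})
    for sid in ("placenta", "blood", "liver_1"):
        print(f"{sid}: PMDs cover "
              f"{pmd_genome_fraction(pmd_sets[sid], lengths):.1%} "
              f"of the genome")

    drops = detect_drops(pmd_sets, ds.sheet)
    bio.write_segments(drops, args.out / "drops.bed",
                       header={"caller": "drops"})
    n_peri = sum("pericentromeric" in d.flags for d in drops)
    print(f"{len(drops)} methylation drops "
          f"({n_peri} pericentromeric, first 3 Mb rule):")
    for d in drops:
        print(f"  {d.chrom}:{d.start}-{d.end} "
              f"({(d.end - d.start) / 1e6:.2f} Mb) {','.join(d.flags) or '-'}")

    sizes = hmr_size_distribution(hmr_sets, ds.annotation.genes)
    sizes.to_csv(args.out / "hmr_size_modes.tsv", sep="\t", index=False,
                 float_format="%.0f")
    print("modal HMR sizes (bp):")
    print(sizes.to_string(index=False))


if __name__ == "__main__":
    main()
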