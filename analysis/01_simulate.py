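#!/usr/bin/env python
"""Generate the default multi-tissue WGBS study and write it to disk.

Produces the 3 x 5 Mb, 12-sample synthetic study (sperm, placenta, blood
and six somatic tissues at ~16x coverage) together with its ground-truth
files: per-sample cytosine reports, gene models, repeats, het SNPs,
expression and the planted HMR/PMD/drop/island intervals.  Every later
analysis script regenerates the same dataset in memory from the seed, so
these files are for inspection and for the command-line pipeline.
"""
import argparse
from pathlib import Path

from bovmeth.core import global_levels
from bovmeth.simulate import SimConfig, generate, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    ds = generate(SimConfig(seed=args.seed))
    write_dataset(ds, args.out)

    print(f"wrote dataset for seed {args.seed} to {args.out}")
    print(f"  {len(ds.sheet)} samples, "
          f"{sum(len(p) for p in ds.annotation.cpg_positions.values())} CpGs, "
          f"{len(ds.annotation.genes)} genes, "
          f"{len(ds.annotation.repeats)} repeats")
    for sid in ("sperm", "placenta", "blood", "liver_1"):
        cg, _ = global_levels(ds.methylomes[sid])
        print(f"  global CG level {sid}: {cg:.1%}")


if __name__ == "__main__":
    main()
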