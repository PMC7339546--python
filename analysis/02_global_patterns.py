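#!/usr/bin/env python
"""Global methylome comparison: clustering, PCA, conserved/variable regions.

Builds 500-bp window levels per sample, clusters the samples (average
linkage on 1 - Pearson), runs PCA, and classifies 10-kb windows into the
1% lowest-SD (conserved) and highest-SD (variable) tails, splitting the
variable tail by the sperm level.  Writes the correlation matrix, PCA
scores and region calls under results/.
"""
import argparse
from pathlib import Path

import pandas as pd
from scipy.cluster.hierarchy import fcluster

from bovmeth.core import (build_sample_matrix, conserved_variable_regions,
                          hierarchical_cluster, make_window_track,
                          pairwise_correlation, pca)
from bovmeth.simulate import SimConfig, generate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ds = generate(SimConfig(seed=args.seed))
    lengths = ds.annotation.chrom_lengths

    tracks = [make_window_track(ds.methylomes[s.sample_id], 500, min_cov=5,
                                chrom_lengths=lengths) for s in ds.sheet]
    mat = build_sample_matrix(tracks)
    corr = pairwise_correlation(mat)
    corr.to_csv(args.out / "sample_correlations.tsv", sep="\t",
                float_format="%.4f")

    Z = hierarchical_cluster(mat)
    labels = fcluster(Z, t=3, criterion="maxclust")
    groups = {}
    for sid, lab in zip(mat.columns, labels):
        groups.setdefault(lab, []).append(sid)
    print("three top-level clusters from 500-bp window levels:")
    for lab, members in sorted(groups.items()):
        print(f"  cluster {lab}: {', '.join(members)}")

    scores, frac = pca(mat, n_components=3)
    scores.to_csv(args.out / "pca_scores.tsv", sep="\t",
                  float_format="%.4f")
    print("PCA variance fractions:",
          ", ".join(f"PC{i + 1} {f:.1%}" for i, f in enumerate(frac)))

    tracks10 = [make_window_track(ds.methylomes[s.sample_id], 10_000,
                                  chrom_lengths=lengths) for s in ds.sheet]
    mat10 = build_sample_matrix(tracks10)
    sperm = [s.sample_id for s in ds.sheet if s.cluster_group == "sperm"]
    calls = conserved_variable_regions(mat10, sperm)
    tab = pd.DataFrame([(c.chrom, c.start, c.end, c.klass,
                         c.sd_across_samples, c.mean_level)
                        for c in calls if c.klass != "background"],
                       columns=["chrom", "start", "end", "class", "sd",
                                "mean"])
    tab.to_csv(args.out / "conserved_variable_regions.tsv", sep="\t",
               index=False, float_format="%.4f")
    print("non-background 10-kb windows by class:")
    print(tab["class"].value_counts().to_string())


if __name__ == "__main__":
    main()
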