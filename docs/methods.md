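# Methods

`bovmeth` analyses multi-tissue whole-genome bisulfite sequencing (WGBS)
methylomes: it segments per-CpG methylation into hypomethylated regions
(HMRs), partially methylated domains (PMDs) and multi-tissue
"methylation drops", calls differentially methylated cytosines and
regions (DMCs/DMRs), predicts and experimentally validates CpG islands,
classifies genes by how their transcription start sites (TSSs) relate to
HMRs, and relates promoter hypomethylation to gene expression and to
repeat-element biology. A synthetic-data generator reproduces the
statistical structure of such a study with known ground truth; every
analysis is exercised against it.

## Data model

A methylome is a per-sample, per-chromosome ordered array of
strand-merged CpG read counts (methylated, unmethylated). CpG
methylation is symmetric, so counts from the reverse-strand C at
position p+1 fold into the forward-strand record at p; non-CG cytosines
stay per-strand. All internal coordinates are 0-based, half-open;
1-based conventions (Bismark cytosine reports, GTF, VCF) are converted
only at the I/O boundary. Every summary level is the *weighted*
methylation level — summed methylated reads over summed total reads —
which is robust to uneven coverage.

Heterozygous SNPs are masked before analysis: bisulfite conversion
cannot distinguish an unmethylated C from a C>T variant, so any CpG
whose C or G coincides with a het SNP is removed.

## Two-state beta-binomial HMM segmentation

HMRs and PMDs come from a shared two-state hidden Markov model over
(methylated, total) counts. Each state emits beta-binomial counts; the
beta component absorbs the extra-binomial dispersion of bisulfite data.
State 0 is the low state (HMR ~0.1, PMD ~0.5), state 1 the methylated
background (~0.8); the ordering is enforced after every update.

* **Fitting.** Baum–Welch with a method-of-moments M-step: each state's
  mean and intra-class correlation are estimated from posterior-weighted
  per-site fractions (the moment identity
  Var(p̂) = μ(1−μ)[1/n + (1−1/n)ρ] solved for ρ). A moments update is
  not guaranteed to increase the likelihood, so an update that would
  decrease it by more than 1e-8 is rejected and the fit stops at the
  previous parameters; the recorded log-likelihood trace is
  non-decreasing by construction. Convergence: relative log-likelihood
  change < 1e-4, at most 100 iterations. Defaults: initial means 0.1/0.8
  (HMR) or 0.5/0.8 (PMD), intra-class correlation 0.1, self-transition
  0.99, uniform initial state. The fit is deterministic (single start);
  the `seed` parameter is reserved for randomized restarts.
* **Forward–backward.** Scaled (linear-space) recursions with per-site
  emission rescaling; the rescaling cancels in the posteriors and is
  added back into the log-likelihood. Verified against exhaustive path
  enumeration on short chains to 1e-9.
* **HMR calling** (per-CpG). Sites with zero coverage are dropped;
  chains break at CpG deserts (> 5,000 bp between covered CpGs), which
  prevents decoding across unobserved spans. Hypo-state runs with >= 5
  sites and a positive summed posterior log-odds become segments;
  boundaries extend from the first/last CpG by half the gap to the
  flanking CpG, capped at half the desert gap.
* **PMD calling** (10-kb windows). Windows with < 10 total reads are
  missing and break the chain; fitting refuses genomes with < 50
  informative windows. Runs separated by <= 1 window merge; merged runs
  shorter than 100 kb are discarded — PMDs are domains of at least
  ~100 kb by definition, and this filter is what removes island-driven
  single-window artefacts and the generator's sub-100-kb decoys.
  Highly methylated domains (HMDs) are the complementary background
  runs, reported on request (relevant for placenta).
* **Drop detection.** A drop is a run of genome positions inside PMDs
  of >= 80% of the non-blood somatic samples and of zero blood-related
  samples, merged across gaps <= 100 kb. Calls outside 0.3–1.8 Mb are
  kept but flagged `out_of_range`; a call starting within the first
  3 Mb of its chromosome is flagged `pericentromeric` (bovine autosomes
  are acrocentric). The support threshold and merge gap are this
  package's choices; the blood-exclusion rule is the defining property.

## Differential methylation

Per-site tests are Fisher's exact test on the 2x2 table
[[m_a, u_a], [m_b, u_b]] (two-sided, hypergeometric enumeration with an
LRU cache keyed on the table), with Benjamini–Hochberg FDR across all
tested sites. DMCs require >= 10x depth in both samples,
|difference| > 0.3 and q < 0.05. DMRs are 500-bp windows tested on
pooled counts (Fisher + BH across windows) with the same thresholds,
and additionally need >= 5 DMCs whose sign matches the window's
direction. Direction is A − B with A the first-named sample.

Tissue-specific DMRs rank windows by how often they are a
same-direction DMR across the focal tissue's pairwise comparisons
(ties by |mean difference| then coordinate), keep the top fraction
(default 0.1%, configurable within 0.01–0.3%), merge overlapping
selections, and require differential status against every other tissue
group. This ranking is intentionally stringent: at desk scale it
returns a handful of regions.

Element-level methylation applies the size-dependent detection rule:
elements with more than 50 CpGs need >= 10% of them detected at >= 5x;
smaller elements need >= 5 detected CpGs. Promoters are TSS ± 1,000 bp.

## CpG islands and experimental validation

Islands are predicted from genomic CpG positions alone (not coverage).
Per chromosome, the distance threshold tau is the median
consecutive-CpG gap; clusters are maximal runs of gaps <= tau with at
least 5 CpGs, spanning first-CpG start to last-CpG end (single-base
resolution). Significance uses the run length: under uniform CpG
placement a maximal run of sub-threshold gaps has geometric length, so
conditional on reaching `min_cpgs` sites,
p = q0^(n_cpgs − min_cpgs) with q0 the empirical fraction of gaps
<= tau. This p-value is uniform under the null by construction and
stays valid under the BH correction across candidates; a
span-conditional binomial is biased here because maximal runs are
selected for density. BH keeps clusters at q < 0.05.

Validation: a sample is evaluable for an island when >= 5 CpGs exceed
5x coverage inside it; the island is an eCGI if its weighted level is
below 30% in at least one evaluable sample, else neCGI. Placenta-group
samples are excluded from the panel (genome-wide hypomethylation would
validate everything). C/T heterozygote rates (counting C/T and G/A
pairs) per kb compare eCGIs against methylated regions — methyl-C
deaminates to T, so methylated islands accumulate C/T hets.

## TSS-HMR gene classes

Each gene receives exactly one of five classes, evaluated across all
samples with precedence TOTAL_IN_HMR > T3 > T2 > T1 > NO_TSS_HMR:
whole gene inside one HMR in >= 1 sample; >= 2 transcripts with TSSs in
non-identical HMRs (within one sample, or across samples in
non-overlapping HMRs — configurable to within-sample only); an
opposite-strand partner's TSS sharing the HMR (twin genes, both members
T2); any TSS in an HMR; none. The precedence forces exclusivity.
Classification is verified against an independent naive quadratic
re-implementation.

Derived analyses: core (intersection of a gene's TSS-HMRs across
samples) and strand-oriented flanks from the union; signed
boundary/center offsets from the TSS; across-sample correlation of CpG
pairs versus distance, per region class; gene x sample TSS-in-HMR
presence with tissue-specific calls (present in all samples of exactly
one tissue); DMR-vs-expression Spearman correlation of log2(TPM+1) in
strand-oriented 500-bp bins from −2 kb to +10 kb around the assigned
gene's TSS, stratified by CpG density at the median; twin-gene
co-expression (Pearson on log2(TPM+1)) against uniformly random pairs
and distance-matched (±10%) opposite-strand control pairs that are not
themselves twin pairs, compared by one-sided Mann–Whitney; and
cross-species consistency of twin pairs through an ortholog map
(mutually nearest opposite-strand neighbours, optionally sharing an HMR
in the other species).

## Repeat analyses

Per-element methylation uses the element detection rule above. An
element is hypomethylated at level <= 0.3 (mirroring the eCGI rule).
TSS-proximity enrichment compares the fraction of hypomethylated
elements with midpoints within ±2 kb of a TSS against the same fraction
for all elements, with a label-shuffling p-value. Full-length elements
(integrity = consensus span / consensus length > 0.8) overlapping
TSS-HMRs are counted per subclass; observed/expected ratios assume
bp-proportional placement (expected = genome-wide count x TSS-HMR bp /
genome bp), flagging subclasses with expected < 1. Age trends are
Spearman correlations of divergence (a clock) against level per
subclass per sample, requiring >= 20 elements. Nested insertions are
triples where two fragments of one older element (same name and strand,
sequential consensus coordinates within 30 bp) flank a younger element
of a different subclass within 50 bp on each side.

## The synthetic study

The generator emulates the structure of a multi-tissue WGBS + RNA-seq
study at desk scale. Defaults (all configurable):

* **Genome.** 3 chromosomes around 5 Mb (length factors 1.0/1.3/0.9)
  with distinct gene densities (1.0/0.78/0.95) so per-chromosome count
  statistics are informative and gene content is not a proxy for
  length. Background CpGs are Poisson at 0.008/bp; islands 0.08/bp over
  800 bp; repeat bodies 0.02/bp (young SINEs 0.05/bp — young elements
  retain their CpGs, which also means a distance-based island predictor
  legitimately reports them as dense clusters).
* **Samples.** 12 methylomes: sperm, placenta, blood (blood-related
  flag) and nine non-blood somatic samples over six tissues (liver,
  kidney, heart x2; muscle, brain, rumen x1). Median coverage 16x
  (Poisson); counts are Binomial(coverage, pi) with per-sample beta
  jitter at concentration 50 (settable to 0 for pure-binomial oracle
  work). Replicates share the tissue surface and differ only by
  sampling noise.
* **Features.** The methylated background sits at 0.8. Planted HMRs:
  promoter HMRs ~2,000 bp centred ~250 bp downstream of the TSS;
  distal HMRs ~500 bp (widened to ~5,000 bp in placenta); free-standing
  hypomethylated islands; sperm also hypomethylates flagged young
  SINEs and carries sixteen 10-kb sperm-only hypo windows per
  chromosome (its distinct germline methylome, and the source of
  sperm-hypo variable regions). Gene classes are planted directly:
  head-to-head twin pairs sharing one promoter HMR, control pairs with
  the same geometry but methylated promoters, two-promoter genes with
  15-kb-separated TSSs, short genes inside 6-kb HMRs, genes with no
  promoter HMR, tissue-specific promoter HMRs (liver/kidney/heart), and
  graded-promoter genes whose level runs 0.1–0.8 across the somatic
  tissues (blood and sperm pinned at background) — gradual tissue DMRs,
  without which all-or-nothing promoters cap the per-DMR Spearman
  correlation near −0.5 through rank ties.
* **Domains.** Tissue PMD blocks of 120–260 kb at level 0.5; placenta
  tiles 40% of every Mb as PMD; four drops of 0.3–0.6 Mb present in all
  nine non-blood somatic samples (three start inside the first 3 Mb);
  one "universal" 0.5-Mb partial region present in *every* sample
  including blood (which must therefore never be called a drop); and
  three sub-100-kb decoy blocks that the PMD length filter must remove.
  Drop lengths sit at the short end of the 0.3–1.8 Mb class so that the
  desk genome is not swamped by intermediate-level sequence.
* **Expression.** log2(TPM+1) = gene baseline + 6 x (0.4 − promoter
  truth level) + twin-pair shared factor (sd 1.5) + noise (sd 0.5).
  Setting the coupling to 0 also silences the twin factor — the null
  mode in which expression is independent of everything planted.
* **SNPs.** Baseline het SNVs at 5e-4/bp; C/T (G/A) hets at CpGs with
  elevated probability (x5) where the somatic truth methylation is
  >= 0.5, depleting C/T hets inside hypomethylated islands.

Everything is deterministic given the seed; the same configuration
writes byte-identical files. The generator emits exactly the formats
the readers consume (cytosine reports, GTF, RepeatMasker .out, VCF,
TPM table, sample-sheet CSV) plus truth BED/JSON.

**What the generator does not model.** Read-level artefacts (mapping
bias, conversion failure), sequence composition beyond CpG placement,
chromatin context, cell-type heterogeneity within a tissue, and
spatially continuous methylation autocorrelation outside planted
features. Feature placement is slot-based rather than free, so
inter-feature spacing is more regular than in real genomes. Passing
recovery tests here demonstrates that the algorithms implement their
definitions correctly at realistic coverage and dispersion — not that
they would meet the same numbers on a 2.7-Gb cattle assembly.

## Evaluation choices

* HMR recovery is scored on the blood-like sample, which carries the
  planted hypomethylated set but no PMDs/drops; in samples with
  intermediate-level domains the two-state HMR model and the planted
  HMR truth are no longer the same question.
* The planted-cluster oracle for island prediction measures recall on
  the planted islands and precision against all planted CpG-enriched
  features (islands and repeat bodies).
* Null calibration of the differential tests uses pure-binomial
  sampling from one shared truth; per-sample beta jitter is biological
  signal, not sampling noise, and would rightly inflate rejections.
* The exact Fisher power oracle enumerates the joint table distribution
  at the stated margins and finds the BH-effective threshold as the
  fixed point t = alpha x G(t) of the p-value CDF.

## Numerical notes and degenerate inputs

Beta-binomial parameters are clamped to means in [1e-4, 1−1e-4] and
intra-class correlations in [1e-6, 0.5]. A fit whose low state holds
< 0.5% of posterior mass is flagged degenerate (single-state data).
Empty SNP sets, empty chromosomes, windows without CpGs, constant
expression rows and constant methylation columns are all defined
no-ops, exclusions or explicit errors — see the operation docstrings.
Ties in SD ranking (conserved/variable tails) and in DMR ranking break
by input order and coordinate respectively, keeping outputs
deterministic. Sample-level PCA centres each window across samples and
fixes signs by making the largest-|score| sample positive.

## Known limitations

* The drop detector's support threshold (0.8) and merge gap (100 kb)
  are conventions; the boundary between a "drop" and a recurrent PMD is
  soft.
* Two-state segmentation of a genuinely three-level methylome (e.g. a
  placenta with abundant hypo, partial and high sequence) fits the two
  dominant levels; HMD/PMD output on such samples should be read
  per-sample, not compared across samples with different mixtures.
* DMC/DMR counts depend on the shared-coverage footprint of each pair;
  no normalisation for common data amount is applied.
* Cross-species consistency consumes an ortholog table; it does not
  infer orthology.
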