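# Methods

This note documents the statistical procedures implemented in `coregbuf`, the
synthetic-study model used to validate them, the numerical choices that matter,
and what the tests do and do not establish about real data.

## Preprocessing

Expression tables are gene × sample matrices of log2 abundance ratios against a
common reference sample (mRNA: log2 RPKM ratios; protein: log2 SILAC
light/heavy ratios; ribosome occupancy as a third optional layer). Three steps
produce the analysis-ready dataset:

1. **Detection filter.** mRNA keeps genes observed in ≥ `min_detect` samples
   (default 30); protein uses the strict variant (genes observed in
   `min_detect` samples *or fewer* are removed). The two conventions are
   deliberate and flag-controlled.
2. **Layer matching.** Only genes with an unambiguous 1:1 mapping between the
   two id spaces survive; ambiguity is judged on the full map, so a protein
   targeted by two transcripts disqualifies all its links. Samples are
   intersected and ordered identically in both matrices.
3. **Sample centering.** Each sample's median log2 ratio is set to zero.
   Without this, technical sample-level offsets (e.g. uneven mixing of
   light/heavy material) inflate every pairwise correlation. Centering is
   idempotent and leaves the missing-value pattern untouched.

Coordinates are 0-based half-open everywhere inside the package; GFF3 input is
converted on read. The TSS is the outermost transcript start: `body_start` for
+ genes, `body_end` for − genes.

## Co-regulation calls

Pairwise Pearson correlations are computed over pairwise-complete samples; a
pair with fewer than `min_overlap` (default 30) paired observations, or a
zero-variance gene, receives *no call* rather than a negative call. The
two-sided p-value uses the t-transform with n−2 degrees of freedom; a
permutation p-value is available for small n. Benjamini–Hochberg adjustment is
applied within the pair list of one named analysis, never pooled across
analyses — the thresholds (PCC > 0.5, adjusted p < 0.001) are calibrated to a
specific family of tests. Anti-regulation (PCC < −0.5 at the same significance)
is recorded separately and never counts as co-regulation.

**Divergent-pair geometry.** A pair is head-to-head (bidirectional-promoter
candidate) when the genes lie on opposite strands and transcription points
away from the shared intergenic region: with the − strand member's TSS at *m*
and the + strand member's at *p*, divergent ⇔ *m* < *p*:

```
      <─────┤m         p├─────>
    (− gene)   promoter   (+ gene)
```

Bidirectional requires divergence and TSS distance < 1,000 bp (strict);
closeby is < 50,000 bp (strict) without the orientation requirement.
Overlapping gene bodies are classified by TSS distance alone.

**Distance curves.** The PCC-vs-distance trend uses a local weighted mean with
a tricube kernel whose bandwidth covers a fixed fraction of the points
(default 0.3). A weighted mean — unlike local linear fits — cannot leave the
range of the PCC values in its window, which keeps the curve interpretable as
a running average. The smoother is a pluggable contract, not a model claim.

**Maps.** Chromosome co-regulation maps are full pairwise PCC matrices over
genes in TSS order (rectangular for interchromosomal maps). Map-vs-Hi-C
correlation vectorises the strict upper triangle (diagonal excluded) and uses
pairwise-complete Pearson correlation.

## Hi-C handling

Contact maps arrive as normalized binned triplets (balancing happens
upstream; 10 kb intra / 50 kb inter are the module defaults for external
data). The contact frequency of a gene pair is the **median** over the pixel
block formed by all bins overlapping ± 40 kb windows around the two TSSs
(partially overlapping bins included). Absent sparse entries are zeros —
the convention for normalized Hi-C — while stored NaNs (failed balancing) are
excluded from the median; a block with no stored finite entry is flagged
zero-coverage rather than silently zero. Subcompartment labels are assigned by
the half-open interval containing the TSS.

## Regulation groups

k-means (Lloyd, squared Euclidean, `init="random"`, best of 5 starts, 300
iterations, fixed random state) clusters genes by expression profile; k is
chosen as the smallest value whose clusters explain ≥ 50% of total variance
(k = 4 mRNA, k = 3 protein in the reference configuration). Missing values
default to imputation at 0 — the log2 ratio of an unchanged gene — because
dropping incomplete genes would bias clusters against the protein layer's
missingness; a flag drops them instead. Cluster labels are canonicalised by
decreasing size so "T1" is reproducibly the largest transcriptome group.
Cluster feature enrichment is log2(cluster median / overall median) for
numeric features (pseudocount guard for non-positive medians) and
observed-vs-expected percentages for categorical ones.

## Noise and clustering degrees

Expression noise is CV = sd/mean of (log2 ratio + 10) per gene over non-missing
samples, with the sample (n−1) standard deviation; the offset keeps the mean
far from zero where a CV is meaningless. Three per-gene density metrics:

- `degree_seq`: mean bp distance to the 3 nearest same-chromosome dataset
  genes by TSS — **lower = denser**;
- `degree_intra3d`: mean contact of the 3 strongest same-chromosome partners
  at least 500 kb away in sequence (to capture folding, not adjacency) —
  **higher = denser**;
- `degree_inter3d`: the same over partners on other chromosomes.

The inverted sign convention on the 3D metrics is deliberate: contacts measure
closeness, and the extreme-group analyses consume ranks, for which any
monotone transform is equivalent. Every consumer in the package documents
which tail is "dense". Extreme-group comparisons take the top and bottom 5%
of genes by a degree metric (ties broken by gene id) and compare noise
distributions with a two-sample two-sided Kolmogorov–Smirnov test.

## Epigenetic similarity and mechanism separation

Gene-body signals for the similarity feature set (histone marks + CpG
methylation; GC content, gene length and replication timing are excluded) are
standardised to z-scores; their covariance is estimated from all genes,
ridge-regularised by `reg × trace/p` on the diagonal (default reg = 1e-6), and
genes are mapped through the inverse Cholesky factor. Euclidean distance in
that whitened space is the Mahalanobis distance; it is invariant under
invertible linear mixing of the features, which is the point — strongly
covarying marks are not double-counted.

For the mechanism analysis, intrachromosomal pairs (TSSs < 2 Mb apart by
default) are assigned to per-axis quantile bins of similarity (= −distance, so
high bins are similar) and Hi-C contact (3 × 3 by default). The per-bin
percentage of co-regulated pairs at each layer separates two routes to
non-functional co-regulation: high-similarity/low-contact pairs respond to
shared chromatin factors (fluctuation), low-similarity/high-contact pairs to
regulatory interference between spatial neighbours.

Heterochromatin profiles merge the five inactive chromatin-state labels
("Heterochromatin", "Repressed", "Repetitive", "Poised_Promoter", "Insulator";
configurable) and scan 100-bp windows from −50 kb to +10 kb around the TSS,
strand-oriented, reporting the fraction of genes whose window overlaps the
merged state. A gene counts as "co-regulated with its neighbours" when it is
mRNA co-regulated with at least one gene < 50 kb away.

## Post-transcriptional buffering

Pairs called at both layers are categorised sustained / buffered / neither.
Five predicates probe shared post-transcriptional regimes: half-life ratio
(more/less stable) < 1.5 using per-gene mean half-life across replicates;
≥ 1 shared targeting miRNA; ribosome-occupancy correlation with the same
PCC/BH thresholds (the ribosome layer reuses the co-regulation machinery
verbatim); ≥ 1 non-exponentially-degraded (NED) protein in the pair; protein
length ratio < 1.5. Pairs lacking an annotation drop out of that predicate's
denominator. Enrichment in sustained vs buffered pairs uses Fisher's exact
test (one-sided by default, per-test flag); the reported odds ratio is
Haldane–Anscombe corrected when a cell is zero, and degenerate margins yield
p = 1 with a warning. Generic pair resources plug in as annotation tables:
association scores (functional-link threshold 0.7) and paralog pairs filtered
at ≥ 25% sequence identity.

## The synthetic study

The generator builds a study in which every downstream claim has planted
ground truth. Default scale: 4 chromosomes × 25 Mb × 500 genes, 60 samples —
pair counts comparable to a per-chromosome analysis of a real cell-line panel
at desk scale. Mechanisms, per sample *s*:

- **Domains.** Chromosomes are tiled with chromatin domains (mean 400 kb).
  Each domain *d* has activity
  a<sub>d</sub>(s) = σ<sub>dom</sub> · v<sub>d</sub> · (√ρ · c<sub>t(d)</sub>(s) + √(1−ρ) · ε<sub>d</sub>(s)),
  where c<sub>t</sub> is a per-domain-type factor (ρ = 0.65 of the activity
  variance is type-shared — a fluctuating chromatin-modifier pool), and
  v<sub>d</sub> is the domain's volatility.
- **Density/volatility coupling.** Dense domains (gene placement weight 3:1)
  are stable (v = 0.6); sparse domains volatile (v = 1.5). This one coupling
  plants both the noise–density relationship and domain-level co-regulation;
  switching the domain machinery off (σ<sub>dom</sub> = 0) removes the
  noise–density association entirely, which is what the null-calibration test
  checks.
- **Heterochromatin spreading.** 70% of sparse domains are heterochromatin-
  flanked: their volatility is boosted ×1.3, their genes are placed as loose
  pairs (8–40 kb), and inactive-state intervals are written 2–25 kb upstream
  of 80% of their genes. With the mechanism off, no inactive intervals exist
  and no volatility boost applies.
- **Interference.** Each gene receives
  w · Σ<sub>|Δ|<50 kb</sub> exp(−Δ/20 kb) · base(neighbour) with w = 0.35.
  The kernel and weight are generator conventions, not biological claims.
- **Functional programs.** 8% of genes form pairs sharing a program factor
  (σ = 1.5) present at *both* layers; 40% of those pairs are placed 5–45 kb
  apart (functionally related neighbours exist), the rest anywhere.
- **Buffering.** With buffering on, protein = program + N(0, 0.15): the
  domain and interference terms are dropped — post-transcriptional control is
  uncoordinated for everything but shared programs. With buffering off,
  protein = mRNA signal + N(0, 0.15).
- **Contacts.** Intra: count ∝ max(d,1)<sup>−1</sup> in 20-kb bins within
  5 Mb, ×2 same-domain, × compartment boost for same-label bins (A1 3.0,
  A2 2.5, B 1.2), lognormal pixel noise (σ = 0.25, unit mean). Dense domains
  carry A labels. Inter maps (100-kb bins) boost same-label B pairs —
  interchromosomal clustering is a property of gene-poor regions here.
  The power-law exponent is recovered by regression beyond the domain scale,
  where domain boosts no longer distort the decay.
- **Epigenome.** Domain types have orthonormal signature vectors over the
  12 features (amplitude √(p/2)), plus per-gene noise (σ = 0.3) and a built-in
  strongly correlated mark pair (H3K9ac ≈ 0.85·H3K4me3) to exercise the
  covariance-aware distance. Orthogonal signatures keep the whitened
  between-type separation well clear of the within-type chi noise; random
  signatures can collapse under Mahalanobis whitening when two types land
  close together.
- **Post-transcriptional annotations.** Half-lives (lognormal, median 6 h),
  NED flags (15%), protein lengths (lognormal), 60 miRNAs at ~3 targets per
  gene, and 7 translation programs feeding the ribosome layer
  (0.45·mRNA + program + noise). With sharing on, functional pairs draw
  matched half-lives and lengths (ratio < 1.35), a forced common miRNA, an
  elevated NED rate, and a common translation program.
- **Technical features.** Per-sample batch offsets (σ = 0.3, removed by
  centering), missingness 2% (mRNA) / 6.7% (protein), and per-sample
  median-centered output after preprocessing. Byte-identical output for a
  fixed seed.

Generator defaults were calibrated once so that the default bundle reproduces
the qualitative study contrasts (strong mRNA co-regulation of close pairs
buffered at the protein level; noise reduction in dense regions;
similarity- and contact-driven co-regulation bins; predicate enrichment in
sustained pairs) while keeping every analysis stage fast enough to run many
seeds; they are versioned with the package and not meant to be tuned per run.

**What the synthetic data does not emulate:** read-level sampling noise and
depth-dependent missingness (missingness is uniform, not abundance-dependent),
mean–variance coupling of expression noise, isoform structure, copy-number or
eQTL effects, translational regulation beyond a linear mRNA term, and the
long-tailed, locus-specific structure of real Hi-C maps (no loops, no TADs
beyond the planted domains). Passing tests therefore demonstrate that the
*pipeline* recovers planted structure of realistic magnitude — not that any
particular biological dataset will show these effect sizes.

## Numerical choices and degenerate inputs

- PCC is clipped to [−1, 1] after computation; |r| = 1 yields p = 0 exactly.
- Pairs below the overlap threshold or with zero variance are excluded from BH
  (no call), not counted as negatives.
- Quantile bins use rank-based qcut with first-occurrence tie-breaking, so bin
  occupancy is deterministic under ties.
- The Mahalanobis covariance is always ridge-regularised (scale-free because
  features are standardised first); a singular covariance after regularisation
  is an error, not a silent pseudo-inverse.
- The extreme-group cut breaks ties by gene id, making group membership
  deterministic across runs.
- k-means determinism is inherited from the fixed random state and iteration
  cap; equivalence across environments is at the level of cluster structure.
- Gzip map outputs are written with a fixed mtime so identical runs are
  byte-identical.

## Known limitations

- The BH family is per-analysis by design; merging analyses changes calls.
- `degree_inter3d` depends strongly on the inter-map normalisation; only its
  ranks should be interpreted.
- The LOWESS-style distance curve is descriptive; no confidence band is
  computed.
- Stage skipping in `run-all` is checksum-based at file granularity; touching
  any input file forces an explicit mismatch error rather than a partial
  recompute, which is conservative but predictable.
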