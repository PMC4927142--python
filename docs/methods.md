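# Methods

`hapblocks` analyzes *extended haplotype-genotype blocks*: multi-SNP segments
that are transmitted as units because recombination within them is suppressed
(for example by a chromosomal inversion, though the package is agnostic about
the mechanism). This note documents the models, the synthetic-data generator
that every validation study runs on, the numerical choices, and the known
limitations.

## Block detection: the ΔBIC linkage scan

For a candidate segment with breakpoints (s, e) we code, on every phased
chromosome, the local haplotype of the k SNPs just inside each end (default
k = 2, the smallest width that captures block-level rather than single-SNP
linkage). Let L and R be the observed left/right code alphabets and n the
number of chromosomes without missing alleles in either window.

- **M0 (independence)**: one component with independent left and right
  multinomials; (|L|−1) + (|R|−1) parameters.
- **M1 (linkage)**: a two-component mixture of such independent-block
  products plus a mixing weight, fitted by EM. If a subset of chromosomes
  carries the segment as a unit, their (left, right) pairs concentrate on a
  few combinations and the mixture absorbs that excess linkage.

The score is ΔBIC = BIC(M0) − BIC(M1) with BIC = −2·logL + p·ln n; ΔBIC > 0
declares a positive window. Windows of several sizes are slid across the
region (step = half the smallest window) and positive windows are merged by
interval union into candidate segments.

EM details: 5 random restarts with Dirichlet(1,1)-initialized cell
responsibilities, plus one restart pinned at the independence solution — a
fixed point of EM whose likelihood equals M0's, which guarantees
logL(M1) ≥ logL(M0) structurally; tolerance 1e−6 on the log-likelihood,
maximum 500 iterations; all restarts seeded. The mixture (rather than a
saturated joint multinomial) is the alternative because the signal of
interest is a *subset* of chromosomes with elevated block linkage; a
saturated model is available conceptually through the independence
log-likelihood helper for cross-checks.

## Diplotype calling: MDS + k-means with diplotype geometry

Within a called block, individuals carrying a of deeply diverged haplotype
alleles form a(a+1)/2 clusters in the first two components of a classical
(Torgerson) MDS of their genotype-dosage vectors (0/1/2 per SNP; missing
sites dropped pairwise, with distances rescaled to the full site count).
Classical MDS on Euclidean distances is algebraically a PCA of the centered
dosage matrix; we use the double-centered Gram eigendecomposition because it
is deterministic and matches the "first two components" usage. Component
signs are fixed (reference sample positive, else largest-magnitude
coordinate positive) so runs are reproducible.

Calling is clustering plus geometry:

1. k-means with k = a(a+1)/2, 20 seeded restarts, best inertia kept.
2. The a **homozygote clusters** are those whose centroids maximize the sum
   of pairwise distances (robust in 1-D and 2-D alike, unlike a convex-hull
   rule).
3. Every remaining cluster is labeled the **heterozygote** of the homozygote
   pair whose centroid midpoint is nearest. A heterozygote centroid whose
   two nearest midpoints differ by less than 5% of the mean
   homozygote-centroid distance is flagged ambiguous and its calls marked
   low-confidence.
4. The allele of the reference sample's homozygote cluster (or the largest
   homozygote cluster when no reference is given) is named H1; the rest are
   named by decreasing cluster size. Allele names are labels only; accuracy
   against truth is always evaluated over all label bijections.

The nearest-midpoint rule is this package's formalization of the visual
cluster-to-genotype assignment; it is asserted as an invariant on synthetic
data (each heterozygote centroid is nearer its own homozygote-pair midpoint
than any other).

**1-D sparse-panel fallback.** Genotyping arrays may carry only a handful of
tag SNPs, leaving a single informative MDS component. With three alleles and
a panel tagging two of them, the six diplotypes project to five distinct
values (two diplotypes collide), the expected "five-cluster" pattern, which
the caller verifies before proceeding. Each sample's dosages of the two
panel-resolvable alleles are then read from its orientation-corrected mean
tag dosages and snapped to the nearest valid diplotype (a, b, 2−a−b); the
third allele's homozygotes emerge as the samples carrying zero copies of
both resolvable alleles ("double non-carriers"). Samples whose fractional
dosages sit far from every valid diplotype (squared error > 0.25) are
flagged low-confidence.

**Tag SNPs** are discovered as SNPs whose dosage correlates with an allele's
dosage at r² ≥ 0.9 (threshold configurable); the correlation sign is
reported so panels can be orientation-corrected.

**Hardy–Weinberg screening** folds each allele to carrier dose 0/1/2 and
applies the 1-df chi-square test against p², 2pq, q²; alleles with p < 0.01
are the screening flags. The chi-square (not an exact test) mirrors the
screening use on large samples.

## Trio validation and TDT

A trio is Mendelian-consistent iff the child's unordered allele pair can be
formed by taking one allele from each parent; the error rate is errors over
evaluable trios (any trio with an uncalled member leaves the denominator).
The TDT folds multi-allelic calls to carrier dose of the target allele; both
parents contribute independently when heterozygous, homozygous parents are
uninformative, and Mendelian-inconsistent trios are excluded. The statistic
is (b−c)²/(b+c) on a 1-df chi-square reference; b + c = 0 yields a flagged
undefined result rather than a p-value.

## Population-genetic layer

- **FST**: Weir–Cockerham (1984) genotype-based estimator (components a, b,
  c; θ = a/(a+b+c)); multi-allelic blocks are folded per allele. Note the
  point estimate on identical populations is O(1/n) below zero — the
  estimator debiases by within-population variance — so "no
  differentiation" is asserted as |θ| small, not exactly zero.
- **Recombination-rate depression**: the mean rate of an interval is
  Δ(cumulative map)/Δ(length), exactly the length-weighted mean of
  per-interval rates. The permutation null draws same-length segments with
  uniformly random integer starts across the map span (the observed segment
  is not excluded; a flag could exclude it but the effect is ≤ 1/n).
  When the number of possible starts is at most the requested resamples the
  test enumerates all of them instead — this makes small cases exactly
  checkable against brute force.
- **Clinal gradient**: observed R² of per-population frequency regressed on
  distance from the origin; the null is the same R² for genome-background
  SNPs whose origin-region mean frequency matches the target's within an
  absolute tolerance (default 0.02 — "similar frequency" made concrete).
  If the matched pool is smaller than the requested resamples each matched
  SNP is used once, with a warning.
- **Empirical p-values** always use (k+1)/(n+1), so p is never zero, and
  the tail is an explicit argument.
- **Geography**: great-circle (haversine, R = 6371 km) legs summed along
  per-continent waypoint routes that detour around major water masses. The
  default route table (origin Addis Ababa; Cairo; south Iran; Bengal;
  Siberia/Bering for the Americas) is a deliberately coarse, documented
  default — real analyses should supply their own waypoints.
- **Phylogeny**: pairwise Hamming distances between haplotype (or clade
  consensus) sequences, missing sites dropped pairwise; Saitou–Nei neighbor
  joining with deterministic tie-breaking (lowest index pair in the
  Q-matrix) and negative branch lengths clamped to zero with the deficit
  moved to the sister branch. An outgroup is assigned to the clade with
  minimum Hamming distance; exact ties are flagged, not resolved.

## Association and meta-analysis

Codings are additive (allele copies, 0/1/2) or recessive (homozygote vs all
others — the homozygote-vs-rest contrast, documented here because carrier
contrasts are a plausible alternative reading). Quantitative scores can be
standardized to mean 100, SD 15 (the IQ convention). Models are OLS with
covariates supplied as columns (ancestry PCs are accepted as input, never
computed); covariates collinear with the design are dropped with a warning,
and the dosage term's p-value uses the t reference with residual degrees of
freedom. Fixed-effects meta-analysis pools with inverse-variance weights;
the pooled z-test uses the normal reference (standard fixed-effects
practice) and Cochran's Q with k−1 df is always reported. Cis-expression
scans fit one regression per gene on the log scale (a flag covers
pre-logged input) and apply the Bonferroni threshold α/n_genes exactly —
for α = 0.05 and 11 genes that is 4.545e−3; a printed rule of "4e−3" for
that design is the same threshold rounded down, and the exact value is used.

## The synthetic-data generator

The generator produces the structure the pipeline assumes, with truth
labels, so every layer has a scored test surface:

- **Locus**: a block of 200 SNPs flanked by 300 SNPs per side at 2 kb
  spacing (block ≈ 0.4 Mb — large enough for stable MDS geometry, small
  enough for seconds-scale studies). Chromosomes draw a founder clade
  (default frequencies 0.59/0.24/0.17, the European-like three-clade
  configuration) and copy its block haplotype with per-site flips
  (within-clade mutation, default 0.01). Founder divergence (default 0.3)
  is planted as *disjoint fixed-difference site sets per clade pair* rather
  than a coalescent: clade geometry stays controllable and the deep-clade
  structure is what matters for testing. Flank SNPs are independent
  Bernoulli draws per chromosome from a shared frequency spectrum
  (U(0.05, 0.95)) — free recombination by construction.
- **Trios**: each child receives one uniformly chosen haplotype per parent;
  crossovers (probability `flank_recomb` per meiosis) are placed only at
  flank boundaries, so the block is never split — its suppressed
  recombination is the premise. Genotyping error flips each transmitted
  allele independently.
- **Phenotypes**: y = 100 + Σ effectₖ·1[homozygous for clade k] +
  covariates·β + N(0, 15). The default planted effects (−2 to −3 points on
  an IQ-like scale against noise SD 15) are deliberately small relative to
  noise: single-cohort power is modest and pooling is required, as in
  realistic cognitive-trait designs.
- **Expression**: log-expression = baseline + allele dose × effect +
  N(0, σ), effects on designated target genes only.
- **Clinal frequencies**: logistic(logit(base) + slope·km/1000 + drift
  noise), clamped to [0, 1].

All generators are pure functions of (config, seed); per-replicate seeds in
the validation studies come from `numpy.random.SeedSequence.spawn`, which
guarantees independent streams (arithmetic seed derivation does not).

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: coalescent genealogy and shared ancestral
polymorphism between clades, LD decay within flanks, genotyping-array error
structure beyond uniform flips, population admixture, selection, and
phasing error (phased input is required and assumed correct). Calling
accuracy on real arrays will be bounded by phasing and array quality, not
by the geometry tested here.

## Validation studies and problem sizes

`hapblocks.evaluation` packages the studies the test suite and
`scripts/acceptance.py` run; sizes are chosen to finish in minutes on one
core:

- calling recovery: 1000 individuals, one locus (2-D) plus its 8-SNP tag
  panel (1-D);
- scan operating characteristics: 100 planted and 100 structureless loci of
  500 individuals, window sizes 250/300/400 kb;
- trio layer: 200 error-free trios through the full pipeline; 2000 null
  trio sets of 200 trios for TDT type-I error;
- oracle agreement: small fixed designs versus independent linear-algebra
  and closed-form routes;
- permutation calibration: brute-force enumeration on a 6-point map; 500
  exchangeable-map draws and 200 drift-only clinal replicates for
  uniformity;
- effect recovery: 200 replicates of three cohorts (900/1200/1000) with a
  planted −3.2-point recessive effect;
- phylogeny: 20 zero-noise loci with a synthetic outgroup (clade 1's
  consensus plus private mutations).

## Known limitations

- The scan requires phased haplotypes; genotype-level (EM-phased) scanning
  is future work.
- Calling supports at most three alleles (six clusters); more alleles would
  need k > 6 and a different ambiguity analysis.
- Coordinates are treated as opaque 1-based positions; no liftover between
  genome builds.
- The recessive coding is homozygote-vs-rest; no dominance or general
  genotype models.
- ORCADES-style family structure (kinship/mixed models) is out of scope;
  cohorts are assumed unrelated within.
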