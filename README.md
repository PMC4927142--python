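# hapblocks

Detection, calling and population-genetic analysis of **extended
haplotype-genotype blocks** in phased SNP data.

Some genomic segments — often, but not only, those spanning inversion
polymorphisms — are inherited as units because recombination within them is
suppressed. Chromosomes then fall into a few deeply diverged haplotype
clades, and each individual carries an unordered pair of clade alleles (a
*diplotype*, e.g. N1a/N2) that behaves like a multi-allelic super-locus:
it can be tagged by SNPs, tested for Hardy–Weinberg equilibrium and
transmission distortion in trios, mapped across populations, and used as
the genotype in trait and expression association models. `hapblocks` is a
toolkit for that whole workflow, aimed at statistical geneticists working
with phased cohort data (VCF) plus pedigree, phenotype and expression
tables.

## What it computes

- **Block scan** — slides windows across a region and scores each
  breakpoint pair with ΔBIC = BIC(independence) − BIC(two-component
  mixture) over the local k-SNP haplotype codes at the two ends; ΔBIC > 0
  flags chromosomes with excess long-range block linkage, and positive
  windows are merged into candidate segments.
- **Diplotype calling** — classical MDS of genotype-dosage vectors, k-means
  with k = a(a+1)/2 for a alleles, and geometric labeling: the mutually
  most distant clusters are the homozygotes, every other cluster is the
  heterozygote of the nearest homozygote-pair midpoint. A 1-D fallback
  calls sparse tag-SNP panels (five-cluster pattern, two resolvable
  alleles, third-allele homozygotes as double non-carriers).
- **Trio layer** — Mendelian-consistency error rate and the transmission
  disequilibrium test, χ² = (b−c)²/(b+c) over heterozygous parents.
- **Population genetics** — per-population allele frequencies and HWE
  screening, tag-SNP discovery at r² ≥ 0.9, Weir–Cockerham F_ST,
  permutation tests for recombination-rate depression and clinal
  frequency-vs-distance gradients (empirical p = (k+1)/(n+1)), waypoint
  great-circle distances, and Hamming-distance neighbor-joining phylogeny
  with outgroup assignment.
- **Association** — additive (0/1/2) and recessive (homozygote indicator)
  codings, covariate-adjusted OLS for quantitative traits (IQ-style
  standardization to mean 100, SD 15), per-gene cis-expression scans with
  exact Bonferroni control, and inverse-variance fixed-effects
  meta-analysis with Cochran's Q heterogeneity.
- **Synthetic data** — a generator that plants the assumed structure
  (three-clade block, free-recombining flanks, trios with genotyping
  error, recessive phenotype effects, additive expression effects, clinal
  frequencies) with truth labels, so every stage is testable end to end.

The scan, 2-D caller and tag-panel caller are scikit-learn-style estimators
(`BlockScanner`, `DiplotypeCaller`, `TagPanelCaller` with
`fit`/`fit_predict`, `get_params`/`set_params` and fitted `_` attributes);
the statistical tests are plain functions returning result objects.

## Worked example

```python
from hapblocks import (
    DiplotypeCaller, EffectSpec, call_accuracy, calls_from_truth,
    encode_dosage, fit_gaussian_model, meta_fixed_effects, scan_region,
    simulate_diplotypes, simulate_locus, simulate_phenotypes)
from hapblocks.simulate import LocusConfig

cfg = LocusConfig(n_individuals=500, seed=7)   # 3 clades at 0.59/0.24/0.17
gm, truth = simulate_locus(cfg, seed=7)        # block spans 15:1600000-1998000

scan = scan_region(gm, [250_000, 300_000, 400_000], seed=0)
print(scan.segments)
#    start_bp   end_bp  max_bic_diff
# 0   1625000  1925000   1136.648452

caller = DiplotypeCaller(n_alleles=3, region="15:1600000-1998000",
                         random_state=0).fit(gm)
print(call_accuracy(caller.calls_, truth))       # 1.0
print(caller.calls_.allele_frequencies())
# {'H1': 0.599, 'H2': 0.243, 'H3': 0.158}
print(caller.cluster_model_.hwe_pvalues)
# {'H1': 0.08, 'H2': 0.539, 'H3': 0.237}
```

The merged segment (1.625–1.925 Mb) sits inside the planted block; calling
recovers every diplotype, the three allele frequencies match the simulated
0.59/0.24/0.17, and all alleles pass Hardy–Weinberg screening.

Recessive association with a planted −3.2-point effect on clade-3
homozygotes (IQ-like noise, SD 15), pooled over three cohorts:

```python
spec = EffectSpec(recessive_effects={2: -3.2}, noise_sd=15)
per_study = []
for k, n in enumerate((900, 1200, 1000)):
    t = simulate_diplotypes(n, seed=100 + k)
    pheno = simulate_phenotypes(t, spec, seed=200 + k)
    dose = encode_dosage(calls_from_truth(t), "H3", "recessive")
    per_study.append(fit_gaussian_model(pheno["phenotype"], dose,
                                        model="recessive"))
meta = meta_fixed_effects(per_study)
print(meta.pooled_beta, meta.pooled_se, meta.Q)
# -1.83  1.77  1.39   (95% CI -5.31 to 1.65; p_heterogeneity 0.50)
```

With only ~3% of samples homozygous for the rare allele, a single
three-cohort draw is noisy — here the pooled estimate is −1.8 ± 1.8 around
the true −3.2. What matters is calibration, not one draw: across 200
replicates the pooled 95% CI covers the planted effect 95% of the time
(see below).

A `hapblocks` command-line interface mirrors the library
(`simulate | scan | call | trios | popgen | assoc | meta | eqtl`); every
stochastic subcommand takes `--seed`.

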