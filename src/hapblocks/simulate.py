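"""Synthetic data with the structure the pipeline assumes.

The central generator plants one extended haplotype block — a run of SNPs
inherited as a unit because recombination within it is suppressed — flanked
on both sides by freely recombining SNPs.  Chromosomes at the block descend
from a small number of deeply diverged founder haplotypes ("clades"); an
individual's unordered pair of clades is its diplotype, the truth label every
downstream caller is scored against.

Defaults mirror a three-clade European-like block: clade frequencies
0.59 / 0.24 / 0.17, a 200-SNP block with 300-SNP flanks, 30% of block sites
fixed-different between each clade pair, and 1% within-clade mutation.
Quantitative phenotypes are IQ-like (mean 100, SD 15) with recessive
per-clade effects of a few points; expression effects are additive per
allele on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PedigreeTable, PopulationTable

DEFAULT_CLADE_FREQS = (0.59, 0.24, 0.17)


@dataclass
class LocusConfig:
    """Parameters of the planted-block locus generator."""

    n_individuals: int = 1000
    n_block_snps: int = 200
    n_flank_snps: int = 300  # per side
    clade_freqs: Sequence[float] = DEFAULT_CLADE_FREQS
    divergence: float = 0.3  # fraction of block sites fixed-different per clade pair
    within_clade_mut: float = 0.01  # per-site flip probability
    flank_recomb: float = 0.5  # per-meiosis crossover probability in flanks
    snp_spacing_bp: int = 2000
    start_bp: int = 1_000_000
    chrom: str = "15"
    seed: Optional[int] = None

    def __post_init__(self):
        freqs = np.asarray(self.clade_freqs, dtype=float)
        if len(freqs) < 2:
            raise ValueError("need at least 2 clades")
        if not math.isclose(freqs.sum(), 1.0, abs_tol=1e-8):
            raise ValueError(f"clade_freqs must sum to 1, got {freqs.sum()}")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")
        if not 0 <= self.within_clade_mut <= 1:
            raise ValueError("within_clade_mut must be in [0, 1]")
        n_pairs = len(freqs) * (len(freqs) - 1) // 2
        if n_pairs * math.ceil(self.divergence * self.n_block_snps) > self.n_block_snps:
            raise ValueError(
                "divergence too high: disjoint fixed-difference site sets for "
                f"{n_pairs} clade pairs do not fit in {self.n_block_snps} block SNPs"
            )

    @property
    def n_clades(self) -> int:
        return len(self.clade_freqs)

    @property
    def n_snps(self) -> int:
        return self.n_block_snps + 2 * self.n_flank_snps

    @property
    def block_slice(self) -> slice:
        return slice(self.n_flank_snps, self.n_flank_snps + self.n_block_snps)

    @property
    def block_span_bp(self):
        """(start, end) positions of the block SNPs, 1-based inclusive."""
        pos = self.start_bp + np.arange(self.n_snps) * self.snp_spacing_bp
        return int(pos[self.n_flank_snps]), int(pos[self.n_flank_snps + self.n_block_snps - 1])


@dataclass
class TruthLabels:
    """Ground truth emitted alongside simulated genotypes."""

    chromosome_clades: np.ndarray  # shape (2n,), founder clade per haplotype
    sample_ids: list

    @property
    def diplotypes(self):
        """Per-sample unordered clade pair, as sorted (lo, hi) tuples."""
        c = self.chromosome_clades
        pairs = np.sort(np.column_stack([c[0::2], c[1::2]]), axis=1)
        return [tuple(p) for p in pairs]

    def to_frame(self) -> pd.DataFrame:
        d = self.diplotypes
        return pd.DataFrame(
            {"id": self.sample_ids,
             "clade_a": [p[0] for p in d],
             "clade_b": [p[1] for p in d]}
        )


@dataclass
class EffectSpec:
    """Planted genotype-phenotype and genotype-expression effects.

    ``recessive_effects`` maps clade index to the phenotype shift of that
    clade's homozygotes; ``expression_effects`` maps clade index to the
    per-allele (additive) shift in log expression.
    """

    recessive_effects: Dict[int, float] = field(default_factory=dict)
    expression_effects: Dict[int, float] = field(default_factory=dict)
    covariate_effects: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 15.0
    expression_noise_sd: float = 0.5
    baseline: float = 100.0
    expression_baseline: float = 8.0

    def __post_init__(self):
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _founder_haplotypes(cfg: LocusConfig, rng: np.random.Generator) -> np.ndarray:
    """Deeply diverged founder block haplotypes.

    Divergence is planted as disjoint fixed-difference site sets: for each
    clade pair a dedicated set of ⌈divergence × n_block⌉ sites is forced to
    differ between the two (one clade gets 0, the other 1), guaranteeing at
    least that many fixed differences per pair without a coalescent.
    """
    K, m = cfg.n_clades, cfg.n_block_snps
    base = rng.integers(0, 2, size=m, dtype=np.int8)
    founders = np.tile(base, (K, 1))
    d = math.ceil(cfg.divergence * m)
    if d == 0:
        return founders
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    sites = rng.permutation(m)[: d * len(pairs)]
    for idx, (i, j) in enumerate(pairs):
        s = sites[idx * d: (idx + 1) * d]
        founders[i, s] = 0
        founders[j, s] = 1
    return founders


def simulate_locus(cfg: LocusConfig, seed: Optional[int] = None):
    """Simulate a planted-block locus.

    Returns ``(GenotypeMatrix, TruthLabels)``.  Block SNPs: each chromosome
    copies its founder clade's haplotype with per-site flips at rate
    ``within_clade_mut``.  Flank SNPs: independent Bernoulli draws per
    chromosome from a shared site frequency spectrum (free recombination).
    """
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    n = cfg.n_individuals
    n_chrom = 2 * n
    freqs = np.asarray(cfg.clade_freqs, dtype=float)

    founders = _founder_haplotypes(cfg, rng)
    clades = rng.choice(cfg.n_clades, size=n_chrom, p=freqs)

    block = founders[clades].copy()
    if cfg.within_clade_mut > 0:
        flips = rng.random(block.shape) < cfg.within_clade_mut
        block[flips] = 1 - block[flips]

    def flank(n_snps):
        f = rng.uniform(0.05, 0.95, size=n_snps)
        return (rng.random((n_chrom, n_snps)) < f).astype(np.int8)

    alleles = np.hstack([flank(cfg.n_flank_snps), block, flank(cfg.n_flank_snps)])

    pos = cfg.start_bp + np.arange(cfg.n_snps) * cfg.snp_spacing_bp
    variants = pd.DataFrame(
        {"chrom": cfg.chrom, "pos": pos,
         "id": [f"snp{i:05d}" for i in range(cfg.n_snps)],
         "ref": "A", "alt": "G"}
    )
    sample_ids = [f"ind{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(sample_ids=sample_ids, variants=variants, alleles=alleles)
    truth = TruthLabels(chromosome_clades=clades, sample_ids=sample_ids)
    return gm, truth


def simulate_diplotypes(n: int, clade_freqs=DEFAULT_CLADE_FREQS, seed=None,
                        prefix: str = "ind") -> TruthLabels:
    """Draw diplotypes only (no genotypes), under Hardy–Weinberg proportions."""
    rng = np.random.default_rng(seed)
    freqs = np.asarray(clade_freqs, dtype=float)
    clades = rng.choice(len(freqs), size=2 * n, p=freqs / freqs.sum())
    return TruthLabels(chromosome_clades=clades,
                       sample_ids=[f"{prefix}{i:04d}" for i in range(n)])


def simulate_trios(parents: GenotypeMatrix, parent_truth: TruthLabels,
                   cfg: LocusConfig, n_trios: int, error_rate: float = 0.0,
                   seed: Optional[int] = None):
    """Simulate trio children by Mendelian transmission from paired parents.

    Parents ``2t`` and ``2t+1`` form trio ``t``.  Each child receives one
    uniformly chosen haplotype per parent; with probability ``flank_recomb``
    a single crossover is placed at a uniformly chosen flank boundary (the
    block itself is never split, modelling its suppressed recombination).
    Each transmitted allele is then flipped independently with probability
    ``error_rate`` (genotyping error).

    Returns ``(children GenotypeMatrix, PedigreeTable, child TruthLabels)``.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
    if parents.n_samples < 2 * n_trios:
        raise ValueError(f"{parents.n_samples} parents cannot form {n_trios} trios")
    rng = np.random.default_rng(seed)
    m = parents.n_variants
    blk = cfg.block_slice
    # crossover points: flank SNP boundaries only
    cut_points = np.concatenate([
        np.arange(1, cfg.n_flank_snps + 1),
        np.arange(cfg.n_flank_snps + cfg.n_block_snps, m),
    ])

    child_alleles = np.empty((2 * n_trios, m), dtype=np.int8)
    child_clades = np.empty(2 * n_trios, dtype=int)
    trios = []
    for t in range(n_trios):
        father_i, mother_i = 2 * t, 2 * t + 1
        for k, parent_i in enumerate((father_i, mother_i)):
            h = rng.integers(2)
            hap_a = parents.alleles[2 * parent_i + h].copy()
            hap_b = parents.alleles[2 * parent_i + 1 - h]
            clade = parent_truth.chromosome_clades[2 * parent_i + h]
            if cfg.flank_recomb > 0 and rng.random() < cfg.flank_recomb:
                cp = int(rng.choice(cut_points))
                hap_a[cp:] = hap_b[cp:]
                if cp <= blk.start:  # block inherited from the other haplotype
                    clade = parent_truth.chromosome_clades[2 * parent_i + 1 - h]
            child_alleles[2 * t + k] = hap_a
            child_clades[2 * t + k] = clade
        trios.append((f"child{t:04d}", parents.sample_ids[father_i], parents.sample_ids[mother_i]))

    if error_rate > 0:
        flips = rng.random(child_alleles.shape) < error_rate
        ok = child_alleles != MISSING
        flips &= ok
        child_alleles[flips] = 1 - child_alleles[flips]

    children = GenotypeMatrix(
        sample_ids=[t[0] for t in trios],
        variants=parents.variants.copy(),
        alleles=child_alleles,
    )
    truth = TruthLabels(chromosome_clades=child_clades, sample_ids=children.sample_ids)
    return children, PedigreeTable(trios=trios), truth


def calls_from_truth(truth: TruthLabels, allele_names: Optional[Sequence[str]] = None):
    """Turn truth labels into perfect :class:`~hapblocks.calling.DiplotypeCalls`.

    Clade index ``k`` becomes allele ``allele_names[k]`` (default
    ``H1, H2, ...``).  Useful for calibration studies of downstream layers
    that should not be confounded with calling error.
    """
    from .calling import DiplotypeCalls

    n_clades = int(np.max(truth.chromosome_clades)) + 1
    if allele_names is None:
        allele_names = tuple(f"H{k + 1}" for k in range(n_clades))
    pairs = [(allele_names[a], allele_names[b]) for a, b in truth.diplotypes]
    return DiplotypeCalls(sample_ids=list(truth.sample_ids), pairs=pairs,
                          allele_names=tuple(allele_names))


def simulate_trio_diplotypes(n_trios: int, clade_freqs=DEFAULT_CLADE_FREQS, seed=None):
    """Diplotype-level trios under null (random) transmission.

    Parents draw diplotypes under Hardy–Weinberg; each child receives one
    uniformly chosen allele from each parent.  Returns ``(TruthLabels for
    parents+children, PedigreeTable)`` with parents named ``fa####``/``mo####``
    and children ``child####``.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(clade_freqs, dtype=float)
    K = len(freqs)
    fa = rng.choice(K, size=(n_trios, 2), p=freqs)
    mo = rng.choice(K, size=(n_trios, 2), p=freqs)
    child = np.column_stack([
        fa[np.arange(n_trios), rng.integers(2, size=n_trios)],
        mo[np.arange(n_trios), rng.integers(2, size=n_trios)],
    ])
    clades = np.concatenate([fa.ravel(), mo.ravel(), child.ravel()])
    ids = ([f"fa{t:04d}" for t in range(n_trios)]
           + [f"mo{t:04d}" for t in range(n_trios)]
           + [f"child{t:04d}" for t in range(n_trios)])
    truth = TruthLabels(chromosome_clades=clades, sample_ids=ids)
    ped = PedigreeTable(trios=[(f"child{t:04d}", f"fa{t:04d}", f"mo{t:04d}")
                               for t in range(n_trios)])
    return truth, ped


def simulate_phenotypes(truth: TruthLabels, spec: EffectSpec,
                        covariates: Optional[pd.DataFrame] = None,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Quantitative phenotype with recessive per-clade effects.

    ``y = baseline + Σ_k effect_k · 1[homozygous for clade k] + covariates·β
    + N(0, noise_sd)``.  Defaults give an IQ-like scale (baseline 100,
    noise SD 15).
    """
    rng = np.random.default_rng(seed)
    diplos = truth.diplotypes
    n = len(diplos)
    y = np.full(n, spec.baseline, dtype=float)
    n_clades = int(np.max(truth.chromosome_clades)) + 1
    for clade, eff in spec.recessive_effects.items():
        if not 0 <= clade < n_clades:
            raise ValueError(f"unknown clade {clade} in effect spec")
        hom = np.array([d == (clade, clade) for d in diplos])
        y[hom] += eff
    out = pd.DataFrame({"id": truth.sample_ids})
    if covariates is not None:
        cov = covariates.set_index("id").loc[truth.sample_ids] if "id" in covariates.columns else covariates
        if len(cov) != n:
            raise ValueError("covariate table not aligned to samples")
        for name, beta in spec.covariate_effects.items():
            y += beta * cov[name].to_numpy(dtype=float)
        for c in cov.columns:
            out[c] = cov[c].to_numpy()
    elif spec.covariate_effects:
        raise ValueError("covariate_effects given but no covariate table")
    y += rng.normal(0.0, spec.noise_sd, size=n)
    out["phenotype"] = y
    return out


def simulate_clinal_frequencies(distances_km, base_freq: float,
                                slope_per_1000km: float, drift_sd: float,
                                n_samples_per_pop: int = 100,
                                seed: Optional[int] = None) -> PopulationTable:
    """Population allele frequencies declining (or rising) with distance.

    ``freq_k = logistic(logit(base_freq) + slope · d_k / 1000 + N(0, drift_sd))``,
    emulating a clinal out-of-Africa-style gradient with drift noise.
    """
    if not 0 < base_freq < 1:
        raise ValueError(f"base_freq must be in (0, 1), got {base_freq}")
    d = np.asarray(distances_km, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    rng = np.random.default_rng(seed)
    logit = math.log(base_freq / (1 - base_freq))
    eta = logit + slope_per_1000km * d / 1000.0 + rng.normal(0, drift_sd, size=len(d))
    freq = 1.0 / (1.0 + np.exp(-eta))
    freq = np.clip(freq, 0.0, 1.0)
    table = pd.DataFrame({
        "pop_code": [f"POP{k:02d}" for k in range(len(d))],
        "n_samples": n_samples_per_pop,
        "distance_km": d,
        "allele_freq": freq,
    })
    return PopulationTable(table=table)


def simulate_expression(truth: TruthLabels, spec: EffectSpec, n_genes: int,
                        target_genes: Optional[Sequence[str]] = None,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Per-gene log-expression with additive per-allele effects.

    Only ``target_genes`` (default: the first gene) carry the planted
    per-clade allele-dosage effects; all other genes are pure noise.
    Returns a genes × samples table with gene ids as the row index.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = [f"GENE{g:03d}" for g in range(n_genes)]
    if target_genes is None:
        target_genes = [gene_ids[0]] if spec.expression_effects else []
    unknown = set(target_genes) - set(gene_ids)
    if unknown:
        raise ValueError(f"target genes not in panel: {sorted(unknown)}")
    n = len(truth.sample_ids)
    expr = spec.expression_baseline + rng.normal(
        0.0, spec.expression_noise_sd, size=(n_genes, n))
    c = truth.chromosome_clades
    for clade, eff in spec.expression_effects.items():
        dose = (c[0::2] == clade).astype(float) + (c[1::2] == clade).astype(float)
        for g in target_genes:
            expr[gene_ids.index(g)] += eff * dose
    return pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene"),
                        columns=truth.sample_ids)
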