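"""Validation studies: simulate → analyze → score, for every pipeline layer.

Each function runs one self-contained study on synthetic data under the
package's reference conditions (three clades at frequencies 0.59/0.24/0.17,
divergence 0.3, within-clade mutation 0.01, IQ-like phenotypes with noise
SD 15) and returns the operating characteristics a user would quote:
calling accuracy, scan power and specificity, trio-layer calibration,
oracle agreement, permutation-test calibration, meta-analytic coverage and
phylogeny recovery.  The acceptance script and the test suite both run
these studies; problem sizes are arguments so they can be scaled.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats

from .association import fit_gaussian_model, meta_fixed_effects
from .calling import (
    DiplotypeCaller,
    TagPanelCaller,
    call_accuracy,
    discover_tag_snps,
    mds_embed,
)
from .io import GenotypeMatrix, RecombinationMap, concat_samples
from .popgen import (
    assign_outgroup,
    clinal_permutation_test,
    consensus_sequence,
    fst_two_level,
    hamming_matrix,
    mean_recombination_rate,
    neighbor_joining,
    recomb_rate_permutation_test,
)
from .scan import scan_region
from .simulate import (
    EffectSpec,
    LocusConfig,
    calls_from_truth,
    simulate_diplotypes,
    simulate_locus,
    simulate_phenotypes,
    simulate_trio_diplotypes,
    simulate_trios,
)

REFERENCE_FREQS = (0.59, 0.24, 0.17)
SCAN_WINDOWS = (250_000, 300_000, 400_000)


def build_tag_panel(calls, gm: GenotypeMatrix, cfg: LocusConfig,
                    per_allele: int = 4):
    """Top tag SNPs (r² ≥ 0.9) for the two most frequent alleles."""
    block = gm.region(cfg.chrom, *cfg.block_span_bp)
    tags = discover_tag_snps(calls, block, 0.9)
    freqs = calls.allele_frequencies()
    top2 = sorted(freqs, key=freqs.get, reverse=True)[:2]
    panel, amap = [], {}
    for a in top2:
        best = tags[tags.allele == a].nlargest(per_allele, "r2")
        for r in best.itertuples(index=False):
            panel.append(r.snp_id)
            amap[r.snp_id] = (a, r.sign)
    return panel, amap


def calling_recovery_study(n_individuals: int = 1000, seed: int = 0) -> Dict:
    """2-D MDS calling and 8-SNP 1-D fallback accuracy against truth."""
    cfg = LocusConfig(n_individuals=n_individuals, clade_freqs=REFERENCE_FREQS,
                      divergence=0.3, within_clade_mut=0.01)
    gm, truth = simulate_locus(cfg, seed=seed)
    region = "%s:%d-%d" % (cfg.chrom, *cfg.block_span_bp)
    caller = DiplotypeCaller(n_alleles=3, region=region, random_state=seed)
    calls = caller.fit_predict(gm)
    acc2d = call_accuracy(calls, truth)

    panel, amap = build_tag_panel(calls, gm, cfg)
    tp = TagPanelCaller(tag_snp_panel=panel, allele_map=amap,
                        random_state=seed).fit(gm)
    acc1d = call_accuracy(tp.calls_, truth)
    return {"accuracy_2d": acc2d, "accuracy_1d": acc1d,
            "n": n_individuals, "panel_size": len(panel)}


def scan_power_study(n_replicates: int = 100, n_individuals: int = 500,
                     seed: int = 0) -> Dict:
    """Detection power on planted blocks and false-positive rate on nulls."""
    hits = false = 0
    streams = np.random.SeedSequence(seed).spawn(3 * n_replicates)
    for rep in range(n_replicates):
        cfg = LocusConfig(n_individuals=n_individuals,
                          clade_freqs=REFERENCE_FREQS)
        gm, _ = simulate_locus(cfg, seed=streams[3 * rep])
        res = scan_region(gm, SCAN_WINDOWS, seed=streams[3 * rep + 1])
        start, end = cfg.block_span_bp
        seg = res.segments
        if not seg.empty and ((seg.start_bp <= end) & (seg.end_bp >= start)).any():
            hits += 1

        cfg0 = LocusConfig(n_individuals=n_individuals, divergence=0.0)
        gm0, _ = simulate_locus(cfg0, seed=streams[3 * rep + 2])
        res0 = scan_region(gm0, SCAN_WINDOWS, seed=streams[3 * rep + 1])
        false += not res0.segments.empty
    return {"power": hits / n_replicates,
            "false_positive_rate": false / n_replicates,
            "n_replicates": n_replicates, "n": n_individuals}


def trio_study(n_trios: int = 200, n_null_sets: int = 2000,
               trios_per_set: int = 200, seed: int = 0) -> Dict:
    """Error-free Mendelian rate through the full pipeline + TDT type I."""
    from .trios import mendelian_error_rate, tdt

    cfg = LocusConfig(n_individuals=2 * n_trios, clade_freqs=REFERENCE_FREQS)
    gm, truth = simulate_locus(cfg, seed=seed)
    children, ped, _ = simulate_trios(gm, truth, cfg, n_trios,
                                      error_rate=0.0, seed=seed + 1)
    both = concat_samples(gm, children)
    region = "%s:%d-%d" % (cfg.chrom, *cfg.block_span_bp)
    calls = DiplotypeCaller(n_alleles=3, region=region,
                            random_state=seed).fit_predict(both)
    mendel_rate, _ = mendelian_error_rate(calls, ped)

    rejections = 0
    streams = np.random.SeedSequence((seed, 2)).spawn(n_null_sets)
    for rep in range(n_null_sets):
        t, p = simulate_trio_diplotypes(trios_per_set,
                                        clade_freqs=REFERENCE_FREQS,
                                        seed=streams[rep])
        res = tdt(calls_from_truth(t), p, "H1")
        rejections += res.p_value < 0.05
    return {"mendelian_error_rate": mendel_rate,
            "tdt_type1_rate": rejections / n_null_sets,
            "n_null_sets": n_null_sets, "n_trios": n_trios}


def oracle_deviation_study(seed: int = 0) -> Dict:
    """Max deviation of each estimator from its independent oracle."""
    rng = np.random.default_rng(seed)

    # MDS vs eigen-solution of the centered dosage matrix (SVD route)
    dosage = rng.integers(0, 3, size=(12, 6)).astype(float)
    alleles = np.zeros((24, 6), dtype=np.int8)
    alleles[0::2] = dosage >= 1
    alleles[1::2] = dosage == 2
    variants = pd.DataFrame({"chrom": "1", "pos": 100 * (1 + np.arange(6)),
                             "id": [f"rs{i}" for i in range(6)],
                             "ref": "A", "alt": "G"})
    gm = GenotypeMatrix([f"s{i}" for i in range(12)], variants, alleles)
    coords = mds_embed(gm, n_components=2)
    X = dosage - dosage.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    oracle = U[:, :2] * S[:2]
    mds_dev = 0.0
    for c in range(2):
        col, ora = coords[:, c], oracle[:, c]
        if col @ ora < 0:
            ora = -ora
        mds_dev = max(mds_dev, float(np.abs(col - ora).max()))

    # OLS vs normal equations
    n = 50
    dose = rng.integers(0, 3, n).astype(float)
    cov = pd.DataFrame({"age": rng.normal(10, 2, n)})
    y = 1.0 - 2.0 * dose + 0.5 * cov["age"].to_numpy() + rng.normal(0, 1, n)
    res = fit_gaussian_model(y, dose, covariates=cov)
    Xd = np.column_stack([np.ones(n), dose, cov["age"]])
    bh = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    resid = y - Xd @ bh
    se = np.sqrt(resid @ resid / (n - 3) * np.linalg.inv(Xd.T @ Xd)[1, 1])
    ols_dev = max(abs(res.beta - bh[1]), abs(res.se - se))

    # FST vs a re-derivation of the Weir-Cockerham components
    d = np.concatenate([rng.binomial(2, 0.2, 40), rng.binomial(2, 0.7, 50)])
    labels = np.array(["P1"] * 40 + ["P2"] * 50)
    theta = fst_two_level(d, labels)
    n_i = np.array([40.0, 50.0])
    p_i = np.array([d[:40].mean() / 2, d[40:].mean() / 2])
    h_i = np.array([np.mean(d[:40] == 1), np.mean(d[40:] == 1)])
    r = 2
    nbar, ntot = n_i.mean(), n_i.sum()
    nc = (ntot - (n_i ** 2).sum() / ntot) / (r - 1)
    pbar = (n_i * p_i).sum() / ntot
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / ntot
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    fst_dev = abs(theta - a / (a + b + c))

    # meta-analysis vs closed form
    m = meta_fixed_effects([(-2.0, 1.0), (-4.0, 1.0)])
    meta_dev = max(abs(m.pooled_beta - (-3.0)),
                   abs(m.pooled_se - np.sqrt(0.5)), abs(m.Q - 2.0))
    return {"mds_max_dev": float(mds_dev), "ols_max_dev": float(ols_dev),
            "fst_dev": float(fst_dev), "meta_dev": float(meta_dev)}


def _exchangeable_map(n_intervals: int, rng) -> RecombinationMap:
    pos = 1000 + 1000 * np.arange(n_intervals + 1)
    rates = rng.exponential(1.0, size=n_intervals + 1)
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * 1000 / 1e6)])
    return RecombinationMap(pos, rates, cum)


def permutation_calibration_study(n_draws: int = 500, n_replicates: int = 200,
                                  seed: int = 0) -> Dict:
    """Exhaustive-enumeration agreement and null uniformity of both tests."""
    rng = np.random.default_rng(seed)

    # exact agreement with brute-force enumeration on a tiny map
    pos = np.array([100, 120, 140, 160, 180, 200])
    rates = np.array([1.0, 0.2, 3.0, 0.5, 2.0, 0.0])
    cum = np.concatenate([[0], np.cumsum(rates[:-1] * np.diff(pos) / 1e6)])
    rmap = RecombinationMap(pos, rates, cum)
    max_dev = 0.0
    for interval in ((120, 160), (100, 150), (130, 180)):
        res = recomb_rate_permutation_test(rmap, interval, n_resamples=10_000)
        length = interval[1] - interval[0]
        null = [mean_recombination_rate(rmap, (s, s + length))
                for s in range(100, 200 - length + 1)]
        obs = mean_recombination_rate(rmap, interval)
        brute = (sum(v <= obs for v in null) + 1) / (len(null) + 1)
        max_dev = max(max_dev, abs(res.empirical_p - brute))

    # recombination-rate null uniformity: exchangeable (i.i.d.-rate) maps
    pvals = []
    for _ in range(n_draws):
        m = _exchangeable_map(200, rng)
        lo, hi = m.span
        length = int(rng.integers(5, 40)) * 1000
        start = int(rng.integers(lo, hi - length))
        res = recomb_rate_permutation_test(
            m, (start, start + length), n_resamples=199,
            seed=int(rng.integers(2 ** 31)), exhaustive=False)
        pvals.append(res.empirical_p)
    recomb_ks_p = float(stats.kstest(pvals, "uniform").pvalue)

    # clinal null uniformity: slope-0 target against a slope-0 matched pool
    distances = np.linspace(0, 12_000, 26)
    cl_pvals = []
    cl_streams = np.random.SeedSequence((seed, 5)).spawn(n_replicates)
    for rep in range(n_replicates):
        r2 = np.random.default_rng(cl_streams[rep])
        def drift_freqs(n):
            eta = (np.log(0.4 / 0.6)
                   + r2.normal(0, 0.4, size=(n, len(distances))))
            return 1 / (1 + np.exp(-eta))
        target = drift_freqs(1)[0]
        pool_f = drift_freqs(300)
        pool = pd.DataFrame(pool_f, columns=[f"P{i}" for i in range(len(distances))])
        pool.insert(0, "origin_freq", 0.4)
        res = clinal_permutation_test(target, distances, pool, 0.4,
                                      match_tolerance=0.5, n_resamples=299,
                                      seed=rep)
        cl_pvals.append(res.empirical_p)
    clinal_ks_p = float(stats.kstest(cl_pvals, "uniform").pvalue)
    return {"exhaustive_max_dev": float(max_dev),
            "recomb_ks_p": recomb_ks_p, "clinal_ks_p": clinal_ks_p,
            "n_draws": n_draws, "n_replicates": n_replicates}


def effect_recovery_study(n_replicates: int = 200, effect: float = -3.2,
                          noise_sd: float = 15.0, seed: int = 0) -> Dict:
    """Pooled fixed-effects CI coverage of a planted recessive effect.

    Three cohorts (n = 900, 1200, 1000) mirror a discovery + two replication
    design; the planted effect acts on homozygotes of the rarest clade.
    """
    cohort_sizes = (900, 1200, 1000)
    spec = EffectSpec(recessive_effects={2: effect}, noise_sd=noise_sd)
    covered = 0
    pooled = []
    streams = np.random.SeedSequence((seed, 3)).spawn(n_replicates)
    for rep in range(n_replicates):
        per_study = []
        cohort_streams = streams[rep].spawn(2 * len(cohort_sizes))
        for k, size in enumerate(cohort_sizes):
            truth = simulate_diplotypes(size, clade_freqs=REFERENCE_FREQS,
                                        seed=cohort_streams[2 * k])
            pheno = simulate_phenotypes(truth, spec, seed=cohort_streams[2 * k + 1])
            calls = calls_from_truth(truth)
            dose = (calls.dosage("H3") == 2).astype(float)
            per_study.append(fit_gaussian_model(
                pheno["phenotype"].to_numpy(), dose, model="recessive"))
        meta = meta_fixed_effects(per_study)
        lo, hi = meta.ci95()
        covered += lo <= effect <= hi
        pooled.append(meta.pooled_beta)
    return {"coverage": covered / n_replicates,
            "mean_pooled_beta": float(np.mean(pooled)),
            "n_replicates": n_replicates, "effect": effect}


def _siblings(newick: str, a: str, b: str) -> bool:
    import re
    for group in re.findall(r"\(([^()]*)\)", newick):
        names = {part.split(":")[0] for part in group.split(",")}
        if {a, b} <= names:
            return True
    return False


def phylogeny_study(n_replicates: int = 20, n_individuals: int = 150,
                    n_private_mutations: int = 12, seed: int = 0) -> Dict:
    """NJ recovery of the planted clade topology with a known outgroup.

    The outgroup is built as clade 1's consensus plus private mutations, so
    both the tree and the nearest-clade assignment must place it with
    clade 1.  Also checks exact recovery of a hand-built additive 4-taxon
    metric.
    """
    topo = assigned = 0
    streams = np.random.SeedSequence((seed, 4)).spawn(2 * n_replicates)
    for rep in range(n_replicates):
        cfg = LocusConfig(n_individuals=n_individuals,
                          clade_freqs=REFERENCE_FREQS, within_clade_mut=0.0)
        gm, truth = simulate_locus(cfg, seed=streams[2 * rep])
        rng = np.random.default_rng(streams[2 * rep + 1])
        blk = gm.alleles[:, cfg.block_slice]
        cons = {f"clade{k}": consensus_sequence(blk[truth.chromosome_clades == k])
                for k in range(3)}
        out = cons["clade1"].copy()
        flips = rng.choice(len(out), n_private_mutations, replace=False)
        out[flips] = 1 - out[flips]
        seqs = list(cons.values()) + [out]
        D = hamming_matrix(seqs)
        nwk = neighbor_joining(D, list(cons.keys()) + ["outgroup"])
        topo += _siblings(nwk, "clade1", "outgroup") or _siblings(nwk, "clade0", "clade2")
        assigned += assign_outgroup(out, cons).clade == "clade1"

    D4 = np.array([[0, 4, 7, 10], [4, 0, 9, 12],
                   [7, 9, 0, 7], [10, 12, 7, 0]], float)
    nwk4 = neighbor_joining(D4, ["A", "B", "C", "D"])
    four_taxon_exact = _siblings(nwk4, "A", "B") or _siblings(nwk4, "C", "D")
    return {"topology_rate": topo / n_replicates,
            "outgroup_rate": assigned / n_replicates,
            "four_taxon_exact": bool(four_taxon_exact),
            "n_replicates": n_replicates}
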