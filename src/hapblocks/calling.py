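"""Diplotype calling: MDS embedding, k-means clustering and genotype labeling.

Within a candidate block, individuals carrying ``a`` deeply diverged
haplotype alleles fall into ``a(a+1)/2`` clusters in the first two components
of a classical multidimensional scaling of their genotype-dosage vectors:
the ``a`` homozygote clusters sit at the extremes and every heterozygote
cluster lies near the midpoint of its two homozygote clusters.  Calling is
therefore clustering plus geometry: find the clusters, pick the mutually
most distant ``a`` as homozygotes, and label each remaining cluster as the
heterozygote of the homozygote pair whose centroid midpoint is nearest.

A 1-D fallback handles sparse tag-SNP panels where only the first MDS
component resolves (typically five clusters for three alleles), calling the
two resolvable alleles from tag dosages and inferring the third allele's
homozygotes as double non-carriers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import chi2 as chi2_dist
from sklearn.cluster import KMeans

from .io import GenotypeMatrix, parse_region

logger = logging.getLogger(__name__)


class CallingError(ValueError):
    pass


@dataclass
class DiplotypeCalls:
    """Per-sample unordered pair of named haplotype alleles for one block."""

    sample_ids: list
    pairs: list  # of (allele, allele) tuples, sorted
    allele_names: tuple
    cluster_ids: Optional[np.ndarray] = None
    quality: Optional[np.ndarray] = None  # distance to assigned centroid
    low_confidence: Optional[np.ndarray] = None

    def __post_init__(self):
        self.pairs = [tuple(sorted(p)) for p in self.pairs]
        bad = {a for p in self.pairs for a in p} - set(self.allele_names)
        if bad:
            raise CallingError(f"calls use undeclared alleles: {sorted(bad)}")

    def __len__(self):
        return len(self.sample_ids)

    def dosage(self, allele: str) -> np.ndarray:
        """Copies of ``allele`` carried per sample (0/1/2)."""
        if allele not in self.allele_names:
            raise CallingError(f"unknown allele {allele!r}")
        return np.array([p.count(allele) for p in self.pairs], dtype=float)

    def allele_frequencies(self) -> Dict[str, float]:
        n = 2 * len(self)
        return {a: float(sum(p.count(a) for p in self.pairs)) / n
                for a in self.allele_names}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "id": self.sample_ids,
            "allele1": [p[0] for p in self.pairs],
            "allele2": [p[1] for p in self.pairs],
        })
        if self.cluster_ids is not None:
            df["cluster"] = self.cluster_ids
        if self.quality is not None:
            df["quality"] = self.quality
        if self.low_confidence is not None:
            df["low_confidence"] = self.low_confidence
        return df


@dataclass
class ClusterModel:
    """Fitted embedding, centroids and their diplotype labels."""

    coords: np.ndarray
    centroids: np.ndarray
    centroid_diplotypes: Dict[int, Tuple[str, str]]
    homozygote_clusters: Dict[str, int]  # allele -> cluster index
    hwe_pvalues: Dict[str, float] = field(default_factory=dict)
    ambiguous_clusters: tuple = ()


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def _pairwise_sq_dists(dosage: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances with missing sites dropped pairwise.

    Distances over partially shared sites are rescaled to the full site count
    so samples with missing data stay on a comparable scale.
    """
    if not np.isnan(dosage).any():
        return squareform(pdist(dosage, metric="sqeuclidean"))
    m = dosage.shape[1]
    filled = np.nan_to_num(dosage)
    obs = (~np.isnan(dosage)).astype(float)
    # sum over shared sites of (x_i - x_j)^2, computed via masked products
    sq = filled ** 2
    d2 = (sq @ obs.T) + (obs @ sq.T) - 2 * (filled @ filled.T)
    shared = obs @ obs.T
    if (shared < 1).any():
        raise CallingError("a sample pair shares no genotyped site")
    return d2 * (m / shared)


def mds_embed(gm: GenotypeMatrix, region: Optional[str] = None,
              n_components: int = 2,
              reference_sample: Optional[str] = None) -> np.ndarray:
    """Classical (Torgerson) MDS of per-sample genotype-dosage vectors.

    Double-centers the squared Euclidean distance matrix and takes the top
    eigenvectors scaled by the root eigenvalues — equivalently a PCA of the
    centered dosage matrix.  Component signs are fixed so the reference
    sample (if given) has a non-negative first coordinate; otherwise each
    component's largest-magnitude coordinate is made positive.
    """
    sub = gm.region(*parse_region(region)) if region is not None else gm
    if sub.n_variants < 2:
        raise CallingError("need at least 2 SNPs in the region")
    if sub.n_samples < 3:
        raise CallingError("need at least 3 samples")
    d2 = _pairwise_sq_dists(sub.dosages())
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if reference_sample is not None and c == 0:
            ref_i = gm.sample_ids.index(reference_sample)
            if col[ref_i] < 0:
                coords[:, c] = -col
        elif col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords


# ---------------------------------------------------------------------------
# Clustering and labeling
# ---------------------------------------------------------------------------

def n_diplotype_clusters(n_alleles: int) -> int:
    return n_alleles * (n_alleles + 1) // 2


def cluster_diplotypes(coords: np.ndarray, n_alleles: int,
                       seed: Optional[int] = None, n_init: int = 20):
    """Seeded k-means with ``k = a(a+1)/2`` on MDS coordinates.

    Returns ``(labels, centroids)``.
    """
    k = n_diplotype_clusters(n_alleles)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < coords.shape[1] and coords.shape[1] > 2:
        coords = coords.T
    n_distinct = len(np.unique(coords.round(12), axis=0))
    if n_distinct < k:
        raise CallingError(
            f"only {n_distinct} distinct points for k={k} clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords)
    return labels, km.cluster_centers_


def label_clusters(labels: np.ndarray, coords: np.ndarray,
                   centroids: np.ndarray, n_alleles: int,
                   sample_ids: Sequence[str],
                   reference_sample: Optional[str] = None,
                   ambiguity_tol: float = 0.05):
    """Map clusters to diplotypes by homozygote-extremes / midpoint geometry.

    The ``a`` homozygote clusters are those whose centroids maximize the sum
    of pairwise distances; every remaining cluster is the heterozygote of the
    homozygote pair whose centroid midpoint is nearest.  The allele of the
    reference sample's homozygote cluster (or, absent a reference, of the
    largest homozygote cluster) is named ``"H1"``; remaining alleles are
    named by decreasing homozygote-cluster size.

    A heterozygote centroid whose two nearest midpoints are closer together
    than ``ambiguity_tol`` × (midpoint-distance scale) is flagged ambiguous
    and its calls marked low confidence.
    """
    k = n_diplotype_clusters(n_alleles)
    if centroids.shape[0] != k:
        raise CallingError(f"expected {k} clusters, got {centroids.shape[0]}")
    # homozygote clusters: max total pairwise centroid distance
    best, best_score = None, -np.inf
    for combo in itertools.combinations(range(k), n_alleles):
        sub = centroids[list(combo)]
        score = pdist(sub).sum() if len(combo) > 1 else 0.0
        if score > best_score:
            best, best_score = combo, score
    hom_clusters = list(best)

    # allele naming: reference's cluster (if homozygote) first, then by size
    sizes = np.bincount(labels, minlength=k)
    order = sorted(hom_clusters, key=lambda c: -sizes[c])
    if reference_sample is not None:
        ref_cluster = int(labels[list(sample_ids).index(reference_sample)])
        if ref_cluster in order:
            order.remove(ref_cluster)
            order.insert(0, ref_cluster)
        else:
            logger.warning(
                "reference sample %s is not in a homozygote cluster; "
                "falling back to largest-cluster naming", reference_sample)
    allele_names = tuple(f"H{i + 1}" for i in range(n_alleles))
    hom_map = {allele_names[i]: c for i, c in enumerate(order)}

    # heterozygote clusters: nearest homozygote-pair midpoint
    pairs = list(itertools.combinations(range(n_alleles), 2))
    midpoints = np.array([
        (centroids[hom_map[allele_names[i]]] + centroids[hom_map[allele_names[j]]]) / 2
        for i, j in pairs])
    centroid_diplotypes: Dict[int, Tuple[str, str]] = {
        c: (a, a) for a, c in hom_map.items()}
    ambiguous = []
    het_clusters = [c for c in range(k) if c not in hom_clusters]
    if het_clusters:
        dmid = cdist(centroids[het_clusters], midpoints)
        scale = pdist(centroids[hom_clusters]).mean() if n_alleles > 1 else 1.0
        for row, c in enumerate(het_clusters):
            ranked = np.argsort(dmid[row])
            i, j = pairs[ranked[0]]
            centroid_diplotypes[c] = tuple(sorted((allele_names[i], allele_names[j])))
            if len(ranked) > 1 and (dmid[row, ranked[1]] - dmid[row, ranked[0]]) < ambiguity_tol * scale:
                ambiguous.append(c)

    dists = np.linalg.norm(coords - centroids[labels], axis=1)
    low_conf = np.isin(labels, ambiguous)
    calls = DiplotypeCalls(
        sample_ids=list(sample_ids),
        pairs=[centroid_diplotypes[int(c)] for c in labels],
        allele_names=allele_names,
        cluster_ids=np.asarray(labels),
        quality=dists,
        low_confidence=low_conf,
    )
    model = ClusterModel(
        coords=coords, centroids=centroids,
        centroid_diplotypes=centroid_diplotypes,
        homozygote_clusters=hom_map,
        hwe_pvalues={a: hwe_test(genotype_counts(calls, a))[1] for a in allele_names},
        ambiguous_clusters=tuple(ambiguous),
    )
    return calls, model


# ---------------------------------------------------------------------------
# Hardy–Weinberg
# ---------------------------------------------------------------------------

def genotype_counts(calls: DiplotypeCalls, allele: str):
    """(n_non-carrier, n_heterozygote, n_homozygote) for one allele."""
    dose = calls.dosage(allele).astype(int)
    return (int((dose == 0).sum()), int((dose == 1).sum()), int((dose == 2).sum()))


def hwe_test(counts):
    """1-df chi-square Hardy–Weinberg test on (n0, n1, n2) genotype counts.

    Returns ``(chi_square, p_value)`` against the p², 2pq, q² expectations
    at the observed allele frequency.
    """
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n == 0:
        raise CallingError("no informative samples for HWE test")
    q = (2 * n2 + n1) / (2 * n)
    p = 1 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    if q in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: trivially in equilibrium
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((observed - expected) ** 2 / expected))
    return chi2, float(chi2_dist.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Tag SNPs
# ---------------------------------------------------------------------------

def discover_tag_snps(calls: DiplotypeCalls, gm: GenotypeMatrix,
                      r2_threshold: float = 0.9) -> pd.DataFrame:
    """SNPs whose dosage tags an allele's dosage at r² ≥ threshold.

    Returns a DataFrame (allele, snp_id, pos, r2, sign); ``sign`` is the
    sign of the correlation, so an oriented tag dosage is ``alt_dose`` when
    positive and ``2 − alt_dose`` when negative.  Monomorphic SNPs are
    skipped.
    """
    if list(calls.sample_ids) != list(gm.sample_ids):
        gm = gm.subset_samples(calls.sample_ids)
    dos = gm.dosages()
    rows = []
    for allele in calls.allele_names:
        y = calls.dosage(allele)
        if np.nanstd(y) == 0:
            continue
        for j in range(gm.n_variants):
            x = dos[:, j]
            ok = ~np.isnan(x)
            if ok.sum() < 2 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            if r * r >= r2_threshold:
                rows.append((allele, gm.variants["id"].iloc[j],
                             int(gm.variants["pos"].iloc[j]), float(r * r),
                             1 if r >= 0 else -1))
    return pd.DataFrame(rows, columns=["allele", "snp_id", "pos", "r2", "sign"])


# ---------------------------------------------------------------------------
# 1-D sparse-panel fallback
# ---------------------------------------------------------------------------

def call_1d_fallback(gm: GenotypeMatrix, tag_snp_panel: Sequence[str],
                     allele_map: Dict[str, Tuple[str, int]],
                     third_allele: str = "H3",
                     seed: Optional[int] = None) -> Tuple[DiplotypeCalls, ClusterModel]:
    """Call diplotypes from a sparse tag-SNP panel on one MDS component.

    ``allele_map`` maps each panel SNP id to ``(allele_name, sign)`` — which
    of the two panel-resolvable alleles it tags and its orientation (as
    reported by :func:`discover_tag_snps`).  The first MDS component of the
    panel dosages must show the expected five-cluster pattern (for three
    alleles, two resolvable); each sample's dosages of the two resolvable
    alleles are then read off its oriented tag dosages and snapped to the
    nearest valid diplotype, the third allele's homozygotes emerging as the
    samples carrying zero copies of both resolvable alleles.
    """
    if not tag_snp_panel:
        raise CallingError("empty tag-SNP panel")
    ids = list(gm.variants["id"])
    missing = [s for s in tag_snp_panel if s not in ids]
    if missing:
        raise CallingError(f"panel SNPs absent from genotypes: {missing}")
    tag_snp_panel = sorted(set(tag_snp_panel), key=ids.index)
    sub = gm.subset_variants(np.array([ids.index(s) for s in tag_snp_panel]))

    resolvable = sorted({a for a, _ in allele_map.values()})
    if len(resolvable) != 2:
        raise CallingError(
            f"1-D fallback needs exactly 2 panel-resolvable alleles, got {resolvable}")
    a_name, b_name = resolvable
    allele_names = tuple(sorted([a_name, b_name, third_allele]))

    coords = mds_embed(sub, n_components=1)
    comp1 = coords[:, 0].reshape(-1, 1)
    scale = max(np.ptp(comp1), 1.0)
    distinct = np.unique(np.round(comp1[:, 0] / scale, 4))
    if len(distinct) < 5:
        raise CallingError(
            "fewer than 5 occupied clusters on the first MDS component; "
            "use 2-D calling")
    k5 = KMeans(n_clusters=5, n_init=20, random_state=seed)
    labels = k5.fit_predict(comp1)
    if len(np.unique(labels)) < 5:
        raise CallingError(
            "fewer than 5 occupied clusters on the first MDS component; "
            "use 2-D calling")

    dos = sub.dosages()
    oriented = {a_name: [], b_name: []}
    for j, snp in enumerate(tag_snp_panel):
        allele, sign = allele_map[snp]
        oriented[allele].append(dos[:, j] if sign > 0 else 2.0 - dos[:, j])
    mean_dose = {a: np.nanmean(np.vstack(v), axis=0) for a, v in oriented.items()}

    valid = [(a, b) for a in range(3) for b in range(3 - a)]  # doses of (A, B)
    pairs, low_conf = [], []
    for da, db in zip(mean_dose[a_name], mean_dose[b_name]):
        if np.isnan(da) or np.isnan(db):
            pairs.append((third_allele, third_allele))
            low_conf.append(True)
            continue
        errs = [(da - a) ** 2 + (db - b) ** 2 for a, b in valid]
        a, b = valid[int(np.argmin(errs))]
        geno = [a_name] * a + [b_name] * b + [third_allele] * (2 - a - b)
        pairs.append(tuple(sorted(geno)))
        low_conf.append(min(errs) > 0.25)

    quality = np.abs(comp1[:, 0] - k5.cluster_centers_[labels, 0])
    calls = DiplotypeCalls(
        sample_ids=list(gm.sample_ids), pairs=pairs, allele_names=allele_names,
        cluster_ids=labels, quality=quality,
        low_confidence=np.array(low_conf),
    )
    # cluster -> modal called diplotype, for reporting
    cdip = {}
    for c in range(5):
        members = [pairs[i] for i in np.flatnonzero(labels == c)]
        cdip[c] = max(set(members), key=members.count) if members else None
    model = ClusterModel(
        coords=comp1, centroids=k5.cluster_centers_,
        centroid_diplotypes=cdip, homozygote_clusters={},
        hwe_pvalues={a: hwe_test(genotype_counts(calls, a))[1]
                     for a in allele_names},
    )
    return calls, model


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class DiplotypeCaller:
    """Call block diplotypes by 2-D MDS + k-means with geometric labeling.

    Parameters
    ----------
    n_alleles : int
        Declared haplotype alleles at the block (2 or 3); k-means uses
        ``k = n_alleles(n_alleles+1)/2`` clusters.
    region : str, optional
        ``chrom:start-end`` restriction (1-based inclusive).
    reference_sample : str, optional
        Sample whose homozygote cluster's allele is named ``"H1"``
        (e.g. a reference-genome pseudo-sample).
    n_init : int
        Seeded k-means restarts (default 20).
    random_state : int, optional

    Attributes
    ----------
    embedding_ : (n_samples, 2) MDS coordinates.
    cluster_model_ : :class:`ClusterModel` with centroids, labels and HWE.
    calls_ : :class:`DiplotypeCalls` for the fitted samples.
    """

    def __init__(self, n_alleles=3, region=None, reference_sample=None,
                 n_init=20, random_state=None, ambiguity_tol=0.05):
        self.n_alleles = n_alleles
        self.region = region
        self.reference_sample = reference_sample
        self.n_init = n_init
        self.random_state = random_state
        self.ambiguity_tol = ambiguity_tol

    def get_params(self, deep=True):
        return {"n_alleles": self.n_alleles, "region": self.region,
                "reference_sample": self.reference_sample,
                "n_init": self.n_init, "random_state": self.random_state,
                "ambiguity_tol": self.ambiguity_tol}

    def set_params(self, **params):
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, gm: GenotypeMatrix):
        coords = mds_embed(gm, region=self.region, n_components=2,
                           reference_sample=self.reference_sample)
        labels, centroids = cluster_diplotypes(
            coords, self.n_alleles, seed=self.random_state, n_init=self.n_init)
        calls, model = label_clusters(
            labels, coords, centroids, self.n_alleles, gm.sample_ids,
            reference_sample=self.reference_sample,
            ambiguity_tol=self.ambiguity_tol)
        self.embedding_ = coords
        self.cluster_model_ = model
        self.calls_ = calls
        return self

    def fit_predict(self, gm: GenotypeMatrix) -> DiplotypeCalls:
        return self.fit(gm).calls_


class TagPanelCaller:
    """1-D sparse-panel fallback caller (five clusters, two resolvable alleles).

    Parameters mirror :func:`call_1d_fallback`; fitted attributes are
    ``calls_`` and ``cluster_model_``.
    """

    def __init__(self, tag_snp_panel=(), allele_map=None, third_allele="H3",
                 random_state=None):
        self.tag_snp_panel = tag_snp_panel
        self.allele_map = allele_map
        self.third_allele = third_allele
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"tag_snp_panel": self.tag_snp_panel,
                "allele_map": self.allele_map,
                "third_allele": self.third_allele,
                "random_state": self.random_state}

    def set_params(self, **params):
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, gm: GenotypeMatrix):
        calls, model = call_1d_fallback(
            gm, list(self.tag_snp_panel), dict(self.allele_map or {}),
            third_allele=self.third_allele, seed=self.random_state)
        self.calls_ = calls
        self.cluster_model_ = model
        return self

    def fit_predict(self, gm: GenotypeMatrix) -> DiplotypeCalls:
        return self.fit(gm).calls_


def call_accuracy(calls: DiplotypeCalls, truth) -> float:
    """Fraction of samples whose called diplotype matches truth.

    Called allele names are arbitrary labels; accuracy is maximized over all
    bijections between called alleles and true clade ids.
    """
    true_pairs = truth.diplotypes if hasattr(truth, "diplotypes") else list(truth)
    if len(true_pairs) != len(calls):
        raise CallingError("calls and truth differ in sample count")
    clade_ids = sorted({c for p in true_pairs for c in p})
    best = 0.0
    for perm in itertools.permutations(calls.allele_names, len(clade_ids)):
        mapping = dict(zip(clade_ids, perm))
        hits = sum(
            tuple(sorted((mapping[t[0]], mapping[t[1]]))) == c
            for t, c in zip(true_pairs, calls.pairs))
        best = max(best, hits / len(calls))
    return best
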