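"""Population-genetic characterization of called haplotype alleles.

Frequencies and Hardy–Weinberg screening per population, LD-based tagging,
Weir–Cockerham FST, permutation nulls for recombination-rate depression and
clinal frequency gradients, great-circle distances along waypoint routes,
and Hamming-distance neighbor-joining phylogeny with outgroup assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calling import DiplotypeCalls
from .io import MISSING, PopulationTable, RecombinationMap

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class PopgenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Frequencies & LD
# ---------------------------------------------------------------------------

def allele_frequencies_by_population(calls: DiplotypeCalls,
                                     pop_labels: Sequence[str]) -> pd.DataFrame:
    """Per-population frequency of each called allele, with denominators."""
    if len(pop_labels) != len(calls):
        raise PopgenError("pop_labels length does not match calls")
    df = pd.DataFrame({"pop": list(pop_labels)})
    for a in calls.allele_names:
        df[a] = calls.dosage(a)
    rows = []
    for pop, grp in df.groupby("pop", sort=True):
        n = len(grp)
        if n == 0:
            logger.warning("population %s empty; excluded", pop)
            continue
        row = {"pop_code": pop, "n_samples": n}
        for a in calls.allele_names:
            row[f"freq_{a}"] = grp[a].sum() / (2 * n)
        rows.append(row)
    return pd.DataFrame(rows)


def ld_r2(dosage_x, dosage_y) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Pairs with a missing (NaN) value are dropped; constant vectors are an
    error (r² undefined).
    """
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise PopgenError("fewer than 2 paired non-missing observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PopgenError("r^2 undefined for a constant dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def fst_two_level(dosages, pop_labels) -> float:
    """Weir–Cockerham (1984) FST for one biallelic locus across populations.

    ``dosages`` are per-individual allele counts (0/1/2, NaN missing);
    multi-allelic blocks are folded per allele by the caller.  Uses the
    genotype-based estimator with variance components a (among populations),
    b (among individuals within populations) and c (within individuals):
    θ = a / (a + b + c).
    """
    d = np.asarray(dosages, dtype=float)
    labels = np.asarray(pop_labels)
    ok = ~np.isnan(d)
    d, labels = d[ok], labels[ok]
    pops = np.unique(labels)
    n_i, p_i, h_i = [], [], []
    for pop in pops:
        g = d[labels == pop]
        if len(g) < 2:
            continue
        n_i.append(len(g))
        p_i.append(g.mean() / 2.0)
        h_i.append(np.mean(g == 1))
    r = len(n_i)
    if r < 2:
        raise PopgenError("FST needs >= 2 populations with >= 2 samples each")
    n_i = np.array(n_i, dtype=float)
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    n_tot = n_i.sum()
    nbar = n_tot / r
    nc = (n_tot - (n_i ** 2).sum() / n_tot) / (r - 1)
    pbar = (n_i * p_i).sum() / n_tot
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / n_tot

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return 0.0  # monomorphic overall: no differentiation measurable
    return float(a / denom)


# ---------------------------------------------------------------------------
# Recombination rate
# ---------------------------------------------------------------------------

def _cum_cm_at(rmap: RecombinationMap, pos) -> np.ndarray:
    """Cumulative genetic map (cM) at arbitrary positions, piecewise linear."""
    return np.interp(np.asarray(pos, dtype=float),
                     rmap.positions.astype(float), rmap.cum_cm)


def mean_recombination_rate(rmap: RecombinationMap, interval_bp) -> float:
    """Length-weighted mean rate (cM/Mb) over a 1-based inclusive interval.

    Equals Δ(cumulative map) / Δ(physical length), which is exactly the
    length-weighted mean of the map's per-interval rates.
    """
    start, end = int(interval_bp[0]), int(interval_bp[1])
    if end <= start:
        raise PopgenError(f"zero- or negative-length interval ({start}, {end})")
    lo, hi = rmap.span
    if start < lo or end > hi:
        raise PopgenError(
            f"interval ({start}, {end}) outside map span ({lo}, {hi})")
    dcm = _cum_cm_at(rmap, end) - _cum_cm_at(rmap, start)
    return float(dcm / ((end - start) / 1e6))


@dataclass
class PermutationNull:
    """Observed statistic, resampled null and empirical tail p-value.

    ``empirical_p = (#{null in tail of observed} + 1) / (n + 1)``, so p is
    never zero.
    """

    observed: float
    null_values: np.ndarray
    tail: str  # "lower" | "upper"
    exhaustive: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tail not in ("lower", "upper"):
            raise PopgenError(f"tail must be 'lower' or 'upper', got {self.tail!r}")
        self.null_values = np.asarray(self.null_values, dtype=float)

    @property
    def n_resamples(self) -> int:
        return len(self.null_values)

    @property
    def empirical_p(self) -> float:
        if self.tail == "lower":
            k = int((self.null_values <= self.observed).sum())
        else:
            k = int((self.null_values >= self.observed).sum())
        return (k + 1) / (self.n_resamples + 1)


def recomb_rate_permutation_test(rmap: RecombinationMap, interval_bp,
                                 n_resamples: int = 10_000,
                                 seed: Optional[int] = None,
                                 tail: str = "lower",
                                 exhaustive: Optional[bool] = None) -> PermutationNull:
    """Is the interval's mean recombination rate unusually low?

    The null resamples ``n_resamples`` same-length segments with uniformly
    random integer start over the map span (the observed segment is not
    excluded).  With ``exhaustive=True`` — or automatically when the number
    of possible starts is at most ``n_resamples`` — every possible start is
    enumerated once instead.
    """
    if n_resamples < 1:
        raise PopgenError("n_resamples must be >= 1")
    start, end = int(interval_bp[0]), int(interval_bp[1])
    length = end - start
    lo, hi = rmap.span
    if length <= 0 or length >= hi - lo:
        raise PopgenError("interval length must be positive and below the map span")
    observed = mean_recombination_rate(rmap, (start, end))
    n_possible = hi - length - lo + 1
    if exhaustive is None:
        exhaustive = n_possible <= n_resamples
    if exhaustive:
        starts = np.arange(lo, hi - length + 1)
    else:
        rng = np.random.default_rng(seed)
        starts = rng.integers(lo, hi - length + 1, size=n_resamples)
    dcm = _cum_cm_at(rmap, starts + length) - _cum_cm_at(rmap, starts)
    null = dcm / (length / 1e6)
    return PermutationNull(observed=observed, null_values=null, tail=tail,
                           exhaustive=bool(exhaustive),
                           extra={"length_bp": length})


# ---------------------------------------------------------------------------
# Clinal distribution
# ---------------------------------------------------------------------------

def _regression_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R² of the simple linear regression of y on x."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clinal_permutation_test(target_freqs, distances_km, null_snp_pool: pd.DataFrame,
                            target_origin_freq: float,
                            match_tolerance: float = 0.02,
                            n_resamples: int = 10_000,
                            seed: Optional[int] = None) -> PermutationNull:
    """Does distance from the origin explain a haplotype's frequencies more
    than expected under drift?

    The observed statistic is the R² of the regression of per-population
    frequency on distance.  The null is the same R² for pool SNPs whose
    origin-region mean frequency is within ``match_tolerance`` of the
    target's (frequency matching controls the drift expectation).  The pool
    DataFrame needs one row per SNP: an ``origin_freq`` column plus one
    frequency column per population, in the same order as ``distances_km``.
    Upper-tail empirical p with the (k+1)/(n+1) convention.
    """
    if isinstance(target_freqs, PopulationTable):
        target_freqs = target_freqs.table["allele_freq"].to_numpy()
    y = np.asarray(target_freqs, dtype=float)
    x = np.asarray(distances_km, dtype=float)
    if len(y) != len(x):
        raise PopgenError("frequencies and distances differ in length")
    observed = _regression_r2(x, y)

    if "origin_freq" not in null_snp_pool.columns:
        raise PopgenError("null_snp_pool needs an 'origin_freq' column")
    freq_cols = [c for c in null_snp_pool.columns if c != "origin_freq"]
    if len(freq_cols) != len(x):
        raise PopgenError(
            f"pool has {len(freq_cols)} population columns, expected {len(x)}")
    matched = null_snp_pool[
        (null_snp_pool["origin_freq"] - target_origin_freq).abs() <= match_tolerance]
    if matched.empty:
        raise PopgenError(
            f"no pool SNP matches origin frequency {target_origin_freq} "
            f"within {match_tolerance}")
    rng = np.random.default_rng(seed)
    exhaustive = len(matched) <= n_resamples
    if exhaustive:
        if len(matched) < n_resamples:
            logger.warning(
                "matched pool (%d) smaller than n_resamples (%d); "
                "using each matched SNP once", len(matched), n_resamples)
        sel = matched
    else:
        sel = matched.iloc[rng.choice(len(matched), size=n_resamples, replace=False)]
    F = sel[freq_cols].to_numpy(dtype=float)
    xc = x - x.mean()
    yc = F - F.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (yc @ xc) / denom, 0.0)
    return PermutationNull(observed=observed, null_values=r ** 2, tail="upper",
                           exhaustive=exhaustive,
                           extra={"n_matched": len(matched)})


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance (km) on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise PopgenError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise PopgenError(f"longitude {lon} outside [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def waypoint_distance(origin_lat_lon: Tuple[float, float],
                      pop_lat_lon: Tuple[float, float],
                      waypoints: Sequence[Tuple[float, float]] = ()) -> float:
    """Distance origin → waypoints → population as summed great-circle legs.

    Waypoint routes model migration paths that detour around major water
    masses rather than crossing them.
    """
    path = [origin_lat_lon, *waypoints, pop_lat_lon]
    return float(sum(
        haversine_km(a[0], a[1], b[0], b[1]) for a, b in zip(path, path[1:])))


# Default waypoint routes (lat, lon) keyed by continent code, approximating
# overland out-of-Africa expansion paths; origin Addis Ababa (9.03N, 38.74E).
ETHIOPIA = (9.03, 38.74)
DEFAULT_WAYPOINTS: Dict[str, tuple] = {
    "AFR": (),
    "EUR": ((30.0, 31.0),),                     # Cairo
    "SAS": ((30.0, 31.0), (27.0, 60.0)),        # Cairo, south Iran
    "EAS": ((30.0, 31.0), (27.0, 60.0), (25.0, 90.0)),   # + Bengal
    "AMR": ((30.0, 31.0), (27.0, 60.0), (61.0, 130.0), (64.0, -168.0)),  # + Siberia, Bering
}


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def hamming_matrix(sequences) -> np.ndarray:
    """Pairwise counts of differing sites; missing alleles dropped pairwise.

    ``sequences`` is a list of equal-length allele vectors (0/1/-1 for
    missing) or strings (with ``N`` for missing).
    """
    seqs = []
    for s in sequences:
        if isinstance(s, str):
            seqs.append(np.array([MISSING if ch in "Nn?." else int(ch) for ch in s]))
        else:
            seqs.append(np.asarray(s, dtype=int))
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise PopgenError(f"sequence lengths differ: {sorted(lengths)}")
    arr = np.vstack(seqs)
    valid = arr != MISSING
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            D[i, j] = D[j, i] = int((arr[i, ok] != arr[j, ok]).sum())
    return D


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted Newick string.

    Ties in the Q-matrix are broken by the lexicographically lowest index
    pair; negative branch lengths are clamped to 0 with the deficit moved to
    the sister branch.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise PopgenError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise PopgenError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 2:
        raise PopgenError("need >= 2 taxa")
    nodes = [str(l) for l in labels]
    if len(nodes) != n:
        raise PopgenError("label count does not match matrix size")
    if n == 2:
        h = D[0, 1] / 2
        return f"({nodes[0]}:{h:.6f},{nodes[1]}:{h:.6f});"

    D = D.copy()
    active = list(range(n))
    newick = {i: nodes[i] for i in range(n)}

    def fmt(x):
        return f"{max(x, 0.0):.6f}"

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest index pair on ties
        best = np.unravel_index(np.argmin(q), q.shape)
        i_, j_ = sorted(best)
        i, j = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (totals[i_] - totals[j_]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = D.shape[0]
        drow = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new, active] = drow
        D[active, new] = drow
        D[new, new] = 0.0
        newick[new] = f"({newick[i]}:{fmt(li)},{newick[j]}:{fmt(lj)})"
        active = [a for a in active if a not in (i, j)] + [new]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    # clamp negatives, deficit to the sister branches of the final star
    ls = [la, lb, lc]
    for idx in range(3):
        if ls[idx] < 0:
            for other in range(3):
                if other != idx:
                    ls[other] += ls[idx] / 2
            ls[idx] = 0.0
    return (f"({newick[a]}:{fmt(ls[0])},{newick[b]}:{fmt(ls[1])},"
            f"{newick[c]}:{fmt(ls[2])});")


def consensus_sequence(haplotypes: np.ndarray) -> np.ndarray:
    """Per-site majority allele over a set of haplotypes (ties → 1)."""
    h = np.asarray(haplotypes)
    valid = h != MISSING
    with np.errstate(invalid="ignore"):
        frac = np.where(valid, h, 0).sum(axis=0) / np.maximum(valid.sum(axis=0), 1)
    return (frac >= 0.5).astype(np.int8)


@dataclass
class OutgroupAssignment:
    clade: Optional[str]
    distances: Dict[str, float]
    ambiguous: bool


def assign_outgroup(outgroup_sequence, clade_consensus: Dict[str, np.ndarray]) -> OutgroupAssignment:
    """Nearest clade (Hamming) for an outgroup sequence; ties flagged."""
    seqs = [outgroup_sequence] + list(clade_consensus.values())
    D = hamming_matrix(seqs)
    names = list(clade_consensus.keys())
    dists = {name: float(D[0, k + 1]) for k, name in enumerate(names)}
    dmin = min(dists.values())
    nearest = [name for name, d in dists.items() if d == dmin]
    if len(nearest) > 1:
        return OutgroupAssignment(clade=None, distances=dists, ambiguous=True)
    return OutgroupAssignment(clade=nearest[0], distances=dists, ambiguous=False)
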