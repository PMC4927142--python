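"""Readers, writers and containers for the external formats the pipeline consumes.

All genomic coordinates are 1-based inclusive (the VCF convention); region
strings like ``"15:1600000-1998000"`` are parsed the same way.  Missing
alleles are encoded as ``-1`` in the haplotype matrix and propagate: any
statistic touching a missing allele drops that chromosome/sample from its
denominator rather than imputing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class DataError(ValueError):
    """Raised when an input file violates a format contract."""


@dataclass
class GenotypeMatrix:
    """Phased biallelic SNP haplotypes for a set of samples.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per diploid sample.
    variants : pandas.DataFrame
        Columns ``chrom, pos, id, ref, alt``; positions strictly increasing
        within a chromosome.
    alleles : ndarray of int8, shape (2 * n_samples, n_variants)
        Two haplotype rows per sample, in phase order; entries are 0, 1 or
        ``MISSING`` (-1).
    pop_labels : list of str, optional
        Per-sample population code.
    """

    sample_ids: list
    variants: pd.DataFrame
    alleles: np.ndarray
    pop_labels: Optional[list] = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise DataError(
                f"allele matrix has {self.alleles.shape[0]} rows; expected "
                f"{2 * len(self.sample_ids)} (two per sample)"
            )
        if self.alleles.shape[1] != len(self.variants):
            raise DataError("allele matrix width does not match variant count")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise DataError("alleles must be 0, 1 or missing (-1)")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise DataError(f"positions not strictly increasing on {chrom}")
        if self.pop_labels is not None and len(self.pop_labels) != len(self.sample_ids):
            raise DataError("pop_labels length does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def dosages(self) -> np.ndarray:
        """Per-sample ALT dosage (0/1/2), NaN where either allele is missing."""
        a = self.alleles.astype(float)
        a[a == MISSING] = np.nan
        return a[0::2] + a[1::2]

    def subset_variants(self, mask) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask)) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            alleles=self.alleles[:, idx],
            pop_labels=None if self.pop_labels is None else list(self.pop_labels),
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise DataError(f"unknown sample ids: {missing[:5]}")
        rows = np.concatenate([[2 * lookup[s], 2 * lookup[s] + 1] for s in ids])
        return GenotypeMatrix(
            sample_ids=list(ids),
            variants=self.variants.copy(),
            alleles=self.alleles[rows],
            pop_labels=None
            if self.pop_labels is None
            else [self.pop_labels[lookup[s]] for s in ids],
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Variants with ``chrom`` and ``start <= pos <= end`` (1-based inclusive)."""
        v = self.variants
        mask = (v["chrom"].astype(str) == str(chrom)) & (v["pos"] >= start) & (v["pos"] <= end)
        return self.subset_variants(mask.to_numpy())


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices over the same variants into one sample set."""
    if not a.variants[VARIANT_COLUMNS].equals(b.variants[VARIANT_COLUMNS]):
        raise DataError("cannot concatenate: variant tables differ")
    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        raise DataError(f"duplicate sample ids: {sorted(dup)[:5]}")
    pops = None
    if a.pop_labels is not None and b.pop_labels is not None:
        pops = list(a.pop_labels) + list(b.pop_labels)
    return GenotypeMatrix(
        sample_ids=list(a.sample_ids) + list(b.sample_ids),
        variants=a.variants.copy(),
        alleles=np.vstack([a.alleles, b.alleles]),
        pop_labels=pops,
    )


@dataclass
class PedigreeTable:
    """Trio definitions: one (child, father, mother) id triple per row."""

    trios: list  # of (child_id, father_id, mother_id)

    def __post_init__(self):
        for child, father, mother in self.trios:
            if child == father or child == mother:
                raise DataError(f"sample {child!r} listed as its own parent")

    def __len__(self):
        return len(self.trios)


@dataclass
class RecombinationMap:
    """HapMap-style genetic map: position, local rate (cM/Mb), cumulative cM."""

    positions: np.ndarray
    rates_cm_per_mb: np.ndarray
    cum_cm: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates_cm_per_mb = np.asarray(self.rates_cm_per_mb, dtype=float)
        self.cum_cm = np.asarray(self.cum_cm, dtype=float)
        if len(self.positions) == 0:
            raise DataError("empty recombination map")
        if not (np.diff(self.positions) > 0).all():
            raise DataError("map positions not strictly increasing")
        if (np.diff(self.cum_cm) < -1e-9).any():
            raise DataError("cumulative map decreases")
        if (self.rates_cm_per_mb < 0).any():
            raise DataError("negative recombination rate")

    @property
    def span(self):
        return int(self.positions[0]), int(self.positions[-1])


@dataclass
class PopulationTable:
    """Per-population sample sizes, coordinates and allele frequency."""

    table: pd.DataFrame  # pop_code, n_samples, [latitude, longitude, distance_km, allele_freq]

    def __post_init__(self):
        t = self.table
        for col in ("pop_code", "n_samples"):
            if col not in t.columns:
                raise DataError(f"population table missing column {col!r}")
        if (t["n_samples"] < 1).any():
            raise DataError("population with n_samples < 1")
        if "allele_freq" in t.columns:
            f = t["allele_freq"].dropna()
            if ((f < 0) | (f > 1)).any():
                raise DataError("allele frequency outside [0, 1]")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(region: str):
    m = _REGION_RE.match(region)
    if not m:
        raise DataError(f"malformed region {region!r}; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start > end:
        raise DataError(f"region start after end in {region!r}")
    return chrom, start, end


def read_phased_vcf(path, region: Optional[str] = None, phase_required: bool = True) -> GenotypeMatrix:
    """Read phased diploid GT fields from a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNPs are retained; multi-allelic and indel records are
    skipped (a count is logged).  ``region`` is ``chrom:start-end``, 1-based
    inclusive on POS.  With ``phase_required``, the first record carrying an
    unphased non-missing heterozygous or homozygous genotype raises an error
    naming it; set it false for data phased by construction elsewhere.
    """
    from cyvcf2 import VCF

    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    want = parse_region(region) if region is not None else None

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows, haps = [], []
    n_skipped = 0
    for var in vcf:
        if want is not None:
            chrom, start, end = want
            if str(var.CHROM) != chrom or not (start <= var.POS <= end):
                continue
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(gts):
            a0, a1 = gt[0], gt[1]
            phased = bool(gt[-1])
            if phase_required and not phased and a0 >= 0 and a1 >= 0:
                raise DataError(
                    f"unphased genotype for sample {sample_ids[i]} at "
                    f"{var.CHROM}:{var.POS} ({var.ID or '.'})"
                )
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        rows.append((str(var.CHROM), int(var.POS), var.ID or ".", var.REF, var.ALT[0]))
        haps.append(col)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise DataError(f"no biallelic SNP records in {path}" + (f" for region {region}" if region else ""))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    alleles = np.column_stack(haps)
    # coordinate-sort so region queries do not depend on record order
    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    variants = variants.iloc[order].reset_index(drop=True)
    alleles = alleles[:, order]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, alleles=alleles)


def write_phased_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal phased VCF 4.2 for a :class:`GenotypeMatrix`."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, gm.sample_ids)) + "\n")
        sym = {0: "0", 1: "1", MISSING: "."}
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            gts = "\t".join(
                f"{sym[int(gm.alleles[2 * i, j])]}|{sym[int(gm.alleles[2 * i + 1, j])]}"
                for i in range(gm.n_samples)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------

def minor_allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant MAF over non-missing alleles; NaN for all-missing sites."""
    a = gm.alleles
    valid = a != MISSING
    with np.errstate(invalid="ignore"):
        alt = np.where(valid, a, 0).sum(axis=0) / valid.sum(axis=0)
    return np.minimum(alt, 1.0 - alt)


def filter_by_maf(gm: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop variants with minor allele frequency below ``threshold``."""
    if not 0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    if threshold == 0:
        return gm
    maf = minor_allele_frequencies(gm)
    keep = maf >= threshold
    if not keep.any():
        raise DataError(
            f"MAF filter at {threshold} removed every variant; lower the threshold"
        )
    return gm.subset_variants(keep)


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------

def read_recombination_map(path) -> RecombinationMap:
    """Read a HapMap-format rate file: position, cM/Mb rate, cumulative cM.

    Whitespace-delimited, one header line.  Checks the arithmetic consistency
    Δcum / Δpos × 10⁶ ≈ rate and warns on intervals where it fails.
    """
    pos, rate, cum = [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise DataError(f"empty recombination map file {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected 3 columns")
            p, r, c = int(float(parts[0])), float(parts[1]), float(parts[2])
            if pos and p <= pos[-1]:
                raise DataError(f"{path}:{lineno}: position {p} not increasing")
            if r < 0:
                raise DataError(f"{path}:{lineno}: negative rate {r}")
            pos.append(p); rate.append(r); cum.append(c)
    if not pos:
        raise DataError(f"no data rows in recombination map {path}")
    rmap = RecombinationMap(np.array(pos), np.array(rate), np.array(cum))
    if len(pos) > 1:
        implied = np.diff(rmap.cum_cm) / np.diff(rmap.positions) * 1e6
        off = np.abs(implied - rmap.rates_cm_per_mb[:-1]) > 0.05
        if off.any():
            logger.warning(
                "recombination map %s: %d interval(s) where cumulative map "
                "disagrees with stated rate", path, int(off.sum()),
            )
    return rmap


def write_recombination_map(rmap: RecombinationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\trate_cM_Mb\tmap_cM\n")
        for p, r, c in zip(rmap.positions, rmap.rates_cm_per_mb, rmap.cum_cm):
            fh.write(f"{p}\t{r:.6f}\t{c:.8f}\n")


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_table(path, required=(), dtypes=None, index_col=None, id_col=None) -> pd.DataFrame:
    """Read a TSV with header, coerce columns and check integrity.

    ``required`` names columns that must be present; ``dtypes`` maps column
    to dtype; ``id_col`` names a column that must hold unique identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    for col in required:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    if dtypes:
        for col, dt in dtypes.items():
            if col in df.columns:
                df[col] = df[col].astype(dt)
    if id_col is not None:
        if df[id_col].duplicated().any():
            dups = df.loc[df[id_col].duplicated(), id_col].tolist()[:5]
            raise DataError(f"{path}: duplicate ids in {id_col!r}: {dups}")
    if index_col is not None and df.index.duplicated().any():
        raise DataError(f"{path}: duplicate index entries")
    return df


def align_samples(df: pd.DataFrame, gm: GenotypeMatrix, id_col: str = "id"):
    """Reorder ``df`` rows to match ``gm.sample_ids``; report unmatched ids."""
    lookup = df.set_index(id_col)
    matched = [s for s in gm.sample_ids if s in lookup.index]
    unmatched_gm = [s for s in gm.sample_ids if s not in lookup.index]
    unmatched_df = [s for s in lookup.index if s not in set(gm.sample_ids)]
    if unmatched_gm or unmatched_df:
        logger.warning(
            "sample alignment: %d genotyped samples without table rows, "
            "%d table rows without genotypes", len(unmatched_gm), len(unmatched_df),
        )
    return lookup.loc[matched].reset_index(), unmatched_gm, unmatched_df


def read_pedigree(path) -> PedigreeTable:
    """Read trios from a 3-column TSV (child, father, mother) or PLINK FAM."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] >= 6:  # FAM: fid iid father mother sex pheno
        trios = [
            (r[1], r[2], r[3])
            for r in df.itertuples(index=False)
            if r[2] not in ("0", "NA") and r[3] not in ("0", "NA")
        ]
    elif df.shape[1] >= 3:
        first = df.iloc[0]
        if list(first[:3]) == ["child", "father", "mother"]:
            df = df.iloc[1:]
        trios = [tuple(r[:3]) for r in df.itertuples(index=False)]
    else:
        raise DataError(f"{path}: expected 3-column trio TSV or PLINK FAM")
    if not trios:
        raise DataError(f"{path}: no complete trios found")
    return PedigreeTable(trios=trios)


def write_pedigree(ped: PedigreeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tfather\tmother\n")
        for c, f, m in ped.trios:
            fh.write(f"{c}\t{f}\t{m}\n")
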