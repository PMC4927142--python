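"""Genotype-phenotype and genotype-expression association.

Diplotype calls are folded to numeric codings — additive (copies of an
allele, 0/1/2) or recessive (homozygote indicator) — and fitted by ordinary
least squares with covariates; per-cohort estimates are pooled by
inverse-variance fixed-effects meta-analysis with Cochran's Q heterogeneity.
Cis-expression scans apply an exact Bonferroni threshold over the genes
tested in the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .calling import DiplotypeCalls

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


def encode_dosage(calls: DiplotypeCalls, allele: str, model: str = "additive") -> np.ndarray:
    """Numeric coding of one allele: additive 0/1/2 or recessive 0/1."""
    dose = calls.dosage(allele)
    if model == "additive":
        return dose
    if model == "recessive":
        return (dose == 2).astype(float)
    raise AssociationError(f"model must be 'additive' or 'recessive', got {model!r}")


def standardize_scores(values) -> np.ndarray:
    """Affine transform to sample mean 100 and SD 15 (IQ convention)."""
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if len(np.unique(finite)) < 2 or finite.std(ddof=0) == 0:
        raise AssociationError("cannot standardize a constant score vector")
    return (x - finite.mean()) / finite.std(ddof=0) * 15.0 + 100.0


@dataclass
class AssociationResult:
    """One dosage-term estimate from a covariate-adjusted OLS fit."""

    beta: float
    se: float
    p: float
    n: int
    model: str
    allele: Optional[str] = None
    cohort: Optional[str] = None
    dropped_covariates: tuple = ()

    def ci95(self):
        return self.beta - 1.959963984540054 * self.se, self.beta + 1.959963984540054 * self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def fit_gaussian_model(y, dosage, covariates: Optional[pd.DataFrame] = None,
                       model: str = "additive", allele: Optional[str] = None,
                       cohort: Optional[str] = None) -> AssociationResult:
    """OLS of a quantitative trait on a dosage term plus covariates.

    Rows with any missing value are dropped.  Covariate columns collinear
    with the rest of the design are dropped with a warning; rank deficiency
    involving the dosage column itself is an error.  The dosage p-value uses
    the t reference with residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if len(y) != len(dosage):
        raise AssociationError("y and dosage differ in length")
    cols = {"dosage": dosage}
    if covariates is not None:
        for c in covariates.columns:
            cols[str(c)] = covariates[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    ok = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[ok], X.loc[ok].reset_index(drop=True)

    design = np.column_stack([np.ones(len(X)), X["dosage"].to_numpy()])
    names = ["const", "dosage"]
    dropped = []
    for c in [c for c in X.columns if c != "dosage"]:
        cand = np.column_stack([design, X[c].to_numpy()])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(design):
            design = cand
            names.append(c)
        else:
            dropped.append(c)
            logger.warning("covariate %r collinear with design; dropped", c)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise AssociationError("design matrix rank deficient")
    if np.linalg.matrix_rank(np.delete(design, 1, axis=1)) == np.linalg.matrix_rank(design):
        raise AssociationError("dosage column collinear with covariates")
    if len(y) <= design.shape[1]:
        raise AssociationError("fewer observations than model parameters")

    fit = sm.OLS(y, pd.DataFrame(design, columns=names)).fit()
    return AssociationResult(
        beta=float(fit.params["dosage"]), se=float(fit.bse["dosage"]),
        p=float(fit.pvalues["dosage"]), n=len(y), model=model,
        allele=allele, cohort=cohort, dropped_covariates=tuple(dropped))


@dataclass
class MetaResult:
    """Inverse-variance fixed-effects pooled estimate with heterogeneity."""

    pooled_beta: float
    pooled_se: float
    z: float
    p: float
    Q: float
    df: int
    p_heterogeneity: float
    weights: np.ndarray
    single_study: bool = False

    def ci95(self):
        return (self.pooled_beta - 1.959963984540054 * self.pooled_se,
                self.pooled_beta + 1.959963984540054 * self.pooled_se)


def meta_fixed_effects(per_study: Sequence) -> MetaResult:
    """Fixed-effects meta-analysis of (beta, se) pairs.

    Weights are the reciprocal estimated variances; the pooled z-test uses
    the normal reference.  Cochran's Q = Σ w (β − pooled)² with k − 1 df is
    always reported; for a single study Q is undefined (df 0, flagged).
    """
    pairs = [(s.beta, s.se) if isinstance(s, AssociationResult) else tuple(s)
             for s in per_study]
    if not pairs:
        raise AssociationError("meta-analysis needs at least one study")
    betas = np.array([b for b, _ in pairs], dtype=float)
    ses = np.array([s for _, s in pairs], dtype=float)
    if (ses <= 0).any():
        raise AssociationError("all standard errors must be positive")
    w = 1.0 / ses ** 2
    pooled = float((w * betas).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    z = pooled / pooled_se
    p = float(2 * norm.sf(abs(z)))
    k = len(pairs)
    if k == 1:
        return MetaResult(pooled, pooled_se, z, p, float("nan"), 0,
                          float("nan"), w, single_study=True)
    Q = float((w * (betas - pooled) ** 2).sum())
    return MetaResult(pooled, pooled_se, z, p, Q, k - 1,
                      float(chi2_dist.sf(Q, df=k - 1)), w)


def eqtl_scan(expression: pd.DataFrame, calls: DiplotypeCalls, allele: str,
              model: str = "additive", alpha: float = 0.05,
              covariates: Optional[pd.DataFrame] = None,
              log_transform: bool = False) -> pd.DataFrame:
    """Per-gene association of expression with an allele coding.

    ``expression`` is genes × samples (columns are sample ids, aligned to
    the calls).  Each gene is regressed on the coded dosage (plus optional
    covariates); the Bonferroni threshold ``alpha / n_genes`` is computed
    exactly and both the raw p and a significance flag are returned.
    Genes with zero expression variance are skipped with a warning.
    """
    cols = [c for c in expression.columns if c in set(calls.sample_ids)]
    if len(cols) < 3:
        raise AssociationError("fewer than 3 samples shared between expression and calls")
    expr = expression[cols]
    sub_idx = [calls.sample_ids.index(c) for c in cols]
    dose_full = encode_dosage(calls, allele, model)[sub_idx]
    cov = covariates.loc[cols] if covariates is not None else None

    threshold = alpha / len(expr)
    rows = []
    for gene, values in expr.iterrows():
        y = values.to_numpy(dtype=float)
        if log_transform:
            if (y <= 0).any():
                logger.warning("gene %s has non-positive values; skipped", gene)
                continue
            y = np.log(y)
        if np.nanstd(y) == 0:
            logger.warning("gene %s has zero expression variance; skipped", gene)
            continue
        res = fit_gaussian_model(y, dose_full, covariates=cov, model=model,
                                 allele=allele)
        rows.append({"gene": gene, "beta": res.beta, "se": res.se,
                     "p": res.p, "n": res.n,
                     "significant": res.p < threshold})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_genes_tested"] = len(rows)
    return out
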