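"""Phenotype and genotype preparation.

Rank-based inverse-normal (quantile) normalization, covariate regression,
principal components of the genome-wide realized relatedness, and
region standardization (MAF filter, mean-0/variance-1 scaling, local
relatedness kernel).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .genosim import DegenerateRegionError, DosageMatrix
from .lmm import RegionGenotypes

__all__ = [
    "quantile_normalize",
    "QuantileNormalizer",
    "compute_pcs",
    "regress_out_covariates",
    "standardize_region",
    "CovariateMatrix",
]


def quantile_normalize(values, offset: float = 0.5) -> np.ndarray:
    """Map ranks to standard-normal quantiles at (rank - offset) / n.

    Ties receive averaged ranks (stable on integer-valued traits).  The
    output depends only on the ranks, so any strictly monotone transform of
    the input yields an identical result.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("constant vector cannot be quantile-normalized")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / values.size)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Per-column rank-based inverse-normal transform (stateless)."""

    def __init__(self, offset: float = 0.5):
        self.offset = offset

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return quantile_normalize(X, self.offset)
        return np.column_stack(
            [quantile_normalize(X[:, j], self.offset) for j in range(X.shape[1])]
        )


class CovariateMatrix:
    """Fixed-effect covariates with provenance labels (intercept/measured/PC)."""

    def __init__(self, values: np.ndarray, labels, kinds):
        self.values = np.asarray(values, dtype=float)
        self.labels = list(labels)
        self.kinds = list(kinds)
        if self.values.ndim != 2 or len(self.labels) != self.values.shape[1]:
            raise ValueError("labels must match column count")
        if self.values.shape[1] and np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("covariates must have full column rank")

    @classmethod
    def build(cls, n: int, measured=None, measured_labels=None, pcs=None):
        """Intercept + optional measured covariates + optional PCs."""
        cols = [np.ones((n, 1))]
        labels = ["intercept"]
        kinds = ["intercept"]
        if measured is not None:
            measured = np.atleast_2d(np.asarray(measured, dtype=float))
            if measured.shape[0] != n:
                measured = measured.T
            cols.append(measured)
            mlab = measured_labels or [f"cov{j}" for j in range(measured.shape[1])]
            labels += list(mlab)
            kinds += ["measured"] * measured.shape[1]
        if pcs is not None:
            pcs = np.asarray(pcs, dtype=float)
            cols.append(pcs)
            labels += [f"PC{j + 1}" for j in range(pcs.shape[1])]
            kinds += ["PC"] * pcs.shape[1]
        return cls(np.hstack(cols), labels, kinds)


def compute_pcs(genomewide: DosageMatrix, n_components: int = 10) -> np.ndarray:
    """Top eigenvectors of the standardized genome-wide realized relatedness.

    Returns unit-norm eigenvectors (N x n_components) with a deterministic
    sign convention: the entry of largest magnitude is made positive.
    """
    X = np.asarray(genomewide.dosages, dtype=float)
    n = X.shape[0]
    if n_components >= n:
        raise ValueError("n_components must be < number of individuals")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    R = Z @ Z.T / Z.shape[1]
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1][:n_components]
    pcs = vecs[:, order]
    for j in range(pcs.shape[1]):
        k = np.argmax(np.abs(pcs[:, j]))
        if pcs[k, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def regress_out_covariates(y, covariates) -> np.ndarray:
    """OLS residuals of y on the covariate columns."""
    y = np.asarray(y, dtype=float).ravel()
    X = covariates.values if isinstance(covariates, CovariateMatrix) else np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        return y.copy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariates")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def standardize_region(raw: DosageMatrix, maf_min: float = 0.02) -> RegionGenotypes:
    """MAF-filter and standardize a region's dosages; derive Rs = G G^T / S.

    Monomorphic variants are dropped before the variant count S is fixed.
    """
    X = np.asarray(raw.dosages, dtype=float)
    freqs = X.mean(axis=0) / 2.0
    sd = X.std(axis=0)
    keep = (freqs >= maf_min) & (freqs <= 1.0 - maf_min) & (sd > 0)
    if not keep.any():
        raise DegenerateRegionError("degenerate region: no variants survive standardization")
    X = X[:, keep]
    G = (X - X.mean(axis=0)) / X.std(axis=0)
    return RegionGenotypes(
        G,
        variant_ids=np.asarray(raw.variant_ids)[keep],
        positions=np.asarray(raw.positions)[keep],
        chrom=raw.chrom,
    )
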