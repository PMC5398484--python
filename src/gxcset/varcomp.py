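"""Variance decomposition, BLUP prediction and enrichment statistics.

The constrained set models decompose the variance explained by a region
into persistent, rescaling-GxC and heterogeneity-GxC parts by nested-fit
attribution: the block model captures only persistent variance, the
rank-one model adds rescaling, and the full model adds heterogeneity.
Because genotypes are standardized and Rs has unit mean diagonal, the
expected per-context variance of the set component equals Cs[c, c].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats
from sklearn.base import BaseEstimator

from .lmm import RegionGenotypes, StudyDesign, fit, _CompleteWorkspace, _StratifiedWorkspace

__all__ = [
    "VarianceDecomposition",
    "decompose",
    "VarianceDecomposer",
    "blup_cis",
    "enrichment_odds_ratio",
]


@dataclass
class VarianceDecomposition:
    """Per-region variance fractions (averaged over contexts)."""

    persistent: float
    rescaling: float
    heterogeneity: float
    total_set: float
    residual: float
    converged: bool
    explained_by_kind: dict

    def as_dict(self) -> dict:
        return dict(
            persistent=self.persistent,
            rescaling=self.rescaling,
            heterogeneity=self.heterogeneity,
            total_set=self.total_set,
            residual=self.residual,
        )


def _explained_fraction(model, design: StudyDesign) -> float:
    """Mean over contexts of Cs[c, c] / total per-context trait variance."""
    C = design.n_contexts
    if design.layout == "complete":
        tot = design.Y.var(axis=0)
    else:
        tot = np.array([design.y[design.contexts == c].var() for c in range(C)])
    return float(np.mean(np.diag(model.Cs) / tot))


def decompose(
    design: StudyDesign,
    region: RegionGenotypes,
    restarts: int = 3,
    seed: int = 0,
) -> VarianceDecomposition:
    """Nested-fit variance decomposition of the set component.

    Fits the block, rank-one and full covariance models; the explained set
    variance is made non-decreasing across the nesting by a cumulative
    maximum (guarding against optimizer noise), so the three attributed
    fractions are non-negative and sum exactly to the total.
    """
    ws = (
        _CompleteWorkspace(design, region)
        if design.layout == "complete"
        else _StratifiedWorkspace(design, region)
    )
    models = {
        k: fit(design, region, cov_kind=k, restarts=restarts, seed=seed, workspace=ws)
        for k in ("block", "rank1", "full")
    }
    fr = {k: _explained_fraction(m, design) for k, m in models.items()}
    m1 = fr["block"]
    m2 = max(m1, fr["rank1"])
    m3 = max(m2, fr["full"])
    total = min(m3, 1.0)
    return VarianceDecomposition(
        persistent=m1,
        rescaling=m2 - m1,
        heterogeneity=m3 - m2,
        total_set=total,
        residual=1.0 - total,
        converged=all(m.converged for m in models.values()),
        explained_by_kind=fr,
    )


class VarianceDecomposer(BaseEstimator):
    """sklearn-style facade: fit(G, Y, F=...) -> fractions_ attribute."""

    def __init__(self, restarts=3, random_state=0):
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, G, Y, F=None, contexts=None, n_contexts=None):
        region = RegionGenotypes(np.asarray(G, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 2:
            design = StudyDesign(layout="complete", Y=Y, F=F)
        else:
            design = StudyDesign(
                layout="stratified", y=Y, contexts=contexts, F=F, n_contexts=n_contexts
            )
        self.decomposition_ = decompose(
            design, region, restarts=self.restarts, seed=self.random_state
        )
        self.fractions_ = self.decomposition_.as_dict()
        return self


def blup_cis(y, K_cis, sigma2_cis: float, V, mu: float = 0.0) -> np.ndarray:
    """Best linear unbiased predictor of cis-genetic values.

    y_cis = sigma2_cis * K_cis * V^-1 * (y - 1 mu), for a single-context
    model with cis variance sigma2_cis, cis relatedness K_cis and total
    covariance V.
    """
    y = np.asarray(y, dtype=float).ravel()
    K_cis = np.asarray(K_cis, dtype=float)
    V = np.asarray(V, dtype=float)
    if sigma2_cis == 0.0:
        return np.zeros_like(y)
    try:
        cho = sla.cho_factor(V, lower=True)
    except sla.LinAlgError as exc:
        raise ValueError("V must be positive definite") from exc
    return sigma2_cis * (K_cis @ sla.cho_solve(cho, y - mu))


def fit_single_context_blup(y, region: RegionGenotypes, restarts: int = 3, seed: int = 0):
    """Fit a univariate set model (C = 1) and return its BLUP.

    Convenience wrapper: estimates sigma2_cis (= Cs) and sigma2_n (= Cn) by
    REML with an intercept, then evaluates the BLUP formula.
    """
    y = np.asarray(y, dtype=float).ravel()
    design = StudyDesign(
        layout="complete", Y=y[:, None], F=np.ones((y.size, 1))
    )
    m = fit(design, region, cov_kind="full", restarts=restarts, seed=seed)
    s2 = float(m.Cs[0, 0])
    s2n = float(m.Cn[0, 0])
    mu = float(m.B[0, 0])
    V = s2 * region.Rs + s2n * np.eye(y.size)
    return blup_cis(y, region.Rs, s2, V, mu)


def enrichment_odds_ratio(table) -> dict:
    """Sample odds ratio and one-sided Fisher exact p for a 2x2 count table.

    Returns the cross-product ratio (a*d)/(b*c) -- infinite with a flag when
    the denominator has a zero cell -- and the hypergeometric one-sided
    p-value for enrichment of the top-left cell.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    a, b, c, d = t.ravel()
    infinite = (b == 0) or (c == 0)
    odds = np.inf if infinite else (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="greater")
    return dict(odds_ratio=float(odds), p_value=float(p), infinite=bool(infinite))
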