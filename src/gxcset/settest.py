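"""Set tests for gene-by-context interactions.

Three likelihood-ratio tests on the trait-context covariance of the set
component, each comparing the full-rank model against a constrained null:

* association test (field name mtSet): full vs null (Cs = 0);
* interaction test (iSet): full vs block (persistent-only null);
* heterogeneity test (iSet-het): full vs rank-one (rescaling null).

Because the constrained estimates sit on the boundary of the PSD cone, the
LLRs have no standard asymptotic distribution; empirical p-values are
obtained by pooling J per-region null LLRs across T regions (permutations of
the genotype rows for the association test, parametric bootstrap from the
fitted constrained null for the interaction and heterogeneity tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .lmm import (
    FittedModel,
    RegionGenotypes,
    StudyDesign,
    _CompleteWorkspace,
    _StratifiedWorkspace,
    fit,
    sample_phenotypes,
)

__all__ = [
    "RegionTestResult",
    "NullPool",
    "EmpiricalPValues",
    "TEST_NAMES",
    "test_region",
    "draw_null_llrs",
    "pool_and_pvalues",
    "InteractionSetTest",
    "single_variant_interaction_scan",
    "effective_tests",
    "heterogeneity_baseline_score",
    "classify_architecture",
]

TEST_NAMES = ("assoc", "inter", "het")
_NULL_OF = dict(assoc="null", inter="block", het="rank1")


@dataclass
class RegionTestResult:
    """Observed LLRs (2 x REML log-likelihood difference, clipped at 0)."""

    region_id: str
    models: dict  # kind -> FittedModel
    llr: dict  # test name -> float
    converged: bool

    def __getitem__(self, test: str) -> float:
        return self.llr[test]


@dataclass
class NullPool:
    """Pooled null LLRs: per test, a (T, J) array plus provenance."""

    llrs: dict  # test -> (T, J) array
    region_ids: list
    seeds: list

    @property
    def J(self) -> int:
        return next(iter(self.llrs.values())).shape[1]

    @property
    def T(self) -> int:
        return next(iter(self.llrs.values())).shape[0]

    def pooled(self, test: str) -> np.ndarray:
        return self.llrs[test].ravel()


@dataclass
class EmpiricalPValues:
    """Per-region, per-test empirical p-values and BH q-values."""

    p: dict  # test -> (T,) array
    q: dict
    region_ids: list
    pool_size: int


def _llr(full: FittedModel, reduced: FittedModel) -> float:
    return max(0.0, 2.0 * (full.reml - reduced.reml))


def _fit_kinds(design, region, kinds, restarts, seed, workspace=None):
    out = {}
    for k in kinds:
        out[k] = fit(
            design, region, cov_kind=k, restarts=restarts, seed=seed, workspace=workspace
        )
    return out


def test_region(
    design: StudyDesign,
    region: RegionGenotypes,
    restarts: int = 3,
    seed: int = 0,
    region_id: str = "region",
    tests=TEST_NAMES,
) -> RegionTestResult:
    """Fit the null/block/rank1/full models and report the three LLRs.

    Non-convergence of any fit flags the result; LLRs are still reported
    from the best optima found.
    """
    kinds = {"full"} | {_NULL_OF[t] for t in tests}
    ws = _make_workspace(design, region)
    models = _fit_kinds(design, region, sorted(kinds), restarts, seed, workspace=ws)
    llr = {t: _llr(models["full"], models[_NULL_OF[t]]) for t in tests}
    converged = all(m.converged for m in models.values())
    return RegionTestResult(region_id=region_id, models=models, llr=llr, converged=converged)


def _make_workspace(design, region):
    if design.layout == "complete":
        return _CompleteWorkspace(design, region)
    return _StratifiedWorkspace(design, region)


def _replace_phenotypes(design: StudyDesign, values) -> StudyDesign:
    if design.layout == "complete":
        return StudyDesign(layout="complete", Y=values, F=design.F)
    return StudyDesign(
        layout="stratified",
        y=values,
        contexts=design.contexts,
        F=design.F,
        n_contexts=design.n_contexts,
    )


def draw_null_llrs(
    design: StudyDesign,
    region: RegionGenotypes,
    J: int = 30,
    seed: int = 0,
    restarts: int = 3,
    result: RegionTestResult | None = None,
    tests=TEST_NAMES,
):
    """Per-test null LLR arrays of length J for one region.

    Association nulls permute the individual ordering of the region
    genotypes relative to the phenotypes (the phenotypes themselves are
    untouched, preserving their trait-context covariance).  Interaction and
    heterogeneity nulls are parametric bootstraps: phenotype replicates are
    sampled from the fitted block (resp. rank-one) model and the test is
    refit on each replicate.  A replicate whose refit fails to converge is
    redrawn once with perturbed restarts.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    rng = np.random.default_rng(seed)
    if result is None:
        result = test_region(design, region, restarts=restarts, seed=seed, tests=tests)
    out = {}
    N = design.n_individuals

    if "assoc" in tests:
        vals = np.empty(J)
        null_model = result.models["null"]
        for j in range(J):
            perm = rng.permutation(N)
            region_p = RegionGenotypes(region.G[perm])
            full_p = fit(
                design, region_p, cov_kind="full", restarts=restarts, seed=seed + j + 1
            )
            # the no-genetics null does not involve the region: reuse the fit
            vals[j] = _llr(full_p, null_model)
        out["assoc"] = vals

    for tname in ("inter", "het"):
        if tname not in tests:
            continue
        null_kind = _NULL_OF[tname]
        fitted_null = result.models[null_kind]
        vals = np.empty(J)
        for j in range(J):
            rep_seed = int(rng.integers(2**31))
            Yrep = sample_phenotypes(fitted_null, design, region, seed=rep_seed)
            d_rep = _replace_phenotypes(design, Yrep)
            ws = _make_workspace(d_rep, region)
            mfull = fit(d_rep, region, cov_kind="full", restarts=restarts, seed=rep_seed, workspace=ws)
            mnull = fit(d_rep, region, cov_kind=null_kind, restarts=restarts, seed=rep_seed, workspace=ws)
            if not (mfull.converged and mnull.converged):
                mfull = fit(d_rep, region, cov_kind="full", restarts=restarts + 1,
                            seed=rep_seed + 7, workspace=ws)
                mnull = fit(d_rep, region, cov_kind=null_kind, restarts=restarts + 1,
                            seed=rep_seed + 7, workspace=ws)
            vals[j] = _llr(mfull, mnull)
        out[tname] = vals
    return out


def pool_and_pvalues(results, null_pool: NullPool) -> EmpiricalPValues:
    """Empirical p-values from the pooled null, with BH q-values per test.

    p = (1 + #{null >= observed}) / (1 + J*T); ties count as exceedances.
    The +1 smoothing keeps p > 0 while preserving the 1/(JT) resolution of
    the pooled null asymptotically.
    """
    tests = list(null_pool.llrs)
    p = {}
    q = {}
    for t in tests:
        pool = np.sort(null_pool.pooled(t))
        if pool.size == 0:
            raise ValueError("empty null pool")
        obs = np.array([r.llr[t] for r in results])
        n_ge = pool.size - np.searchsorted(pool, obs, side="left")
        p[t] = (1.0 + n_ge) / (1.0 + pool.size)
        q[t] = multipletests(p[t], method="fdr_bh")[1]
    return EmpiricalPValues(
        p=p, q=q, region_ids=[r.region_id for r in results], pool_size=null_pool.T * null_pool.J
    )


class InteractionSetTest(BaseEstimator):
    """sklearn-style facade over the three set tests for one region.

    After ``fit(G, Y, F=...)`` the attributes ``llr_assoc_``, ``llr_inter_``
    and ``llr_het_`` hold the observed statistics and ``models_`` the four
    constrained fits.  ``null_llrs(J, seed)`` draws the per-region null
    statistics used for pooled empirical p-values.
    """

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
        res = test_region(
            design, region, restarts=self.restarts, seed=self.random_state
        )
        self.result_ = res
        self.models_ = res.models
        self.llr_assoc_ = res.llr["assoc"]
        self.llr_inter_ = res.llr["inter"]
        self.llr_het_ = res.llr["het"]
        self.converged_ = res.converged
        self.design_ = design
        self.region_ = region
        return self

    def null_llrs(self, J=30, seed=None):
        seed = self.random_state if seed is None else seed
        return draw_null_llrs(
            self.design_,
            self.region_,
            J=J,
            seed=seed,
            restarts=self.restarts,
            result=self.result_,
        )


# ---------------------------------------------------------------------------
# Single-variant interaction baseline
# ---------------------------------------------------------------------------


def single_variant_interaction_scan(
    design: StudyDesign,
    region: RegionGenotypes,
    adjustment: str = "bonferroni",
    eff_fraction: float = 0.995,
):
    """Per-variant fixed-effect interaction test plus a region-level p-value.

    Each variant enters a fixed-effect model with one effect per context;
    the interaction is a 1-df Wald test of equal effects across the two
    contexts, with the residual trait-context covariance Cn estimated once
    under the no-genetics model (no per-variant covariance re-estimation).
    The region p-value is the minimum interaction p times either the variant
    count (Bonferroni) or the effective number of independent tests.
    """
    if design.layout != "complete" or design.n_contexts != 2:
        raise ValueError("baseline scan supports complete two-context designs")
    if adjustment not in ("bonferroni", "effective_tests"):
        raise ValueError("adjustment must be 'bonferroni' or 'effective_tests'")
    null_model = fit(design, region, cov_kind="null")
    Cn = null_model.Cn
    from scipy import linalg as sla

    E = sla.cholesky(Cn, lower=True)
    Yw = design.Y @ sla.solve_triangular(E, np.eye(2), lower=True).T  # whitened contexts
    F = design.F
    if F.shape[1]:
        Q, _ = np.linalg.qr(F)
        Yr = Yw - Q @ (Q.T @ Yw)
    else:
        Q = None
        Yr = Yw
    contrast_var = Cn[0, 0] + Cn[1, 1] - 2 * Cn[0, 1]
    S = region.n_variants
    p_int = np.full(S, np.nan)
    p_assoc = np.full(S, np.nan)
    betas = np.full((S, 2), np.nan)
    skipped = []
    for s in range(S):
        g = region.G[:, s]
        if Q is not None:
            g = g - Q @ (Q.T @ g)
        gg = float(g @ g)
        if gg <= 1e-12:
            skipped.append(s)
            continue
        btil = (g @ Yr) / gg  # effects in whitened context basis
        b = E @ btil  # back to original contexts
        betas[s] = b
        z2_int = (b[0] - b[1]) ** 2 * gg / contrast_var
        p_int[s] = stats.chi2.sf(z2_int, df=1)
        chi2_assoc = float(btil @ btil) * gg
        p_assoc[s] = stats.chi2.sf(chi2_assoc, df=2)
    valid = ~np.isnan(p_int)
    if not valid.any():
        raise ValueError("no testable variants in region")
    m = effective_tests(region, fraction=eff_fraction) if adjustment == "effective_tests" else int(valid.sum())
    min_p = float(np.nanmin(p_int))
    region_p = min(1.0, m * min_p)
    return dict(
        p_interaction=p_int,
        p_association=p_assoc,
        betas=betas,
        lead_variant=int(np.nanargmin(p_int)),
        region_p=region_p,
        n_tests=m,
        skipped=skipped,
    )


def effective_tests(region: RegionGenotypes, fraction: float = 0.995) -> int:
    """Effective number of independent tests from the local LD structure.

    The smallest k such that the top-k eigenvalues of the variant
    correlation matrix capture ``fraction`` of its total variance;
    1 <= M_eff <= S.
    """
    G = region.G
    S = G.shape[1]
    if S == 1:
        return 1
    corr = np.corrcoef(G.T)
    vals = np.linalg.eigvalsh(corr)[::-1]
    vals = np.maximum(vals, 0.0)
    cum = np.cumsum(vals)
    k = int(np.searchsorted(cum, fraction * cum[-1]) + 1)
    return min(max(k, 1), S)


# ---------------------------------------------------------------------------
# Lead-variant heterogeneity baseline and architecture classification
# ---------------------------------------------------------------------------


def heterogeneity_baseline_score(lead_significant: tuple, lead_r2: float) -> float:
    """Univariate baseline score for heterogeneity: 1 - r^2 between leads.

    Returns 1 - r^2 between the per-context lead variants when both contexts
    have a significant association; otherwise 0.
    """
    sig0, sig1 = bool(lead_significant[0]), bool(lead_significant[1])
    if not (sig0 and sig1):
        return 0.0
    if lead_r2 is None or not np.isfinite(lead_r2):
        return 0.0
    return float(np.clip(1.0 - lead_r2, 0.0, 1.0))


def classify_architecture(
    lead_significant: tuple,
    lead_r2: float | None,
    effect_signs: tuple | None = None,
    secondary_significant: tuple | None = None,
    secondary_r2: float | None = None,
    r2_low: float = 0.2,
    r2_high: float = 0.8,
) -> dict:
    """Classify a region's cross-context architecture from single-variant scans.

    Labels: ``distinct-leads`` (both contexts significant, lead r^2 < 0.2),
    ``shared-lead`` (lead r^2 > 0.8; sub-label ``context-specific-secondary``
    when a secondary association is significant in only one context or the
    secondary leads are in low LD), ``unresolved`` for intermediate LD
    (0.2 <= r^2 <= 0.8), missing LD, or missing significance.  Shared leads
    are additionally split ``opposite-direction`` vs ``same-direction`` by
    effect-sign concordance.
    """
    sig0, sig1 = bool(lead_significant[0]), bool(lead_significant[1])
    out = dict(label="unresolved", sublabel=None, direction=None)
    if not (sig0 and sig1):
        out["label"] = "unresolved"
        out["sublabel"] = "not-significant-in-both"
        return out
    if lead_r2 is None or not np.isfinite(lead_r2):
        return out
    if lead_r2 < r2_low:
        out["label"] = "distinct-leads"
        return out
    if lead_r2 > r2_high:
        out["label"] = "shared-lead"
        if effect_signs is not None:
            same = np.sign(effect_signs[0]) == np.sign(effect_signs[1])
            out["direction"] = "same-direction" if same else "opposite-direction"
        if secondary_significant is not None:
            s0, s1 = bool(secondary_significant[0]), bool(secondary_significant[1])
            if s0 != s1:
                out["sublabel"] = "context-specific-secondary"
            elif s0 and s1 and secondary_r2 is not None and secondary_r2 < r2_low:
                out["sublabel"] = "context-specific-secondary"
            else:
                out["sublabel"] = "none"
        return out
    out["label"] = "unresolved"
    out["sublabel"] = "intermediate-LD"
    return out
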