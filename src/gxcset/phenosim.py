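"""Phenotype simulation across contexts.

Traits in C contexts (default 2) are composed of four independent parts:
a regional genetic component from a designated causal region, a
population-structure component from genome-wide relatedness, effects of
K hidden confounding factors, and iid Gaussian noise.  Each component is
empirically rescaled to its target variance fraction per context, so the
simulator's variance ledger is exact per replicate rather than only in
expectation.

Genetic architectures across contexts:

* ``persistent`` — identical effect sizes in every context (W columns equal);
* ``rescaling`` — effects in context 2 proportional to context 1 by a factor
  eta in [-1, 1] (eta = 1 is no interaction; eta = 0 is context-exclusive);
* ``heterogeneity`` — disjoint causal variants per context, with the
  cross-context correlation r of the total regional effect controlled by
  rejection sampling.

The population-structure and hidden-factor components have cross-context
correlation ``shared_background`` (alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genosim import DosageMatrix, simulate_mosaic_cohort
from .lmm import RegionGenotypes, StudyDesign
from .preprocess import standardize_region

__all__ = [
    "SimulationConfig",
    "PhenotypeBundle",
    "simulate_phenotypes",
    "apply_misspecification",
    "stratify",
    "simulate_illustration_region",
]

ARCHITECTURES = ("persistent", "rescaling", "heterogeneity")
MISSPECIFICATIONS = ("none", "single_causal", "epistasis", "outliers")


@dataclass
class SimulationConfig:
    """Generative parameters for two-context (or C-context) phenotypes.

    Defaults follow the study conditions of the simulation framework:
    the region explains v_r = 2% of per-context phenotypic variance,
    background effects are shared across contexts with correlation
    alpha = 0.6, hidden factors (K = 10) account for beta = 50% of the
    non-region variance, and four causal variants are drawn per context
    (two in heterogeneity mode).
    """

    n_contexts: int = 2
    region_variance: float = 0.02  # v_r
    shared_background: float = 0.6  # alpha
    hidden_fraction: float = 0.5  # beta
    structure_fraction: float = 0.5  # share of non-hidden residual from structure
    n_hidden: int = 10  # K
    architecture: str = "persistent"
    n_causal: int | None = None  # per context; defaults by architecture
    proportionality: float = 0.0  # eta, rescaling mode
    target_corr: float = 0.0  # r, heterogeneity mode
    corr_tol: float = 0.05
    corr_band: tuple | None = None  # optional (lo, hi) acceptance band on r
    misspecification: str = "none"
    max_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("region_variance", self.region_variance),
            ("shared_background", self.shared_background),
            ("hidden_fraction", self.hidden_fraction),
            ("structure_fraction", self.structure_fraction),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(self.proportionality) > 1:
            raise ValueError("|proportionality| must be <= 1")
        if abs(self.target_corr) > 1:
            raise ValueError("|target_corr| must be <= 1")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.misspecification not in MISSPECIFICATIONS:
            raise ValueError(f"misspecification must be one of {MISSPECIFICATIONS}")
        if self.n_causal is None:
            self.n_causal = 2 if self.architecture == "heterogeneity" else 4
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")


@dataclass
class PhenotypeBundle:
    """Simulated phenotypes with ground-truth components.

    ``components`` maps component name -> (N, C) array; ``fractions`` maps
    component name -> length-C target variance fractions (exact by
    construction); ``W`` holds the realized variants x contexts effects.
    """

    Y: np.ndarray
    components: dict
    fractions: dict
    W: np.ndarray
    causal_indices: list
    config: SimulationConfig
    region: RegionGenotypes
    extras: dict = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.Y.shape[0]

    @property
    def n_contexts(self) -> int:
        return self.Y.shape[1]


def _scale_to(x: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Rescale a vector to exact empirical variance ``target_var``."""
    sd = x.std()
    if sd == 0:
        if target_var == 0:
            return x.copy(), 0.0
        raise ValueError("cannot rescale a constant component")
    f = np.sqrt(target_var) / sd
    return x * f, f


def _background_factor(background, rng):
    """Return a callable drawing one N-vector with cov ~ genome-wide relatedness."""
    if isinstance(background, DosageMatrix):
        X = np.asarray(background.dosages, dtype=float)
        sd = X.std(axis=0)
        keep = sd > 0
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        Z /= np.sqrt(Z.shape[1])
        return lambda: Z @ rng.standard_normal(Z.shape[1])
    background = np.asarray(background, dtype=float)
    # treated as a factor L with relatedness L L^T
    return lambda: background @ rng.standard_normal(background.shape[1])


def _regional_effects(config: SimulationConfig, region: RegionGenotypes, rng):
    """Draw causal sets and effect sizes; return per-context raw effects and W."""
    S = region.n_variants
    C = config.n_contexts
    nc = config.n_causal
    arch = config.architecture
    if arch == "heterogeneity":
        if S < C * nc:
            raise ValueError("insufficient variants for disjoint causal sets")
    elif S < nc:
        raise ValueError("insufficient variants for the causal set")
    W = np.zeros((S, C))
    if arch == "persistent":
        idx = rng.choice(S, size=nc, replace=False)
        w = rng.standard_normal(nc)
        for c in range(C):
            W[idx, c] = w
        causal = [np.sort(idx)] * C
    elif arch == "rescaling":
        idx = rng.choice(S, size=nc, replace=False)
        w = rng.standard_normal(nc)
        scales = np.concatenate([[1.0], np.full(C - 1, config.proportionality)])
        for c in range(C):
            W[idx, c] = scales[c] * w
        causal = [np.sort(idx)] * C
    else:  # heterogeneity: rejection-sample to the target effect correlation
        lo, hi = (
            config.corr_band
            if config.corr_band is not None
            else (config.target_corr - config.corr_tol, config.target_corr + config.corr_tol)
        )
        for _ in range(config.max_attempts):
            perm = rng.permutation(S)
            sets = [np.sort(perm[c * nc : (c + 1) * nc]) for c in range(C)]
            Wtry = np.zeros((S, C))
            for c in range(C):
                Wtry[sets[c], c] = rng.standard_normal(nc)
            g = region.G @ Wtry
            r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
            if lo <= r <= hi:
                W = Wtry
                causal = sets
                break
        else:
            raise RuntimeError(
                f"unreachable target correlation: no draw in [{lo:.3f}, {hi:.3f}] "
                f"after {config.max_attempts} attempts"
            )
    g_raw = region.G @ W
    return g_raw, W, causal


def _scale_regional(architecture, eta, v_r, g_raw, W):
    """Scale regional effects to their variance targets.

    Persistent/heterogeneity: each context scaled to exactly v_r.  Rescaling:
    one shared factor so the cross-context average fraction is v_r while the
    per-context variances keep the 1 : eta^2 ratio and W's proportionality is
    preserved exactly.
    """
    N, C = g_raw.shape
    comp = np.empty((N, C))
    targets = np.empty(C)
    W = W.copy()
    if architecture == "rescaling":
        var1 = g_raw[:, 0].var()
        if var1 == 0:
            raise ValueError("degenerate regional effect")
        t1 = 2.0 * v_r / (1.0 + eta**2)
        f = np.sqrt(t1 / var1)
        comp = g_raw * f
        W *= f
        targets[0] = t1
        targets[1:] = eta**2 * t1
    else:
        for c in range(C):
            comp[:, c], fc = _scale_to(g_raw[:, c], v_r)
            W[:, c] *= fc
        targets[:] = v_r
    return comp, W, targets


def _variance_targets(config: SimulationConfig, region_targets: np.ndarray):
    """Per-context target fractions for structure, hidden and noise."""
    resid = 1.0 - region_targets
    hidden = config.hidden_fraction * resid
    structure = config.structure_fraction * (1.0 - config.hidden_fraction) * resid
    noise = (1.0 - config.structure_fraction) * (1.0 - config.hidden_fraction) * resid
    return structure, hidden, noise


def simulate_phenotypes(
    config: SimulationConfig, region: RegionGenotypes, background
) -> PhenotypeBundle:
    """Simulate a phenotype bundle; deterministic given ``config.seed``.

    ``background`` is either a genome-wide :class:`DosageMatrix` or an
    N x m factor L whose relatedness is L L^T.

    Under persistent and heterogeneity architectures each context's regional
    component is rescaled to exactly v_r; under rescaling, both columns of W
    are scaled by one shared factor so the *average* regional fraction equals
    v_r while the two contexts keep the eta^2 variance ratio (and column 2 of
    W stays exactly eta times column 1).
    """
    rng = np.random.default_rng(config.seed)
    N = region.n_individuals
    C = config.n_contexts
    alpha = config.shared_background

    g_raw, W, causal = _regional_effects(config, region, rng)

    # --- regional component scaling
    region_comp, W, region_targets = _scale_regional(
        config.architecture, config.proportionality, config.region_variance, g_raw, W
    )

    t_struct, t_hidden, t_noise = _variance_targets(config, region_targets)

    # --- population-structure component with cross-context correlation alpha
    draw_u = _background_factor(background, rng)
    u_shared = draw_u()
    structure = np.empty((N, C))
    for c in range(C):
        u = np.sqrt(alpha) * u_shared + np.sqrt(1.0 - alpha) * draw_u()
        structure[:, c], _ = _scale_to(u, t_struct[c])

    # --- hidden confounders: K factors, loadings correlated alpha across contexts
    K = config.n_hidden
    scores = rng.standard_normal((N, K))
    l_shared = rng.standard_normal(K)
    hidden = np.empty((N, C))
    for c in range(C):
        l_c = np.sqrt(alpha) * l_shared + np.sqrt(1.0 - alpha) * rng.standard_normal(K)
        hidden[:, c], _ = _scale_to(scores @ l_c, t_hidden[c])

    # --- iid noise
    noise = np.empty((N, C))
    for c in range(C):
        noise[:, c], _ = _scale_to(rng.standard_normal(N), t_noise[c])

    Y = region_comp + structure + hidden + noise
    components = dict(region=region_comp, structure=structure, hidden=hidden, noise=noise)
    fractions = dict(
        region=region_targets, structure=t_struct, hidden=t_hidden, noise=t_noise
    )
    bundle = PhenotypeBundle(
        Y=Y,
        components=components,
        fractions=fractions,
        W=W,
        causal_indices=causal,
        config=config,
        region=region,
    )
    if config.misspecification != "none":
        bundle = apply_misspecification(bundle, config.misspecification, seed=config.seed + 1)
    return bundle


def apply_misspecification(bundle: PhenotypeBundle, mode: str, seed: int = 0) -> PhenotypeBundle:
    """Perturb a bundle to violate one model assumption.

    ``single_causal``: the regional component is rebuilt from a single causal
    variant (same architecture, same variance targets).
    ``epistasis``: a standardized product term of a random variant pair is
    added to the genetic component, scaled to the regional variance target.
    ``outliers``: 0.1% of the N*C trait entries are shifted by exactly +-8.
    """
    if mode not in MISSPECIFICATIONS[1:]:
        raise ValueError(f"mode must be one of {MISSPECIFICATIONS[1:]}")
    rng = np.random.default_rng(seed)
    N, C = bundle.Y.shape

    if mode == "single_causal":
        cfg = replace(bundle.config, n_causal=1, misspecification="none", seed=seed)
        g_raw, W, causal = _regional_effects(cfg, bundle.region, rng)
        region_comp, W, _ = _scale_regional(
            cfg.architecture, cfg.proportionality, cfg.region_variance, g_raw, W
        )
        comps = dict(bundle.components, region=region_comp)
        Y = sum(comps.values())
        return PhenotypeBundle(
            Y=Y,
            components=comps,
            fractions=bundle.fractions,
            W=W,
            causal_indices=causal,
            config=cfg,
            region=bundle.region,
            extras=dict(bundle.extras, misspecification="single_causal"),
        )

    if mode == "epistasis":
        G = bundle.region.G
        if G.shape[1] < 2:
            raise ValueError("epistasis needs at least 2 variants")
        i, j = rng.choice(G.shape[1], size=2, replace=False)
        prod = G[:, i] * G[:, j]
        if prod.std() == 0:
            prod = prod + 1e-12 * rng.standard_normal(N)
        term = np.empty((N, C))
        for c in range(C):
            term[:, c], _ = _scale_to(prod - prod.mean(), bundle.fractions["region"][c])
        comps = dict(bundle.components, region=bundle.components["region"] + term)
        Y = sum(comps.values())
        return PhenotypeBundle(
            Y=Y,
            components=comps,
            fractions=bundle.fractions,
            W=bundle.W,
            causal_indices=bundle.causal_indices,
            config=bundle.config,
            region=bundle.region,
            extras=dict(
                bundle.extras, misspecification="epistasis", epistasis_term=term,
                epistasis_pair=(int(i), int(j)),
            ),
        )

    # outliers: heavy-tailed contamination of 0.1% of sample entries
    n_entries = N * C
    n_out = max(1, round(0.001 * n_entries))
    flat = rng.choice(n_entries, size=n_out, replace=False)
    signs = rng.choice((-8.0, 8.0), size=n_out)
    Y = bundle.Y.copy()
    Y.flat[flat] += signs
    return PhenotypeBundle(
        Y=Y,
        components=bundle.components,
        fractions=bundle.fractions,
        W=bundle.W,
        causal_indices=bundle.causal_indices,
        config=bundle.config,
        region=bundle.region,
        extras=dict(
            bundle.extras, misspecification="outliers",
            outlier_entries=flat, outlier_offsets=signs,
        ),
    )


def stratify(bundle: PhenotypeBundle, seed: int = 0, F=None) -> StudyDesign:
    """Assign each individual one observed context by a fair Bernoulli draw."""
    if bundle.n_contexts != 2:
        raise ValueError("stratification is defined for two contexts")
    rng = np.random.default_rng(seed)
    ctx = rng.integers(0, 2, size=bundle.n_individuals)
    y = bundle.Y[np.arange(bundle.n_individuals), ctx]
    return StudyDesign(layout="stratified", y=y, contexts=ctx, F=F, n_contexts=2)


def simulate_illustration_region(
    seed: int = 0,
    n_individuals: int = 500,
    locus_length_bp: int = 30_000,
    n_variants_per_locus: int = 60,
    locus_variance: float = 0.05,
):
    """Multi-locus illustration: three disjoint 30-kb causal loci.

    The three loci carry persistent, rescaling-GxC (eta = -0.5, opposite
    directions) and heterogeneity-GxC (r = 0) effects respectively, each
    rescaled to explain ``locus_variance`` (default 5%) of the total
    phenotypic variance (for the rescaling locus, 5% on cross-context
    average with the eta^2 per-context ratio).  Returns a :class:`PhenotypeBundle` whose extras
    hold the per-locus components, architectures and variant index ranges.
    """
    rng = np.random.default_rng(seed)
    gap = 3 * locus_length_bp  # disjoint loci separated along the region
    archs = ("persistent", "rescaling", "heterogeneity")
    regions = []
    for k in range(3):
        dm = simulate_mosaic_cohort(
            n_individuals,
            n_founders=20,
            n_variants=n_variants_per_locus,
            region_length_bp=locus_length_bp,
            recomb_rate=1e-5,
            maf_min=0.02,
            seed=int(rng.integers(2**31)),
            start=k * gap,
        )
        regions.append(standardize_region(dm, maf_min=0.02))

    N, C = n_individuals, 2
    locus_comps, locus_W, locus_causal = [], [], []
    offsets = np.cumsum([0] + [r.n_variants for r in regions])
    for k, (arch, reg) in enumerate(zip(archs, regions)):
        cfg = SimulationConfig(
            architecture=arch,
            region_variance=locus_variance,
            proportionality=-0.5,
            target_corr=0.0,
            seed=int(rng.integers(2**31)),
        )
        sub_rng = np.random.default_rng(cfg.seed)
        g_raw, Wk, causal = _regional_effects(cfg, reg, sub_rng)
        comp, Wk, _ = _scale_regional(arch, cfg.proportionality, locus_variance, g_raw, Wk)
        locus_comps.append(comp)
        locus_W.append(Wk)
        locus_causal.append([ci + offsets[k] for ci in causal])

    base_cfg = SimulationConfig(seed=seed)
    resid = 1.0 - 3 * locus_variance
    t_hidden = base_cfg.hidden_fraction * resid
    t_struct = base_cfg.structure_fraction * (1 - base_cfg.hidden_fraction) * resid
    t_noise = resid - t_hidden - t_struct
    alpha = base_cfg.shared_background

    Gall = np.hstack([r.G for r in regions])
    full_region = RegionGenotypes(Gall)
    # population structure from an independent genome-wide background cohort,
    # not from the causal loci themselves
    bg = simulate_mosaic_cohort(
        n_individuals, n_founders=20, n_variants=200, region_length_bp=200_000,
        recomb_rate=1e-5, maf_min=0.02, seed=int(rng.integers(2**31)),
    )
    draw_u = _background_factor(bg, rng)
    u_shared = draw_u()
    structure = np.empty((N, C))
    hidden = np.empty((N, C))
    noise = np.empty((N, C))
    scores = rng.standard_normal((N, base_cfg.n_hidden))
    l_shared = rng.standard_normal(base_cfg.n_hidden)
    for c in range(C):
        u = np.sqrt(alpha) * u_shared + np.sqrt(1 - alpha) * draw_u()
        structure[:, c], _ = _scale_to(u, t_struct)
        l_c = np.sqrt(alpha) * l_shared + np.sqrt(1 - alpha) * rng.standard_normal(
            base_cfg.n_hidden
        )
        hidden[:, c], _ = _scale_to(scores @ l_c, t_hidden)
        noise[:, c], _ = _scale_to(rng.standard_normal(N), t_noise)

    region_comp = sum(locus_comps)
    Y = region_comp + structure + hidden + noise
    W = np.vstack(locus_W)
    causal_indices = [
        np.sort(np.concatenate([locus_causal[k][c] for k in range(3)])) for c in range(C)
    ]
    return PhenotypeBundle(
        Y=Y,
        components=dict(region=region_comp, structure=structure, hidden=hidden, noise=noise),
        fractions=dict(
            region=np.full(C, 3 * locus_variance),
            structure=np.full(C, t_struct),
            hidden=np.full(C, t_hidden),
            noise=np.full(C, t_noise),
        ),
        W=W,
        causal_indices=causal_indices,
        config=base_cfg,
        region=full_region,
        extras=dict(
            locus_components=locus_comps,
            locus_architectures=archs,
            locus_regions=regions,
            locus_causal=locus_causal,
            locus_variance=locus_variance,
        ),
    )
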