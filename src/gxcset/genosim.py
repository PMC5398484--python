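"""Synthetic genotype cohorts.

Two generators are provided: a mosaic-of-founders simulator that produces
diploid dosages with decaying local linkage disequilibrium (LD), and an
LD-free generator with independent binomial variants.  The mosaic process
copies founder haplotypes piecewise, switching donor haplotypes with a
per-base-pair geometric probability, so LD between two variants decays with
their physical distance at a scale set by ``recomb_rate``.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateRegionError(ValueError):
    """Raised when fewer than two variants survive the MAF filter."""


@dataclass
class DosageMatrix:
    """Diploid allele counts for a cohort.

    Attributes
    ----------
    dosages : (N, S) int array with entries in {0, 1, 2}
    positions : (S,) strictly increasing base-pair coordinates
    chrom : chromosome label
    allele_freqs : (S,) alternate-allele fraction per variant
    variant_ids : (S,) variant identifiers
    """

    dosages: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    variant_ids: np.ndarray | None = None
    allele_freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.positions = np.asarray(self.positions)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if self.positions.shape[0] != self.dosages.shape[1]:
            raise ValueError("positions length must match variant count")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        if self.variant_ids is None:
            self.variant_ids = np.array(
                [f"{self.chrom}_{p}" for p in self.positions]
            )
        else:
            self.variant_ids = np.asarray(self.variant_ids)
        self.allele_freqs = self.dosages.mean(axis=0) / 2.0

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def slice_region(self, start: int, end: int) -> "DosageMatrix":
        """Variants with position in the half-open window [start, end)."""
        keep = (self.positions >= start) & (self.positions < end)
        return DosageMatrix(
            self.dosages[:, keep],
            self.positions[keep],
            chrom=self.chrom,
            variant_ids=self.variant_ids[keep],
        )


def _maf_filter(dosages, positions, ids, maf_min, min_variants=2):
    freqs = dosages.mean(axis=0) / 2.0
    keep = (freqs >= maf_min) & (freqs <= 1.0 - maf_min)
    # monomorphic variants never survive
    keep &= dosages.std(axis=0) > 0
    if keep.sum() < min_variants:
        raise DegenerateRegionError(
            f"degenerate region: {int(keep.sum())} variants survive the "
            f"MAF >= {maf_min} filter"
        )
    return dosages[:, keep], positions[keep], ids[keep]


def _mosaic_haplotypes(founder_haps, positions, n_haplotypes, recomb_rate, rng):
    """Copy founder haplotypes piecewise with geometric switch points."""
    n_f, n_v = founder_haps.shape
    gaps = np.diff(positions).astype(float)
    # probability that at least one switch falls in each inter-variant gap
    p_switch = 1.0 - np.power(1.0 - recomb_rate, gaps) if recomb_rate > 0 else np.zeros(n_v - 1)
    out = np.empty((n_haplotypes, n_v), dtype=np.int8)
    donors = rng.integers(0, n_f, size=n_haplotypes)
    out[:, 0] = founder_haps[donors, 0]
    for j in range(1, n_v):
        if recomb_rate > 0:
            switch = rng.random(n_haplotypes) < p_switch[j - 1]
            if switch.any():
                donors = donors.copy()
                donors[switch] = rng.integers(0, n_f, size=int(switch.sum()))
        out[:, j] = founder_haps[donors, j]
    return out


def _founder_latents(n_founder_haps, positions, ld_scale_bp, rng):
    """Latent AR(1) Gaussians giving founder haplotypes internal LD.

    Adjacent sites at distance g have latent correlation exp(-g/ld_scale_bp),
    so founder-level LD decays smoothly with physical distance.
    """
    n_v = positions.size
    z = np.empty((n_founder_haps, n_v))
    z[:, 0] = rng.standard_normal(n_founder_haps)
    if n_v > 1:
        rho = np.exp(-np.diff(positions).astype(float) / ld_scale_bp)
        eps = rng.standard_normal((n_founder_haps, n_v - 1))
        for j in range(1, n_v):
            r = rho[j - 1]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j - 1]
    return z


def _latents_to_haplotypes(z, freqs):
    """Threshold latent Gaussians at the per-site frequency quantile."""
    from scipy.stats import norm

    return (z < norm.ppf(freqs)).astype(np.int8)


def _draw_founders(n_founder_haps, positions, maf_min, rng, ld_scale_bp=10_000):
    """Founder haplotypes with a U(maf_min, 0.5) frequency spectrum and AR(1) LD."""
    lo = max(maf_min, 0.01)
    freqs = rng.uniform(lo, 0.5, size=positions.size)
    z = _founder_latents(n_founder_haps, positions, ld_scale_bp, rng)
    return _latents_to_haplotypes(z, freqs)


def simulate_mosaic_cohort(
    n_individuals: int,
    n_founders: int = 20,
    n_variants: int = 100,
    region_length_bp: int = 30_000,
    recomb_rate: float = 1e-5,
    maf_min: float = 0.02,
    seed: int = 0,
    chrom: str = "1",
    start: int = 0,
    founder_ld_scale_bp: float = 10_000,
) -> DosageMatrix:
    """Simulate a cohort of mosaic-of-founder diploid genotypes with local LD.

    Each of the 2*N haplotypes is a piecewise copy of founder haplotypes,
    with donor switches arriving as a per-base-pair geometric process
    (exponential inter-switch distances), so nearby variants are correlated
    and LD decays along the region.  Variants whose alternate-allele
    frequency falls outside ``[maf_min, 1 - maf_min]`` are dropped.

    Raises
    ------
    DegenerateRegionError
        If fewer than two variants survive the MAF filter.
    """
    if n_founders < 4:
        raise ValueError("n_founders must be >= 4")
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if recomb_rate < 0:
        raise ValueError("recomb_rate must be >= 0")
    rng = np.random.default_rng(seed)
    positions = start + np.sort(
        rng.choice(region_length_bp, size=min(n_variants, region_length_bp), replace=False)
    )
    founder_haps = _draw_founders(
        2 * n_founders, positions - start, maf_min, rng, ld_scale_bp=founder_ld_scale_bp
    )
    haps = _mosaic_haplotypes(founder_haps, positions, 2 * n_individuals, recomb_rate, rng)
    dosages = haps[0::2] + haps[1::2]
    ids = np.array([f"{chrom}_{p}" for p in positions])
    dosages, positions, ids = _maf_filter(dosages, positions, ids, maf_min)
    return DosageMatrix(dosages, positions, chrom=chrom, variant_ids=ids)


def simulate_independent_genotypes(
    n_individuals: int, mafs, seed: int = 0, chrom: str = "1"
) -> DosageMatrix:
    """LD-free genotypes: each variant is an independent Binomial(2, maf)."""
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size == 0:
        raise ValueError("mafs must be non-empty")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("each maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, mafs, size=(n_individuals, mafs.size)).astype(np.int8)
    positions = np.arange(1, mafs.size + 1) * 1000
    return DosageMatrix(dosages, positions, chrom=chrom)


def two_subpopulation_cohort(
    n_individuals: int,
    divergence: float,
    n_founders: int = 20,
    n_variants: int = 500,
    region_length_bp: int = 500_000,
    recomb_rate: float = 1e-5,
    maf_min: float = 0.02,
    seed: int = 0,
    chrom: str = "1",
):
    """Cohort drawn from two subpopulations with perturbed allele frequencies.

    Founder latent haplotypes are shared between the pools; the pools differ
    only by allele-frequency thresholds perturbed in opposite directions by
    ``divergence`` times a standard normal deviate per variant, so
    ``divergence = 0`` yields identical pools (no structure).  Returns the
    cohort plus the 0/1 subpopulation labels, for validating
    principal-component adjustment.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if n_founders < 4:
        raise ValueError("n_founders must be >= 4")
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(region_length_bp, size=min(n_variants, region_length_bp), replace=False)
    )
    base = rng.uniform(max(maf_min, 0.01), 0.5, size=positions.size)
    delta = divergence * rng.standard_normal(positions.size)
    f1 = np.clip(base + delta, 0.01, 0.99)
    f2 = np.clip(base - delta, 0.01, 0.99)
    z = _founder_latents(2 * n_founders, positions, 10_000, rng)
    n1 = n_individuals // 2
    n2 = n_individuals - n1
    blocks, labels = [], []
    for freqs, n_sub, lab in ((f1, n1, 0), (f2, n2, 1)):
        haps_f = _latents_to_haplotypes(z, freqs)
        haps = _mosaic_haplotypes(haps_f, positions, 2 * n_sub, recomb_rate, rng)
        blocks.append(haps[0::2] + haps[1::2])
        labels.append(np.full(n_sub, lab))
    dosages = np.vstack(blocks)
    labels = np.concatenate(labels)
    ids = np.array([f"{chrom}_{p}" for p in positions])
    dosages, positions, ids = _maf_filter(dosages, positions, ids, maf_min)
    cohort = DosageMatrix(dosages, positions, chrom=chrom, variant_ids=ids)
    return cohort, labels


# ---------------------------------------------------------------------------
# Writers (minimal VCF with GT field; PLINK-style dosage TSV)
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(dm: DosageMatrix, path, sample_ids=None) -> None:
    """Write a minimal VCF (GT field only, all sites biallelic A/G)."""
    n = dm.n_individuals
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={dm.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j in range(dm.n_variants):
            gts = "\t".join(_GT[int(d)] for d in dm.dosages[:, j])
            # VCF positions are 1-based
            fh.write(
                f"{dm.chrom}\t{dm.positions[j] + 1}\t{dm.variant_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dosage_tsv(dm: DosageMatrix, path, sample_ids=None) -> None:
    """PLINK-style dosage text: one row per individual, variants as columns.

    The header row carries ``chrom:pos:id`` tokens so the reader can recover
    coordinates.
    """
    n = dm.n_individuals
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]
    cols = [
        f"{dm.chrom}:{dm.positions[j]}:{dm.variant_ids[j]}"
        for j in range(dm.n_variants)
    ]
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(cols) + "\n")
        for i in range(n):
            row = "\t".join(str(int(d)) for d in dm.dosages[i])
            fh.write(f"{sample_ids[i]}\t{row}\n")
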