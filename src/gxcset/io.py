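"""File readers/writers and window generation.

All coordinates are 0-based half-open.  Genotypes are read from VCF (GT
fields, via cyvcf2) or from the PLINK-style dosage TSV written by
:mod:`gxcset.genosim`; phenotypes and covariates are plain TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genosim import DosageMatrix

logger = logging.getLogger("gxcset")

__all__ = [
    "Window",
    "make_windows",
    "gene_centric_window",
    "read_genotypes",
    "read_phenotypes",
    "read_covariates",
    "read_bed_windows",
    "write_results_tsv",
    "write_null_pool_tsv",
]


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("window start must be < end")


def make_windows(chrom_lengths: dict, size: int = 100_000, step: int = 50_000):
    """Tile half-open sliding windows per chromosome; keep the final partial one."""
    if not 0 < step <= size:
        raise ValueError("require 0 < step <= size")
    windows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        idx = 0
        while start < length:
            end = min(start + size, length)
            windows.append(Window(chrom, start, end, f"{chrom}:{start}-{end}"))
            idx += 1
            start += step
            if end == length:
                break
    return windows


def gene_centric_window(chrom: str, tss: int, flank: int = 50_000, region_id=None) -> Window:
    """A cis window of +-flank around a transcription start site."""
    start = max(0, tss - flank)
    end = tss + flank
    return Window(chrom, start, end, region_id or f"{chrom}:{start}-{end}")


def read_bed_windows(path):
    """Windows from a BED file (chrom, start, end[, name])."""
    windows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i + 1}: {line!r}")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
            windows.append(Window(parts[0], int(parts[1]), int(parts[2]), name))
    return windows


def _impute_round(col: np.ndarray) -> np.ndarray:
    """Replace missing entries by the rounded per-variant mean dosage."""
    miss = col < 0
    if miss.any():
        mean = col[~miss].mean() if (~miss).any() else 0.0
        col = col.copy()
        col[miss] = int(round(mean))
    return col


def read_genotypes(path, fmt: str = "auto"):
    """Read genotypes into a DosageMatrix; returns (matrix, sample_ids).

    VCF GT fields are converted to alternate-allele counts (phased and
    unphased calls treated alike); multi-allelic sites are skipped with a
    logged warning; missing genotypes are imputed to the rounded per-variant
    mean dosage with a logged count.
    """
    path = str(path)
    if fmt == "auto":
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "dosage-tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError("format must be 'vcf' or 'dosage-tsv'")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols, positions, ids = [], [], []
    chrom = None
    n_multi = 0
    n_missing = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            logger.warning("skipping multi-allelic site %s:%s", v.CHROM, v.POS)
            continue
        if chrom is None:
            chrom = v.CHROM
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(v.gt_types)
        dos = np.where(gt == 3, 2, gt).astype(np.int64)
        dos[gt == 2] = -1
        n_missing += int((dos < 0).sum())
        cols.append(_impute_round(dos))
        positions.append(v.POS - 1)  # to 0-based
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS - 1}")
    if not cols:
        raise ValueError(f"no biallelic variants in {path}")
    if n_missing:
        logger.info("imputed %d missing genotype calls", n_missing)
    dm = DosageMatrix(
        np.column_stack(cols),
        np.asarray(positions),
        chrom=chrom or "1",
        variant_ids=np.asarray(ids),
    )
    return dm, samples


def _read_dosage_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError("dosage TSV must have a 'sample_id' first column")
    samples = df["sample_id"].tolist()
    chroms, positions, ids = [], [], []
    for col in df.columns[1:]:
        try:
            chrom, pos, vid = col.split(":", 2)
        except ValueError as exc:
            raise ValueError(f"malformed dosage column header {col!r}") from exc
        chroms.append(chrom)
        positions.append(int(pos))
        ids.append(vid)
    dos = df.iloc[:, 1:].to_numpy()
    dos = np.column_stack([_impute_round(dos[:, j]) for j in range(dos.shape[1])])
    dm = DosageMatrix(
        dos.astype(np.int64),
        np.asarray(positions),
        chrom=chroms[0] if chroms else "1",
        variant_ids=np.asarray(ids),
    )
    return dm, samples


def read_phenotypes(path):
    """Long-format phenotype TSV (sample_id, context, value).

    Returns (Y_wide DataFrame indexed by sample with one column per context,
    context labels).  Missing cells are left as NaN for the caller to
    resolve (complete designs require none; stratified designs expect
    exactly one observed context per sample).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "context", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype TSV needs columns {sorted(required)}")
    wide = df.pivot_table(index="sample_id", columns="context", values="value", sort=False)
    wide = wide.loc[df["sample_id"].drop_duplicates().tolist()]
    return wide, list(wide.columns)


def read_covariates(path):
    """Covariate TSV: sample_id column plus one column per covariate."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("covariate TSV needs a sample_id column")
    return df.set_index("sample_id")


def write_results_tsv(df: pd.DataFrame, path) -> None:
    """Results table with a coordinate-convention header comment."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_null_pool_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
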