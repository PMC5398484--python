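"""Genome-scan orchestrator.

Runs the three set tests over sliding windows (or gene-centric regions),
draws per-region null LLRs, pools them across regions and reports empirical
p-values, BH q-values and Bonferroni-on-windows FWER.  Per-region RNG
streams are derived from (global seed, region index), so chunked parallel
execution produces byte-identical output to a serial run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .genosim import DegenerateRegionError, DosageMatrix
from .io import Window, make_windows, write_null_pool_tsv, write_results_tsv
from .lmm import StudyDesign
from .preprocess import CovariateMatrix, compute_pcs, quantile_normalize, standardize_region
from .settest import TEST_NAMES, NullPool, draw_null_llrs, pool_and_pvalues, test_region

logger = logging.getLogger("gxcset")

__all__ = ["ScanConfig", "run_scan"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class ScanConfig:
    """Resolved configuration of a scan run."""

    genotypes: DosageMatrix
    Y: np.ndarray | None = None  # complete layout, N x C
    y: np.ndarray | None = None  # stratified layout
    contexts: np.ndarray | None = None
    covariates: np.ndarray | None = None  # measured covariates (no intercept)
    windows: list | None = None
    window_size: int = 100_000
    window_step: int = 50_000
    layout: str = "complete"
    J: int = 30
    n_pcs: int = 10
    maf_min: float = 0.02
    quantile_normalize: bool = True
    restarts: int = 3
    seed: int = 0
    n_jobs: int = 1
    chunk_size: int | None = None
    tests: tuple = TEST_NAMES
    sample_ids: list | None = None
    schema_version: int = CONFIG_SCHEMA_VERSION

    def resolved_windows(self):
        if self.windows is not None:
            return self.windows
        chrom = self.genotypes.chrom
        length = int(self.genotypes.positions.max()) + 1
        return make_windows({chrom: length}, self.window_size, self.window_step)


def _region_seed(seed: int, idx: int) -> int:
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _prepare_design(config: ScanConfig):
    geno = config.genotypes
    n = geno.n_individuals
    n_pcs = min(config.n_pcs, n - 1) if config.n_pcs else 0
    pcs = compute_pcs(geno, n_components=n_pcs) if n_pcs else None
    cov = CovariateMatrix.build(n, measured=config.covariates, pcs=pcs)
    if config.layout == "complete":
        Y = np.asarray(config.Y, dtype=float)
        if Y.shape[0] != n:
            raise ValueError(
                f"sample mismatch: {Y.shape[0]} phenotyped vs {n} genotyped individuals"
            )
        if config.quantile_normalize:
            Y = np.column_stack(
                [quantile_normalize(Y[:, c]) for c in range(Y.shape[1])]
            )
        return StudyDesign(layout="complete", Y=Y, F=cov.values)
    y = np.asarray(config.y, dtype=float)
    ctx = np.asarray(config.contexts, dtype=int)
    if y.size != n:
        raise ValueError(f"sample mismatch: {y.size} phenotyped vs {n} genotyped individuals")
    if config.quantile_normalize:
        y = y.copy()
        for c in np.unique(ctx):
            m = ctx == c
            y[m] = quantile_normalize(y[m])
    return StudyDesign(layout="stratified", y=y, contexts=ctx, F=cov.values)


def _process_window(config: ScanConfig, design: StudyDesign, window: Window, idx: int):
    geno = config.genotypes
    raw = geno.slice_region(window.start, window.end)
    seed = _region_seed(config.seed, idx)
    base = dict(
        region_id=window.region_id,
        chrom=window.chrom,
        start=window.start,
        end=window.end,
        seed=seed,
    )
    if raw.n_variants == 0:
        return dict(base, status="NA", n_variants=0, result=None, nulls=None)
    try:
        region = standardize_region(raw, maf_min=config.maf_min)
    except DegenerateRegionError:
        return dict(base, status="NA", n_variants=raw.n_variants, result=None, nulls=None)
    result = test_region(
        design, region, restarts=config.restarts, seed=seed,
        region_id=window.region_id, tests=config.tests,
    )
    nulls = draw_null_llrs(
        design, region, J=config.J, seed=seed, restarts=config.restarts,
        result=result, tests=config.tests,
    )
    return dict(
        base, status="OK", n_variants=region.n_variants, result=result, nulls=nulls
    )


def run_scan(config: ScanConfig, out_results=None, out_nulls=None):
    """Execute the scan; returns (results DataFrame, null-pool DataFrame).

    With ``n_jobs > 1`` regions are processed in chunks via joblib; the
    per-region seed derivation makes the output identical to a serial run.
    """
    design = _prepare_design(config)
    windows = config.resolved_windows()
    T = len(windows)
    tasks = list(enumerate(windows))
    if config.n_jobs > 1:
        rows = Parallel(n_jobs=config.n_jobs, batch_size=config.chunk_size or "auto")(
            delayed(_process_window)(config, design, w, i) for i, w in tasks
        )
    else:
        rows = [_process_window(config, design, w, i) for i, w in tasks]

    ok = [r for r in rows if r["status"] == "OK"]
    tests = list(config.tests)
    if ok:
        pool = NullPool(
            llrs={t: np.vstack([r["nulls"][t] for r in ok]) for t in tests},
            region_ids=[r["region_id"] for r in ok],
            seeds=[r["seed"] for r in ok],
        )
        pvals = pool_and_pvalues([r["result"] for r in ok], pool)
    else:
        pool, pvals = None, None

    T_ok = len(ok)
    records = []
    k_ok = 0
    for r in rows:
        rec = dict(
            region_id=r["region_id"], chrom=r["chrom"], start=r["start"], end=r["end"],
            n_variants=r["n_variants"], status=r["status"],
        )
        if r["status"] == "OK":
            res = r["result"]
            for t in tests:
                rec[f"llr_{t}"] = res.llr[t]
                rec[f"p_{t}"] = pvals.p[t][k_ok]
                rec[f"q_{t}"] = pvals.q[t][k_ok]
                rec[f"fwer_{t}"] = min(1.0, pvals.p[t][k_ok] * T_ok)
            rec["converged"] = res.converged
            k_ok += 1
        else:
            for t in tests:
                rec[f"llr_{t}"] = np.nan
                rec[f"p_{t}"] = np.nan
                rec[f"q_{t}"] = np.nan
                rec[f"fwer_{t}"] = np.nan
            rec["converged"] = False
        records.append(rec)
    results = pd.DataFrame.from_records(records)

    null_records = []
    for r in ok:
        for t in tests:
            for j, v in enumerate(r["nulls"][t]):
                null_records.append(
                    dict(test=t, region_id=r["region_id"], replicate=j, llr=v, seed=r["seed"])
                )
    nulls_df = pd.DataFrame.from_records(
        null_records, columns=["test", "region_id", "replicate", "llr", "seed"]
    )

    logger.info(
        "scan: %d windows (%d testable), J=%d, pool=%d LLRs/test, seed=%d",
        T, T_ok, config.J, T_ok * config.J, config.seed,
    )
    if out_results is not None:
        write_results_tsv(results, out_results)
    if out_nulls is not None:
        write_null_pool_tsv(nulls_df, out_nulls)
    return results, nulls_df
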