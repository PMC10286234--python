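"""Genome scans of allele-frequency differentiation (dAF) between grouped
pools: per-SNP absolute difference of group-mean frequencies, a centered
rolling mean over consecutive SNPs, Bonferroni Z-score outlier flagging,
region calling and top-SNP extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FrequencyMatrix, Region, ValidationError


@dataclass
class Contrast:
    """Two disjoint, non-empty groups of pool ids to compare."""

    name: str
    group1: list[str]
    group2: list[str]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValidationError(f"contrast {self.name}: both groups must be non-empty")
        overlap = set(self.group1) & set(self.group2)
        if overlap:
            raise ValidationError(f"contrast {self.name}: groups overlap on {sorted(overlap)}")


@dataclass
class ScanResult:
    contrast: Contrast
    snps: pd.DataFrame  # chrom, pos (aligned with the arrays below)
    daf: np.ndarray
    rolling_mean: np.ndarray
    z_score: np.ndarray
    outlier: np.ndarray  # bool
    threshold_daf: float
    regions: list[Region] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.snps[["chrom", "pos"]].copy()
        df["daf"] = self.daf
        df["rolling_mean"] = self.rolling_mean
        df["z_score"] = self.z_score
        df["outlier"] = self.outlier
        return df


def daf(freqs: FrequencyMatrix, contrast: Contrast) -> np.ndarray:
    """Per-SNP absolute difference of unweighted group-mean alt frequencies.

    A SNP is missing (NaN) when either group has no informative pool there.
    """
    import warnings

    g1 = freqs.pool_columns(contrast.group1)
    g2 = freqs.pool_columns(contrast.group2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(g1, axis=1)
        m2 = np.nanmean(g2, axis=1)
    return np.abs(m1 - m2)


def rolling_daf(daf_series: np.ndarray, chroms: np.ndarray, window: int = 100) -> np.ndarray:
    """Centered moving average over exactly ``window`` consecutive SNPs,
    computed within each chromosome (windows never span chromosomes);
    positions without a full window are NaN."""
    if window < 2:
        raise ValidationError("window must be >= 2")
    daf_series = np.asarray(daf_series, dtype=float)
    out = np.full(daf_series.size, np.nan)
    chroms = np.asarray(chroms)
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        s = pd.Series(daf_series[idx])
        out[idx] = s.rolling(window, center=True, min_periods=window).mean().to_numpy()
    return out


def bonferroni_z_outliers(
    daf_series: np.ndarray, alpha: float = 0.05, trim: float = 0.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Flag upper-tail outliers of the dAF series with a Bonferroni-adjusted
    Z-score threshold against the genome-wide empirical null.

    The null mean/SD are taken over all non-missing values (optionally
    trimmed symmetrically by ``trim`` on each tail before estimating them).
    Returns (threshold in dAF units, z-scores, boolean flags).
    """
    x = np.asarray(daf_series, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 100:
        raise ValidationError("need >= 100 non-missing values for the Z-score null")
    if trim > 0:
        lo, hi = np.quantile(obs, [trim, 1 - trim])
        null = obs[(obs >= lo) & (obs <= hi)]
    else:
        null = obs
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise ValidationError("degenerate dAF series: zero standard deviation")
    n_tests = obs.size
    z_crit = float(stats.norm.isf(alpha / n_tests))
    threshold = mu + z_crit * sd
    z = (x - mu) / sd
    flags = np.where(np.isnan(x), False, x > threshold)
    return threshold, z, flags


def call_regions(
    flags: np.ndarray,
    snps: pd.DataFrame,
    scores: np.ndarray | None = None,
    merge_gap_bp: int = 100_000,
    min_snps: int = 5,
) -> list[Region]:
    """Merge flagged SNPs into regions: maximal runs where consecutive flagged
    SNPs on one chromosome are <= ``merge_gap_bp`` apart and the run has at
    least ``min_snps`` members. Region span is first to last flagged SNP; the
    score is the peak of ``scores`` (default: 0) over member SNPs."""
    flags = np.asarray(flags, dtype=bool)
    regions: list[Region] = []
    idx = np.where(flags)[0]
    if idx.size == 0:
        return regions
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    run: list[int] = [idx[0]]
    for i in idx[1:]:
        prev = run[-1]
        if chrom_arr[i] == chrom_arr[prev] and pos_arr[i] - pos_arr[prev] <= merge_gap_bp:
            run.append(i)
        else:
            _flush_run(run, chrom_arr, pos_arr, scores, min_snps, regions)
            run = [i]
    _flush_run(run, chrom_arr, pos_arr, scores, min_snps, regions)
    return regions


def _flush_run(run, chrom_arr, pos_arr, scores, min_snps, regions) -> None:
    if len(run) >= min_snps:
        score = float(np.nanmax(scores[run])) if scores is not None else 0.0
        if np.isnan(score):
            score = 0.0
        regions.append(
            Region(
                chrom=str(chrom_arr[run[0]]),
                start=int(pos_arr[run[0]]),
                end=int(pos_arr[run[-1]]),
                score=score,
                n_snps=len(run),
            )
        )


def top_fraction(
    daf_series: np.ndarray, snps: pd.DataFrame, region: Region, q: float = 0.02,
    max_snps: int | None = None,
) -> np.ndarray:
    """Indices of the ceil(q * n) highest-dAF SNPs inside a region, ties broken
    towards the leftmost position; ``max_snps`` caps the number returned."""
    in_region = (
        (snps["chrom"] == region.chrom)
        & (snps["pos"] >= region.start)
        & (snps["pos"] <= region.end)
    ).to_numpy()
    idx = np.where(in_region)[0]
    if idx.size == 0:
        raise ValidationError("region contains no SNPs")
    k = int(np.ceil(q * idx.size))
    if max_snps is not None:
        k = min(k, max_snps)
    vals = np.asarray(daf_series, dtype=float)[idx]
    # sort by (-dAF, position); idx is already position-ordered
    order = np.lexsort((np.arange(idx.size), -vals))
    return np.sort(idx[order[:k]])


def scan_contrast(
    freqs: FrequencyMatrix,
    contrast: Contrast,
    window: int = 100,
    alpha: float = 0.05,
    merge_gap_bp: int = 100_000,
    min_snps: int = 5,
) -> ScanResult:
    """Full dAF scan for one contrast: dAF, rolling mean, Bonferroni-Z flags
    and called regions."""
    d = daf(freqs, contrast)
    chroms = freqs.snps["chrom"].to_numpy()
    rm = rolling_daf(d, chroms, window=window)
    threshold, z, flags = bonferroni_z_outliers(d, alpha=alpha)
    regions = call_regions(flags, freqs.snps, scores=rm, merge_gap_bp=merge_gap_bp, min_snps=min_snps)
    return ScanResult(
        contrast=contrast,
        snps=freqs.snps[["chrom", "pos"]].copy(),
        daf=d,
        rolling_mean=rm,
        z_score=z,
        outlier=flags,
        threshold_daf=threshold,
        regions=regions,
    )
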