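"""Marker-set classification (undifferentiated vs highly differentiated SNPs
by across-pool frequency SD), positional thinning, and PCA on pool
frequencies."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FrequencyMatrix, ValidationError


@dataclass
class MarkerSets:
    undifferentiated: np.ndarray  # SNP row indices
    differentiated: np.ndarray
    sd_cut_low: float
    sd_cut_high: float


def classify_markers(
    sd_profile: np.ndarray, sd_cut_low: float = 0.02, sd_cut_high: float = 0.2
) -> MarkerSets:
    """Split SNPs by their across-pool frequency SD: SD <= low is presumed
    neutral, SD >= high presumed selected; the middle band is discarded.
    SNPs without a defined SD belong to neither set."""
    if not 0 <= sd_cut_low < sd_cut_high:
        raise ValidationError("require 0 <= sd_cut_low < sd_cut_high")
    sd = np.asarray(sd_profile, dtype=float)
    defined = ~np.isnan(sd)
    return MarkerSets(
        undifferentiated=np.where(defined & (sd <= sd_cut_low))[0],
        differentiated=np.where(defined & (sd >= sd_cut_high))[0],
        sd_cut_low=sd_cut_low,
        sd_cut_high=sd_cut_high,
    )


def thin_by_distance(
    snps: pd.DataFrame, subset: np.ndarray, spacing_bp: int, keep: str = "first",
    sd_profile: np.ndarray | None = None,
) -> np.ndarray:
    """Thin a position-sorted SNP subset so consecutive kept SNPs on one
    chromosome are at least ``spacing_bp`` apart.

    ``keep="first"`` is the greedy left-to-right rule; ``keep="max-sd"``
    instead keeps the highest-SD SNP within each greedy window (needs
    ``sd_profile``)."""
    subset = np.asarray(subset)
    if spacing_bp <= 0:
        return subset
    chrom = snps["chrom"].to_numpy()[subset]
    pos = snps["pos"].to_numpy()[subset]
    kept: list[int] = []
    if keep == "first":
        last_chrom, last_pos = None, None
        for i in range(subset.size):
            if chrom[i] != last_chrom or pos[i] - last_pos >= spacing_bp:
                kept.append(subset[i])
                last_chrom, last_pos = chrom[i], pos[i]
    elif keep == "max-sd":
        if sd_profile is None:
            raise ValidationError("keep='max-sd' requires an SD profile")
        sd = np.asarray(sd_profile, dtype=float)[subset]
        i = 0
        while i < subset.size:
            j = i
            while (
                j + 1 < subset.size
                and chrom[j + 1] == chrom[i]
                and pos[j + 1] - pos[i] < spacing_bp
            ):
                j += 1
            best = i + int(np.nanargmax(sd[i : j + 1]))
            kept.append(subset[best])
            i = j + 1
    else:
        raise ValidationError(f"unknown keep rule {keep!r}")
    return np.asarray(kept, dtype=int)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    pct_variance: np.ndarray  # per component, %
    loadings: np.ndarray  # features x components


def _pca(matrix: np.ndarray, labels: list[str]) -> PcaResult:
    """Column-centered PCA via SVD; components with zero variance dropped."""
    X = matrix - matrix.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    keep = var > max(1e-12 * var.sum(), 1e-30)
    U, s, Vt, var = U[:, keep], s[keep], Vt[keep], var[keep]
    total = (X**2).sum()
    pct = 100.0 * var / total if total > 0 else np.zeros(0)
    scores = pd.DataFrame(
        U * s, index=labels, columns=[f"PC{i + 1}" for i in range(s.size)]
    )
    return PcaResult(scores=scores, pct_variance=pct, loadings=Vt.T)


def pca_frequencies(freqs: FrequencyMatrix, subset: np.ndarray | None = None) -> PcaResult:
    """PCA of pools on per-SNP centered allele frequencies (no variance
    scaling); missing cells are mean-imputed per SNP."""
    f = freqs.freq if subset is None else freqs.freq[np.asarray(subset)]
    if f.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 pools")
    X = f.T.copy()  # pools x SNPs
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    X = X[:, ~np.isnan(X).any(axis=0)]  # drop SNPs untyped everywhere
    return _pca(X, freqs.pool_ids)
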