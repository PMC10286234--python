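"""Effective-coverage-corrected pool allele frequencies.

Pool-seq read counts reflect two nested sampling steps: chromosomes into the
DNA pool, then reads from those chromosomes. The effective coverage

    n_eff = (n_chromosomes * depth - 1) / (n_chromosomes + depth)

downweights the raw depth towards the information actually carried by the
two-level sample; it is bounded above by both the depth and the haploid pool
size. Frequencies themselves are the raw read proportions; corrected counts
rescale them to n_eff for downstream estimators that need count-like input.
"""

from __future__ import annotations

import numpy as np

from .containers import FrequencyMatrix, PoolCountMatrix, ValidationError


def effective_depth(n_chromosomes, depth, formula: str = "standard"):
    """Effective number of observed chromosomes for a pooled sample.

    Parameters
    ----------
    n_chromosomes : haploid pool size (2 x diploid individuals); scalar or array.
    depth : read depth at the site; scalar or array. Zero depth yields NaN.
    formula : "standard" keeps the real-valued ratio; "floor" truncates to an
        integer chromosome count.
    """
    n = np.asarray(n_chromosomes, dtype=float)
    c = np.asarray(depth, dtype=float)
    if (n < 1).any():
        raise ValidationError("n_chromosomes must be >= 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        n_eff = np.where(c > 0, (n * c - 1.0) / (n + c), np.nan)
    if formula == "floor":
        n_eff = np.floor(n_eff)
    elif formula != "standard":
        raise ValueError(f"unknown neff formula {formula!r}")
    if np.isscalar(n_chromosomes) and np.isscalar(depth):
        return float(n_eff)
    return n_eff


def estimate_frequencies(counts: PoolCountMatrix, neff_formula: str = "standard") -> FrequencyMatrix:
    """Alt-allele frequencies and effective coverage for every SNP x pool cell.

    Cells with zero depth are missing (NaN frequency and n_eff). Corrected alt
    counts are round(freq * n_eff).
    """
    depth = counts.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, counts.alt_count / np.maximum(depth, 1), np.nan)
    n_eff = effective_depth(
        counts.n_chromosomes[np.newaxis, :], depth, formula=neff_formula
    )
    with np.errstate(invalid="ignore"):
        corrected_alt = np.round(freq * n_eff)
    return FrequencyMatrix(
        snps=counts.snps.copy(),
        freq=freq,
        n_eff=n_eff,
        depth=depth,
        corrected_alt=corrected_alt,
        pools=counts.pools.copy(),
    )


def frequency_sd_profile(freqs: FrequencyMatrix, pool_subset: list[str] | None = None) -> np.ndarray:
    """Per-SNP sample standard deviation (ddof=1) of frequencies across pools.

    Missing cells are excluded; SNPs with fewer than two informative pools get
    NaN. ``pool_subset`` restricts the computation to the named pools.
    """
    if pool_subset is not None:
        if len(pool_subset) == 0:
            raise ValidationError("empty pool subset")
        f = freqs.pool_columns(pool_subset)
    else:
        f = freqs.freq
    n_inf = np.sum(~np.isnan(f), axis=1)
    sd = np.full(f.shape[0], np.nan)
    ok = n_inf >= 2
    if ok.any():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd[ok] = np.nanstd(f[ok], axis=1, ddof=1)
    return sd
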