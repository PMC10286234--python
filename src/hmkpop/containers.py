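"""In-memory containers for pooled count data, allele frequencies and genotypes.

All genomic coordinates are 1-based inclusive; the BED writer in
:mod:`hmkpop.io` is the only 0-based surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_INDEX_COLUMNS = ["chrom", "pos", "ref", "alt"]

POOL_META_COLUMNS = ["pool_id", "n_individuals", "latitude", "longitude", "group_label", "year"]


class ValidationError(ValueError):
    """Raised when an on-disk table or in-memory matrix violates an invariant."""


def validate_pool_meta(pools: pd.DataFrame) -> pd.DataFrame:
    """Validate a pool metadata table (one row per sequenced pool).

    Required columns: ``pool_id``, ``n_individuals``, ``latitude``,
    ``longitude``, ``group_label``; ``year`` is optional. Returns the frame
    with a normalised column order.
    """
    required = ["pool_id", "n_individuals", "latitude", "longitude", "group_label"]
    missing = [c for c in required if c not in pools.columns]
    if missing:
        raise ValidationError(f"pool metadata missing columns: {missing}")
    if "year" not in pools.columns:
        pools = pools.assign(year=pd.NA)
    if pools["pool_id"].duplicated().any():
        dups = pools.loc[pools["pool_id"].duplicated(), "pool_id"].tolist()
        raise ValidationError(f"duplicate pool_id: {dups}")
    if (pools["n_individuals"] < 1).any():
        raise ValidationError("n_individuals must be >= 1 for every pool")
    if (pools["latitude"].abs() > 90).any():
        raise ValidationError("latitude out of range [-90, 90]")
    if (pools["longitude"].abs() > 180).any():
        raise ValidationError("longitude out of range [-180, 180]")
    return pools[POOL_META_COLUMNS].reset_index(drop=True)


def _validate_snp_index(snps: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNP_INDEX_COLUMNS if c not in snps.columns]
    if missing:
        raise ValidationError(f"SNP index missing columns: {missing}")
    for chrom, sub in snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        bad = np.where(np.diff(pos) <= 0)[0]
        if bad.size:
            i = sub.index[bad[0] + 1]
            raise ValidationError(
                f"positions not strictly increasing on {chrom} at row {i} (pos {pos[bad[0] + 1]})"
            )
    return snps.reset_index(drop=True)


@dataclass
class PoolCountMatrix:
    """Per-SNP biallelic read counts for a set of pooled samples.

    Attributes
    ----------
    snps : DataFrame with columns chrom, pos (1-based), ref, alt.
    ref_count, alt_count : int arrays of shape (n_snps, n_pools).
    pools : pool metadata frame (see :func:`validate_pool_meta`).
    """

    snps: pd.DataFrame
    ref_count: np.ndarray
    alt_count: np.ndarray
    pools: pd.DataFrame

    def __post_init__(self) -> None:
        self.snps = _validate_snp_index(self.snps)
        self.pools = validate_pool_meta(self.pools)
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        n_snps, n_pools = len(self.snps), len(self.pools)
        if self.ref_count.shape != (n_snps, n_pools) or self.alt_count.shape != (n_snps, n_pools):
            raise ValidationError(
                f"count arrays must be ({n_snps}, {n_pools}); got "
                f"{self.ref_count.shape} and {self.alt_count.shape}"
            )
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValidationError("negative read counts")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def pool_ids(self) -> list[str]:
        return self.pools["pool_id"].tolist()

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def n_chromosomes(self) -> np.ndarray:
        """Haploid pool sizes (2 x diploid individuals), one per pool."""
        return 2 * self.pools["n_individuals"].to_numpy(dtype=np.int64)

    def pool_index(self, pool_id: str) -> int:
        ids = self.pool_ids
        try:
            return ids.index(pool_id)
        except ValueError:
            raise KeyError(f"unknown pool {pool_id!r}; expected one of {ids}") from None

    def subset_pools(self, pool_ids: list[str]) -> "PoolCountMatrix":
        idx = [self.pool_index(p) for p in pool_ids]
        return PoolCountMatrix(
            snps=self.snps.copy(),
            ref_count=self.ref_count[:, idx],
            alt_count=self.alt_count[:, idx],
            pools=self.pools.iloc[idx].reset_index(drop=True),
        )


@dataclass
class FrequencyMatrix:
    """Alt-allele frequencies per SNP x pool with effective coverage.

    ``freq`` and ``n_eff`` are float arrays with NaN where the pool had zero
    depth at the SNP (untyped). ``corrected_alt`` holds alt read counts
    rescaled to the effective coverage.
    """

    snps: pd.DataFrame
    freq: np.ndarray
    n_eff: np.ndarray
    depth: np.ndarray
    corrected_alt: np.ndarray
    pools: pd.DataFrame

    def __post_init__(self) -> None:
        self.snps = _validate_snp_index(self.snps)
        self.pools = validate_pool_meta(self.pools)
        self.freq = np.asarray(self.freq, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq, initial=0.0) < 0 or np.nanmax(self.freq, initial=0.0) > 1:
                raise ValidationError("frequencies outside [0, 1]")
        untyped = np.asarray(self.depth) == 0
        if not np.array_equal(np.isnan(self.freq), untyped):
            raise ValidationError("freq must be NaN exactly where depth is 0")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def pool_ids(self) -> list[str]:
        return self.pools["pool_id"].tolist()

    def pool_columns(self, pool_ids: list[str]) -> np.ndarray:
        ids = self.pool_ids
        try:
            idx = [ids.index(p) for p in pool_ids]
        except ValueError as exc:
            raise KeyError(f"unknown pool in {pool_ids}; expected subset of {ids}") from exc
        return self.freq[:, idx]

    def snp_labels(self) -> pd.Series:
        return self.snps["chrom"].astype(str) + "_" + self.snps["pos"].astype(str)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype dosages (alt-allele counts 0/1/2, NaN missing)."""

    individuals: pd.DataFrame  # columns: individual_id, site
    snps: pd.DataFrame  # columns: chrom, pos (ref/alt optional)
    geno: np.ndarray  # float, shape (n_individuals, n_snps)

    def __post_init__(self) -> None:
        if self.individuals["individual_id"].duplicated().any():
            dup = self.individuals.loc[
                self.individuals["individual_id"].duplicated(), "individual_id"
            ].tolist()
            raise ValidationError(f"duplicate individual id: {dup}")
        self.geno = np.asarray(self.geno, dtype=float)
        valid = np.isnan(self.geno) | np.isin(self.geno, (0.0, 1.0, 2.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValidationError(
                f"genotype outside {{0,1,2,NA}} at individual "
                f"{self.individuals['individual_id'].iloc[i]!r}, marker column {j}"
            )
        n_ind, n_snp = self.geno.shape
        if n_ind != len(self.individuals) or n_snp != len(self.snps):
            raise ValidationError("genotype array shape does not match labels")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sites(self) -> pd.Series:
        return self.individuals["site"]

    def individual_call_rate(self) -> pd.Series:
        rate = 1.0 - np.isnan(self.geno).mean(axis=1)
        return pd.Series(rate, index=self.individuals["individual_id"].to_numpy())

    def marker_call_rate(self) -> pd.Series:
        rate = 1.0 - np.isnan(self.geno).mean(axis=0)
        return pd.Series(rate, index=self.snp_labels().to_numpy())

    def snp_labels(self) -> pd.Series:
        return self.snps["chrom"].astype(str) + "_" + self.snps["pos"].astype(str)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            individuals=self.individuals.copy(),
            snps=self.snps.iloc[keep].reset_index(drop=True),
            geno=self.geno[:, keep],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            individuals=self.individuals.iloc[keep].reset_index(drop=True),
            snps=self.snps.copy(),
            geno=self.geno[keep, :],
        )


@dataclass
class Region:
    """A called genomic region, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    n_snps: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"region end {self.end} < start {self.start}")
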