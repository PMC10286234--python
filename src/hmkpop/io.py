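"""Readers and writers for the on-disk artifacts of the pipeline.

Canonical interchange formats are plain text: a counts TSV (``chrom  pos  ref
alt`` then one ``ref,alt`` integer pair per pool), CSV genotype matrices, TSV
metadata/environment tables and BED region files. A VCF adapter reads
per-sample allelic depths as pooled counts.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    POOL_META_COLUMNS,
    GenotypeMatrix,
    PoolCountMatrix,
    Region,
    ValidationError,
)

# ---------------------------------------------------------------------------
# pool metadata and environment tables


def read_pool_meta(path: str | Path) -> pd.DataFrame:
    from .containers import validate_pool_meta

    df = pd.read_csv(path, sep="\t")
    return validate_pool_meta(df)


def write_pool_meta(pools: pd.DataFrame, path: str | Path) -> None:
    pools[POOL_META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Environmental variables per site: first column ``site_id``, then one
    numeric column per variable."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "site_id":
        raise ValidationError("environment table must start with a site_id column")
    if df["site_id"].duplicated().any():
        raise ValidationError("duplicate site_id in environment table")
    return df


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pooled read counts


def read_pool_counts(
    path: str | Path,
    meta: pd.DataFrame,
    format_hint: str | None = None,
) -> PoolCountMatrix:
    """Read pooled per-SNP read counts from the counts TSV or a VCF.

    Parameters
    ----------
    path : counts TSV (columns ``chrom pos ref alt`` then one ``ref,alt``
        pair per pool) or a VCF whose per-sample AD field carries the counts.
    meta : validated pool metadata; its pool_ids must match the file columns
        (TSV) or sample names (VCF).
    format_hint : "tsv" or "vcf"; inferred from the suffix when omitted.
    """
    path = Path(path)
    fmt = format_hint or ("vcf" if ".vcf" in path.suffixes else "tsv")
    if fmt == "vcf":
        return _read_counts_vcf(path, meta)
    return _read_counts_tsv(path, meta)


def _read_counts_tsv(path: Path, meta: pd.DataFrame) -> PoolCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = meta["pool_id"].tolist()
    fixed = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    unknown = [c for c in df.columns if c not in fixed and c not in expected]
    absent = [p for p in expected if p not in df.columns]
    if unknown or absent:
        raise ValidationError(
            f"{path}: pool columns do not match metadata; expected {expected}, "
            f"unknown columns {unknown}, absent pools {absent}"
        )
    n = len(df)
    ref_count = np.zeros((n, len(expected)), dtype=np.int64)
    alt_count = np.zeros((n, len(expected)), dtype=np.int64)
    for j, pool in enumerate(expected):
        pairs = df[pool].astype(str).str.split(",", expand=True)
        if pairs.shape[1] != 2 or pairs.isna().any().any():
            bad = pairs.isna().any(axis=1)
            line = df.index[bad][0] + 2 if bad.any() else "?"
            raise ValidationError(f"{path}: malformed count pair for pool {pool} at line {line}")
        try:
            ref_count[:, j] = pairs[0].astype(np.int64)
            alt_count[:, j] = pairs[1].astype(np.int64)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer count in pool column {pool}: {exc}") from exc
    try:
        return PoolCountMatrix(
            snps=df[fixed].copy(), ref_count=ref_count, alt_count=alt_count, pools=meta
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _read_counts_vcf(path: Path, meta: pd.DataFrame) -> PoolCountMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    expected = meta["pool_id"].tolist()
    if list(vcf.samples) != expected:
        raise ValidationError(
            f"{path}: VCF samples {list(vcf.samples)} do not match expected pools {expected}"
        )
    rows, refs, alts = [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise ValidationError(f"{path}: record {rec.CHROM}:{rec.POS} lacks an AD field")
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing AD as a negative sentinel
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-biallelic-SNP records", stacklevel=2)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return PoolCountMatrix(
        snps=snps,
        ref_count=np.asarray(refs, dtype=np.int64).reshape(len(rows), -1),
        alt_count=np.asarray(alts, dtype=np.int64).reshape(len(rows), -1),
        pools=meta,
    )


def write_pool_counts(counts: PoolCountMatrix, path: str | Path) -> None:
    df = counts.snps.copy()
    for j, pool in enumerate(counts.pool_ids):
        df[pool] = [
            f"{r},{a}" for r, a in zip(counts.ref_count[:, j], counts.alt_count[:, j])
        ]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read an individuals x SNPs genotype CSV.

    Layout: ``individual_id, site`` then one column per SNP named
    ``<chrom>_<pos>`` with values in {0, 1, 2, NA}.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "site": str})
    if list(df.columns[:2]) != ["individual_id", "site"]:
        raise ValidationError(f"{path}: first two columns must be individual_id, site")
    marker_cols = list(df.columns[2:])
    geno = df[marker_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(geno) | np.isin(geno, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: invalid genotype {geno[i, j]!r} for individual "
            f"{df['individual_id'].iloc[i]} at marker {marker_cols[j]}"
        )
    chroms, positions = [], []
    for col in marker_cols:
        chrom, _, pos = col.rpartition("_")
        chroms.append(chrom)
        positions.append(int(pos))
    snps = pd.DataFrame({"chrom": chroms, "pos": positions})
    return GenotypeMatrix(individuals=df[["individual_id", "site"]].copy(), snps=snps, geno=geno)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.individuals.copy()
    labels = gm.snp_labels()
    for j, lab in enumerate(labels):
        col = gm.geno[:, j]
        df[lab] = pd.array(
            [None if np.isnan(v) else int(v) for v in col], dtype="Int64"
        )
    df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# regions (BED)


def write_regions_bed(regions: list[Region], path: str | Path) -> None:
    """Write regions as BED: 0-based half-open, sorted by (chrom, start)."""
    lines = ["#chrom\tstart\tend\tscore"]
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.score:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, *rest = line.split("\t")
        score = float(rest[0]) if rest else 0.0
        regions.append(Region(chrom=chrom, start=int(start) + 1, end=int(end), score=score))
    return regions
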