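"""Per-pool nucleotide diversity (pi) in sliding windows.

Per segregating site the heterozygosity is 2 p (1-p) C/(C-1) with p the pool
alt-read fraction and C the read depth — the C/(C-1) factor corrects the
small-sample bias of estimating heterozygosity from C sampled reads. Window
pi is the sum of site heterozygosities over the covered window length,
reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PoolCountMatrix, ValidationError


def site_pi(ref_reads, alt_reads, min_coverage: int = 4) -> np.ndarray:
    """Per-site heterozygosity 2 p (1-p) C/(C-1); sites below ``min_coverage``
    (or below 2 reads) contribute NaN."""
    ref = np.asarray(ref_reads, dtype=float)
    alt = np.asarray(alt_reads, dtype=float)
    depth = ref + alt
    ok = depth >= max(min_coverage, 2)
    d = np.maximum(depth, 2)
    p = alt / d
    pi = 2.0 * p * (1.0 - p) * d / (d - 1.0)
    return np.where(ok, pi, np.nan)


@dataclass
class WindowedDiversity:
    windows: pd.DataFrame  # chrom, start, end + one pi_percent column per pool
    window: int
    step: int


def windowed_pi(
    counts: PoolCountMatrix,
    window: int = 10_000,
    step: int = 2_000,
    min_coverage: int = 4,
    min_covered: float = 0.5,
) -> WindowedDiversity:
    """Sliding-window pi per pool, as a percentage of the covered window
    length.

    With SNP-only input the per-base coverage is unknown; the covered fraction
    defaults to 1 (every non-SNP position assumed covered and monomorphic),
    which is flagged as approximate in the documentation. Windows whose
    fraction of typed SNP sites falls below ``min_covered`` are NaN.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    if step <= 0:
        raise ValidationError("step must be positive")
    pi = np.column_stack(
        [
            site_pi(counts.ref_count[:, j], counts.alt_count[:, j], min_coverage=min_coverage)
            for j in range(counts.n_pools)
        ]
    )
    chrom_arr = counts.snps["chrom"].to_numpy()
    pos_arr = counts.snps["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        pos = pos_arr[sel]
        pi_c = pi[sel]
        chrom_end = pos.max()
        start = 1
        while start + window - 1 <= chrom_end:
            end = start + window - 1
            in_win = (pos >= start) & (pos <= end)
            row: dict = {"chrom": chrom, "start": start, "end": end}
            for j, pool in enumerate(counts.pool_ids):
                vals = pi_c[in_win, j]
                n_sites = vals.size
                typed = ~np.isnan(vals)
                covered_fraction = typed.mean() if n_sites else 1.0
                if covered_fraction < min_covered:
                    row[pool] = np.nan
                else:
                    covered_len = window - n_sites + typed.sum()  # untyped SNP sites uncovered
                    row[pool] = 100.0 * np.nansum(vals) / max(covered_len, 1)
            rows.append(row)
            start += step
    return WindowedDiversity(windows=pd.DataFrame(rows), window=window, step=step)
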