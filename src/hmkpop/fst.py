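"""Pairwise pool-FST, block-jackknife confidence intervals and
isolation-by-distance testing.

The estimator is a method-of-moments ANOVA for pooled sequencing that models
the two-level sampling of pool-seq: chromosomes are drawn into the pool, then
reads are drawn (with replacement) from those chromosomes. Writing Q1 for the
probability that two distinct chromosomes within a pool are identical in state
and Q2 for the same probability between pools,

    FST = (Q1 - Q2) / (1 - Q2).

For a pool of n chromosomes observed through c reads with alt-read fraction
p, the read-pair identity P = [a(a-1) + r(r-1)] / [c(c-1)] (a alt reads,
r ref reads) mixes same-chromosome pairs (probability 1/n, identity 1) with
distinct-chromosome pairs, so Q1 = (nP - 1)/(n - 1) is unbiased for the
within-pool identity. Reads from different pools always come from different
chromosomes, so Q2 = p1 p2 + (1-p1)(1-p2) directly. In the infinite-depth
limit the estimator reduces to Weir & Cockerham's two-population theta.

Multi-SNP estimates are ratio-of-sums (sum of per-SNP numerators over sum of
denominators), the standard aggregation for low-information SNPs, with a
delete-one block jackknife over blocks of consecutive SNPs for the standard
error and 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PoolCountMatrix, ValidationError

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# per-SNP moment components


def _identity_components(
    ref_a, alt_a, n_chrom_a, ref_b, alt_b, n_chrom_b
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (numerator, denominator, usable) of the pairwise pool-FST.

    SNPs with depth < 2 in either pool are unusable (the read-pair identity
    needs two reads).
    """
    ca = np.asarray(ref_a + alt_a, dtype=float)
    cb = np.asarray(ref_b + alt_b, dtype=float)
    usable = (ca >= 2) & (cb >= 2)
    ca_s, cb_s = np.maximum(ca, 2), np.maximum(cb, 2)
    pa = alt_a / ca_s
    pb = alt_b / cb_s
    P_a = (alt_a * (alt_a - 1.0) + ref_a * (ref_a - 1.0)) / (ca_s * (ca_s - 1.0))
    P_b = (alt_b * (alt_b - 1.0) + ref_b * (ref_b - 1.0)) / (cb_s * (cb_s - 1.0))
    q1_a = (n_chrom_a * P_a - 1.0) / (n_chrom_a - 1.0)
    q1_b = (n_chrom_b * P_b - 1.0) / (n_chrom_b - 1.0)
    q1 = 0.5 * (q1_a + q1_b)
    q2 = pa * pb + (1.0 - pa) * (1.0 - pb)
    num = np.where(usable, q1 - q2, 0.0)
    den = np.where(usable, 1.0 - q2, 0.0)
    return num, den, usable


@dataclass
class FstResult:
    pool_a: str
    pool_b: str
    fst: float
    se: float
    ci95: tuple[float, float]
    n_snps_used: int
    block_num: np.ndarray  # per-block numerator sums
    block_den: np.ndarray


def pairwise_pool_fst(
    counts: PoolCountMatrix, pool_a: str, pool_b: str, block_size: int = 1000
) -> FstResult:
    """Pairwise pool-FST between two pools, ratio-of-sums over shared typed
    SNPs, with a block-jackknife SE over blocks of ``block_size`` consecutive
    SNPs (SE and CI are NaN when fewer than two blocks are available)."""
    ia, ib = counts.pool_index(pool_a), counts.pool_index(pool_b)
    n_chrom = counts.n_chromosomes
    num, den, usable = _identity_components(
        counts.ref_count[:, ia],
        counts.alt_count[:, ia],
        n_chrom[ia],
        counts.ref_count[:, ib],
        counts.alt_count[:, ib],
        n_chrom[ib],
    )
    n_used = int(usable.sum())
    if n_used == 0:
        raise ValidationError(f"no shared typed SNPs between {pool_a} and {pool_b}")
    fst = float(num.sum() / den.sum())

    # blocks over usable SNPs in genome order
    u_num, u_den = num[usable], den[usable]
    n_blocks = int(np.ceil(n_used / block_size))
    edges = np.arange(1, n_blocks) * block_size
    block_num = np.array([b.sum() for b in np.split(u_num, edges)])
    block_den = np.array([b.sum() for b in np.split(u_den, edges)])
    if n_blocks >= 2:
        se, ci = block_jackknife_ci(block_num, block_den)
    else:
        se, ci = float("nan"), (float("nan"), float("nan"))
    return FstResult(
        pool_a=pool_a,
        pool_b=pool_b,
        fst=fst,
        se=se,
        ci95=ci,
        n_snps_used=n_used,
        block_num=block_num,
        block_den=block_den,
    )


def block_jackknife_ci(
    block_num: np.ndarray, block_den: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Delete-one-block jackknife of a ratio-of-sums.

    SE = sqrt(((B-1)/B) * sum_i (theta_(i) - mean theta_(i))^2); the 95% CI is
    the full estimate +/- 1.96 SE.
    """
    block_num = np.asarray(block_num, dtype=float)
    block_den = np.asarray(block_den, dtype=float)
    B = block_num.size
    if B < 2:
        raise ValidationError("block jackknife needs at least 2 blocks")
    tot_num, tot_den = block_num.sum(), block_den.sum()
    theta_i = (tot_num - block_num) / (tot_den - block_den)
    se = float(np.sqrt((B - 1) / B * np.sum((theta_i - theta_i.mean()) ** 2)))
    fst = tot_num / tot_den
    return se, (float(fst - 1.96 * se), float(fst + 1.96 * se))


def pairwise_fst_matrix(counts: PoolCountMatrix, block_size: int = 1000) -> pd.DataFrame:
    """Symmetric matrix of pairwise pool-FST over all pool pairs."""
    ids = counts.pool_ids
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            f = pairwise_pool_fst(counts, a, b, block_size=block_size).fst
            mat.loc[a, b] = mat.loc[b, a] = f
    return mat


# ---------------------------------------------------------------------------
# group comparisons


def group_fst_comparison(
    fst_sets: dict[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Two-sided exact-when-possible Wilcoxon rank-sum tests on named pairs of
    pairwise-FST value sets, Holm-adjusted across the declared family.

    ``fst_sets`` maps comparison name -> (values_group1, values_group2).
    """
    from statsmodels.stats.multitest import multipletests

    names, pvals = [], []
    for name, (x, y) in fst_sets.items():
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        if x.size == 0 or y.size == 0:
            raise ValidationError(f"comparison {name}: empty group")
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        names.append(name)
        pvals.append(float(res.pvalue))
    adj = multipletests(pvals, method="holm")[1]
    return pd.DataFrame({"comparison": names, "p_value": pvals, "p_adjusted": adj})


# ---------------------------------------------------------------------------
# geography and isolation by distance


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lat, lon) points on a 6371-km sphere."""
    lat1, lon1 = np.radians(a)
    lat2, lon2 = np.radians(b)
    s = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(s)))


def distance_matrix_km(pools: pd.DataFrame) -> pd.DataFrame:
    ids = pools["pool_id"].tolist()
    coords = pools[["latitude", "longitude"]].to_numpy()
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = great_circle_km(tuple(coords[i]), tuple(coords[j]))
            mat.iloc[i, j] = mat.iloc[j, i] = d
    return mat


def linearize_fst(fst: np.ndarray) -> np.ndarray:
    """Rousset linearization FST / (1 - FST); undefined at FST = 1."""
    fst = np.asarray(fst, dtype=float)
    if np.any(fst >= 1.0):
        raise ValidationError("FST of 1 cannot be linearized")
    return fst / (1.0 - fst)


@dataclass
class IbdResult:
    slope: float  # linearized FST per km
    intercept: float
    mantel_r: float
    p_value: float
    n_permutations: int


def ibd_test(
    fst_matrix: pd.DataFrame,
    pools: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    exclude: list[str] | None = None,
) -> IbdResult:
    """Isolation-by-distance: regress linearized pairwise FST on great-circle
    km and assess the association with a one-sided Mantel permutation test
    (p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), permuting site labels)."""
    meta = pools
    if exclude:
        keep = [p for p in fst_matrix.index if p not in exclude]
        fst_matrix = fst_matrix.loc[keep, keep]
        meta = pools[pools["pool_id"].isin(keep)].reset_index(drop=True)
    ids = list(fst_matrix.index)
    if not np.allclose(fst_matrix.to_numpy(), fst_matrix.to_numpy().T):
        raise ValidationError("FST matrix must be symmetric")
    km = distance_matrix_km(meta).loc[ids, ids].to_numpy()
    lin = linearize_fst(fst_matrix.to_numpy())
    iu = np.triu_indices(len(ids), k=1)
    x, y = km[iu], lin[iu]
    slope, intercept = np.polyfit(x, y, 1)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(ids)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = lin[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, y_perm)[0, 1] >= r_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return IbdResult(
        slope=float(slope),
        intercept=float(intercept),
        mantel_r=r_obs,
        p_value=float(p),
        n_permutations=n_perm,
    )
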