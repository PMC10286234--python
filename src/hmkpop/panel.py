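"""Reduced SNP-panel analysis on individual genotypes: call-rate QC,
Hardy-Weinberg exact tests, linkage-disequilibrium grouping, per-locus and
pairwise Weir-Cockerham FST, panel reduction, individual PCA, and NMF-based
admixture with cross-entropy model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix, ValidationError
from .markers import PcaResult, _pca

# ---------------------------------------------------------------------------
# QC


@dataclass
class QcReport:
    genotypes: GenotypeMatrix
    dropped_markers: list[str]
    dropped_individuals: list[str]


def genotyping_qc(
    gm: GenotypeMatrix,
    threshold: float = 0.8,
    replicate_pairs: list[tuple[str, str]] | None = None,
) -> QcReport:
    """Retain markers and individuals with call rate strictly above
    ``threshold`` (markers first, then individuals over the retained
    markers), and drop monomorphic markers and markers with conflicting
    homozygote calls between declared replicate pairs."""
    marker_rate = gm.marker_call_rate().to_numpy()
    labels = gm.snp_labels().to_numpy()
    keep_m = marker_rate > threshold

    # replicate concordance: a homozygote-vs-opposite-homozygote conflict fails the marker
    if replicate_pairs:
        ids = gm.individuals["individual_id"].tolist()
        for a, b in replicate_pairs:
            if a not in ids or b not in ids:
                continue
            ga = gm.geno[ids.index(a)]
            gb = gm.geno[ids.index(b)]
            conflict = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
            keep_m &= ~conflict

    sub = gm.subset_markers(np.where(keep_m)[0])
    ind_rate = sub.individual_call_rate().to_numpy()
    keep_i = ind_rate > threshold
    sub = sub.subset_individuals(np.where(keep_i)[0])

    # monomorphic after filtering
    with np.errstate(invalid="ignore"):
        mono = np.array(
            [
                bool(np.nanmin(c) == np.nanmax(c)) if np.any(~np.isnan(c)) else True
                for c in sub.geno.T
            ],
            dtype=bool,
        )
    final = sub.subset_markers(np.where(~mono)[0])
    if final.n_snps == 0 or final.n_individuals == 0:
        raise ValidationError("QC removed every marker or individual")
    kept_labels = set(final.snp_labels())
    kept_ids = set(final.individuals["individual_id"])
    return QcReport(
        genotypes=final,
        dropped_markers=[l for l in labels if l not in kept_labels],
        dropped_individuals=[
            i for i in gm.individuals["individual_id"] if i not in kept_ids
        ],
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic marker.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (two-sided, by probability ordering).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValidationError("empty genotype counts")
    n_a = 2 * n_hom_ref + n_het  # ref allele copies
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a constant:
    #   log n! - log n_AA! - log h! - log n_aa! + h log 2
    n_aa = (n_a - hets) // 2
    n_bb = (n_b - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(n_aa + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_scan(gm: GenotypeMatrix) -> pd.DataFrame:
    """HWE exact p per marker with Holm adjustment across the marker family."""
    from statsmodels.stats.multitest import multipletests

    pvals = []
    for j in range(gm.n_snps):
        g = gm.geno[:, j]
        g = g[~np.isnan(g)]
        pvals.append(hwe_exact(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())))
    adj = multipletests(pvals, method="holm")[1]
    return pd.DataFrame(
        {"marker": gm.snp_labels(), "hwe_p": pvals, "hwe_p_adjusted": adj}
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_test(
    g1: np.ndarray, g2: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float] | None:
    """Composite genotypic LD between two dosage vectors: squared Pearson
    correlation over individuals called at both markers, with a permutation
    p-value (shuffling one vector). Returns None with < 10 shared calls."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < 10:
        return None
    x, y = g1[ok], g2[ok]
    if x.std() == 0 or y.std() == 0:
        return None
    r_obs = np.corrcoef(x, y)[0, 1]
    r2 = r_obs**2
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        r = np.corrcoef(x, rng.permutation(y))[0, 1]
        if r * r >= r2 - 1e-15:
            n_ge += 1
    return float(r2), (1 + n_ge) / (n_perm + 1)


def ld_groups(
    gm: GenotypeMatrix,
    n_perm: int = 200,
    alpha: float = 0.05,
    proximity_bp: int = 1_000_000,
    seed: int = 0,
) -> list[list[int]]:
    """Partition markers into linkage groups: connected components of the
    union of (a) pairs with Holm-significant permutation LD and (b)
    same-chromosome pairs within ``proximity_bp`` (linked by physical
    closeness regardless of significance)."""
    from statsmodels.stats.multitest import multipletests

    n = gm.n_snps
    chrom = gm.snps["chrom"].to_numpy()
    pos = gm.snps["pos"].to_numpy()
    pairs, pvals = [], []
    prox_edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if chrom[i] == chrom[j] and abs(int(pos[i]) - int(pos[j])) <= proximity_bp:
                prox_edges.append((i, j))
            res = ld_test(gm.geno[:, i], gm.geno[:, j], n_perm=n_perm, seed=seed + i * n + j)
            if res is not None:
                pairs.append((i, j))
                pvals.append(res[1])
    edges = list(prox_edges)
    if pvals:
        sig = multipletests(pvals, method="holm")[1] <= alpha
        edges += [p for p, s in zip(pairs, sig) if s]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [sorted(v) for v in sorted(groups.values(), key=lambda g: g[0])]


# ---------------------------------------------------------------------------
# Weir-Cockerham FST from genotypes


def _wc_components(gm: GenotypeMatrix, pop_labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components (a, a+b+c) over
    the populations in ``pop_labels``; loci where fewer than two populations
    have two typed individuals yield NaN."""
    pops = pd.unique(pop_labels)
    r_max = len(pops)
    n_loci = gm.n_snps
    a_out = np.full(n_loci, np.nan)
    abc_out = np.full(n_loci, np.nan)
    masks = [(pop_labels == p).to_numpy() for p in pops]
    for l in range(n_loci):
        g = gm.geno[:, l]
        ns, ps, hs = [], [], []
        for m in masks:
            gl = g[m]
            gl = gl[~np.isnan(gl)]
            if gl.size >= 2:
                ns.append(gl.size)
                ps.append(gl.mean() / 2.0)
                hs.append(np.mean(gl == 1))
        r = len(ns)
        if r < 2:
            continue
        ns = np.asarray(ns, dtype=float)
        ps = np.asarray(ps)
        hs = np.asarray(hs)
        n_bar = ns.mean()
        n_c = (r * n_bar - (ns**2).sum() / (r * n_bar)) / (r - 1)
        p_bar = (ns * ps).sum() / (r * n_bar)
        s2 = (ns * (ps - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (ns * hs).sum() / (r * n_bar)
        if n_c == 0 or n_bar <= 1:
            continue
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0
        a_out[l] = a
        abc_out[l] = a + b + c
    return a_out, abc_out


def wc_fst(gm: GenotypeMatrix, pop_labels: pd.Series | None = None) -> dict:
    """Weir-Cockerham theta from individual genotypes.

    Returns per-locus theta, the multi-locus ratio-of-sums estimate, a
    per-locus mean-over-population-pairs theta (used for panel ranking) and
    the pairwise population matrix.
    """
    if pop_labels is None:
        pop_labels = gm.sites
    pops = list(pd.unique(pop_labels))
    if len(pops) < 2:
        raise ValidationError("need >= 2 populations")
    a, abc = _wc_components(gm, pop_labels)
    if np.all(np.isnan(a)):
        raise ValidationError("no locus has two populations with >= 2 typed individuals")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / abc
    multi = float(np.nansum(a) / np.nansum(abc))

    pairwise = pd.DataFrame(0.0, index=pops, columns=pops)
    pair_locus = np.zeros((gm.n_snps, 0))
    pair_cols = []
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            m = pop_labels.isin([pa, pb])
            sub = gm.subset_individuals(np.where(m.to_numpy())[0])
            ap, abcp = _wc_components(sub, pop_labels[m].reset_index(drop=True))
            pairwise.loc[pa, pb] = pairwise.loc[pb, pa] = float(
                np.nansum(ap) / np.nansum(abcp)
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                pair_locus = np.column_stack([pair_locus, ap / abcp])
            pair_cols.append(f"{pa}|{pb}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_pair = np.nanmean(pair_locus, axis=1)
    return {
        "per_locus": pd.Series(per_locus, index=gm.snp_labels().to_numpy()),
        "multi_locus": multi,
        "per_locus_pair_mean": pd.Series(mean_pair, index=gm.snp_labels().to_numpy()),
        "pairwise": pairwise,
    }


def reduce_panel(
    gm: GenotypeMatrix, groups: list[list[int]], per_locus_fst: pd.Series
) -> list[int]:
    """Keep one marker per linkage group: the one with the highest mean
    per-locus FST, ties resolved towards the lowest genomic position."""
    labels = gm.snp_labels().to_numpy()
    pos = gm.snps["pos"].to_numpy()
    kept = []
    for grp in groups:
        vals = np.array([per_locus_fst.get(labels[i], np.nan) for i in grp])
        vals = np.where(np.isnan(vals), -np.inf, vals)
        best = min(
            range(len(grp)), key=lambda t: (-vals[t], pos[grp[t]])
        )
        kept.append(grp[best])
    return sorted(kept)


# ---------------------------------------------------------------------------
# individual PCA


def individual_pca(gm: GenotypeMatrix) -> PcaResult:
    """Centered PCA of individuals on dosages, missing mean-imputed per marker."""
    if gm.n_individuals < 3:
        raise ValidationError("need >= 3 individuals")
    X = gm.geno.copy()
    col_mean = np.nanmean(X, axis=0)
    i, j = np.where(np.isnan(X))
    X[i, j] = col_mean[j]
    return _pca(X, gm.individuals["individual_id"].tolist())


# ---------------------------------------------------------------------------
# NMF admixture with masked cross-entropy


def _project_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = Q.shape
    s = -np.sort(-Q, axis=1)
    css = np.cumsum(s, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = s - css / ind > 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(Q - theta[:, None], 0.0)


@dataclass
class AdmixtureFit:
    Q: np.ndarray  # individuals x selected_K ancestry proportions
    G: np.ndarray  # selected_K x markers ancestral alt frequencies
    cross_entropy: pd.DataFrame  # columns K, repetition, cross_entropy
    selected_K: int
    individuals: pd.DataFrame = field(default=None, repr=False)

    def mean_cross_entropy(self) -> pd.Series:
        return self.cross_entropy.groupby("K")["cross_entropy"].mean()

    def summary(self) -> str:
        lines = ["NMF admixture (masked cross-entropy model selection)"]
        mce = self.mean_cross_entropy()
        for K, ce in mce.items():
            mark = " <- selected" if K == self.selected_K else ""
            lines.append(f"  K = {K}: mean cross-entropy {ce:.4f}{mark}")
        return "\n".join(lines)


class Admixture:
    """sNMF-style admixture model: factorize the individuals x markers
    dosage/2 matrix as Q G with Q rows on the probability simplex and G in
    [0, 1], by alternating least squares with EM-style filling of masked and
    missing entries. Model selection minimizes the cross-entropy of held-out
    masked entries, choosing the smallest K within one SE of the minimum."""

    def __init__(self, genotypes: GenotypeMatrix):
        self.genotypes = genotypes

    def _run_single(self, X, observed, K, iterations, held, rng, alpha=10.0):
        from scipy.optimize import nnls

        n, m = X.shape
        train = observed & ~held
        Q = rng.dirichlet(np.ones(K), size=n)
        G = rng.uniform(0.2, 0.8, size=(K, m))
        eye = 1e-8 * np.eye(K)
        for _ in range(iterations):
            # EM fill of non-training (missing or held-out) entries
            Xw = np.where(train, X, Q @ G)
            G = np.linalg.solve(Q.T @ Q + eye, Q.T @ Xw)
            np.clip(G, 0.0, 1.0, out=G)
            # simplex-constrained rows via augmented NNLS: an extra equation
            # alpha * sum_k q_k = alpha softly enforces sum-to-one, NNLS the
            # nonnegativity; rows are renormalised exactly afterwards
            Xw = np.where(train, X, Q @ G)
            A = np.vstack([G.T, alpha * np.ones((1, K))])
            for i in range(n):
                q, _ = nnls(A, np.concatenate([Xw[i], [alpha]]))
                s = q.sum()
                Q[i] = q / s if s > 0 else 1.0 / K
        pred = np.clip(Q @ G, 1e-6, 1.0 - 1e-6)
        if held.any():
            x = X[held]
            g = pred[held]
            ce = float(-np.mean(x * np.log(g) + (1.0 - x) * np.log(1.0 - g)))
        else:
            ce = float("nan")
        return Q, G, ce

    def fit(
        self,
        K_range=range(1, 10),
        repetitions: int = 10,
        iterations: int = 200,
        mask_fraction: float = 0.05,
        seed: int = 0,
    ) -> AdmixtureFit:
        gm = self.genotypes
        X = gm.geno / 2.0
        observed = ~np.isnan(gm.geno)
        X = np.where(observed, X, 0.0)
        Ks = list(K_range)
        if max(Ks) > gm.n_individuals:
            raise ValidationError("K exceeds the number of individuals")
        rows = []
        best: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
        ss = np.random.SeedSequence(seed)
        mask_ss, init_ss = ss.spawn(2)
        # one held-out mask per repetition, shared by every K, so that
        # cross-entropy comparisons across K are paired within a repetition
        mask_rngs = [np.random.default_rng(s) for s in mask_ss.spawn(repetitions)]
        held_masks = [
            observed & (r.random(X.shape) < mask_fraction) for r in mask_rngs
        ]
        streams = iter(init_ss.spawn(len(Ks) * repetitions))
        for K in Ks:
            for rep in range(repetitions):
                rng = np.random.default_rng(next(streams))
                Q, G, ce = self._run_single(X, observed, K, iterations, held_masks[rep], rng)
                rows.append({"K": K, "repetition": rep, "cross_entropy": ce})
                if K not in best or ce < best[K][0]:
                    best[K] = (ce, Q, G)
        ce_table = pd.DataFrame(rows)
        stats = ce_table.groupby("K")["cross_entropy"].agg(["mean", "sem"])
        k_min = stats["mean"].idxmin()
        cutoff = stats.loc[k_min, "mean"] + (
            stats.loc[k_min, "sem"] if repetitions > 1 else 0.0
        )
        selected_K = int(min(k for k in stats.index if stats.loc[k, "mean"] <= cutoff))
        _, Q, G = best[selected_K]
        return AdmixtureFit(
            Q=Q, G=G, cross_entropy=ce_table, selected_K=selected_K,
            individuals=gm.individuals,
        )
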