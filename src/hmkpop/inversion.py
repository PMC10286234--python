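"""Genotyping a chromosomal inversion from diagnostic SNPs.

A polymorphic inversion suppresses recombination between arrangements, so
individuals fall into three clusters along the first principal component of
their genotypes at diagnostic SNPs: the two homozygote arrangements at the
poles and heterozygotes in the middle. Heterozygotes are validated by their
elevated observed heterozygosity across the diagnostic SNPs, and per-site
arrangement ("haplotype") frequencies follow from the cluster counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import GenotypeMatrix, ValidationError
from .markers import PcaResult, _pca

GENOTYPE_LABELS = {0: "southern-hom", 1: "het", 2: "northern-hom"}


def genotype_pca(gm: GenotypeMatrix) -> PcaResult:
    """Centered PCA of individuals on diagnostic-SNP dosages; missing
    genotypes mean-imputed per SNP."""
    if gm.n_individuals < 3 or gm.n_snps < 2:
        raise ValidationError("need >= 3 individuals and >= 2 diagnostic SNPs")
    X = gm.geno.copy()
    col_mean = np.nanmean(X, axis=0)
    i, j = np.where(np.isnan(X))
    X[i, j] = col_mean[j]
    if np.allclose(X, X[0]):
        raise ValidationError("no genotypic variance among individuals")
    return _pca(X, gm.individuals["individual_id"].tolist())


def cluster_genotypes(scores: pd.DataFrame, k: int = 3, seed: int = 0) -> np.ndarray:
    """k-means on the first two PCA axes (25 seeded k-means++ restarts, best
    inertia kept), clusters relabeled 1..k by ascending PC1 centroid."""
    X = scores.iloc[:, : min(2, scores.shape[1])].to_numpy()
    if len(np.unique(X, axis=0)) < k:
        raise ValidationError(f"fewer than {k} distinct score points")
    km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(X)
    order = np.argsort(km.cluster_centers_[:, 0])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[km.labels_]


def cluster_heterozygosity(gm: GenotypeMatrix, labels: np.ndarray) -> pd.Series:
    """Observed heterozygosity per cluster: the fraction of non-missing
    diagnostic-SNP calls equal to 1. Empty clusters get NaN."""
    out = {}
    for c in sorted(set(labels)):
        g = gm.geno[labels == c]
        n_called = np.sum(~np.isnan(g))
        out[c] = float(np.nansum(g == 1) / n_called) if n_called else float("nan")
    return pd.Series(out, name="Ho")


def haplotype_frequencies(genotype_dose: np.ndarray, site_labels: pd.Series) -> pd.Series:
    """Per-site southern-arrangement frequency (2*hom + het) / (2n) from
    southern-dosage calls (0 = northern-hom, 1 = het, 2 = southern-hom)."""
    dose = np.asarray(genotype_dose, dtype=float)
    out = {}
    for site, idx in pd.Series(range(len(site_labels)), index=site_labels.values).groupby(level=0):
        d = dose[idx.to_numpy()]
        out[site] = float(d.sum() / (2 * d.size))
    return pd.Series(out, name="southern_haplotype_freq")


class InversionGenotyper:
    """Model object: build from genotypes at the diagnostic SNPs, then
    :meth:`fit` clusters individuals and calls inversion genotypes.

    ``reference_site`` declares which site's dominant pole is the "southern"
    arrangement (dosage polarity of raw SNP calls is arbitrary); by default
    the southernmost site in the metadata is used.
    """

    def __init__(self, genotypes: GenotypeMatrix, reference_site: str | None = None,
                 site_latitudes: dict[str, float] | None = None):
        self.genotypes = genotypes
        if reference_site is None and site_latitudes:
            reference_site = min(site_latitudes, key=site_latitudes.get)
        self.reference_site = reference_site

    def fit(self, seed: int = 0) -> "InversionCalls":
        gm = self.genotypes
        pca = genotype_pca(gm)
        labels = cluster_genotypes(pca.scores, k=3, seed=seed)
        ho = cluster_heterozygosity(gm, labels)
        # dose along PC1: cluster 1 -> 0, 2 -> 1, 3 -> 2; flip so the
        # reference (southernmost) site is enriched for dose 2
        dose = labels - 1
        sites = gm.sites
        ref = self.reference_site
        if ref is not None and (sites == ref).any():
            if dose[(sites == ref).to_numpy()].mean() < 1.0:
                dose = 2 - dose
        freq = haplotype_frequencies(dose, sites)
        return InversionCalls(
            genotypes=gm, pca=pca, cluster=labels, southern_dose=dose,
            cluster_ho=ho, site_frequencies=freq,
        )


@dataclass
class InversionCalls:
    genotypes: GenotypeMatrix
    pca: PcaResult
    cluster: np.ndarray  # 1..3 by ascending PC1
    southern_dose: np.ndarray  # 0/1/2 southern-arrangement copies
    cluster_ho: pd.Series
    site_frequencies: pd.Series

    @property
    def genotype_label(self) -> list[str]:
        return [GENOTYPE_LABELS[int(d)] for d in self.southern_dose]

    def summary(self) -> str:
        counts = pd.Series(self.cluster).value_counts().sort_index()
        lines = ["Inversion genotyping"]
        for c, n in counts.items():
            ho = self.cluster_ho.get(c, float("nan"))
            lines.append(f"  cluster {c}: {n} individuals, Ho = {ho:.3f}")
        lines.append("  southern-haplotype frequency per site:")
        for site, f in self.site_frequencies.items():
            lines.append(f"    {site}: {f:.3f}")
        return "\n".join(lines)
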