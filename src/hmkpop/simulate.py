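"""Synthetic pool-seq metapopulations with planted structure.

The generator emulates the sampling design of a marine pool-seq survey:
a handful of sites along a latitudinal gradient, each contributing one pool
of 30-96 diploids sequenced to ~25-46x; a genome of a few chromosomes carrying
mostly neutral SNPs whose per-site frequencies diverge from a shared ancestral
frequency under a Balding-Nichols model (low background FST); a small number
of localized outlier loci with configured per-site target frequencies; one
large chromosomal inversion segregating along the latitudinal cline, tagged by
diagnostic SNPs in complete association with the inversion haplotype; and
environmental covariates (mean temperature, temperature range) that are linear
in latitude plus noise, with an optional warm-anomaly override for a
Mediterranean-style site.

Every draw comes from named substreams fanned out from one global seed so that
stages (frequencies, individuals, depths, reads, dropout, environment) can be
re-run independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PoolCountMatrix, ValidationError, validate_pool_meta

_SUBSTREAMS = ("frequencies", "individuals", "chromosomes", "depths", "reads", "dropout", "env")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


@dataclass
class OutlierLocus:
    """A localized selected region: SNPs near ``center`` get the per-site
    target alt frequencies instead of Balding-Nichols draws."""

    name: str
    chrom: str
    center: int
    width_bp: int
    site_freqs: dict[str, float]
    n_snps: int = 20
    sweep_background: bool = False  # also pin background SNPs inside the span
    # (emulates the diversity loss of a selective sweep, not just high dAF)


@dataclass
class InversionSpec:
    """A polymorphic inversion; diagnostic SNPs inside it are in complete
    association with the haplotype (alt allele marks the southern arrangement)."""

    chrom: str
    start: int
    end: int
    n_diagnostic_snps: int = 12
    site_freqs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValidationError("inversion end must exceed start")


@dataclass
class SimConfig:
    site_ids: list[str]
    pool_sizes: list[int]  # diploid individuals per pool
    latitudes: list[float]
    longitudes: list[float]
    group_labels: list[str]
    chrom_lengths: dict[str, int]
    n_neutral_snps: int = 5000
    background_fst: float = 0.007
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    mean_depths: list[float] | None = None  # per pool; default spread 26-46x
    outlier_loci: list[OutlierLocus] = field(default_factory=list)
    inversion: InversionSpec | None = None
    # environment: linear-in-latitude with Gaussian noise
    temp_mean_intercept: float = 22.0
    temp_mean_slope: float = -0.25  # degC per degree latitude
    temp_range_intercept: float = 3.0
    temp_range_slope: float = 0.10
    env_noise_sd: float = 0.3
    warm_anomaly_site: str | None = None  # Mediterranean-style override
    warm_anomaly_delta: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.site_ids)
        for name in ("pool_sizes", "latitudes", "longitudes", "group_labels"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} must have one entry per site")
        if self.mean_depths is None:
            self.mean_depths = list(np.linspace(26.0, 46.0, n))
        if any(d <= 0 for d in self.mean_depths):
            raise ValidationError("mean depths must be positive")
        if not 0.0 <= self.background_fst < 1.0:
            raise ValidationError("background_fst must be in [0, 1)")
        for loc in self.outlier_loci:
            if loc.chrom not in self.chrom_lengths:
                raise ValidationError(f"outlier locus {loc.name} on unknown chromosome {loc.chrom}")
            if not 1 <= loc.center <= self.chrom_lengths[loc.chrom]:
                raise ValidationError(f"outlier locus {loc.name} outside chromosome bounds")
            for f in loc.site_freqs.values():
                if not 0.0 <= f <= 1.0:
                    raise ValidationError("target frequencies must be in [0, 1]")
        if self.inversion is not None:
            if self.inversion.chrom not in self.chrom_lengths:
                raise ValidationError("inversion on unknown chromosome")
            for f in self.inversion.site_freqs.values():
                if not 0.0 <= f <= 1.0:
                    raise ValidationError("inversion frequencies must be in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def pool_meta(self) -> pd.DataFrame:
        return validate_pool_meta(
            pd.DataFrame(
                {
                    "pool_id": self.site_ids,
                    "n_individuals": self.pool_sizes,
                    "latitude": self.latitudes,
                    "longitude": self.longitudes,
                    "group_label": self.group_labels,
                    "year": [pd.NA] * self.n_sites,
                }
            )
        )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-like defaults: 11 pools along the eastern Atlantic cline
    (pool sizes 30-96), a 4-chromosome genome with a 9.9 Mb inversion on the
    last chromosome, two localized outlier loci, and background FST of 0.007.
    """
    site_ids = ["WIE1", "WIE2", "NOS1", "NOS2", "NPT1", "SPT1", "NPT2", "SPT2", "NAF", "NES", "MED"]
    latitudes = [54.42, 52.76, 54.15, 54.07, 39.83, 37.26, 41.14, 36.84, 20.20, 43.59, 36.49]
    longitudes = [-10.62, -11.00, 3.30, 2.85, -9.20, -8.92, -9.03, -8.38, -17.50, -2.78, -4.42]
    pool_sizes = [51, 62, 96, 70, 64, 30, 47, 48, 57, 96, 49]
    groups = [
        "northern", "northern", "north_sea", "north_sea", "northern",
        "southern", "southern", "southern", "southern", "northern", "mediterranean",
    ]
    chrom_lengths = {"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000, "chr4": 15_000_000}
    north = {s for s, lat in zip(site_ids, latitudes) if lat > 42}
    inv_freqs = {s: (0.05 if s in north else (0.5 if s in ("SPT1", "SPT2") else 0.9)) for s in site_ids}
    inv_freqs["NPT1"] = 0.15
    inv_freqs["MED"] = 0.1
    inversion = InversionSpec(chrom="chr4", start=3_000_000, end=12_900_000,
                              n_diagnostic_snps=12, site_freqs=inv_freqs)
    outliers = [
        OutlierLocus(
            name="north_sea_chr1", chrom="chr1", center=17_500_000, width_bp=200_000,
            site_freqs={s: (0.95 if s in ("NOS1", "NOS2") else 0.25) for s in site_ids},
        ),
        OutlierLocus(
            name="med_chr2", chrom="chr2", center=8_000_000, width_bp=150_000,
            site_freqs={s: (0.9 if s == "MED" else 0.3) for s in site_ids},
        ),
    ]
    cfg = dict(
        site_ids=site_ids,
        pool_sizes=pool_sizes,
        latitudes=latitudes,
        longitudes=longitudes,
        group_labels=groups,
        chrom_lengths=chrom_lengths,
        outlier_loci=outliers,
        inversion=inversion,
        warm_anomaly_site="MED",
        seed=seed,
    )
    cfg.update(overrides)
    # YAML/dict overrides may carry plain mappings for the planted features
    cfg["outlier_loci"] = [
        OutlierLocus(**loc) if isinstance(loc, dict) else loc for loc in cfg["outlier_loci"]
    ]
    if isinstance(cfg["inversion"], dict):
        cfg["inversion"] = InversionSpec(**cfg["inversion"])
    # when only the genome is overridden, keep just the default planted
    # features that still fit inside it
    lengths = cfg["chrom_lengths"]
    if "outlier_loci" not in overrides:
        cfg["outlier_loci"] = [
            loc
            for loc in cfg["outlier_loci"]
            if loc.chrom in lengths and loc.center <= lengths[loc.chrom]
        ]
    if "inversion" not in overrides and cfg["inversion"] is not None:
        inv = cfg["inversion"]
        if inv.chrom not in lengths or inv.end > lengths[inv.chrom]:
            cfg["inversion"] = None
    return SimConfig(**cfg)


@dataclass
class SimTruth:
    """Ground truth of a simulated metapopulation."""

    config: SimConfig
    snps: pd.DataFrame  # chrom, pos, ref, alt, kind ("neutral"/"outlier:<name>"/"inversion")
    site_freqs: np.ndarray  # (n_snps, n_sites) population alt-allele frequencies
    inversion_freq: dict[str, float]  # southern-haplotype frequency per site
    inversion_genotypes: np.ndarray | None  # southern-dose per individual, or None
    individual_sites: np.ndarray  # site index per simulated individual
    individual_geno: np.ndarray  # (n_individuals_total, n_snps) dosages int8
    env: pd.DataFrame  # site_id, temp_mean, temp_range

    @property
    def diagnostic_mask(self) -> np.ndarray:
        return (self.snps["kind"] == "inversion").to_numpy()


def _snp_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out neutral, outlier and diagnostic SNPs along the genome."""
    rows: list[tuple[str, int, str]] = []
    lengths = config.chrom_lengths
    total_len = sum(lengths.values())
    for chrom, length in lengths.items():
        n = int(round(config.n_neutral_snps * length / total_len))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(n, length), replace=False))
        rows.extend((chrom, int(p), "neutral") for p in pos)
    for loc in config.outlier_loci:
        half = loc.width_bp // 2
        lo = max(1, loc.center - half)
        hi = min(lengths[loc.chrom], loc.center + half)
        pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=loc.n_snps, replace=False))
        rows.extend((loc.chrom, int(p), f"outlier:{loc.name}") for p in pos)
    inv = config.inversion
    if inv is not None:
        pos = np.sort(
            rng.choice(np.arange(inv.start, inv.end + 1), size=inv.n_diagnostic_snps, replace=False)
        )
        rows.extend((inv.chrom, int(p), "inversion") for p in pos)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "kind"])
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="last")
    order = {c: i for i, c in enumerate(lengths)}
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    df.insert(2, "ref", "A")
    df.insert(3, "alt", "G")
    return df.reset_index(drop=True)


def simulate_metapopulation(config: SimConfig) -> SimTruth:
    """Draw population allele frequencies and individual genomes.

    Neutral SNPs: per-site frequencies ~ Beta with mean equal to a shared
    ancestral frequency and the Balding-Nichols parameterisation at
    F = ``background_fst``. Outlier and inversion SNPs take their configured
    per-site targets. Individuals are Hardy-Weinberg draws per site, except at
    diagnostic SNPs where the dosage equals the individual's inversion dosage.
    """
    rngs = _rngs(config.seed)
    rng_f = rngs["frequencies"]
    snps = _snp_positions(config, rng_f)
    n_snps, n_sites = len(snps), config.n_sites
    lo, hi = config.ancestral_freq_range
    ancestral = rng_f.uniform(lo, hi, size=n_snps)
    F = config.background_fst
    if F == 0.0:
        site_freqs = np.repeat(ancestral[:, None], n_sites, axis=1)
    else:
        a = ancestral * (1.0 - F) / F
        b = (1.0 - ancestral) * (1.0 - F) / F
        site_freqs = rng_f.beta(a[:, None], b[:, None], size=(n_snps, n_sites))

    site_index = {s: j for j, s in enumerate(config.site_ids)}
    kind = snps["kind"].to_numpy()
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    for loc in config.outlier_loci:
        mask = kind == f"outlier:{loc.name}"
        if loc.sweep_background:
            half = loc.width_bp // 2
            mask = mask | (
                (chrom_arr == loc.chrom)
                & (pos_arr >= loc.center - half)
                & (pos_arr <= loc.center + half)
                & (kind == "neutral")
            )
        for s, f in loc.site_freqs.items():
            site_freqs[mask, site_index[s]] = f
    inv = config.inversion
    inversion_freq: dict[str, float] = {}
    diag_mask = kind == "inversion"
    if inv is not None:
        inversion_freq = {s: float(inv.site_freqs.get(s, 0.0)) for s in config.site_ids}
        for s, f in inversion_freq.items():
            site_freqs[diag_mask, site_index[s]] = f

    # individuals: Hardy-Weinberg per site; inversion dosage shared by all
    # diagnostic SNPs of an individual (complete association)
    rng_i = rngs["individuals"]
    sizes = np.asarray(config.pool_sizes)
    individual_sites = np.repeat(np.arange(n_sites), sizes)
    n_ind = int(sizes.sum())
    geno = np.empty((n_ind, n_snps), dtype=np.int8)
    inv_geno = np.zeros(n_ind, dtype=np.int8) if inv is not None else None
    row = 0
    for j in range(n_sites):
        n = int(sizes[j])
        p = site_freqs[:, j]
        geno[row : row + n] = rng_i.binomial(2, p[None, :], size=(n, n_snps)).astype(np.int8)
        if inv is not None:
            f = inversion_freq[config.site_ids[j]]
            dose = rng_i.binomial(2, f, size=n).astype(np.int8)
            inv_geno[row : row + n] = dose
            geno[row : row + n, diag_mask] = dose[:, None]
        row += n

    env = _environment(config, rngs["env"])
    return SimTruth(
        config=config,
        snps=snps,
        site_freqs=site_freqs,
        inversion_freq=inversion_freq,
        inversion_genotypes=inv_geno,
        individual_sites=individual_sites,
        individual_geno=geno,
        env=env,
    )


def _environment(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lat = np.asarray(config.latitudes)
    tmean = config.temp_mean_intercept + config.temp_mean_slope * lat
    trange = config.temp_range_intercept + config.temp_range_slope * lat
    tmean = tmean + rng.normal(0.0, config.env_noise_sd, size=lat.size)
    trange = trange + rng.normal(0.0, config.env_noise_sd, size=lat.size)
    env = pd.DataFrame({"site_id": config.site_ids, "temp_mean": tmean, "temp_range": trange})
    if config.warm_anomaly_site is not None and config.warm_anomaly_site in config.site_ids:
        env.loc[env["site_id"] == config.warm_anomaly_site, "temp_mean"] += config.warm_anomaly_delta
    return env


def pool_and_sequence(truth: SimTruth) -> PoolCountMatrix:
    """Two-level sampling of pooled read counts from the true site frequencies.

    Per site and SNP: the pool's chromosome count k ~ Binomial(2N, p_site),
    then depth ~ Poisson(mean_depth) and alt reads ~ Binomial(depth, k / 2N).
    A depth draw of zero records counts (0, 0), i.e. the site is untyped in
    that pool.
    """
    config = truth.config
    rngs = _rngs(config.seed)
    rng_c, rng_d, rng_r = rngs["chromosomes"], rngs["depths"], rngs["reads"]
    n_snps, n_sites = truth.site_freqs.shape
    ref = np.zeros((n_snps, n_sites), dtype=np.int64)
    alt = np.zeros((n_snps, n_sites), dtype=np.int64)
    for j in range(n_sites):
        two_n = 2 * config.pool_sizes[j]
        k = rng_c.binomial(two_n, truth.site_freqs[:, j])
        depth = rng_d.poisson(config.mean_depths[j], size=n_snps)
        alt[:, j] = rng_r.binomial(depth, k / two_n)
        ref[:, j] = depth - alt[:, j]
    return PoolCountMatrix(
        snps=truth.snps[["chrom", "pos", "ref", "alt"]].copy(),
        ref_count=ref,
        alt_count=alt,
        pools=config.pool_meta(),
    )


def simulate_env_panel(
    n_pools: int = 10,
    n_neutral: int = 134,
    planted: dict[str, str] | None = None,
    background_sd: float = 0.05,
    effect: float = 0.25,
    planted_noise_sd: float = 0.02,
    seed: int = 0,
):
    """A pool x SNP frequency panel with environment-associated loci planted
    in a low-differentiation background, for genotype-environment association
    checks.

    Two standardized predictors are generated: ``temp_mean`` follows a smooth
    cline across pools, ``temp_range`` is independent noise. Neutral loci are
    a per-locus base frequency plus N(0, background_sd) across pools —
    the across-pool scatter of a weakly structured metapopulation. Each
    planted locus (mapping name -> predictor) tracks its predictor linearly
    with slope ``effect``. Returns (frequencies, predictors, planted map).
    """
    if planted is None:
        planted = {"adaptive_temp": "temp_mean", "adaptive_range": "temp_range"}
    rng = np.random.default_rng(seed)
    idx = [f"pool{i}" for i in range(n_pools)]
    temp = np.linspace(-1.5, 1.5, n_pools) + rng.normal(0, 0.2, n_pools)
    trange = rng.normal(size=n_pools)
    X = pd.DataFrame({"temp_mean": temp, "temp_range": trange}, index=idx)
    X = (X - X.mean()) / X.std(ddof=1)
    base = rng.uniform(0.2, 0.8, size=n_neutral)
    Y = base[None, :] + rng.normal(0, background_sd, size=(n_pools, n_neutral))
    cols = [f"neutral{j}" for j in range(n_neutral)]
    for name, predictor in planted.items():
        y = 0.5 + effect * X[predictor].to_numpy() + rng.normal(0, planted_noise_sd, n_pools)
        Y = np.column_stack([Y, y])
        cols.append(name)
    Y = pd.DataFrame(np.clip(Y, 0.0, 1.0), index=idx, columns=cols)
    return Y, X, planted


def genotype_panel_sample(
    truth: SimTruth,
    n_per_site: int,
    snp_list: np.ndarray | list[int] | None = None,
    dropout: float = 0.0,
) -> GenotypeMatrix:
    """Sample a genotyping panel: the first ``n_per_site`` simulated
    individuals of each site, typed at the SNPs in ``snp_list`` (row indices
    into the truth SNP table; default all), with an optional per-call dropout
    rate producing missing values."""
    config = truth.config
    if snp_list is None:
        snp_list = np.arange(len(truth.snps))
    snp_list = np.asarray(snp_list)
    rows = []
    for j, size in enumerate(config.pool_sizes):
        if n_per_site > size:
            raise ValidationError(
                f"n_per_site {n_per_site} exceeds the {size} simulated individuals at "
                f"{config.site_ids[j]}"
            )
        site_rows = np.where(truth.individual_sites == j)[0][:n_per_site]
        rows.append(site_rows)
    rows = np.concatenate(rows)
    geno = truth.individual_geno[np.ix_(rows, snp_list)].astype(float)
    if dropout > 0:
        rng = _rngs(config.seed)["dropout"]
        mask = rng.random(geno.shape) < dropout
        geno[mask] = np.nan
    individuals = pd.DataFrame(
        {
            "individual_id": [f"{config.site_ids[truth.individual_sites[r]]}_{r}" for r in rows],
            "site": [config.site_ids[truth.individual_sites[r]] for r in rows],
        }
    )
    snps = truth.snps.iloc[snp_list][["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    return GenotypeMatrix(individuals=individuals, snps=snps, geno=geno)
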