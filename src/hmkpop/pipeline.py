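"""End-to-end pipeline orchestration from one configuration mapping.

Stages run in dependency order, each writing TSV outputs plus one JSON run
manifest recording parameters, seeds, input checksums and package versions;
a rerun with identical config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ValidationError
from .diversity import windowed_pi
from .frequencies import estimate_frequencies, frequency_sd_profile
from .fst import ibd_test, pairwise_fst_matrix
from .inversion import InversionGenotyper
from .io import (
    read_env_table,
    read_genotypes,
    read_pool_counts,
    read_pool_meta,
    write_env_table,
    write_genotypes,
    write_pool_counts,
    write_pool_meta,
    write_regions_bed,
)
from .markers import classify_markers, pca_frequencies, thin_by_distance
from .panel import Admixture, genotyping_qc, hwe_scan, ld_groups, reduce_panel, wc_fst, individual_pca
from .rda import RDA, prune_correlated, standardize_env
from .scan import Contrast, scan_contrast, top_fraction
from .simulate import default_config, genotype_panel_sample, pool_and_sequence, simulate_metapopulation

DEFAULT_PARAMS = {
    "block_size": 1000,
    "window": 100,
    "alpha": 0.05,
    "merge_gap_bp": 100_000,
    "min_snps": 5,
    "sd_cut_low": 0.02,
    "sd_cut_high": 0.2,
    "thin_neutral_bp": 1000,
    "thin_outlier_bp": 10_000,
    "pi_window": 10_000,
    "pi_step": 2000,
    "pi_min_coverage": 4,
    "n_perm": 1000,
    "per_region_top": 10,
    "r2_threshold": 0.7,
    "qc_threshold": 0.8,
    "neff_formula": "standard",
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages and return the manifest (also written as
    ``manifest.json`` in ``out_dir``).

    ``config`` keys: ``seed``; either ``simulate`` (truthy / override mapping)
    or ``inputs`` (paths ``counts``, ``meta``, and optionally ``env``,
    ``genotypes``); ``contrasts`` (list of name/group1/group2 mappings);
    ``stages`` (subset of freqs, fst, ibd, scan, classify, pca, diversity,
    rda, panel, inversion); ``params`` overriding :data:`DEFAULT_PARAMS`;
    ``rda_exclude`` pool list; ``inversion_region`` mapping chrom/start/end.
    """
    out = Path(out_dir)
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    seed = int(config.get("seed", 0))
    stages = config.get(
        "stages",
        ["freqs", "fst", "ibd", "scan", "classify", "pca", "diversity", "rda", "panel", "inversion"],
    )

    # ---- pre-flight validation before anything is written
    inputs = config.get("inputs", {})
    simulate = config.get("simulate")
    if not simulate and ("counts" not in inputs or "meta" not in inputs):
        raise ValidationError("config needs either a simulate block or counts+meta inputs")
    if "rda" in stages and not simulate and "env" not in inputs:
        raise ValidationError("RDA stage requested but no environment table configured")
    if ("panel" in stages or "inversion" in stages) and not simulate and "genotypes" not in inputs:
        raise ValidationError("genotype stages requested but no genotype matrix configured")
    contrasts = [Contrast(**c) for c in config.get("contrasts", [])]
    if "scan" in stages and not contrasts and not simulate:
        raise ValidationError("scan stage requested but no contrasts configured")

    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "params": params,
        "stages": {},
        "inputs": {},
    }

    # ---- acquire inputs
    truth = None
    panel_snps = None
    if simulate:
        overrides = simulate if isinstance(simulate, dict) else {}
        sim_cfg = default_config(seed=seed, **overrides)
        truth = simulate_metapopulation(sim_cfg)
        counts = pool_and_sequence(truth)
        meta = sim_cfg.pool_meta()
        env = truth.env
        # genotype a reduced panel (outlier + diagnostic SNPs plus a thinned
        # neutral subset), mirroring a targeted genotyping assay
        kind = truth.snps["kind"].to_numpy()
        non_neutral = np.where(kind != "neutral")[0]
        neutral = np.where(kind == "neutral")[0]
        step = max(1, neutral.size // 24)
        panel_snps = np.sort(np.concatenate([non_neutral, neutral[::step][:24]]))
        geno = genotype_panel_sample(
            truth, n_per_site=min(20, min(sim_cfg.pool_sizes)), snp_list=panel_snps
        )
        write_pool_counts(counts, out / "counts.tsv")
        write_pool_meta(meta, out / "meta.tsv")
        write_env_table(env, out / "env.tsv")
        write_genotypes(geno, out / "genotypes.csv")
        if not contrasts:
            contrasts = [
                Contrast(
                    name="north_sea_vs_rest",
                    group1=[s for s, g in zip(sim_cfg.site_ids, sim_cfg.group_labels) if g == "north_sea"],
                    group2=[s for s, g in zip(sim_cfg.site_ids, sim_cfg.group_labels) if g != "north_sea"],
                )
            ]
        manifest["inputs"]["simulate"] = {"seed": seed}
    else:
        meta = read_pool_meta(inputs["meta"])
        counts = read_pool_counts(inputs["counts"], meta)
        env = read_env_table(inputs["env"]) if "env" in inputs else None
        geno = read_genotypes(inputs["genotypes"]) if "genotypes" in inputs else None
        for key, path in inputs.items():
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(Path(path))}

    # ---- pool-seq branch
    freqs = estimate_frequencies(counts, neff_formula=params["neff_formula"])
    if "freqs" in stages:
        df = freqs.snps.copy()
        for j, p in enumerate(freqs.pool_ids):
            df[p] = freqs.freq[:, j]
        df.to_csv(out / "freqs.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["freqs"] = {"n_snps": int(freqs.n_snps)}

    if "fst" in stages:
        mat = pairwise_fst_matrix(counts, block_size=params["block_size"])
        mat.to_csv(out / "fst.tsv", sep="\t", float_format="%.6g")
        iu = np.triu_indices(len(mat), k=1)
        manifest["stages"]["fst"] = {"global_mean": float(mat.to_numpy()[iu].mean())}
        if "ibd" in stages:
            ibd = ibd_test(mat, meta, n_perm=params["n_perm"], seed=seed)
            manifest["stages"]["ibd"] = {
                "mantel_r": ibd.mantel_r,
                "p_value": ibd.p_value,
                "slope_per_km": ibd.slope,
            }

    scans = {}
    if "scan" in stages:
        bed_regions = []
        scan_frames = []
        for c in contrasts:
            res = scan_contrast(
                freqs, c, window=params["window"], alpha=params["alpha"],
                merge_gap_bp=params["merge_gap_bp"], min_snps=params["min_snps"],
            )
            scans[c.name] = res
            df = res.to_frame()
            df.insert(0, "contrast", c.name)
            scan_frames.append(df)
            bed_regions.extend(res.regions)
        pd.concat(scan_frames).to_csv(out / "scan.tsv", sep="\t", index=False, float_format="%.6g")
        write_regions_bed(bed_regions, out / "regions.bed")
        manifest["stages"]["scan"] = {
            c.name: {"n_regions": len(scans[c.name].regions), "threshold": scans[c.name].threshold_daf}
            for c in contrasts
        }

    sd = frequency_sd_profile(freqs)
    if "classify" in stages:
        sets = classify_markers(sd, params["sd_cut_low"], params["sd_cut_high"])
        neutral = thin_by_distance(freqs.snps, sets.undifferentiated, params["thin_neutral_bp"])
        outlier = thin_by_distance(freqs.snps, sets.differentiated, params["thin_outlier_bp"])
        manifest["stages"]["classify"] = {
            "n_neutral": int(neutral.size),
            "n_outlier": int(outlier.size),
        }
        if "pca" in stages:
            for name, subset in (("neutral", neutral), ("outlier", outlier)):
                if subset.size >= 2:
                    pca = pca_frequencies(freqs, subset)
                    pca.scores.to_csv(out / f"pca_{name}.tsv", sep="\t", float_format="%.6g")
                    manifest["stages"][f"pca_{name}"] = {
                        "pct_variance_pc1_pc2": float(pca.pct_variance[:2].sum())
                    }

    if "diversity" in stages:
        wd = windowed_pi(
            counts, window=params["pi_window"], step=params["pi_step"],
            min_coverage=params["pi_min_coverage"],
        )
        wd.windows.to_csv(out / "pi.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["diversity"] = {"n_windows": int(len(wd.windows))}

    if "rda" in stages and env is not None and scans:
        snp_idx: list[int] = []
        for res in scans.values():
            for region in res.regions:
                snp_idx.extend(top_fraction(res.daf, freqs.snps, region, q=1.0,
                                            max_snps=params["per_region_top"]))
        snp_idx = sorted(set(snp_idx))
        if len(snp_idx) >= 2:
            exclude = set(config.get("rda_exclude", []))
            keep_pools = [p for p in freqs.pool_ids if p not in exclude]
            env_used = env[env["site_id"].isin(keep_pools)].set_index("site_id").loc[keep_pools]
            std = standardize_env(env_used.reset_index().rename(columns={"index": "site_id"}))
            std = std.set_index("site_id")
            kept_vars = prune_correlated(std.reset_index(), r2_threshold=params["r2_threshold"],
                                         priority=["temp_mean", "temp_range"])
            Y = pd.DataFrame(
                freqs.freq[np.ix_(snp_idx, [freqs.pool_ids.index(p) for p in keep_pools])].T,
                index=keep_pools,
                columns=freqs.snp_labels().iloc[snp_idx],
            ).fillna(0.5)
            fit = RDA(Y, std[kept_vars]).fit()
            perm = fit.permutation_test(n_perm=params["n_perm"], seed=seed)
            cands = fit.candidate_snps(perm["axes"])
            pd.DataFrame([c.__dict__ for c in cands]).to_csv(
                out / "rda_candidates.tsv", sep="\t", index=False, float_format="%.6g"
            )
            manifest["stages"]["rda"] = {
                "proportion_constrained": fit.proportion_constrained,
                "model_p": perm["model"],
                "n_candidates": len(cands),
                "predictors": kept_vars,
            }

    # ---- genotype branch
    if geno is not None and ("panel" in stages or "inversion" in stages):
        if "panel" in stages:
            qc = genotyping_qc(geno, threshold=params["qc_threshold"])
            hwe = hwe_scan(qc.genotypes)
            hwe.to_csv(out / "hwe.tsv", sep="\t", index=False, float_format="%.6g")
            groups = ld_groups(qc.genotypes, n_perm=min(params["n_perm"], 200), seed=seed)
            fst = wc_fst(qc.genotypes)
            fst["pairwise"].to_csv(out / "panel_fst.tsv", sep="\t", float_format="%.6g")
            panel_idx = reduce_panel(qc.genotypes, groups, fst["per_locus_pair_mean"])
            final = qc.genotypes.subset_markers(np.asarray(panel_idx))
            write_genotypes(final, out / "panel_genotypes.csv")
            pca = individual_pca(final)
            pca.scores.to_csv(out / "panel_pca.tsv", sep="\t", float_format="%.6g")
            adm = Admixture(final).fit(K_range=range(1, 5), repetitions=3,
                                       iterations=100, mask_fraction=0.1, seed=seed)
            manifest["stages"]["panel"] = {
                "n_markers_after_qc": int(qc.genotypes.n_snps),
                "n_final_panel": int(final.n_snps),
                "selected_K": adm.selected_K,
            }
        if "inversion" in stages:
            inv_region = config.get("inversion_region")
            if inv_region:
                mask = (
                    (geno.snps["chrom"] == inv_region["chrom"])
                    & (geno.snps["pos"] >= inv_region["start"])
                    & (geno.snps["pos"] <= inv_region["end"])
                ).to_numpy()
            elif truth is not None:
                mask = truth.diagnostic_mask[panel_snps]
            else:
                mask = np.ones(geno.n_snps, dtype=bool)
            diag = geno.subset_markers(np.where(mask)[0])
            lat = dict(zip(meta["pool_id"], meta["latitude"]))
            calls = InversionGenotyper(diag, site_latitudes=lat).fit(seed=seed)
            calls.site_frequencies.to_csv(out / "inversion_freqs.tsv", sep="\t")
            manifest["stages"]["inversion"] = {
                "cluster_ho": {str(k): v for k, v in calls.cluster_ho.items()},
                "site_frequencies": calls.site_frequencies.to_dict(),
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
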