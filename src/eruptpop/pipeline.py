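"""End-to-end orchestration: filter -> stats -> structure -> resample ->
demography on a two-time-point dataset, emitting one structured JSON report.

The report is the single source of truth for a run: every statistic is
keyed by population x period group, every seed is recorded, and re-running
the same configuration is bit-identical.  Raw p-values from the report's
many KS / t tests are reported alongside Benjamini-Hochberg-adjusted
values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import false_discovery_control

from . import demosig, popstats, resample, sitefilters, structure
from .genio import (
    GenotypeMatrix,
    SampleMetadata,
    read_metadata,
    read_vcf,
    write_vcf,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters for one comparison run.

    Defaults follow the package's standard study design: 100 resampling
    iterations, 20 SFS subsampling iterations, a 50,000-simulation outlier
    envelope at FDR 0.1, 100-bp Tajima windows, admixture at K in {2, 3}
    and a 50% survivor-drift fraction.
    """

    vcf: str
    metadata: str
    out_dir: str = "eruptpop_run"
    seed: int = 7
    hwe_alpha: float = 0.05
    outlier_sims: int = 50_000
    fdr: float = 0.1
    reps: int = 100
    sfs_reps: int = 20
    window_bp: int = 100
    step_bp: int | None = None
    admixture_k: tuple[int, ...] = (2, 3)
    admixture_starts: int = 10
    drift_fraction: float = 0.5
    loci_panel: int = 100
    callable_length: int | None = None
    run_loci_curve: bool = False
    ks_unit: str = "per_site"  # or "bootstrap"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "admixture_k" in raw:
            raw["admixture_k"] = tuple(int(k) for k in raw["admixture_k"])
        return cls(**raw)


def _jsonable(x):
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return v if np.isfinite(v) else None
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    return x


def _group_label(key: tuple) -> str:
    return ":".join(key)


def run_compare(config: RunConfig, matrix: GenotypeMatrix | None = None,
                metadata: SampleMetadata | None = None) -> dict:
    """Execute all stages and write ``report.json`` (plus filtered VCF and
    ancillary TSVs) under ``config.out_dir``; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix = read_vcf(config.vcf)
    if metadata is None:
        metadata = read_metadata(config.metadata)
    meta = metadata.for_samples(matrix.sample_ids)
    groups = meta.groups(("population", "period"))
    labels = np.asarray([f"{p}:{t}" for p, t in zip(meta.column("population"), meta.column("period"))])

    # out_dir is a placement detail, not part of the analysis identity:
    # runs of one configuration to two directories must be byte-identical
    cfg_dict = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    report: dict = {"config": _jsonable(cfg_dict), "n_samples": matrix.n_samples,
                    "n_sites_input": matrix.n_sites, "groups": {}}
    tests: list[dict] = []

    # -- stage 1: site filters ------------------------------------------------
    log.info("stage filter: HWE + outlier scan on %d sites", matrix.n_sites)
    try:
        outliers = sitefilters.fst_outlier_scan(
            matrix, labels, n_sims=config.outlier_sims, fdr=config.fdr, seed=config.seed,
        )
    except ValueError as exc:  # e.g. a single group
        log.warning("outlier scan skipped: %s", exc)
        outliers = []
    filtered, filter_report = sitefilters.apply_site_filters(
        matrix, hwe_alpha=config.hwe_alpha, outliers=outliers, pop_labels=labels,
    )
    write_vcf(filtered, out / "filtered.vcf")
    report["filter"] = filter_report.to_dict()
    report["n_sites_final"] = filtered.n_sites

    group_mats = {_group_label(k): filtered.subset(samples=v) for k, v in groups.items()}
    group_meta = {_group_label(k): meta.for_samples(v) for k, v in groups.items()}

    # -- stage 2: per-group diversity -----------------------------------------
    for gl, gm in group_mats.items():
        div = popstats.per_site_diversity(gm)
        taj = popstats.tajimas_d_windows(gm, window_bp=config.window_bp, step_bp=config.step_bp)
        f = popstats.inbreeding_f(gm)
        block = {
            "n": gm.n_samples,
            "mean_het_snp_sites": popstats.mean_heterozygosity(gm, "snp_sites"),
            "pi_per_site_mean": float(np.mean(div.pi)),
            "theta_w_per_site_mean": float(np.mean(div.theta_w)),
            "tajimas_d_mean": float(np.mean(taj.values)) if len(taj.values) else None,
            "tajimas_d_windows": len(taj.values),
            "inbreeding_f_mean": float(np.nanmean(f)),
        }
        if config.callable_length:
            block["mean_het_all_callable"] = popstats.mean_heterozygosity(
                gm, "all_callable_sites", callable_length=config.callable_length
            )
        report["groups"][gl] = block

    # -- stage 3: structure ---------------------------------------------------
    gls = sorted(group_mats)
    fst_block = {}
    for i in range(len(gls)):
        for j in range(i + 1, len(gls)):
            a, b = gls[i], gls[j]
            pair = filtered.subset(samples=group_mats[a].sample_ids + group_mats[b].sample_ids)
            pair_labels = [a] * group_mats[a].n_samples + [b] * group_mats[b].n_samples
            try:
                fst_block[f"{a}|{b}"] = structure.weir_cockerham_fst(pair, pair_labels).fst
            except ValueError as exc:
                log.warning("FST %s|%s skipped: %s", a, b, exc)
    report["fst_pairwise"] = fst_block
    try:
        pca = structure.pca_genotypes(filtered)
        report["pca"] = {
            "explained_variance": _jsonable(pca.explained_variance[:5]),
            "pc1_range": float(np.ptp(pca.coordinates[:, 0])),
        }
        np.savetxt(
            out / "pca_coordinates.tsv",
            pca.coordinates[:, :5],
            delimiter="\t",
            header="\t".join(f"PC{i+1}" for i in range(min(5, pca.coordinates.shape[1]))),
            comments="",
        )
    except ValueError as exc:
        log.warning("PCA skipped: %s", exc)
    admix_block = {}
    for K in config.admixture_k:
        fit = structure.admixture_em(
            filtered, K=K, seed=config.seed + K, n_starts=config.admixture_starts
        )
        admix_block[str(K)] = {
            "loglik": fit.loglik,
            "converged": bool(fit.converged),
            "max_assignment_mean": float(fit.Q.max(axis=1).mean()),
        }
        np.savetxt(out / f"admixture_Q_K{K}.tsv", fit.Q, delimiter="\t",
                   header="\t".join(f"Q{k+1}" for k in range(K)), comments="")
    report["admixture"] = admix_block

    # -- stage 4: resampling designs + pre/post tests -------------------------
    min_n = min(m.n_samples for m in group_mats.values())
    boot = {}
    for gl, gm in group_mats.items():
        r_ind = resample.resample_statistic(
            gm, group_meta[gl], scheme="individuals", n=min_n, reps=config.reps,
            statistic="mean_het", seed=config.seed,
        )
        r_loc = resample.resample_statistic(
            gm, group_meta[gl], scheme="loci", n=min(config.loci_panel, gm.n_sites),
            reps=config.reps, statistic="mean_het", seed=config.seed,
        )
        boot[gl] = {
            "individuals_equalized": {"n": r_ind.n, "mean": r_ind.mean, "sd": r_ind.sd},
            "loci_subsample": {"n": r_loc.n, "mean": r_loc.mean, "sd": r_loc.sd},
            "_values": r_ind.values,
        }
    report["bootstrap"] = {
        gl: {k: v for k, v in b.items() if not k.startswith("_")} for gl, b in boot.items()
    }
    if config.run_loci_curve:
        for gl, gm in group_mats.items():
            curve = resample.loci_sd_curve(gm, reps=config.reps, seed=config.seed)
            with open(out / f"loci_curve_{gl.replace(':', '_')}.tsv", "w") as fh:
                fh.write("n\tmean\tsd\n")
                for n_, m_, s_ in curve:
                    fh.write(f"{n_}\t{m_:.8g}\t{s_:.8g}\n")

    # pre vs post comparisons within each population
    pops = sorted({k[0] for k in groups})
    comparisons = {}
    for pop in pops:
        pre_l, post_l = f"{pop}:pre", f"{pop}:post"
        if pre_l not in group_mats or post_l not in group_mats:
            continue
        pre_m, post_m = group_mats[pre_l], group_mats[post_l]
        if config.ks_unit == "bootstrap":
            x, y = boot[pre_l]["_values"], boot[post_l]["_values"]
        else:
            x = popstats.per_site_heterozygosity(pre_m)
            y = popstats.per_site_heterozygosity(post_m)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        D, p_ks = resample.ks_two_sample(x, y)
        t, p_t = resample.welch_t_two_sample(boot[pre_l]["_values"], boot[post_l]["_values"])
        het_pre = report["groups"][pre_l]["mean_het_snp_sites"]
        het_post = report["groups"][post_l]["mean_het_snp_sites"]
        comp = {
            "het_pre": het_pre,
            "het_post": het_post,
            "het_change": het_post - het_pre,
            "ks_D": D,
            "welch_t": t,
            "delta_inbreeding_f": report["groups"][post_l]["inbreeding_f_mean"]
            - report["groups"][pre_l]["inbreeding_f_mean"],
        }
        tests.append({"name": f"{pop}:het_ks", "p": p_ks})
        tests.append({"name": f"{pop}:het_welch", "p": p_t})

        # folded SFS under equalised subsampling
        eq = min(pre_m.n_samples, post_m.n_samples)
        sfs_pre = popstats.folded_sfs(pre_m, eq, reps=config.sfs_reps, seed=config.seed)
        sfs_post = popstats.folded_sfs(post_m, eq, reps=config.sfs_reps, seed=config.seed + 1)
        comp["sfs"] = {
            "pre": _jsonable(sfs_pre.class_counts),
            "post": _jsonable(sfs_post.class_counts),
            "n_haplotypes": sfs_pre.n_haplotypes,
        }
        with np.errstate(invalid="ignore", divide="ignore"):
            low_pre = sfs_pre.per_rep[:, 0] / sfs_pre.per_rep.sum(axis=1)
            low_post = sfs_post.per_rep[:, 0] / sfs_post.per_rep.sum(axis=1)
        t_sfs, p_sfs = resample.welch_t_two_sample(low_pre, low_post)
        comp["sfs_singleton_t"] = t_sfs
        tests.append({"name": f"{pop}:sfs_singleton_welch", "p": p_sfs})
        comparisons[pop] = comp
    report["pre_post"] = comparisons

    # private / shared alleles across all groups
    if len(gls) >= 2:
        eq = min(m.n_samples for m in group_mats.values())
        priv = popstats.private_alleles(
            [group_mats[g] for g in gls], equalize_n=eq, reps=config.reps,
            seed=config.seed, labels=gls,
        )
        report["private_alleles"] = {
            g: {"mean": float(m), "se": float(s)} for g, m, s in zip(gls, priv.mean, priv.se)
        }
        for pop in pops:
            pre_l, post_l = f"{pop}:pre", f"{pop}:post"
            if pre_l in gls and post_l in gls:
                t_pa, p_pa = resample.welch_t_two_sample(
                    priv.per_rep[:, gls.index(pre_l)], priv.per_rep[:, gls.index(post_l)]
                )
                tests.append({"name": f"{pop}:private_alleles_welch", "p": p_pa})
    if len(gls) == 3:
        shared = popstats.shared_alleles_pairwise(
            [group_mats[g] for g in gls], equalize_n=eq, reps=config.reps,
            seed=config.seed, labels=gls,
        )
        report["shared_alleles"] = {
            f"{a}|{b}": {"mean": float(m), "se": float(s)}
            for (a, b), m, s in zip(shared.labels, shared.mean, shared.se)
        }

    # -- stage 5: demographic signals ------------------------------------------
    demo = {}
    for gl, gm in group_mats.items():
        dist = demosig.mismatch_distribution(gm)
        demo[gl] = {
            "raggedness": demosig.raggedness(dist),
            "mismatch_mean": float(dist.pair_diffs.mean()),
            "n_pairs": dist.n_pairs,
        }
    for pop in pops:
        pre_l, post_l = f"{pop}:pre", f"{pop}:post"
        if pre_l in group_mats and post_l in group_mats:
            try:
                D_mm, p_mm = demosig.compare_mismatch(
                    demosig.mismatch_distribution(group_mats[pre_l]),
                    demosig.mismatch_distribution(group_mats[post_l]),
                )
                comparisons[pop]["mismatch_ks_D"] = D_mm
                tests.append({"name": f"{pop}:mismatch_ks", "p": p_mm})
            except ValueError as exc:
                log.warning("mismatch comparison skipped for %s: %s", pop, exc)
            drift = demosig.survivor_drift_sim(
                group_mats[pre_l], fraction=config.drift_fraction,
                reps=config.reps, seed=config.seed,
            )
            comparisons[pop]["survivor_drift"] = {
                "pre_mean_het": drift.pre_mean_het,
                "post_mean_het": drift.post_mean_het,
                "post_sd_het": drift.post_sd_het,
                "t": drift.t,
                "p": drift.p,
                "fraction": drift.fraction,
            }
    report["mismatch"] = demo

    # -- multiple testing across the report's tests -----------------------------
    ps = np.asarray([t["p"] for t in tests], dtype=float)
    ok = np.isfinite(ps)
    adj = np.full(len(ps), np.nan)
    if ok.any():
        adj[ok] = false_discovery_control(np.clip(ps[ok], 0, 1), method="bh")
    report["tests"] = [
        {"name": t["name"], "p": _jsonable(t["p"]), "p_bh": _jsonable(a)}
        for t, a in zip(tests, adj)
    ]

    report = _jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
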