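"""Configuration, VCF input, and the end-to-end pipeline drivers.

Ties the stages together: simulation / VCF input → SNP thinning → SFS
projection → demographic model fitting and selection → unit conversion,
and genotypes → FST / distances / π / kinship / PCA / DAPC reports. Every
run emits a machine-readable manifest carrying the configuration hash and
every seed used, so reruns are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import MISSING, GenotypeMatrix
from .sfs_ops import sfs_from_genotypes, thin_one_snp_per_locus
from . import demography as dm
from . import popstruct as ps

log = logging.getLogger("rangeedge")


@dataclass
class RunConfig:
    """Flat key-value configuration for the pipeline drivers.

    ``paper_mode()`` returns the template matching the study the package
    emulates: μ = 7.7e−10 per site per generation, generation time 2
    years, projection target m = 70 allele copies, 4 optimisation rounds
    of 50 replicates with 25 iterations, and 100 bootstrap replicates.
    """

    vcf: str | None = None
    out_dir: str = "rangeedge_out"
    mu: float = 7.7e-10
    gen_time: float = 2.0
    L: float | None = None  # assayed bp; default: loci × locus length of the input
    projection_m: int = 70
    fold: bool = True
    models: tuple = ("two_epoch", "growth", "bottlegrowth", "three_epoch")
    rounds: int = 4
    reps_per_round: int = 50
    maxiter: int = 25
    gof_reps: int = 100
    bootstrap_reps: int = 100
    run_gof: bool = False
    run_bootstrap: bool = False
    n_pcs: int = 10
    seed_thin: int = 11
    seed_fit: int = 12
    seed_gof: int = 13
    seed_bootstrap: int = 14

    @classmethod
    def paper_mode(cls, **overrides) -> "RunConfig":
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        data = asdict(self)
        data["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` via cyvcf2.

    Keeps biallelic SNP records only, skipping others with a logged
    count; the locus identifier is the CHROM field (the minimal dialect
    written by this package uses one contig per RAD locus). Missing
    genotypes are preserved as ``-1``; population labels default to the
    sample-name prefix before the last ``_`` and can be overwritten.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    locus_length = 51
    n_loci = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##rangeedge_locus_length="):
            locus_length = int(line.split("=", 1)[1])
        elif line.startswith("##rangeedge_n_loci_assayed="):
            n_loci = int(line.split("=", 1)[1])
    cols, loci, pos = [], [], []
    n_skipped = 0
    gt_map = {0: 0, 1: 1, 3: 2, 2: MISSING}  # cyvcf2 gt_types: UNKNOWN == 2
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.REF is None or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        cols.append(np.array([gt_map[int(t)] for t in rec.gt_types], dtype=np.int8))
        loci.append(rec.CHROM)
        pos.append(rec.POS)
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    geno = (
        np.column_stack(cols).astype(np.int8)
        if cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    pops = np.array([s.rsplit("_", 1)[0] for s in samples], dtype=object)
    return GenotypeMatrix(
        geno,
        samples,
        pops,
        np.array(loci, dtype=object),
        np.array(pos, dtype=int),
        locus_length=locus_length,
        n_loci_assayed=n_loci,
        metadata={"n_skipped_records": n_skipped},
    )


def _stage(name: str, t0: float, **shapes) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0,
             " ".join(f"{k}={v}" for k, v in shapes.items()))


def _manifest(config: RunConfig, seeds: dict, extra: dict | None = None) -> dict:
    data = {
        "package": "rangeedge",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seeds": seeds,
    }
    if extra:
        data.update(extra)
    return data


def run_demography_pipeline(
    config: RunConfig, G: GenotypeMatrix | None = None
) -> dict:
    """thin → project → fit all models → select → (GOF, bootstrap) → units.

    Returns a report bundle (dict) and writes TSVs plus a JSON manifest
    into ``config.out_dir``: a model-selection table, a demographic-units
    table for the best model, and optional goodness-of-fit / bootstrap-CI
    summaries. Deterministic for fixed config seeds.
    """
    if G is None:
        if not config.vcf:
            raise ValueError("run_demography_pipeline: no genotype input configured")
        G = read_vcf(config.vcf)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    thinned = thin_one_snp_per_locus(G, seed=config.seed_thin)
    _stage("thin", t0, sites_in=G.n_sites, sites_out=thinned.n_sites)

    t0 = time.time()
    obs = sfs_from_genotypes(thinned, fold=config.fold, project_to=config.projection_m)
    _stage("sfs", t0, n=obs.n, snps=round(obs.total(), 1))

    fits = []
    for i, name in enumerate(config.models):
        t0 = time.time()
        fit = dm.optimize(
            name,
            obs,
            rounds=config.rounds,
            reps_per_round=config.reps_per_round,
            maxiter=config.maxiter,
            seed=config.seed_fit + i,
        )
        _stage(f"fit:{name}", t0, loglik=round(fit.loglik, 2))
        fits.append(fit)
    table = dm.model_selection(fits)
    table_fmt = dm.format_selection_table(table)
    table_fmt.to_csv(out / "model_selection.tsv", sep="\t", index=False)

    best = fits[int(np.argmin([f.aic for f in fits]))]
    L = float(config.L if config.L is not None else G.L)
    units = dm.to_demographic_units(best, mu=config.mu, L=L, gen_time=config.gen_time)
    units_rows = [
        {"quantity": "Nref_individuals", "value": units.Nref},
        *({"quantity": f"{k}_ratio", "value": v} for k, v in units.size_ratios.items()),
        *({"quantity": f"{k}_years", "value": v} for k, v in units.times_years.items()),
    ]
    report = {
        "observed_sfs": obs,
        "fits": {f.model.name: f for f in fits},
        "selection": table,
        "best_model": best.model.name,
        "units": units,
    }

    seeds = {"thin": config.seed_thin, "fit": config.seed_fit}
    if config.run_gof:
        t0 = time.time()
        gof = dm.gof_parametric_bootstrap(
            best, obs, n_reps=config.gof_reps, seed=config.seed_gof
        )
        _stage("gof", t0, quantile=round(gof.quantile, 3))
        seeds["gof"] = config.seed_gof
        report["gof"] = gof
        (out / "gof.json").write_text(
            json.dumps(
                {
                    "empirical_loglik": gof.empirical_loglik,
                    "sim_loglik_min": float(gof.sim_logliks.min()),
                    "sim_loglik_max": float(gof.sim_logliks.max()),
                    "quantile": gof.quantile,
                    "within_range": gof.within_range,
                },
                indent=2,
            )
        )
    if config.run_bootstrap:
        t0 = time.time()
        cis = dm.ci_nonparametric_bootstrap(
            G,
            best.model,
            best,
            n_reps=config.bootstrap_reps,
            seed=config.seed_bootstrap,
            project_to=config.projection_m,
            fold=config.fold,
        )
        _stage("bootstrap", t0, reps=config.bootstrap_reps)
        seeds["bootstrap"] = config.seed_bootstrap
        report["bootstrap"] = cis
        frame = cis.as_frame()
        # convert time-parameter CI rows to years as well
        years_low = dm.times_to_years(
            best.model, cis.lower, best.theta_hat, config.mu, L, config.gen_time
        )
        years_high = dm.times_to_years(
            best.model, cis.upper, best.theta_hat, config.mu, L, config.gen_time
        )
        frame["ci_low_years"] = [years_low.get(p, np.nan) for p in frame["parameter"]]
        frame["ci_high_years"] = [years_high.get(p, np.nan) for p in frame["parameter"]]
        frame.to_csv(out / "bootstrap_ci.tsv", sep="\t", index=False)
        for name, lo, hi in zip(best.model.param_names, cis.lower, cis.upper):
            if name.startswith("T"):
                continue
            units_rows.append(
                {"quantity": f"{name}_ratio_ci", "value": f"{lo:.4g}-{hi:.4g}"}
            )
    pd.DataFrame(units_rows).to_csv(out / "demographic_units.tsv", sep="\t", index=False)
    manifest = _manifest(config, seeds, {"best_model": best.model.name, "L": L})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    report["manifest"] = manifest
    return report


def run_structure_pipeline(config: RunConfig, G: GenotypeMatrix | None = None) -> dict:
    """FST / distance matrix, π per population, kinship screen, PCA, DAPC."""
    if G is None:
        if not config.vcf:
            raise ValueError("run_structure_pipeline: no genotype input configured")
        G = read_vcf(config.vcf)
    pops = [p for p in dict.fromkeys(G.populations.tolist())]
    if not pops:
        raise ValueError("population map is empty")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    fst = ps.weir_cockerham_fst(G, pops)
    _stage("fst", t0, pairs=len(pops) * (len(pops) - 1) // 2)

    # combined matrix: FST upper triangle, minimum pairwise distance lower
    combined = pd.DataFrame("", index=pops, columns=pops, dtype=object)
    for i, pa in enumerate(pops):
        for j, pb in enumerate(pops):
            if i < j:
                combined.loc[pa, pb] = f"{fst.loc[pa, pb]:.3g}"
            elif i > j:
                d = ps.min_pairwise_distance(G, pa, pb)
                combined.loc[pa, pb] = f"{d:.3g}"
    combined.to_csv(out / "fst_distance_matrix.tsv", sep="\t")

    pi = pd.DataFrame(
        {
            "population": pops,
            "pi": [ps.nucleotide_diversity(G, pop=p) for p in pops],
        }
    )
    pi.to_csv(out / "pi.tsv", sep="\t", index=False)

    t0 = time.time()
    kin = ps.king_kinship(G)
    _stage("kinship", t0, pairs=len(kin))
    kin.to_csv(out / "kinship.tsv", sep="\t", index=False)

    pca = ps.pca_genotypes(G, n_components=min(config.n_pcs, G.n_individuals - 1))
    scores = pd.DataFrame(
        pca.scores,
        index=G.samples,
        columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
    )
    scores.insert(0, "population", G.populations)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")

    dapc_res = ps.dapc(G, n_pcs=min(config.n_pcs, G.n_individuals - len(pops) - 1))
    dapc_res.confusion.to_csv(out / "dapc_confusion.tsv", sep="\t")

    manifest = _manifest(config, {"thin": config.seed_thin})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "fst": fst,
        "combined_matrix": combined,
        "pi": pi,
        "kinship": kin,
        "pca": pca,
        "dapc": dapc_res,
        "flagged_relatives": kin[kin["degree"] != "unrelated"],
        "manifest": manifest,
    }
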