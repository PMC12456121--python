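"""The simulate -> qc -> kernels -> blues -> fit -> cv -> report pipeline.

Each stage reads its inputs from the run directory (or the paths named in
the configuration), writes its artifacts there, and logs stage name, seed
and wall time.  Re-running with an identical configuration reproduces
identical outputs: deterministic stages bit-for-bit, stochastic stages via
seeded chains.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from menvgp import io as mio
from menvgp.config import RunConfig
from menvgp.evaluation import compare_models, make_cv_plans, run_cv
from menvgp.kernels import ec_kernel, center_standardize, grm_vanraden, qc_markers
from menvgp.models import (
    MCMCConfig,
    fit_gblup_single_env,
    fit_gxc,
    fit_mtm,
    fit_mxe,
    genetic_correlations,
    heritability,
    variance_proportions,
)
from menvgp.sim import SimConfig, exchangeable_cov, simulate_study
from menvgp.spatial import extract_blues, fit_spatial_model

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "kernels", "blues", "fit", "cv", "report")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


class _Stage:
    def __init__(self, name: str, cfg: RunConfig):
        self.name = name
        self.cfg = cfg
        self.t0 = 0.0

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage=%s seed=%s starting", self.name, self.cfg.seed)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage=%s wall_time=%.2fs done", self.name, dt)
        else:
            logger.error("stage=%s failed after %.2fs: %s; partial outputs in %s",
                         self.name, dt, exc, self.cfg.output_dir)
        return False


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    s = cfg.simulate
    with _Stage("simulate", cfg):
        sim_cfg = SimConfig(
            n_lines=s.n_lines,
            n_markers=s.n_markers,
            maf_range=(s.maf_low, s.maf_high),
            n_envs=s.n_envs,
            env_cov_matrix=exchangeable_cov(s.n_envs, corr=s.env_corr),
            h2_per_env=None if s.h2_per_env is None else np.asarray(s.h2_per_env),
            n_reps=s.n_reps,
            spatial_amplitude=s.spatial_amplitude,
            missing_cell_fraction=s.missing_cell_fraction,
            seed=cfg.stage_seed(0),
        )
        study = simulate_study(sim_cfg, n_covs=s.n_covs, trait=cfg.trait)
        mio.write_genotypes_tsv(study["genotypes"], out / "genotypes.tsv")
        mio.write_phenotypes(study["plots"], out / "plots.csv")
        mio.write_ecs(study["ec"], out / "ecs.csv")
        study["truth"].true_u.to_csv(out / "truth_breeding_values.tsv", sep="\t")


def _genotype_path(cfg: RunConfig) -> Path:
    return Path(cfg.genotypes) if cfg.genotypes else _outdir(cfg) / "genotypes.tsv"


def stage_qc(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    with _Stage("qc", cfg):
        path = _genotype_path(cfg)
        logger.info("input=%s sha256=%s", path, _file_hash(path))
        G = mio.read_genotypes(path)
        Gq, report = qc_markers(G, cfg.qc.maf_max_removed, cfg.qc.miss_max,
                                cfg.qc.corr_max)
        mio.write_genotypes_tsv(Gq, out / "genotypes_qc.tsv")
        mio.write_qc_report(report, out / "qc_report.tsv")


def stage_kernels(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    with _Stage("kernels", cfg):
        G = mio.read_genotypes(out / "genotypes_qc.tsv")
        W = center_standardize(G)
        K = grm_vanraden(W, line_ids=G.line_ids)
        mio.write_kernel(K, out / "grm.csv")
        ec_path = Path(cfg.ecs) if cfg.ecs else out / "ecs.csv"
        if ec_path.exists():
            Omega = ec_kernel(mio.read_ecs(ec_path))
            mio.write_kernel(Omega, out / "omega.csv")


def stage_blues(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    with _Stage("blues", cfg):
        pheno_path = Path(cfg.phenotypes) if cfg.phenotypes else out / "plots.csv"
        plots = mio.read_phenotypes(pheno_path, trait=cfg.trait)
        K = mio.read_kernel(out / "grm.csv", kind="grm")
        fits = {}
        summary = []
        for env, sub in plots.groupby("env"):
            fit = fit_spatial_model(sub.reset_index(drop=True), trait=cfg.trait)
            fits[env] = fit
            row = {"env": env, "converged": fit.converged, "n_iter": fit.n_iter}
            row.update({f"sigma2_{k}": v for k, v in fit.varcomp.items()})
            row.update({f"lambda_{k}": v for k, v in fit.lambdas.items()})
            summary.append(row)
        blues = extract_blues(fits, K=K)
        mio.write_blues(blues, out / "blues.csv")
        pd.DataFrame(summary).to_csv(out / "spatial_summary.tsv", sep="\t",
                                     index=False)


def _mcmc(cfg: RunConfig, stage: int) -> MCMCConfig:
    return MCMCConfig(n_iter=cfg.mcmc.n_iter, burn_in=cfg.mcmc.burn_in,
                      thin=cfg.mcmc.thin, seed=cfg.stage_seed(stage))


def stage_fit(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    with _Stage("fit", cfg):
        blues = mio.read_blues(out / "blues.csv")
        K = mio.read_kernel(out / "grm.csv", kind="grm")
        omega_path = out / "omega.csv"
        Omega = mio.read_kernel(omega_path, kind="env") if omega_path.exists() else None
        mcmc = _mcmc(cfg, 4)
        rows = []
        for model in cfg.models:
            if model == "gblup":
                h2 = {}
                for env in blues.values.columns:
                    fit = fit_gblup_single_env(blues.values[env], K, mcmc)
                    h2[env] = heritability(fit)
                pd.Series(h2, name="h2").to_csv(out / "heritability.tsv", sep="\t")
                continue
            if model == "gxc":
                if Omega is None:
                    logger.warning("skipping gxc: no environment kernel")
                    continue
                fit = fit_gxc(blues, K, Omega, mcmc)
            elif model == "mxe":
                fit = fit_mxe(blues, K, mcmc)
            elif model == "mtm1":
                fit = fit_mtm(blues, K, mcmc, extra_component=False)
                genetic_correlations(fit).to_csv(out / "genetic_correlations.csv")
            elif model == "mtm2":
                fit = fit_mtm(blues, K, mcmc, extra_component=True)
            else:
                raise ValueError(f"unknown model {model!r}")
            props = variance_proportions(fit)
            for comp, val in props.items():
                rows.append({"model": model, "component": comp, "proportion": val})
            vc = pd.DataFrame({
                "component": list(fit.varcomp_samples),
                "posterior_mean": [float(np.mean(v))
                                   for v in fit.varcomp_samples.values()],
                "posterior_sd": [float(np.std(v))
                                 for v in fit.varcomp_samples.values()],
            })
            vc.to_csv(out / f"varcomp_{model}.tsv", sep="\t", index=False)
        if rows:
            pd.DataFrame(rows).to_csv(out / "variance_proportions.tsv", sep="\t",
                                      index=False)


def stage_cv(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    with _Stage("cv", cfg):
        blues = mio.read_blues(out / "blues.csv")
        K = mio.read_kernel(out / "grm.csv", kind="grm")
        omega_path = out / "omega.csv"
        Omega = mio.read_kernel(omega_path, kind="env") if omega_path.exists() else None
        mcmc = _mcmc(cfg, 5)
        multi_models = [m for m in cfg.models if m != "gblup"]
        if Omega is None:
            multi_models = [m for m in multi_models if m != "gxc"]
        all_records = []
        for scheme in cfg.cv.schemes:
            plans = make_cv_plans(
                blues.values.index, blues.values.columns, scheme,
                n_reps=cfg.cv.n_reps, frac_test=cfg.cv.frac_test,
                seed=cfg.stage_seed(6),
            )
            res = run_cv(blues, K, multi_models, plans, mcmc, Omega=Omega)
            all_records.append(res.records)
        pd.concat(all_records, ignore_index=True).to_csv(
            out / "cv_results.tsv", sep="\t", index=False)


def stage_report(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    with _Stage("report", cfg):
        cv_path = out / "cv_results.tsv"
        if not cv_path.exists():
            raise FileNotFoundError("run the cv stage before report")
        records = pd.read_csv(cv_path, sep="\t")
        summary = (records.groupby(["scheme", "model", "env"])["r"]
                   .agg(["mean", "std", "count"]).reset_index())
        summary.to_csv(out / "cv_summary.tsv", sep="\t", index=False)

        comparisons = []
        base = records.query("scheme == 'single_env' and model == 'gblup'")
        if len(base):
            base_vec = (base.pivot_table(index=["env", "replicate"], values="r")
                        .sort_index())
            for scheme in ("cv1", "cv2"):
                for model in records.query("scheme == @scheme")["model"].unique():
                    cand = records.query("scheme == @scheme and model == @model")
                    cand_vec = (cand.pivot_table(index=["env", "replicate"],
                                                 values="r").sort_index())
                    common = base_vec.index.intersection(cand_vec.index)
                    if len(common) < 3:
                        continue
                    rep = compare_models(base_vec.loc[common, "r"],
                                         cand_vec.loc[common, "r"])
                    rep.update({"scheme": scheme, "model": model,
                                "baseline": "gblup_single_env"})
                    comparisons.append(rep)
        if comparisons:
            pd.DataFrame(comparisons).to_csv(out / "model_comparisons.tsv",
                                             sep="\t", index=False)
        manifest = {
            "config": cfg.model_dump(),
            "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "kernels": stage_kernels,
    "blues": stage_blues,
    "fit": stage_fit,
    "cv": stage_cv,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> Path:
    """Execute the requested stages in order; returns the artifact directory."""
    out = _outdir(cfg)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        if stage == "simulate" and cfg.genotypes and cfg.phenotypes:
            logger.info("stage=simulate skipped (real inputs supplied)")
            continue
        _STAGE_FUNCS[stage](cfg)
    return out
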