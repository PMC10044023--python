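"""End-to-end analysis pipeline: clean -> fit -> covariates -> bootstrap ->
VPC -> EBE -> targets -> Monte Carlo PTA -> exposure.

Every stochastic stage receives a logged sub-seed derived from the master
seed by a counter scheme, so any single stage can be re-run from the
manifest alone.  All tabular outputs are CSV with fixed column order;
figures are byproducts of the same numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diagnostics, estimation, simulation, targets
from .cohort import CohortSpec, sample_cohort
from .dataset_io import Dataset, clean_dataset, read_dataset, renal_group, write_dataset
from .estimation import FINAL_MODEL_SPEC, ModelSpec
from .pk_model import ConcentrationProfile, IndividualParameters

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


def _sub_seed(master: int, k: int) -> int:
    return int((master * 1_000_003 + 7919 * k + 1) % (2**31))


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: str
    seed: int
    dataset_path: str | None = None  # use a real-format CSV instead of synthesis
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    initials: dict | None = None
    fit_max_iter: int = 1500
    run_covariates: bool = True
    candidates: tuple = estimation.DEFAULT_CANDIDATES
    bootstrap_replicates: int = 200
    vpc_n_sim: int = 1000
    pta_n_replicates: int = 1000
    mic_grid: tuple = targets.EUCAST_MIC_GRID

    def validate(self) -> None:
        if self.seed is None or int(self.seed) < 0:
            raise ValueError("a non-negative master seed is required")
        if self.bootstrap_replicates < 2:
            raise ValueError("bootstrap_replicates must be >= 2")
        if self.pta_n_replicates < 1:
            raise ValueError("pta_n_replicates must be >= 1")
        self.cohort_spec.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec_kwargs = raw.pop("cohort_spec", None)
        cfg = cls(**raw)
        if spec_kwargs:
            cfg.cohort_spec = CohortSpec(**spec_kwargs)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _profiles_from_ebe(ds: Dataset, ebe: pd.DataFrame, cov: pd.DataFrame) -> dict:
    """Individual profiles under each subject's *observed* dose history."""
    profiles = {}
    for _, row in ebe.iterrows():
        sid = row["ID"]
        d = ds.events[(ds.events["ID"] == sid) & (ds.events["EVID"] == 1)]
        from .pk_model import DoseEvent, Regimen

        regimen = Regimen(
            doses=tuple(
                DoseEvent(r["TIME"], r["AMT"], r["DUR"]) for _, r in d.iterrows()
            ),
            label=f"subject {sid}",
        )
        ip = IndividualParameters(cl=row["CL"], v=row["V"],
                                  eta_cl=row["ETA_CL"], eta_v=row["ETA_V"])
        profiles[sid] = ConcentrationProfile(ip, regimen)
    return profiles


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": int(config.seed),
                "stages": {}, "artifacts": {}}
    stage_idx = 0

    def record(stage, artifact_paths, seed=None):
        manifest["stages"][stage] = {"seed": seed}
        for name, p in artifact_paths.items():
            manifest["artifacts"][name] = str(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def run_stage(name, fn):
        nonlocal stage_idx
        seed = _sub_seed(config.seed, stage_idx)
        stage_idx += 1
        try:
            return fn(seed), seed
        except Exception as exc:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # --- dataset ------------------------------------------------------
    def stage_dataset(seed):
        if config.dataset_path:
            ds = read_dataset(config.dataset_path)
            truth = None
        else:
            ds, truth = sample_cohort(config.cohort_spec, seed=seed)
            truth.to_csv(out / "truth.csv", index=False)
        write_dataset(ds, out / "dataset_raw.csv")
        ds = clean_dataset(ds)
        write_dataset(ds, out / "dataset_clean.csv")
        return ds, truth

    (ds, truth), seed = run_stage("dataset_io", stage_dataset)
    record("dataset_io", {"dataset_clean": out / "dataset_clean.csv"}, seed)

    # --- base + final fit --------------------------------------------
    def stage_fit(seed):
        base = estimation.fit(ds, ModelSpec(), initials=config.initials,
                              max_iter=config.fit_max_iter, compute_rse=False)
        final = estimation.fit(ds, FINAL_MODEL_SPEC, initials=config.initials,
                               max_iter=config.fit_max_iter)
        return base, final

    (base_fit, final_fit), seed = run_stage("estimation", stage_fit)
    fit_report = {
        "base_ofv": base_fit.ofv,
        "final": final_fit.estimates(),
        "final_ofv": final_fit.ofv,
        "rse_percent": final_fit.rse_percent,
        "shrinkage_percent": final_fit.shrinkage_percent,
        "converged": final_fit.converged,
    }
    (out / "fit.json").write_text(json.dumps(fit_report, indent=2, default=float))
    record("estimation", {"fit": out / "fit.json"}, seed)

    # --- covariate analysis ------------------------------------------
    if config.run_covariates:
        def stage_cov(seed):
            return estimation.covariate_step(
                ds, base_fit, candidates=config.candidates,
                fit_kwargs={"max_iter": config.fit_max_iter},
            )

        cov_report, seed = run_stage("covariates", stage_cov)
        cov_report.univariate.to_csv(out / "covariates_univariate.csv", index=False)
        cov_report.multivariate.to_csv(out / "covariates_multivariate.csv", index=False)
        (out / "covariates.json").write_text(json.dumps(
            {"retained": list(cov_report.retained),
             "iiv_cl_trajectory_percent_cv": cov_report.iiv_cl_trajectory},
            indent=2))
        record("covariates", {"covariates_univariate": out / "covariates_univariate.csv"},
               seed)

    # --- bootstrap ----------------------------------------------------
    def stage_boot(seed):
        return estimation.bootstrap(
            ds, FINAL_MODEL_SPEC, n_replicates=config.bootstrap_replicates,
            seed=seed, initials=final_fit.estimates(),
            fit_kwargs={"max_iter": max(300, config.fit_max_iter // 3)},
        )

    boot, seed = run_stage("bootstrap", stage_boot)
    (out / "bootstrap.json").write_text(json.dumps(
        {"n_replicates": boot["n_replicates"], "n_failed": boot["n_failed"],
         "parameters": boot["parameters"]}, indent=2, default=float))
    boot["replicates"].to_csv(out / "bootstrap_replicates.csv", index=False)
    record("bootstrap", {"bootstrap": out / "bootstrap.json"}, seed)

    # --- VPC + GOF ----------------------------------------------------
    def stage_vpc(seed):
        return diagnostics.pc_vpc(ds, final_fit, n_sim=config.vpc_n_sim, seed=seed)

    vpc, seed = run_stage("vpc", stage_vpc)
    vpc_df = vpc.observed.copy()
    vpc_df.insert(0, "bin_mid", vpc.bin_mid)
    for pct in (5, 50, 95):
        vpc_df[f"band{pct}_lo"], vpc_df[f"band{pct}_hi"] = vpc.bands[pct]
    vpc_df.to_csv(out / "vpc.csv", index=False)
    record("vpc", {"vpc": out / "vpc.csv"}, seed)

    gof = diagnostics.gof_tables(ds, final_fit)
    gof["observations"].to_csv(out / "gof.csv", index=False)
    (out / "gof_summary.json").write_text(json.dumps(gof["summary"], indent=2))
    record("gof", {"gof": out / "gof.csv"})

    # --- EBEs and target attainment ----------------------------------
    ebe = estimation.empirical_bayes(ds, final_fit)
    ebe.to_csv(out / "ebe.csv", index=False)
    cov = ds.covariates().reset_index()
    subjects = cov.rename(columns={"index": "ID"})
    subjects["GROUP"] = subjects["EGFR_CKDEPI"].map(renal_group)
    profiles = _profiles_from_ebe(ds, ebe, subjects)

    pta_frames = []
    for target in (targets.TARGET_50_0_24, targets.TARGET_100_0_24,
                   targets.TARGET_50_24_48):
        pta_frames.append(targets.pta_table(subjects, profiles, target,
                                            config.mic_grid))
    pta_all = pd.concat(pta_frames, ignore_index=True)
    pta_all.to_csv(out / "pta_observed.csv", index=False)
    record("targets", {"pta_observed": out / "pta_observed.csv"})

    exposure = targets.exposure_summary(subjects, profiles)
    (out / "exposure.json").write_text(json.dumps(
        {k: {"kruskal_statistic": v["kruskal_statistic"], "p_value": v["p_value"],
             "groups": {g: {kk: vv for kk, vv in d.items() if kk != "values"}
                        for g, d in v["groups"].items()}}
         for k, v in exposure.items()}, indent=2, default=float))
    record("exposure", {"exposure": out / "exposure.json"})

    # --- Monte Carlo PTA ---------------------------------------------
    def stage_sim(seed):
        cfg = simulation.SimulationConfig(
            seed=seed, n_replicates=config.pta_n_replicates,
            pop=final_fit.to_population_parameters(),
            cohort=subjects[["ID", "GROUP", "EGFR_CKDEPI", "ABX"]],
            mic_grid=config.mic_grid,
        )
        return simulation.simulate_pta(cfg)

    sim, seed = run_stage("pta_simulation", stage_sim)
    sim.pooled.to_csv(out / "pta_simulated.csv", index=False)
    sim.per_replicate.to_csv(out / "pta_simulated_replicates.csv", index=False)
    record("pta_simulation", {"pta_simulated": out / "pta_simulated.csv"}, seed)

    if truth is not None:
        shift_cmp = simulation.compare_shift_vs_exact(
            truth, final_fit.to_population_parameters()
        )
        shift_cmp.to_csv(out / "shift_vs_exact.csv", index=False)
        record("shift_comparison", {"shift_vs_exact": out / "shift_vs_exact.csv"})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
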