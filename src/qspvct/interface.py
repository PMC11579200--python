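"""Configuration, orchestration and artifact serialization.

Ties the pipeline stages together in workflow order — synthesize inputs,
generate plausible patients, select virtual patients, run trial arms,
analyze — with one master seed spawning named sub-seeds per stage so any
stage can be re-run in isolation reproducibly.  All artifacts are plain
CSV/JSON in the configured output directory; the fully-resolved config is
serialized alongside them for provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import model_core as mc
from . import stats_analysis as sa
from . import synthetic_data as sd
from . import trial_engine as te
from . import vp_generation as vg
from . import vp_selection as vs

__all__ = [
    "RunConfig",
    "DependencyError",
    "load_config",
    "run_synth",
    "run_generate",
    "run_select",
    "run_trial_stage",
    "run_analyze",
    "run_full",
    "load_cohort",
]

log = logging.getLogger(__name__)


class DependencyError(RuntimeError):
    """A stage was invoked before its upstream artifacts exist."""


# -------------------------------------------------------------------- config

class CohortConfig(BaseModel):
    n_proposed: int = Field(200, ge=1)
    horizon_days: float = Field(8000.0, gt=0)
    inoculum_cells: float = Field(100.0, gt=0)


class SynthConfig(BaseModel):
    n_samples: int = Field(2000, ge=20)


class RegimenConfig(BaseModel):
    dose_mg_per_kg: float = Field(10.0, ge=0)
    interval_days: float = Field(14.0, gt=0)
    duration_days: float = Field(400.0, ge=0)
    arms: list[str] = ["masked", "unmasked"]

    @field_validator("arms")
    @classmethod
    def _arms_valid(cls, v):
        bad = set(v) - {"masked", "unmasked"}
        if bad:
            raise ValueError(f"unknown arm(s) {sorted(bad)}")
        if not v:
            raise ValueError("at least one arm required")
        return v

    def regimen(self, arm: str) -> mc.Regimen:
        return mc.Regimen(self.dose_mg_per_kg, self.interval_days,
                          self.duration_days, arm)


class AnnealingSettings(BaseModel):
    n_iter: int = Field(500, ge=1)
    t0: float = Field(0.1, ge=0)
    cooling: float = Field(0.99, gt=0, le=1)
    step: float = Field(0.5, gt=0)
    lam: float = Field(5.0, ge=0)

    def to_config(self) -> vs.AnnealingConfig:
        return vs.AnnealingConfig(n_iter=self.n_iter, t0=self.t0,
                                  cooling=self.cooling, step=self.step,
                                  lam=self.lam)


class SelectionConfig(BaseModel):
    constraints: list[str] = ["x1", "x2", "x3"]
    mode: str = "product"
    min_density_samples: int = Field(20, ge=2)
    annealing: AnnealingSettings = AnnealingSettings()
    rate_table: bool = True

    @field_validator("constraints")
    @classmethod
    def _constraints_valid(cls, v):
        bad = set(v) - set(vs.RATIO_NAMES)
        if bad or not v:
            raise ValueError(f"constraints must be a non-empty subset of "
                             f"{vs.RATIO_NAMES}")
        return v

    @field_validator("mode")
    @classmethod
    def _mode_valid(cls, v):
        if v not in ("product", "joint"):
            raise ValueError("mode must be 'product' or 'joint'")
        return v

    def indices(self) -> tuple[int, ...]:
        return tuple(sorted(vs.RATIO_NAMES.index(c) for c in self.constraints))


class AnalysisConfig(BaseModel):
    prcc: bool = True
    biomarkers: bool = True
    median_split: bool = True
    tcc_stratified: bool = False
    tcc_n_per_group: int = Field(100, ge=10)
    prcc_parameters: list[str] = [
        "growth_rate", "init_diameter_cm", "kd_neoantigen", "tcc",
        "k_cleave", "mask_km", "k_exhaust", "k_kill"]


class PathsConfig(BaseModel):
    param_distributions: str | None = None
    omics_table: str | None = None


class RunConfig(BaseModel):
    """Schema-validated run configuration (YAML or JSON on disk)."""

    seed: int = 0
    output_dir: str = "qspvct_out"
    eps: float = Field(0.01, gt=0, lt=0.5)
    rtol: float = Field(1e-8, gt=0)
    paths: PathsConfig = PathsConfig()
    synth: SynthConfig = SynthConfig()
    cohort: CohortConfig = CohortConfig()
    regimen: RegimenConfig = RegimenConfig()
    selection: SelectionConfig = SelectionConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @property
    def out(self) -> Path:
        return Path(self.output_dir)

    def ratio_cfg(self) -> vs.RatioConfig:
        return vs.RatioConfig(self.eps)

    def seed_for(self, stage: str) -> int:
        return vg.child_seed(self.seed, stage)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data or {})


def _write_provenance(cfg: RunConfig) -> None:
    cfg.out.mkdir(parents=True, exist_ok=True)
    with open(cfg.out / "config.yaml", "w") as fh:
        yaml.safe_dump(json.loads(cfg.model_dump_json()), fh,
                       sort_keys=False)


def _event(cfg: RunConfig, stage: str, **payload) -> None:
    """Append a JSON-lines event to the run log."""
    cfg.out.mkdir(parents=True, exist_ok=True)
    with open(cfg.out / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps({"stage": stage, **payload}, default=float)
                 + "\n")


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{stage}' needs {path} — run '{produced_by}' first")
    return path


# -------------------------------------------------------------------- stages

def run_synth(cfg: RunConfig) -> dict:
    """Write the synthetic omics reference table and the parameter
    distribution table into the output directory."""
    _write_provenance(cfg)
    spec = sd.OmicsTableSpec(n=cfg.synth.n_samples,
                             seed=cfg.seed_for("omics"))
    table, truth = sd.make_omics_table(spec)
    table.to_csv(cfg.out / "omics_table.csv", index=False)
    (cfg.out / "omics_table.groundtruth.json").write_text(truth.to_json())
    dists = _distribution_set(cfg, allow_default=True)
    dists.to_csv(cfg.out / "distributions.csv")
    _event(cfg, "synth", n_samples=spec.n, seed=spec.seed)
    return {"omics_table": str(cfg.out / "omics_table.csv"),
            "distributions": str(cfg.out / "distributions.csv")}


def _distribution_set(cfg: RunConfig, allow_default: bool = True
                      ) -> vg.ParameterDistributionSet:
    if cfg.paths.param_distributions:
        return vg.ParameterDistributionSet.from_csv(
            cfg.paths.param_distributions)
    local = cfg.out / "distributions.csv"
    if local.exists():
        return vg.ParameterDistributionSet.from_csv(local)
    if not allow_default:
        raise DependencyError("no parameter distribution table found")
    return vg.default_distribution_set()


def _omics_table(cfg: RunConfig) -> pd.DataFrame:
    if cfg.paths.omics_table:
        return pd.read_csv(cfg.paths.omics_table)
    local = cfg.out / "omics_table.csv"
    _require(local, "select", "synth")
    return pd.read_csv(local)


def run_generate(cfg: RunConfig) -> dict:
    """Sample proposed patients and build the plausible cohort."""
    _write_provenance(cfg)
    dists = _distribution_set(cfg)
    plausible, n_prop = vg.build_plausible_cohort(
        dists, cfg.cohort.n_proposed, cfg.seed_for("lhs"),
        horizon=cfg.cohort.horizon_days,
        inoculum_cells=cfg.cohort.inoculum_cells, rtol=cfg.rtol)
    vg.cohort_to_frame(plausible).to_csv(
        cfg.out / "plausible_params.csv", index=False)
    vg.states_to_frame(plausible).to_csv(
        cfg.out / "plausible_states.csv", index=False)
    meta = {"n_proposed": n_prop, "n_plausible": len(plausible),
            "seed": cfg.seed_for("lhs")}
    (cfg.out / "generate_meta.json").write_text(json.dumps(meta))
    _event(cfg, "generate", **meta)
    log.info("generate: %d/%d plausible", len(plausible), n_prop)
    return meta


def load_cohort(params_csv: Path, states_csv: Path
                ) -> list[vg.PlausiblePatient]:
    """Rebuild a cohort from its parameter and state tables."""
    pdf = pd.read_csv(params_csv)
    sdf = pd.read_csv(states_csv)
    cohort = []
    state_cols = [f"{c.value}.{n}" for n, c in mc.STATE_NAMES]
    for (_, prow), (_, srow) in zip(pdf.iterrows(), sdf.iterrows()):
        params = mc.PatientParameters(
            {k: float(prow[k]) for k in mc.PARAM_NAMES if k in prow})
        y = np.array([float(srow[c]) for c in state_cols])
        cohort.append(vg.PlausiblePatient(
            params, mc.ModelState(y),
            float(prow.get("time_to_target_days", np.nan))))
    return cohort


def run_select(cfg: RunConfig) -> dict:
    """Calibrate the inclusion model and select the virtual cohort."""
    _write_provenance(cfg)
    _require(cfg.out / "plausible_params.csv", "select", "generate")
    plausible = load_cohort(cfg.out / "plausible_params.csv",
                            cfg.out / "plausible_states.csv")
    meta = json.loads((cfg.out / "generate_meta.json").read_text())
    omics = _omics_table(cfg)
    rcfg = cfg.ratio_cfg()
    ref_ratios = vs.ratios_from_table(omics, rcfg)
    pla_ratios = vs.ratios_from_cohort(plausible, rcfg)
    constraints = cfg.selection.indices()
    ann = cfg.selection.annealing.to_config()

    f_ref = vs.fit_density(ref_ratios, constraints, mode=cfg.selection.mode,
                           min_samples=cfg.selection.min_density_samples)
    f_pla = vs.fit_density(pla_ratios, constraints, mode=cfg.selection.mode,
                           min_samples=cfg.selection.min_density_samples)
    model = vs.InclusionModel(f_ref, f_pla)
    beta = vs.calibrate_beta(model, pla_ratios, ref_ratios,
                             cfg.seed_for("annealing"), ann)
    cohort, idx, rate = vs.select_vps(plausible, pla_ratios, model,
                                      cfg.seed_for("selection"),
                                      n_proposed=meta["n_proposed"])
    vg.cohort_to_frame(cohort).to_csv(cfg.out / "virtual_params.csv",
                                      index=False)
    vg.states_to_frame(cohort).to_csv(cfg.out / "virtual_states.csv",
                                      index=False)
    np.savetxt(cfg.out / "virtual_ratios.csv",
               pla_ratios[idx], delimiter=",", comments="",
               header="x1,x2,x3")
    report = {"beta": beta, "eps": cfg.eps,
              "constraints": list(cfg.selection.constraints),
              "seed": cfg.seed_for("selection"),
              "n_proposed": meta["n_proposed"],
              "n_plausible": len(plausible),
              "n_virtual": len(cohort), "acceptance_rate_pct": rate}
    if cfg.selection.rate_table:
        table = vs.acceptance_rate_table(
            plausible, pla_ratios, ref_ratios, meta["n_proposed"],
            cfg.seed_for("rate_table"), annealing=ann,
            mode=cfg.selection.mode,
            min_samples=cfg.selection.min_density_samples)
        table.to_csv(cfg.out / "acceptance_rate_table.csv", index=False)
        report["acceptance_rate_table"] = table.to_dict("records")
    (cfg.out / "selection_report.json").write_text(
        json.dumps(report, indent=2, default=float))
    _event(cfg, "select", beta=beta, n_virtual=len(cohort),
           acceptance_rate_pct=rate)
    log.info("select: beta=%.4g, %d virtual patients (%.1f%%)",
             beta, len(cohort), rate)
    return report


def run_trial_stage(cfg: RunConfig) -> dict:
    """Run every configured trial arm over the virtual cohort."""
    _write_provenance(cfg)
    _require(cfg.out / "virtual_params.csv", "trial", "select")
    cohort = load_cohort(cfg.out / "virtual_params.csv",
                         cfg.out / "virtual_states.csv")
    if not cohort:
        raise DependencyError("virtual cohort is empty; nothing to simulate")
    summary = {}
    for arm in cfg.regimen.arms:
        regimen = cfg.regimen.regimen(arm)
        result = te.run_trial(cohort, regimen, rtol=cfg.rtol)
        arm_dir = cfg.out / f"trial_{arm}"
        arm_dir.mkdir(exist_ok=True)
        result.to_frame().to_csv(arm_dir / "outcomes.csv", index=False)
        result.waterfall().to_csv(arm_dir / "waterfall.csv", index=False)
        result.spider.to_csv(arm_dir / "spider.csv", index=False)
        result.pfs().to_csv(arm_dir / "pfs.csv", index=False)
        summary[arm] = {"orr_pct": result.orr_pct, "n": result.n,
                        "n_failed": len(result.failed_ids)}
        _event(cfg, "trial", arm=arm, **summary[arm])
        log.info("trial %s: ORR %.1f%% (n=%d)", arm, result.orr_pct,
                 result.n)
    (cfg.out / "trial_summary.json").write_text(
        json.dumps(summary, indent=2))
    return summary


def run_analyze(cfg: RunConfig) -> dict:
    """PRCC, responder biomarkers, median-split labels and (optionally)
    the TCC-percentile-stratified trial."""
    _write_provenance(cfg)
    _require(cfg.out / "virtual_params.csv", "analyze", "select")
    cohort = load_cohort(cfg.out / "virtual_params.csv",
                         cfg.out / "virtual_states.csv")
    if not cohort:
        raise DependencyError("virtual cohort is empty; nothing to analyze")
    arm = cfg.regimen.arms[0]
    regimen = cfg.regimen.regimen(arm)
    result = te.run_trial(cohort, regimen, rtol=cfg.rtol,
                          keep_trajectories=True)
    ana_dir = cfg.out / "analysis"
    ana_dir.mkdir(exist_ok=True)
    produced = {}

    pre_states = [pt.pretreatment_state for pt in cohort]
    post_states = [traj.state_at(-1) for traj in result.trajectories]

    if cfg.analysis.prcc:
        X = pd.DataFrame([{k: pt.params[k]
                           for k in cfg.analysis.prcc_parameters}
                          for pt in cohort])
        Y = sa.biomarker_table(cohort, post_states)
        Y["pct_change"] = [o.pct_change for o in result.outcomes]
        mat = sa.prcc_matrix(X, Y)
        mat.to_csv(ana_dir / "prcc.csv")
        produced["prcc"] = str(ana_dir / "prcc.csv")

    if cfg.analysis.biomarkers:
        pre = sa.biomarker_table(cohort, pre_states)
        post = sa.biomarker_table(cohort, post_states)
        comp = sa.compare_responders(result, pre, post)
        comp.to_csv(ana_dir / "biomarker_comparison.csv", index=False)
        produced["biomarkers"] = str(ana_dir / "biomarker_comparison.csv")

    if cfg.analysis.median_split:
        ratios = vs.ratios_from_cohort(cohort, cfg.ratio_cfg())
        split = sa.median_split_waterfall(result, ratios)
        split.to_csv(ana_dir / "median_split_waterfall.csv", index=False)
        produced["median_split"] = str(ana_dir / "median_split_waterfall.csv")

    if cfg.analysis.tcc_stratified:
        dists = _distribution_set(cfg)
        omics = _omics_table(cfg)
        ref_ratios = vs.ratios_from_table(omics, cfg.ratio_cfg())
        strat = sa.tcc_stratified_trial(
            dists, cfg.analysis.tcc_n_per_group, regimen,
            cfg.seed_for("stratified"), ref_ratios=ref_ratios,
            ratio_cfg=cfg.ratio_cfg(),
            annealing=cfg.selection.annealing.to_config(),
            constraints=cfg.selection.indices(), rtol=cfg.rtol)
        strat.to_csv(ana_dir / "tcc_stratified.csv", index=False)
        produced["tcc_stratified"] = str(ana_dir / "tcc_stratified.csv")

    _event(cfg, "analyze", **{k: True for k in produced})
    return produced


def run_full(cfg: RunConfig) -> dict:
    """synth -> generate -> select -> trial -> analyze."""
    out = {}
    out["synth"] = run_synth(cfg)
    out["generate"] = run_generate(cfg)
    out["select"] = run_select(cfg)
    out["trial"] = run_trial_stage(cfg)
    out["analyze"] = run_analyze(cfg)
    return out
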