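"""Sensitivity, biomarker and TCC-stratification analyses.

* PRCC — partial rank correlation coefficients of patient parameters
  against trial biomarkers (rank-transform everything, partial out all
  other parameters by linear regression on ranks, correlate residuals).
* Responder vs non-responder biomarker comparison (two-sided Mann-Whitney
  rank-sum by default) with significance stars at 0.05 / 0.01 / 0.001.
* Median-split labels of the waterfall by pre-treatment immune ratio.
* TCC-percentile-stratified virtual trials: the tumor-specific T-cell
  clone (TCC) distribution — the model's proxy for tumor mutational
  burden — is cut into 10 equal-probability bands and the full
  generate -> select -> treat pipeline is run per band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .model_core import CompartmentId, ConfigurationError, ModelState, Regimen
from .trial_engine import TrialResult, run_trial
from .vp_generation import (
    ParameterDistribution,
    ParameterDistributionSet,
    PlausiblePatient,
    build_plausible_cohort,
    child_seed,
)
from .vp_selection import (
    AnnealingConfig,
    InclusionModel,
    RatioConfig,
    calibrate_beta,
    fit_density,
    ratios_from_cohort,
    select_vps,
)

__all__ = [
    "prcc",
    "biomarker_table",
    "compare_responders",
    "significance_stars",
    "median_split_waterfall",
    "tcc_group_bounds",
    "tcc_stratified_trial",
    "geometric_median",
    "BIOMARKERS",
]

BIOMARKERS = ("cd8_density", "cd4_density", "treg_density",
              "teff_treg_ratio", "m1_m2_ratio")


# ----------------------------------------------------------------------- PRCC

def prcc(X: pd.DataFrame | np.ndarray, y: np.ndarray,
         param_names: Sequence[str] | None = None) -> pd.Series:
    """Partial rank correlation coefficient of each column of X with y.

    All columns and y are rank-transformed; for parameter j the ranks of
    x_j and y are each residualized on the ranks of all other parameters
    (linear regression with intercept) and the Pearson correlation of the
    residuals is returned.  Constant columns are dropped with a warning
    (rho = NaN); a singular partial regression flags the parameter as NaN.
    """
    if isinstance(X, pd.DataFrame):
        param_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if param_names is None:
            param_names = [f"p{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ConfigurationError(
            f"need n > p + 2 samples for PRCC (n={n}, p={p})")

    keep = np.std(X, axis=0) > 0
    if not keep.all():
        dropped = [param_names[j] for j in np.nonzero(~keep)[0]]
        warnings.warn(f"constant parameter column(s) dropped: {dropped}",
                      RuntimeWarning)

    rx = np.column_stack([stats.rankdata(X[:, j]) for j in range(p)])
    ry = stats.rankdata(y)
    rho = np.full(p, np.nan)
    for j in range(p):
        if not keep[j]:
            continue
        others = [k for k in range(p) if k != j and keep[k]]
        A = np.column_stack([np.ones(n), rx[:, others]])
        try:
            bx, *_ = np.linalg.lstsq(A, rx[:, j], rcond=None)
            by, *_ = np.linalg.lstsq(A, ry, rcond=None)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular partial regression for "
                          f"{param_names[j]}", RuntimeWarning)
            continue
        ex = rx[:, j] - A @ bx
        ey = ry - A @ by
        sx, sy = np.std(ex), np.std(ey)
        if sx == 0 or sy == 0:
            warnings.warn(f"degenerate residuals for {param_names[j]}",
                          RuntimeWarning)
            continue
        rho[j] = float(np.clip(np.mean(ex * ey) / (sx * sy), -1.0, 1.0))
    return pd.Series(rho, index=list(param_names), name="prcc")


def prcc_matrix(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """PRCC of every parameter against every biomarker column of Y."""
    return pd.DataFrame({col: prcc(X, Y[col].to_numpy())
                         for col in Y.columns})


# ----------------------------------------------------------- biomarker tables

def biomarker_table(cohort: Sequence[PlausiblePatient],
                    states: Sequence[ModelState]) -> pd.DataFrame:
    """Key immune biomarkers per patient for a set of model states.

    Densities are cells/mL of tumor at that state's tumor volume; the
    Teff/Treg and M1/M2 ratios are dimensionless (0/0 reported as NaN).
    """
    T = CompartmentId.TUMOR
    rows = []
    for pt, s in zip(cohort, states):
        v_ml = max(s.cancer_cells * pt.params["cell_volume_ml"]
                   / pt.params["packing_fraction"], 1e-9)
        cd8, cd4 = s[("cd8_teff", T)], s[("cd4_th", T)]
        treg = s[("treg", T)]
        m1, m2 = s[("m1_mac", T)], s[("m2_mac", T)]
        rows.append({
            "cd8_density": cd8 / v_ml,
            "cd4_density": cd4 / v_ml,
            "treg_density": treg / v_ml,
            "teff_treg_ratio": cd8 / treg if treg > 0 else np.nan,
            "m1_m2_ratio": m1 / m2 if m2 > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_responders(result: TrialResult, pre: pd.DataFrame,
                       post: pd.DataFrame, test: str = "ranksum",
                       biomarkers: Sequence[str] = BIOMARKERS
                       ) -> pd.DataFrame:
    """Responder (PR/CR) vs non-responder comparison per biomarker and
    timepoint.

    ``pre`` and ``post`` are biomarker tables aligned with
    ``result.outcomes``.  Two-sided Mann-Whitney rank-sum by default
    (``test='welch'`` switches to Welch's t).  Returns a tidy table with
    p-values and significance stars; comparisons with fewer than two
    patients in a group are skipped with a warning.
    """
    responder = np.array([o.responder for o in result.outcomes])
    if responder.sum() < 2 or (~responder).sum() < 2:
        warnings.warn("fewer than 2 patients in a response group; "
                      "comparison skipped", RuntimeWarning)
        return pd.DataFrame(columns=["biomarker", "timepoint", "n_responder",
                                     "n_nonresponder", "median_responder",
                                     "median_nonresponder", "p_value",
                                     "stars"])
    rows = []
    for label, table in (("pre", pre), ("post", post)):
        for bm in biomarkers:
            v = table[bm].to_numpy(dtype=float)
            ok = np.isfinite(v)
            a = v[responder & ok]
            b = v[~responder & ok]
            if a.size < 2 or b.size < 2:
                warnings.warn(f"{bm}/{label}: group too small, skipped",
                              RuntimeWarning)
                continue
            if test == "ranksum":
                if np.array_equal(np.sort(a), np.sort(b)):
                    p = 1.0  # identical samples carry no evidence
                else:
                    p = float(stats.mannwhitneyu(
                        a, b, alternative="two-sided").pvalue)
            elif test == "welch":
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                raise ConfigurationError(f"unknown test {test!r}")
            rows.append({
                "biomarker": bm, "timepoint": label,
                "n_responder": int(a.size), "n_nonresponder": int(b.size),
                "median_responder": float(np.median(a)),
                "median_nonresponder": float(np.median(b)),
                "p_value": min(p, 1.0), "stars": significance_stars(p),
            })
    return pd.DataFrame(rows)


def median_split_waterfall(result: TrialResult,
                           ratios: np.ndarray) -> pd.DataFrame:
    """Label each patient per immune ratio as >= median or < median.

    The median is computed over the virtual cohort's pre-treatment ratios;
    ties label as ">= median".  Returns one row per patient with the
    percent change and a label column per ratio.
    """
    if not result.outcomes:
        raise ConfigurationError("cohort must be nonempty")
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    med = np.median(ratios, axis=0)
    out = pd.DataFrame({
        "patient_id": [o.patient_id for o in result.outcomes],
        "pct_change": [o.pct_change for o in result.outcomes],
        "recist": [o.recist for o in result.outcomes],
    })
    for j, name in enumerate(("x1", "x2", "x3")[:ratios.shape[1]]):
        out[f"{name}_label"] = np.where(ratios[:, j] >= med[j],
                                        ">= median", "< median")
    return out


# ------------------------------------------------------- TCC stratification

def geometric_median(samples: np.ndarray) -> float:
    """exp(median(log(samples))) — the sample median on the log scale."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ConfigurationError("samples must be nonempty")
    if np.any(samples <= 0):
        raise ConfigurationError("samples must be positive")
    return float(np.exp(np.median(np.log(samples))))


def tcc_group_bounds(dist: ParameterDistribution,
                     n_groups: int = 10) -> np.ndarray:
    """Quantile boundaries cutting the (truncated) TCC distribution into
    ``n_groups`` equal-probability bands."""
    q = np.linspace(0.0, 1.0, n_groups + 1)
    # ppf of the truncated marginal at the band edges
    eps = 1e-12
    return dist.ppf(np.clip(q, eps, 1.0 - eps))


@dataclass
class StratifiedGroup:
    group: int
    tcc_lo: float
    tcc_hi: float
    n_proposed: int
    n_plausible: int
    n_selected: int
    orr_pct: float
    ci_lo_pct: float
    ci_hi_pct: float


def tcc_stratified_trial(dists: ParameterDistributionSet, n_per_group: int,
                         regimen: Regimen, seed: int,
                         ref_ratios: np.ndarray | None = None,
                         n_groups: int = 10,
                         ratio_cfg: RatioConfig | None = None,
                         annealing: AnnealingConfig | None = None,
                         constraints: tuple[int, ...] = (0, 1, 2),
                         rtol: float = 1e-8,
                         min_density_samples: int = 20) -> pd.DataFrame:
    """ORR as a function of the TCC percentile band.

    Builds ``n_groups`` cohorts identical except that group g samples the
    TCC only within its [g/n, (g+1)/n] percentile band of the original
    distribution; each runs the full generate -> select -> treat pipeline.
    When ``ref_ratios`` is None the selection step is skipped (all
    plausible patients are treated).  ORR confidence intervals are 95%
    Wilson score intervals.
    """
    if "tcc" not in dists.names:
        raise ConfigurationError("distribution set has no 'tcc' parameter")
    base = dists["tcc"]
    bounds = tcc_group_bounds(base, n_groups)
    rows = []
    for g in range(n_groups):
        lo, hi = float(bounds[g]), float(bounds[g + 1])
        gdists = dists.replace("tcc", ParameterDistribution(
            "tcc", base.family, base.p1, base.p2, lo, hi, base.units))
        gseed = child_seed(seed, f"group{g}")
        plausible, n_prop = build_plausible_cohort(
            gdists, n_per_group, gseed, rtol=rtol)
        cohort = plausible
        if ref_ratios is not None and len(plausible) >= min_density_samples:
            pla_ratios = ratios_from_cohort(plausible, ratio_cfg)
            f_ref = fit_density(ref_ratios, constraints,
                                min_samples=min_density_samples)
            f_pla = fit_density(pla_ratios, constraints,
                                min_samples=min_density_samples)
            model = InclusionModel(f_ref, f_pla)
            calibrate_beta(model, pla_ratios, ref_ratios,
                           child_seed(gseed, "beta"), annealing)
            cohort, _, _ = select_vps(plausible, pla_ratios, model,
                                      child_seed(gseed, "select"),
                                      n_proposed=n_prop)
        if not cohort:
            warnings.warn(f"TCC group {g}: no virtual patients selected",
                          RuntimeWarning)
            rows.append(StratifiedGroup(g, lo, hi, n_prop, len(plausible),
                                        0, np.nan, np.nan, np.nan))
            continue
        result = run_trial(cohort, regimen, rtol=rtol)
        n_resp = sum(o.responder for o in result.outcomes)
        ci_lo, ci_hi = proportion_confint(n_resp, result.n, alpha=0.05,
                                          method="wilson")
        rows.append(StratifiedGroup(
            g, lo, hi, n_prop, len(plausible), len(cohort),
            result.orr_pct, 100.0 * ci_lo, 100.0 * ci_hi))
    return pd.DataFrame([r.__dict__ for r in rows])
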