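"""Omics-informed virtual-patient selection.

Plausible patients are compared with a reference cohort (an iAtlas-style
table of immune-subset proportions) through three clamped immune subset
ratios::

    x1 = M1 / (M1 + M2)        (M1 share of macrophages)
    x2 = Treg / (Treg + CD8)   (Treg share of Treg + CD8)
    x3 = CD4 / (CD4 + CD8)     (CD4 share of CD4 + CD8)

each clamped to [eps, 1 - eps] to avoid divergences in log space.  Because
the ratios are computed identically on model cell densities (cells/mL) and
on omics proportions of leukocytes, units cancel and the two sides are
directly comparable.

The probability of including a plausible patient in the virtual cohort is
``min(1, beta * f_ref(x) / f_pla(x))`` where the densities are kernel
estimates over the log-ratios and the normalization factor ``beta`` is
calibrated by simulated annealing to admit as many patients as possible
without letting probability clipping distort the match to the reference
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import CompartmentId, ConfigurationError
from .vp_generation import PlausiblePatient, child_seed

__all__ = [
    "RatioConfig",
    "ImmuneRatios",
    "RatioDensity",
    "InclusionModel",
    "AnnealingConfig",
    "compute_ratios",
    "ratios_from_table",
    "ratios_from_cohort",
    "epsilon_diagnostic",
    "fit_density",
    "inclusion_probability",
    "calibrate_beta",
    "select_vps",
    "acceptance_rate_table",
    "ALL_CONSTRAINT_SUBSETS",
    "RATIO_NAMES",
]

RATIO_NAMES = ("x1", "x2", "x3")

#: the 7 non-empty subsets of {x1, x2, x3}, as index tuples
ALL_CONSTRAINT_SUBSETS: tuple[tuple[int, ...], ...] = tuple(
    c for k in (1, 2, 3) for c in combinations(range(3), k))


@dataclass(frozen=True)
class RatioConfig:
    """Clamp constant eps bounding every ratio to [eps, 1 - eps]."""

    eps: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.eps < 0.5:
            raise ConfigurationError("eps must satisfy 0 < eps < 0.5")


@dataclass(frozen=True)
class ImmuneRatios:
    x1: float
    x2: float
    x3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3])


def _clamped_fraction(num, den_other, eps):
    """eps-clamped num / (num + den_other), defined even at 0/0."""
    num = np.asarray(num, dtype=float)
    den_other = np.asarray(den_other, dtype=float)
    total = num + den_other
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(total > 0, num / np.where(total > 0, total, 1.0), 0.0)
    return np.clip(raw, eps, 1.0 - eps)


def compute_ratios(m1, m2, treg, cd8, cd4,
                   cfg: RatioConfig | None = None) -> ImmuneRatios:
    """Clamped immune subset ratios from the five subset densities."""
    cfg = cfg or RatioConfig()
    for name, v in (("m1", m1), ("m2", m2), ("treg", treg),
                    ("cd8", cd8), ("cd4", cd4)):
        if v < 0:
            raise ConfigurationError(f"negative density for {name}")
    return ImmuneRatios(
        x1=float(_clamped_fraction(m1, m2, cfg.eps)),
        x2=float(_clamped_fraction(treg, cd8, cfg.eps)),
        x3=float(_clamped_fraction(cd4, cd8, cfg.eps)),
    )


def ratios_from_table(table: pd.DataFrame,
                      cfg: RatioConfig | None = None) -> np.ndarray:
    """Vectorized ratios from a table with columns M1, M2, Treg, CD8, CD4.

    Returns an (n, 3) array of clamped ratios.
    """
    cfg = cfg or RatioConfig()
    required = {"M1", "M2", "Treg", "CD8", "CD4"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"table missing columns {sorted(missing)}")
    for col in sorted(required):
        if (table[col] < 0).any():
            raise ConfigurationError(f"negative density in column {col}")
    x1 = _clamped_fraction(table["M1"].to_numpy(), table["M2"].to_numpy(),
                           cfg.eps)
    x2 = _clamped_fraction(table["Treg"].to_numpy(), table["CD8"].to_numpy(),
                           cfg.eps)
    x3 = _clamped_fraction(table["CD4"].to_numpy(), table["CD8"].to_numpy(),
                           cfg.eps)
    return np.column_stack([x1, x2, x3])


def ratios_from_cohort(cohort: Sequence[PlausiblePatient],
                       cfg: RatioConfig | None = None) -> np.ndarray:
    """Pre-treatment immune ratios for a plausible cohort, (n, 3)."""
    rows = []
    T = CompartmentId.TUMOR
    for pt in cohort:
        s = pt.pretreatment_state
        rows.append({
            "M1": s[("m1_mac", T)], "M2": s[("m2_mac", T)],
            "Treg": s[("treg", T)], "CD8": s[("cd8_teff", T)],
            "CD4": s[("cd4_th", T)],
        })
    if not rows:
        return np.empty((0, 3))
    return ratios_from_table(pd.DataFrame(rows), cfg)


def epsilon_diagnostic(samples: np.ndarray,
                       eps_grid: np.ndarray) -> np.ndarray:
    """Relative error of the median induced by the clamp, per eps.

    For each eps the raw fractions are clamped to [eps, 1 - eps] and the
    relative change of the median, (median_clamped - median_raw) /
    median_raw, is returned.  The curve dips to zero when eps equals the
    raw median.  A zero raw median yields NaN (undefined).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ConfigurationError("samples must be nonempty")
    med_raw = np.median(samples)
    out = np.empty(len(eps_grid))
    for i, eps in enumerate(np.asarray(eps_grid, dtype=float)):
        med_eps = np.median(np.clip(samples, eps, 1.0 - eps))
        out[i] = np.nan if med_raw == 0 else (med_eps - med_raw) / med_raw
    return out


# ------------------------------------------------------------------ densities

def _log_ratio(x: np.ndarray) -> np.ndarray:
    """log(x / (1 - x)): the log of the underlying cell-count ratio.

    For x1 this is exactly log(M1/M2), for x2 log(Treg/CD8), for x3
    log(CD4/CD8); the eps clamp bounds it symmetrically, avoiding both
    divergences of the log.
    """
    return np.log(x) - np.log1p(-x)


class RatioDensity:
    """Kernel density over log cell-count ratios for one constraint subset.

    ``mode='product'`` (default) fits an independent 1-D Gaussian KDE
    (Silverman bandwidth) per active ratio and multiplies them;
    ``mode='joint'`` fits one joint KDE over the active ratios.  Degenerate
    (zero-variance) dimensions fall back to a narrow Gaussian atom.
    """

    _ATOM_BW = 1e-3

    def __init__(self, samples: np.ndarray, constraints: tuple[int, ...],
                 mode: str = "product", min_samples: int = 20):
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ConfigurationError("samples must be an (n, 3) ratio array")
        if not constraints:
            raise ConfigurationError("constraint subset must be non-empty")
        if len(samples) < min_samples:
            raise ConfigurationError(
                f"need >= {min_samples} samples to fit a density, "
                f"got {len(samples)}")
        if mode not in ("product", "joint"):
            raise ConfigurationError(f"unknown density mode {mode!r}")
        self.constraints = tuple(sorted(constraints))
        self.mode = mode
        logx = _log_ratio(samples[:, self.constraints])
        self._kdes: list = []
        self._atoms: list = []
        if mode == "joint" and len(self.constraints) > 1:
            if np.any(np.isclose(logx.std(axis=0), 0.0)):
                mode = "product"  # joint KDE needs full-rank covariance
                self.mode = "product"
        if self.mode == "joint" and len(self.constraints) > 1:
            self._kdes = [stats.gaussian_kde(logx.T, bw_method="silverman")]
            self._atoms = [None]
        else:
            for j in range(logx.shape[1]):
                col = logx[:, j]
                if np.isclose(col.std(), 0.0):
                    self._kdes.append(None)
                    self._atoms.append(float(col[0]))
                else:
                    self._kdes.append(
                        stats.gaussian_kde(col, bw_method="silverman"))
                    self._atoms.append(None)

    @property
    def ndim(self) -> int:
        return len(self.constraints)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Density of the log-ratio law at ratio points ``x`` (n, 3)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        logx = _log_ratio(x[:, self.constraints])
        if self.mode == "joint" and len(self._kdes) == 1 and self.ndim > 1:
            return self._kdes[0](logx.T)
        out = np.ones(len(logx))
        for j, (kde, atom) in enumerate(zip(self._kdes, self._atoms)):
            if kde is not None:
                out *= kde(logx[:, j])
            else:
                z = (logx[:, j] - atom) / self._ATOM_BW
                out *= np.exp(-0.5 * z * z) / (
                    self._ATOM_BW * np.sqrt(2.0 * np.pi))
        return out

    def evaluate_ratio_density(self, x: np.ndarray) -> np.ndarray:
        """Density of the ratio law on the original [0, 1] scale (change of
        variables from the log cell-count-ratio space)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xa = x[:, self.constraints]
        jac = np.prod(1.0 / (xa * (1.0 - xa)), axis=1)
        return self.evaluate(x) * jac


def fit_density(samples: np.ndarray, constraints: tuple[int, ...] = (0, 1, 2),
                mode: str = "product", min_samples: int = 20) -> RatioDensity:
    """Fit the ratio density for the given constraint subset."""
    return RatioDensity(samples, constraints, mode=mode,
                        min_samples=min_samples)


# ------------------------------------------------------------ inclusion model

@dataclass
class AnnealingConfig:
    """Simulated-annealing settings for the beta calibration.

    The objective maximized is ``selected_fraction - lam * sum_i
    KS(selected_i, reference_i)`` over the active ratios, where the selected
    distribution is the probability-weighted plausible distribution.  Higher
    ``lam`` favors distribution fidelity over cohort size.
    """

    n_iter: int = 500
    t0: float = 0.1
    cooling: float = 0.99
    step: float = 0.5
    lam: float = 5.0
    log_beta_bounds: tuple[float, float] = (-14.0, 14.0)


@dataclass
class InclusionModel:
    """Fitted densities for reference and plausible cohorts plus beta."""

    f_ref: RatioDensity
    f_pla: RatioDensity
    beta: float | None = None
    density_floor: float = 1e-12

    def __post_init__(self):
        if self.f_ref.constraints != self.f_pla.constraints:
            raise ConfigurationError(
                "reference and plausible densities use different constraints")

    @property
    def constraints(self) -> tuple[int, ...]:
        return self.f_ref.constraints

    def density_ratio(self, x: np.ndarray) -> np.ndarray:
        num = self.f_ref.evaluate(x)
        den = np.maximum(self.f_pla.evaluate(x), self.density_floor)
        return num / den


def inclusion_probability(x, model: InclusionModel) -> np.ndarray:
    """p = min(1, beta * f_ref(x) / f_pla(x)) for ratio point(s) x."""
    if model.beta is None:
        raise RuntimeError("inclusion model is not calibrated (beta is None)")
    if model.beta < 0:
        raise ConfigurationError("beta must be >= 0")
    if isinstance(x, ImmuneRatios):
        x = x.as_array()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.clip(model.beta * model.density_ratio(x), 0.0, 1.0)


def _weighted_ks(values: np.ndarray, weights: np.ndarray,
                 reference: np.ndarray) -> float:
    """KS distance between a weighted ECDF and a reference sample ECDF."""
    if weights.sum() <= 0:
        return 1.0
    grid = np.unique(np.concatenate([values, reference]))
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) / w.sum()
    idx = np.searchsorted(v, grid, side="right")
    ecdf_w = np.where(idx == 0, 0.0, cw[idx - 1])
    ref_sorted = np.sort(reference)
    ecdf_r = np.searchsorted(ref_sorted, grid, side="right") / ref_sorted.size
    return float(np.max(np.abs(ecdf_w - ecdf_r)))


def annealing_objective(log_beta: float, ratio: np.ndarray,
                        pla_ratios: np.ndarray, ref_ratios: np.ndarray,
                        constraints: tuple[int, ...], lam: float) -> float:
    """Objective for one candidate beta (see AnnealingConfig)."""
    p = np.clip(np.exp(log_beta) * ratio, 0.0, 1.0)
    frac = p.mean()
    penalty = 0.0
    for j in constraints:
        penalty += _weighted_ks(pla_ratios[:, j], p, ref_ratios[:, j])
    return frac - lam * penalty


def calibrate_beta(model: InclusionModel, pla_ratios: np.ndarray,
                   ref_ratios: np.ndarray, seed: int,
                   cfg: AnnealingConfig | None = None) -> float:
    """Calibrate the normalization factor beta by simulated annealing.

    Deterministic for a given seed; with ``t0 = 0`` the walk reduces to a
    greedy hill-climb.  Returns (and stores on the model) the best beta
    found; warns when the search was still improving at the end.
    """
    cfg = cfg or AnnealingConfig()
    rng = np.random.default_rng(seed)
    ratio = model.density_ratio(pla_ratios)

    def obj(lb):
        return annealing_objective(lb, ratio, pla_ratios, ref_ratios,
                                   model.constraints, cfg.lam)

    lo, hi = cfg.log_beta_bounds
    # start where the mean inclusion probability is ~0.5 before clipping
    with np.errstate(divide="ignore"):
        lb = float(np.clip(np.log(0.5) - np.log(max(ratio.mean(), 1e-300)),
                           lo, hi))
    cur = obj(lb)
    best_lb, best = lb, cur
    best_iter = 0
    temp = cfg.t0
    for it in range(cfg.n_iter):
        cand = float(np.clip(lb + cfg.step * rng.standard_normal(), lo, hi))
        val = obj(cand)
        delta = val - cur
        if delta >= 0 or (temp > 0 and
                          rng.random() < np.exp(delta / temp)):
            lb, cur = cand, val
            if val > best:
                best_lb, best, best_iter = cand, val, it
        temp *= cfg.cooling
    if best_iter >= cfg.n_iter - max(2, cfg.n_iter // 50):
        warnings.warn("beta annealing still improving at the last iterations;"
                      " returning best-so-far", RuntimeWarning)
    model.beta = float(np.exp(best_lb))
    return model.beta


def select_vps(plausible: Sequence, pla_ratios: np.ndarray,
               model: InclusionModel, seed: int,
               n_proposed: int | None = None):
    """Bernoulli selection of virtual patients by inclusion probability.

    Returns ``(cohort, selected_indices, acceptance_rate_pct)`` where the
    rate is accepted / proposed (proposed defaults to the plausible count).
    """
    plausible = list(plausible)
    n_prop = n_proposed if n_proposed is not None else len(plausible)
    if not plausible:
        return [], np.empty(0, dtype=int), 0.0
    p = inclusion_probability(pla_ratios, model)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(plausible)) < p
    idx = np.nonzero(keep)[0]
    cohort = [plausible[i] for i in idx]
    rate = 100.0 * len(cohort) / n_prop if n_prop else 0.0
    return cohort, idx, rate


def acceptance_rate_table(plausible: Sequence, pla_ratios: np.ndarray,
                          ref_ratios: np.ndarray, n_proposed: int, seed: int,
                          subsets: Sequence[tuple[int, ...]] = ALL_CONSTRAINT_SUBSETS,
                          annealing: AnnealingConfig | None = None,
                          mode: str = "product",
                          min_samples: int = 20) -> pd.DataFrame:
    """Acceptance percentage of proposed patients for each constraint subset.

    Every subset starts from the same proposed/plausible cohort; beta is
    recalibrated per subset.  Returns a table with columns
    ``constraints, beta, n_selected, acceptance_pct``.
    """
    rows = []
    for k, subset in enumerate(subsets):
        if not subset:
            raise ConfigurationError("constraint subsets must be non-empty")
        f_ref = fit_density(ref_ratios, tuple(subset), mode=mode,
                            min_samples=min_samples)
        f_pla = fit_density(pla_ratios, tuple(subset), mode=mode,
                            min_samples=min_samples)
        model = InclusionModel(f_ref, f_pla)
        calibrate_beta(model, pla_ratios, ref_ratios,
                       child_seed(seed, f"beta{k}"), annealing)
        cohort, _, rate = select_vps(plausible, pla_ratios, model,
                                     child_seed(seed, f"select{k}"),
                                     n_proposed=n_proposed)
        rows.append({
            "constraints": "+".join(RATIO_NAMES[j] for j in subset),
            "beta": model.beta, "n_selected": len(cohort),
            "acceptance_pct": rate,
        })
    return pd.DataFrame(rows)
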