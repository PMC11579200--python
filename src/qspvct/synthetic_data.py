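"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here without downloads:
iAtlas-style immune-subset proportion tables (bounded, right-skewed,
rank-correlated beta marginals through a Gaussian copula), paired
reference/plausible-like tables with a known location shift on one immune
ratio, and analytic toy tumor-size trajectories with known RECIST class and
progression day.  Every generator is a pure function of its spec + seed and
attaches its generating parameters as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import ConfigurationError

__all__ = [
    "OmicsTableSpec",
    "GroundTruth",
    "SUBSET_COLUMNS",
    "make_omics_table",
    "make_shifted_cohorts",
    "make_toy_trajectories",
]

SUBSET_COLUMNS = ("M1", "M2", "Treg", "CD8", "CD4")

#: default beta marginals (a, b) per subset: right-skewed proportions with
#: enough mass near 0 that raw ratios reach both clamp regions
_DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "M1": (0.8, 6.0),
    "M2": (0.6, 6.0),
    "Treg": (0.7, 8.0),
    "CD8": (0.9, 6.0),
    "CD4": (1.2, 5.0),
}


def _default_correlation() -> np.ndarray:
    """Mild positive rank correlation within lineages (T cells, macrophages)."""
    r = np.eye(5)
    # order: M1, M2, Treg, CD8, CD4
    r[0, 1] = r[1, 0] = 0.2
    r[2, 3] = r[3, 2] = 0.3
    r[2, 4] = r[4, 2] = 0.3
    r[3, 4] = r[4, 3] = 0.3
    return r


@dataclass
class OmicsTableSpec:
    """Specification of a synthetic immune-subset proportion table."""

    n: int = 1000
    marginals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MARGINALS))
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        missing = set(SUBSET_COLUMNS) - set(self.marginals)
        if missing:
            raise ConfigurationError(
                f"marginals missing for {sorted(missing)}")
        if self.correlation is None:
            self.correlation = _default_correlation()
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (5, 5):
            raise ConfigurationError("correlation must be 5x5")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ConfigurationError("correlation must be symmetric")
        if np.min(np.linalg.eigvalsh(self.correlation)) < -1e-10:
            raise ConfigurationError(
                "correlation matrix is not positive semi-definite")


@dataclass
class GroundTruth:
    """Generating parameters serialized alongside every synthetic artifact."""

    kind: str
    params: dict

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o).__name__)
        return json.dumps({"kind": self.kind, "params": self.params},
                          default=_default, indent=2)


def make_omics_table(spec: OmicsTableSpec
                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Gaussian-copula table with beta marginals and the requested rank
    correlations.  Deterministic per seed; columns sample_id + the five
    subset proportions (each >= 0).

    Point-mass marginals are encoded as (a, b) with b == 0: the column is
    the constant a.
    """
    rng = np.random.default_rng(spec.seed)
    # shrink toward identity just enough to guarantee a usable factor
    corr = spec.correlation
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 1e-10, None)
    a_fact = v @ np.diag(np.sqrt(w))
    z = rng.standard_normal((spec.n, 5)) @ a_fact.T
    u = stats.norm.cdf(z)
    data = {"sample_id": [f"S{i:06d}" for i in range(spec.n)]}
    for j, col in enumerate(SUBSET_COLUMNS):
        a, b = spec.marginals[col]
        if b == 0:  # degenerate point mass
            data[col] = np.full(spec.n, float(a))
        else:
            data[col] = stats.beta(a, b).ppf(u[:, j])
    truth = GroundTruth("omics_table", {
        "n": spec.n, "marginals": {k: list(v) for k, v in
                                   spec.marginals.items()},
        "correlation": spec.correlation, "seed": spec.seed,
        "expected_means": {
            col: (spec.marginals[col][0]
                  if spec.marginals[col][1] == 0 else
                  spec.marginals[col][0]
                  / (spec.marginals[col][0] + spec.marginals[col][1]))
            for col in SUBSET_COLUMNS},
    })
    return pd.DataFrame(data), truth


#: which column is adjusted (holding the denominator partner fixed) to shift
#: each ratio without touching the other two
_SHIFT_COLUMN = {"x1": ("M1", "M2"), "x2": ("Treg", "CD8"),
                 "x3": ("CD4", "CD8")}


def make_shifted_cohorts(base: OmicsTableSpec, shift: str, magnitude: float,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired (reference, plausible-like) tables differing by a known
    location shift of one ratio on the log cell-count-ratio (logit) scale.

    The reference table is drawn from ``base``; the plausible-like table is
    an independent draw (seed + 1) whose designated ratio is moved by
    ``magnitude`` logit units (a support-preserving location shift of
    log(num/den)) via adjusting the numerator column with its partner held
    fixed, so the other two ratios are exactly unchanged.
    """
    if shift not in _SHIFT_COLUMN:
        raise ConfigurationError(f"shift must be one of {set(_SHIFT_COLUMN)}")
    ref, _ = make_omics_table(base)
    base2 = OmicsTableSpec(n=base.n, marginals=dict(base.marginals),
                           correlation=base.correlation.copy(),
                           seed=base.seed + 1)
    pla, _ = make_omics_table(base2)
    num_col, den_col = _SHIFT_COLUMN[shift]
    num = pla[num_col].to_numpy()
    den = pla[den_col].to_numpy()
    tot = num + den
    with np.errstate(invalid="ignore"):
        r = np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), 0.5)
    r = np.clip(r, 1e-9, 1.0 - 1e-9)
    z = np.log(r) - np.log1p(-r) + magnitude
    r_new = 1.0 / (1.0 + np.exp(-z))
    pla[num_col] = r_new * den / (1.0 - r_new)
    truth = GroundTruth("shifted_cohorts", {
        "base_seed": base.seed, "n": base.n, "shift": shift,
        "magnitude": magnitude})
    return ref, pla, truth


def make_toy_trajectories(kind: str, *, baseline_cm: float = 3.0,
                          duration_days: float = 400.0,
                          final_change_pct: float | None = None,
                          nadir_day: float = 100.0,
                          nadir_change_pct: float = -20.0,
                          rebound_pct_per_day: float = 0.2,
                          grid_dt: float = 1.0,
                          ) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Analytic diameter series with known RECIST class and progression day.

    Kinds: ``flat`` (constant), ``shrinking`` / ``growing`` (linear ramp to
    ``final_change_pct`` at the trial end) and ``nadir_rebound`` (linear to
    the nadir, then linear regrowth at ``rebound_pct_per_day`` % of the
    nadir per day).  The ground truth records the RECIST class at trial end
    and the nadir-referenced (+20%) progression day, or None if censored.
    """
    t = np.arange(0.0, duration_days + 0.5 * grid_dt, grid_dt)
    if kind == "flat":
        d = np.full_like(t, baseline_cm)
        truth_cls, prog = "SD", None
    elif kind in ("shrinking", "growing"):
        if final_change_pct is None:
            final_change_pct = -40.0 if kind == "shrinking" else 40.0
        if kind == "shrinking" and final_change_pct >= 0:
            raise ConfigurationError("shrinking needs final_change_pct < 0")
        if kind == "growing" and final_change_pct <= 0:
            raise ConfigurationError("growing needs final_change_pct > 0")
        d = baseline_cm * (1.0 + final_change_pct / 100.0
                           * t / duration_days)
        if kind == "shrinking":
            truth_cls = "PR" if final_change_pct <= -30 else "SD"
            prog = None
        else:
            truth_cls = "PD" if final_change_pct >= 20 else "SD"
            # running nadir is the baseline; progression at +20% over it
            prog = (20.0 / final_change_pct) * duration_days \
                if final_change_pct >= 20 else None
    elif kind == "nadir_rebound":
        if nadir_change_pct >= 0:
            raise ConfigurationError("nadir_change_pct must be < 0")
        nadir = baseline_cm * (1.0 + nadir_change_pct / 100.0)
        d = np.where(
            t <= nadir_day,
            baseline_cm + (nadir - baseline_cm) * t / nadir_day,
            nadir * (1.0 + rebound_pct_per_day / 100.0 * (t - nadir_day)))
        prog_candidate = nadir_day + 20.0 / rebound_pct_per_day
        prog = prog_candidate if prog_candidate <= duration_days else None
        final = d[-1]
        chg = 100.0 * (final - baseline_cm) / baseline_cm
        truth_cls = "PD" if chg >= 20 else ("PR" if chg <= -30 else "SD")
    else:
        raise ConfigurationError(f"unknown toy-trajectory kind {kind!r}")
    truth = GroundTruth("toy_trajectory", {
        "kind": kind, "baseline_cm": baseline_cm,
        "duration_days": duration_days, "recist_class": truth_cls,
        "progression_day": prog})
    return t, d, truth
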