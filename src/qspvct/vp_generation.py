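"""Proposed-patient sampling and plausible-patient construction.

Proposed patients are drawn by Latin hypercube sampling from per-parameter
marginal distributions (with truncation), grown therapy-free from a small
inoculum for up to 8000 days, and kept ("plausible") when the tumor reaches
the patient's pre-treatment target diameter within the horizon.  The model
state at the (interpolated) crossing time becomes the pre-treatment initial
condition for the virtual trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .model_core import (
    ConfigurationError,
    IntegrationError,
    ModelState,
    PatientParameters,
    Regimen,
    Trajectory,
    cells_from_diameter,
    initial_state,
    simulate,
)

__all__ = [
    "ParameterDistribution",
    "ParameterDistributionSet",
    "PlausiblePatient",
    "default_distribution_set",
    "lhs_sample",
    "grow_pretreatment",
    "plausibility_filter",
    "build_plausible_cohort",
    "child_seed",
]

_FAMILIES = ("uniform", "loguniform", "normal", "lognormal", "fixed")


def child_seed(master_seed: int, key: str) -> int:
    """Deterministic named sub-seed (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(sum(ord(c) * (i + 1) for i, c in enumerate(key)),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ParameterDistribution:
    """One marginal: family, family parameters and truncation bounds.

    Parameterizations (``p1``, ``p2``):

    - uniform: lower, upper
    - loguniform: lower, upper (log-uniform between them)
    - normal: mean, standard deviation
    - lognormal: median (scale), sigma of log
    - fixed: value, (ignored)
    """

    name: str
    family: str
    p1: float
    p2: float = 0.0
    lower: float = -np.inf
    upper: float = np.inf
    units: str = ""

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown distribution family {self.family!r} "
                f"for parameter {self.name!r}")
        if self.lower > self.upper:
            raise ConfigurationError(
                f"bounds out of order for parameter {self.name!r}")

    def _frozen(self):
        if self.family == "uniform":
            return stats.uniform(loc=self.p1, scale=self.p2 - self.p1)
        if self.family == "loguniform":
            return stats.loguniform(self.p1, self.p2)
        if self.family == "normal":
            return stats.norm(loc=self.p1, scale=self.p2)
        if self.family == "lognormal":
            return stats.lognorm(s=self.p2, scale=self.p1)
        raise AssertionError(self.family)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function of the truncated marginal, defined on (0, 1)."""
        u = np.asarray(u, dtype=float)
        if self.family == "fixed":
            return np.full_like(u, self.p1)
        dist = self._frozen()
        lo = dist.cdf(self.lower) if np.isfinite(self.lower) else 0.0
        hi = dist.cdf(self.upper) if np.isfinite(self.upper) else 1.0
        if hi <= lo:
            raise ConfigurationError(
                f"truncation bounds leave no mass for {self.name!r}")
        x = dist.ppf(lo + u * (hi - lo))
        return np.clip(x, self.lower, self.upper)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF of the truncated marginal."""
        if self.family == "fixed":
            return (np.asarray(x, dtype=float) >= self.p1).astype(float)
        dist = self._frozen()
        lo = dist.cdf(self.lower) if np.isfinite(self.lower) else 0.0
        hi = dist.cdf(self.upper) if np.isfinite(self.upper) else 1.0
        return np.clip((dist.cdf(x) - lo) / (hi - lo), 0.0, 1.0)


class ParameterDistributionSet:
    """Ordered collection of parameter marginals, CSV round-trippable."""

    def __init__(self, dists: Iterable[ParameterDistribution]):
        self.dists = list(dists)
        names = [d.name for d in self.dists]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate parameter names")

    def __iter__(self):
        return iter(self.dists)

    def __len__(self):
        return len(self.dists)

    def __getitem__(self, name: str) -> ParameterDistribution:
        for d in self.dists:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dists]

    def replace(self, name: str, dist: ParameterDistribution
                ) -> "ParameterDistributionSet":
        out = [dist if d.name == name else d for d in self.dists]
        return ParameterDistributionSet(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"name": d.name, "distribution": d.family, "p1": d.p1,
              "p2": d.p2, "lower": d.lower, "upper": d.upper,
              "units": d.units} for d in self.dists])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterDistributionSet":
        required = {"name", "distribution", "p1"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(
                f"distribution table missing columns {sorted(missing)}")
        dists = []
        for _, row in df.iterrows():
            dists.append(ParameterDistribution(
                name=str(row["name"]), family=str(row["distribution"]),
                p1=float(row["p1"]), p2=float(row.get("p2", 0.0) or 0.0),
                lower=float(row["lower"]) if "lower" in df else -np.inf,
                upper=float(row["upper"]) if "upper" in df else np.inf,
                units=str(row.get("units", "") or "")))
        return cls(dists)

    @classmethod
    def from_csv(cls, path) -> "ParameterDistributionSet":
        return cls.from_frame(pd.read_csv(path))


def default_distribution_set() -> ParameterDistributionSet:
    """Default patient-level parameter distributions.

    Medians follow the package's reduced-model calibration; the TCC marginal
    is lognormal with geometric median 93 clones (the NSCLC setting) and a
    wide spread so that percentile stratification covers a broad
    tumor-mutational-burden range.
    """
    return ParameterDistributionSet([
        ParameterDistribution("growth_rate", "lognormal", 0.015, 0.35,
                              0.005, 0.05, "1/day"),
        ParameterDistribution("init_diameter_cm", "uniform", 2.0, 4.0,
                              2.0, 4.0, "cm"),
        ParameterDistribution("kd_neoantigen", "loguniform", 3e-10, 3e-8,
                              3e-10, 3e-8, "M"),
        ParameterDistribution("tcc", "lognormal", 93.0, 0.8, 1.0, 5000.0,
                              "clones"),
        ParameterDistribution("k_cleave", "lognormal", 0.1, 0.5,
                              0.01, 1.0, "1/day"),
        ParameterDistribution("mask_km", "loguniform", 1e-3, 1e-1,
                              1e-3, 1e-1, ""),
        ParameterDistribution("k_exhaust", "lognormal", 0.08, 0.5,
                              0.008, 0.8, "1/day"),
        ParameterDistribution("k_kill", "lognormal", 5.0, 0.5, 0.5, 50.0,
                              "1/day"),
        ParameterDistribution("k_clear_ab", "lognormal", 0.25, 0.3,
                              0.05, 1.0, "1/day"),
        ParameterDistribution("body_mass_kg", "normal", 70.0, 10.0,
                              40.0, 120.0, "kg"),
        # immune-composition heterogeneity: spreads the pre-treatment
        # M1/M2, Treg/CD8 and CD4/CD8 balances across patients
        ParameterDistribution("k_prime_cd4", "lognormal", 40.0, 0.6,
                              4.0, 400.0, "1/day"),
        ParameterDistribution("k_prime_treg", "lognormal", 8.0, 0.6,
                              0.8, 80.0, "1/day"),
        ParameterDistribution("k_m1_rec", "lognormal", 0.02, 0.6,
                              0.002, 0.2, "1/day"),
        ParameterDistribution("k_m2_rec", "lognormal", 0.01, 0.6,
                              0.001, 0.1, "1/day"),
    ])


def lhs_sample(dists: ParameterDistributionSet, n: int, seed: int
               ) -> list[PatientParameters]:
    """Latin hypercube sample of ``n`` proposed patients.

    Each parameter's n samples occupy the n equal-probability strata of its
    truncated marginal exactly once; the same seed reproduces the cohort.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(dists), seed=int(seed))
    u = sampler.random(n)  # (n, d) in (0, 1), one point per stratum
    cols = {d.name: d.ppf(u[:, j]) for j, d in enumerate(dists)}
    return [PatientParameters({k: float(v[i]) for k, v in cols.items()})
            for i in range(n)]


def grow_pretreatment(params: PatientParameters, horizon: float = 8000.0, *,
                      inoculum_cells: float = 100.0, grid_dt: float = 5.0,
                      rtol: float = 1e-8) -> Trajectory:
    """Therapy-free tumor growth from a small inoculum.

    Integration stops at the first grid point past the patient's target
    pre-treatment diameter (the crossing state is interpolated downstream),
    or at the horizon if the tumor never gets there.
    """
    if horizon <= 0:
        raise ConfigurationError("horizon must be > 0")
    init = initial_state(inoculum_cells)
    return simulate(params, init, horizon,
                    Regimen(dose_mg_per_kg=0.0), grid_dt=grid_dt, rtol=rtol,
                    stop_above_diameter_cm=params["init_diameter_cm"])


@dataclass
class PlausiblePatient:
    """A plausible patient: parameters + interpolated pre-treatment state."""

    params: PatientParameters
    pretreatment_state: ModelState
    time_to_target_days: float

    @property
    def baseline_diameter_cm(self) -> float:
        from .model_core import tumor_diameter
        return tumor_diameter(self.pretreatment_state.cancer_cells,
                              self.params)


@dataclass(frozen=True)
class PlausibilityRules:
    """Declarative plausibility configuration.

    A trajectory is plausible when the tumor reaches the target diameter
    within the horizon, all species are finite and non-negative, and the
    optional pre-treatment immune-density bounds hold.
    """

    require_target_reached: bool = True
    state_bounds: dict = field(default_factory=dict)
    # state_bounds maps (species, CompartmentId) -> (lo, hi) on the
    # pre-treatment state

    def check_state(self, state: ModelState) -> bool:
        for key, (lo, hi) in self.state_bounds.items():
            v = state[key]
            if not (lo <= v <= hi):
                return False
        return True


def plausibility_filter(traj: Trajectory, params: PatientParameters,
                        rules: PlausibilityRules | None = None
                        ) -> tuple[bool, PlausiblePatient | None]:
    """Apply the plausibility rules to a pre-treatment growth trajectory.

    On acceptance the model state is linearly interpolated (in diameter)
    between the grid points bracketing the first crossing of the target
    diameter, so the pre-treatment tumor size equals the target exactly.
    """
    rules = rules or PlausibilityRules()
    if not np.all(np.isfinite(traj.states)):
        return False, None
    if np.any(traj.states < -1e-9):
        return False, None

    target = params["init_diameter_cm"]
    d = traj.diameter_cm
    above = np.nonzero(d >= target)[0]
    if above.size == 0:
        if rules.require_target_reached:
            return False, None
        raise ConfigurationError(
            "plausibility without target crossing is undefined")
    j = int(above[0])
    if j == 0:
        t_cross = float(traj.times[0])
        y_cross = traj.states[0].copy()
    else:
        d0, d1 = d[j - 1], d[j]
        w = (target - d0) / (d1 - d0)
        t_cross = float(traj.times[j - 1] + w * (traj.times[j] - traj.times[j - 1]))
        y_cross = (1.0 - w) * traj.states[j - 1] + w * traj.states[j]
        # pin the interpolated size to the target exactly
        y_cross[0] = cells_from_diameter(target, params)
    state = ModelState(y_cross)
    if not rules.check_state(state):
        return False, None
    return True, PlausiblePatient(params, state, t_cross)


def build_plausible_cohort(dists: ParameterDistributionSet, n: int, seed: int,
                           *, horizon: float = 8000.0,
                           inoculum_cells: float = 100.0,
                           rules: PlausibilityRules | None = None,
                           rtol: float = 1e-8, grid_dt: float = 5.0,
                           ) -> tuple[list[PlausiblePatient], int]:
    """Sample ``n`` proposed patients and keep the plausible ones.

    Returns the plausible cohort and the number proposed (for rate
    bookkeeping).  Patients whose growth simulation fails are counted as
    proposed but not plausible.
    """
    proposed = lhs_sample(dists, n, seed)
    plausible: list[PlausiblePatient] = []
    for params in proposed:
        try:
            traj = grow_pretreatment(params, horizon,
                                     inoculum_cells=inoculum_cells,
                                     grid_dt=grid_dt, rtol=rtol)
        except IntegrationError:
            continue
        ok, patient = plausibility_filter(traj, params, rules)
        if ok:
            plausible.append(patient)
    return plausible, n


def cohort_to_frame(cohort: Sequence[PlausiblePatient]) -> pd.DataFrame:
    """One row per patient, one column per parameter (+ crossing time)."""
    rows = []
    for i, pt in enumerate(cohort):
        row = {"patient_id": i, **dict(pt.params),
               "time_to_target_days": pt.time_to_target_days}
        rows.append(row)
    return pd.DataFrame(rows)


def states_to_frame(cohort: Sequence[PlausiblePatient]) -> pd.DataFrame:
    """Companion table of pre-treatment initial-condition states."""
    from .model_core import STATE_NAMES
    rows = []
    for i, pt in enumerate(cohort):
        row = {"patient_id": i}
        for (name, comp), v in zip(STATE_NAMES, pt.pretreatment_state.y):
            row[f"{comp.value}.{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
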