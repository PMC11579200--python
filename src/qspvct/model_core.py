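"""Reduced compartmental QSP immuno-oncology model with a conditionally
activated (masked, protease-cleavable) anti-PD-L1 antibody.

The model tracks tumor, tumor-draining lymph node (TDLN), central and
peripheral compartments.  Cellular dynamics (cancer cells, CD8/CD4/Treg
T cells, mature APCs, M1/M2 macrophages, a lumped cytokine pool) live in the
tumor, TDLN and central compartments; antibody pharmacokinetics span all
four.  The antibody is tracked in two irreversibly ordered pools per
compartment — *intact* (masks attached) and *cleaved* (at least one linker
cut by tumor proteases) — plus derived masked/open/bound species:

* Mask opening/closing is fast relative to pharmacokinetics, so the two
  masks are treated as independent two-state units at equilibrium.  With
  per-mask equilibrium constant ``K_M`` the binding-competent ("at least one
  site exposed") fraction of the intact pool is ``1 - (1 + K_M)**-2``
  (see :func:`unmasked_fraction`).
* Out-of-synapse PD-L1 occupancy uses the mass-action equilibrium with the
  antibody Kd; receptor amounts are negligible relative to dose, so binding
  does not deplete the antibody (no target-mediated disposition).
* Checkpoint inhibition: PD-1 engagement by unblocked PD-L1 suppresses CD8
  killing and accelerates exhaustion; antibody occupancy relieves both
  monotonically.

The unmasked comparator arm is the same molecule with the masks removed
(binding-competent fraction 1, identical PK constants), i.e. the K_M → ∞
limit of the masked arm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import _ode

__all__ = [
    "CompartmentId",
    "PbTxSpecies",
    "Regimen",
    "PatientParameters",
    "ModelState",
    "Trajectory",
    "ConfigurationError",
    "IntegrationError",
    "DEFAULT_PARAMS",
    "PARAM_NAMES",
    "STATE_NAMES",
    "unmasked_fraction",
    "tumor_diameter",
    "cells_from_diameter",
    "derivatives",
    "simulate",
    "initial_state",
]

N_AVOGADRO = 6.02214076e23


class ConfigurationError(ValueError):
    """Raised for invalid or incomplete model configuration."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class CompartmentId(str, enum.Enum):
    TUMOR = "tumor"
    TDLN = "tdln"
    CENTRAL = "central"
    PERIPHERAL = "peripheral"


class PbTxSpecies(str, enum.Enum):
    """Antibody mask states.

    The two masks are lumped by binding competence: MASKED has both masks
    closed, OPEN has at least one mask transiently open, CLEAVED has at
    least one linker irreversibly cut.  Binding-competent states (OPEN,
    CLEAVED) have PD-L1-bound counterparts.  Cleaving is irreversible.
    """

    MASKED = "masked"
    OPEN = "open"
    CLEAVED = "cleaved"
    BOUND_OPEN = "bound_open"
    BOUND_CLEAVED = "bound_cleaved"


BINDING_COMPETENT = frozenset(
    {PbTxSpecies.OPEN, PbTxSpecies.CLEAVED,
     PbTxSpecies.BOUND_OPEN, PbTxSpecies.BOUND_CLEAVED}
)


@dataclass(frozen=True)
class Regimen:
    """Dosing regimen: bolus `dose_mg_per_kg` every `interval_days` for
    `duration_days`; arm selects the masked molecule or its unmasked parent."""

    dose_mg_per_kg: float = 10.0
    interval_days: float = 14.0
    duration_days: float = 400.0
    arm: str = "masked"

    def __post_init__(self):
        if self.dose_mg_per_kg < 0:
            raise ConfigurationError("dose_mg_per_kg must be >= 0")
        if self.interval_days <= 0:
            raise ConfigurationError("interval_days must be > 0")
        if self.duration_days < 0:
            raise ConfigurationError("duration_days must be >= 0")
        if self.arm not in ("masked", "unmasked"):
            raise ConfigurationError(f"unknown arm {self.arm!r}")

    def dose_times(self) -> np.ndarray:
        if self.dose_mg_per_kg == 0 or self.duration_days == 0:
            return np.empty(0)
        return np.arange(0.0, self.duration_days, self.interval_days)


# --------------------------------------------------------------------- params

#: Parameter order matching the index constants in :mod:`qspvct._ode`.
PARAM_NAMES: tuple[str, ...] = (
    "growth_rate",
    "init_diameter_cm",
    "kd_neoantigen",
    "tcc",
    "k_cleave",
    "mask_km",
    "k_exhaust",
    "k_kill",
    "k_clear_ab",
    "body_mass_kg",
    "cell_volume_ml",
    "packing_fraction",
    "c_max",
    "k_c_half",
    "kd_ab",
    "mw_ab",
    "pdl1_per_cell",
    "s_half",
    "eta_kill",
    "exh_base",
    "v_central_ml",
    "v_peripheral_ml",
    "v_tdln_ml",
    "q_peripheral",
    "q_tdln",
    "k_perm_tumor",
    "kd_ref_neoantigen",
    "k_tcc_half",
    "apc_pool",
    "k_apc_mat",
    "k_apc_mig",
    "d_apc_tumor",
    "d_apc_tdln",
    "k_prime_cd8",
    "k_prime_cd4",
    "k_prime_treg",
    "k_egress",
    "d_t_tdln",
    "d_t_central",
    "d_t_tumor",
    "k_infiltrate",
    "v_half_ml",
    "k_treg_half",
    "k_m2_half",
    "mac_pool",
    "k_m1_rec",
    "k_m2_rec",
    "k_mac_pol",
    "d_mac",
    "k_cyt_kill",
    "k_cyt_tumor",
    "d_cyt",
    "k_cyt_half",
    "sigma_peripheral",
)

assert len(PARAM_NAMES) == _ode.N_PARAM

#: Default parameterization.  Patient-level parameters (first ten) are
#: typically overridden by sampled values; the rest are physiology/config.
DEFAULT_PARAMS: dict[str, float] = {
    "growth_rate": 0.015,        # 1/day
    "init_diameter_cm": 3.0,     # cm, pre-treatment target diameter
    "kd_neoantigen": 3e-9,       # M
    "tcc": 93.0,                 # clones
    "k_cleave": 0.1,             # 1/day
    "mask_km": 0.01,             # dimensionless
    "k_exhaust": 0.08,           # 1/day
    "k_kill": 5.0,               # 1/day per effector cell (saturated contact)
    "k_clear_ab": 0.25,          # 1/day
    "body_mass_kg": 70.0,
    "cell_volume_ml": 2e-9,
    "packing_fraction": 0.6,
    "c_max": 3e11,
    "k_c_half": 5e9,
    "kd_ab": 1e-10,              # M
    "mw_ab": 1.5e5,              # g/mol
    "pdl1_per_cell": 5e4,
    "s_half": 0.2,
    "eta_kill": 0.97,
    "exh_base": 0.2,
    "v_central_ml": 5000.0,
    "v_peripheral_ml": 60000.0,
    "v_tdln_ml": 30.0,
    "q_peripheral": 2000.0,      # mL/day
    "q_tdln": 20.0,              # mL/day
    "k_perm_tumor": 0.25,        # 1/day
    "kd_ref_neoantigen": 3e-9,   # M
    "k_tcc_half": 150.0,
    "apc_pool": 1e7,
    "k_apc_mat": 0.1,
    "k_apc_mig": 0.5,
    "d_apc_tumor": 0.2,
    "d_apc_tdln": 0.3,
    "k_prime_cd8": 40.0,
    "k_prime_cd4": 40.0,
    "k_prime_treg": 8.0,
    "k_egress": 1.0,
    "d_t_tdln": 0.05,
    "d_t_central": 0.1,
    "d_t_tumor": 0.05,
    "k_infiltrate": 0.2,
    "v_half_ml": 5.0,
    "k_treg_half": 3e7,
    "k_m2_half": 2.5e8,
    "mac_pool": 1e9,
    "k_m1_rec": 0.02,
    "k_m2_rec": 0.01,
    "k_mac_pol": 0.02,
    "d_mac": 0.05,
    "k_cyt_kill": 1e-9,
    "k_cyt_tumor": 2.0,
    "d_cyt": 1.0,
    "k_cyt_half": 1.0,
    "sigma_peripheral": 0.02,
}

#: The parameters that vary across patients in the default distribution set.
PATIENT_LEVEL_PARAMS: tuple[str, ...] = PARAM_NAMES[:10]


class PatientParameters(Mapping):
    """A virtual patient's named parameter vector.

    Unspecified parameters fall back to :data:`DEFAULT_PARAMS` unless
    ``complete=True``, in which case every model parameter must be given.
    """

    def __init__(self, values: Mapping[str, float] | None = None, *,
                 complete: bool = False):
        values = dict(values or {})
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(
                f"unknown parameter(s): {sorted(unknown)}")
        if complete:
            missing = set(PARAM_NAMES) - set(values)
            if missing:
                raise ConfigurationError(
                    f"missing parameter(s): {sorted(missing)}")
            self._values = values
        else:
            self._values = {**DEFAULT_PARAMS, **values}
        self._validate()

    def _validate(self):
        v = self._values
        for name in PARAM_NAMES:
            if not math.isfinite(v[name]):
                raise ConfigurationError(f"parameter {name} is not finite")
        if v["tcc"] < 1:
            raise ConfigurationError("tcc must be >= 1")
        if v["mask_km"] < 0:
            raise ConfigurationError("mask_km must be >= 0")
        if v["init_diameter_cm"] <= 0:
            raise ConfigurationError("init_diameter_cm must be > 0")
        non_negative = set(PARAM_NAMES) - {"init_diameter_cm"}
        for name in non_negative:
            if v[name] < 0:
                raise ConfigurationError(f"parameter {name} must be >= 0")

    def __getitem__(self, key):
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def replace(self, **updates) -> "PatientParameters":
        return PatientParameters({**self._values, **updates})

    def to_vector(self) -> np.ndarray:
        return np.array([self._values[n] for n in PARAM_NAMES], dtype=float)

    def to_series(self) -> pd.Series:
        return pd.Series(self._values, name="value")


# --------------------------------------------------------------------- state

#: (name, compartment) for each raw state-vector entry, ordered as in _ode.
STATE_NAMES: tuple[tuple[str, CompartmentId], ...] = (
    ("cancer_cells", CompartmentId.TUMOR),
    ("cd8_teff", CompartmentId.TUMOR),
    ("cd4_th", CompartmentId.TUMOR),
    ("treg", CompartmentId.TUMOR),
    ("mapc", CompartmentId.TUMOR),
    ("m1_mac", CompartmentId.TUMOR),
    ("m2_mac", CompartmentId.TUMOR),
    ("cytokine", CompartmentId.TUMOR),
    ("mapc", CompartmentId.TDLN),
    ("cd8_teff", CompartmentId.TDLN),
    ("cd4_th", CompartmentId.TDLN),
    ("treg", CompartmentId.TDLN),
    ("cd8_teff", CompartmentId.CENTRAL),
    ("cd4_th", CompartmentId.CENTRAL),
    ("treg", CompartmentId.CENTRAL),
    ("ab_intact", CompartmentId.CENTRAL),
    ("ab_cleaved", CompartmentId.CENTRAL),
    ("ab_intact", CompartmentId.PERIPHERAL),
    ("ab_cleaved", CompartmentId.PERIPHERAL),
    ("ab_intact", CompartmentId.TDLN),
    ("ab_cleaved", CompartmentId.TDLN),
    ("ab_intact", CompartmentId.TUMOR),
    ("ab_cleaved", CompartmentId.TUMOR),
    ("ab_cleaved_cumulative", CompartmentId.TUMOR),
)

STATE_INDEX: dict[tuple[str, CompartmentId], int] = {
    key: i for i, key in enumerate(STATE_NAMES)
}

AB_INTACT_IDX = {
    CompartmentId.CENTRAL: _ode.I_AI_C,
    CompartmentId.PERIPHERAL: _ode.I_AI_P,
    CompartmentId.TDLN: _ode.I_AI_L,
    CompartmentId.TUMOR: _ode.I_AI_T,
}
AB_CLEAVED_IDX = {
    CompartmentId.CENTRAL: _ode.I_ACL_C,
    CompartmentId.PERIPHERAL: _ode.I_ACL_P,
    CompartmentId.TDLN: _ode.I_ACL_L,
    CompartmentId.TUMOR: _ode.I_ACL_T,
}


class ModelState:
    """Named view over the flat state vector (cell counts, cytokine a.u.,
    antibody amounts in mol)."""

    def __init__(self, y: np.ndarray | None = None):
        if y is None:
            y = np.zeros(_ode.N_STATE)
        y = np.asarray(y, dtype=float)
        if y.shape != (_ode.N_STATE,):
            raise ConfigurationError(
                f"state vector must have length {_ode.N_STATE}")
        self.y = y

    def __getitem__(self, key: tuple[str, CompartmentId]) -> float:
        return float(self.y[STATE_INDEX[key]])

    def __setitem__(self, key: tuple[str, CompartmentId], value: float):
        self.y[STATE_INDEX[key]] = value

    @property
    def cancer_cells(self) -> float:
        return float(self.y[_ode.I_C])

    def copy(self) -> "ModelState":
        return ModelState(self.y.copy())

    def to_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(
            [(c.value, n) for n, c in STATE_NAMES],
            names=["compartment", "species"])
        return pd.Series(self.y, index=idx)

    def is_nonnegative(self, tol: float = 1e-9) -> bool:
        return bool(np.all(self.y >= -tol))


def initial_state(inoculum_cells: float = 100.0) -> ModelState:
    """Pre-growth initial condition: an inoculum of cancer cells, everything
    else zero (immune populations develop as the tumor grows)."""
    s = ModelState()
    s.y[_ode.I_C] = inoculum_cells
    return s


# ------------------------------------------------------------------ geometry

def tumor_diameter(cancer_cells: float, params: PatientParameters | None = None
                   ) -> float:
    """Diameter (cm) of the sphere holding `cancer_cells` at the configured
    per-cell volume and packing density."""
    if cancer_cells < 0:
        raise ConfigurationError("cancer cell count must be >= 0")
    p = params or _DEFAULT_PP
    v_ml = cancer_cells * p["cell_volume_ml"] / p["packing_fraction"]
    return (6.0 * v_ml / math.pi) ** (1.0 / 3.0)


def cells_from_diameter(diameter_cm: float,
                        params: PatientParameters | None = None) -> float:
    """Inverse of :func:`tumor_diameter`."""
    if diameter_cm < 0:
        raise ConfigurationError("diameter must be >= 0")
    p = params or _DEFAULT_PP
    v_ml = math.pi / 6.0 * diameter_cm ** 3
    return v_ml * p["packing_fraction"] / p["cell_volume_ml"]


# ---------------------------------------------------------------- mask states

def unmasked_fraction(mask_km: float, n_masks: int = 2) -> float:
    """Equilibrium fraction of intact antibody with >= 1 active site exposed.

    Each of the ``n_masks`` masks is an independent two-state (closed/open)
    unit with equilibrium constant ``mask_km = k_open / k_close``, so the
    probability that all masks are closed is ``(1 + K_M)**-n`` and the
    binding-competent fraction is its complement.  Strictly increasing in
    K_M, 0 at K_M = 0, -> 1 as K_M -> inf.
    """
    if mask_km < 0:
        raise ConfigurationError("mask_km must be >= 0")
    if not math.isfinite(mask_km):
        return 1.0
    return -math.expm1(-n_masks * math.log1p(mask_km))


def _effective_fopen(params: PatientParameters, regimen: Regimen) -> float:
    if regimen.arm == "unmasked":
        return 1.0
    return unmasked_fraction(params["mask_km"])


# -------------------------------------------------------------------- solver

def default_atol() -> np.ndarray:
    """Per-state absolute tolerances: cell counts, cytokine a.u. and molar
    antibody amounts live on very different scales."""
    atol = np.full(_ode.N_STATE, 1e-3)
    atol[_ode.I_CY] = 1e-9
    atol[_ode.I_AI_C:_ode.I_CLV + 1] = 1e-18
    return atol


def derivatives(state: ModelState, t: float, params: PatientParameters,
                regimen: Regimen) -> ModelState:
    """Time derivative of every species (same layout as the state)."""
    if not state.is_nonnegative():
        raise IntegrationError("negative state entry", last_valid_time=t)
    p = params.to_vector()
    dy = np.empty(_ode.N_STATE)
    _ode.rhs(t, state.y, p, _effective_fopen(params, regimen), dy)
    return ModelState(dy)


class Trajectory:
    """Time grid + raw states + derived series for one simulation."""

    def __init__(self, times: np.ndarray, states: np.ndarray,
                 params: PatientParameters, fopen: float,
                 dose_times: np.ndarray | None = None,
                 total_dose_mol: float = 0.0):
        times = np.asarray(times, dtype=float)
        states = np.asarray(states, dtype=float)
        if times.ndim != 1 or states.shape != (times.size, _ode.N_STATE):
            raise ConfigurationError("times/states shape mismatch")
        if np.any(np.diff(times) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        self.times = times
        self.states = states
        self.params = params
        self.fopen = fopen
        self.dose_times = np.empty(0) if dose_times is None else dose_times
        self.total_dose_mol = total_dose_mol

    def __len__(self):
        return self.times.size

    def state_at(self, i: int) -> ModelState:
        return ModelState(self.states[i].copy())

    @property
    def cancer_cells(self) -> np.ndarray:
        return self.states[:, _ode.I_C]

    @property
    def diameter_cm(self) -> np.ndarray:
        p = self.params
        v = self.cancer_cells * p["cell_volume_ml"] / p["packing_fraction"]
        return (6.0 * v / math.pi) ** (1.0 / 3.0)

    @property
    def tumor_volume_ml(self) -> np.ndarray:
        p = self.params
        return np.maximum(
            self.cancer_cells * p["cell_volume_ml"] / p["packing_fraction"],
            _ode._V_T_FLOOR)

    def active_antibody_mol(self, compartment: CompartmentId) -> np.ndarray:
        """Amount (mol) of binding-competent ('active') antibody: the open
        fraction of the intact pool plus everything cleaved."""
        ai = self.states[:, AB_INTACT_IDX[compartment]]
        acl = self.states[:, AB_CLEAVED_IDX[compartment]]
        return self.fopen * ai + acl

    def total_antibody_mol(self) -> np.ndarray:
        """Total free antibody summed over compartments and mask states."""
        cols = [*AB_INTACT_IDX.values(), *AB_CLEAVED_IDX.values()]
        return self.states[:, cols].sum(axis=1)

    @property
    def cumulative_cleaved_mol(self) -> np.ndarray:
        return self.states[:, _ode.I_CLV]

    def mask_species_mol(self, compartment: CompartmentId
                         ) -> dict[PbTxSpecies, np.ndarray]:
        """Free antibody split into the lumped mask states (mol)."""
        ai = self.states[:, AB_INTACT_IDX[compartment]]
        acl = self.states[:, AB_CLEAVED_IDX[compartment]]
        return {
            PbTxSpecies.MASKED: (1.0 - self.fopen) * ai,
            PbTxSpecies.OPEN: self.fopen * ai,
            PbTxSpecies.CLEAVED: acl,
        }

    def pdl1_occupancy(self) -> np.ndarray:
        """Out-of-synapse PD-L1 occupancy by active antibody in the tumor
        (quasi-static mass-action with the antibody Kd)."""
        a_act = 1000.0 * self.active_antibody_mol(CompartmentId.TUMOR) \
            / self.tumor_volume_ml
        return a_act / (a_act + self.params["kd_ab"])

    def pdl1_out_of_synapse_mol(self) -> dict[str, np.ndarray]:
        """Free and antibody-bound out-of-synapse PD-L1 (mol), with the bound
        pool split between open- and cleaved-antibody complexes."""
        l_tot = self.params["pdl1_per_cell"] * self.cancer_cells / N_AVOGADRO
        occ = self.pdl1_occupancy()
        ai = self.fopen * self.states[:, _ode.I_AI_T]
        acl = self.states[:, _ode.I_ACL_T]
        act = ai + acl
        w_open = np.divide(ai, act, out=np.zeros_like(ai), where=act > 0)
        bound = occ * l_tot
        return {
            "free": (1.0 - occ) * l_tot,
            PbTxSpecies.BOUND_OPEN.value: bound * w_open,
            PbTxSpecies.BOUND_CLEAVED.value: bound * (1.0 - w_open),
        }

    def pd1_engagement(self) -> np.ndarray:
        """Synapse PD-1 engagement by unblocked PD-L1 (the checkpoint
        inhibition signal), in [0, 1]."""
        l_un = 1.0 - self.pdl1_occupancy()
        return l_un / (l_un + self.params["s_half"])

    #: fixed relative synapse ligand engagements for the species that do not
    #: feed back into the reduced dynamics (competitive quasi-static values
    #: for a nominal synapse composition)
    _STATIC_SYNAPSE = {
        "pd_l2": 0.15, "ctla4": 0.35, "cd28": 0.55, "tcr": 0.6,
        "mhc": 0.6, "cd80": 0.4,
    }

    def synapse_occupancies(self) -> dict[str, np.ndarray]:
        """Quasi-static synapse ligand occupancies, each in [0, 1].

        PD-L1 (antibody occupancy) and PD-1 (engagement by unblocked PD-L1)
        are dynamic; the remaining ligands are held at fixed competitive
        equilibrium values in this reduced model.
        """
        n = self.times.size
        out = {"pd_l1": self.pdl1_occupancy(),
               "pd_1": self.pd1_engagement()}
        for name, v in self._STATIC_SYNAPSE.items():
            out[name] = np.full(n, v)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: time, compartment, species, value."""
        records = []
        for j, (name, comp) in enumerate(STATE_NAMES):
            records.append(pd.DataFrame({
                "time": self.times, "compartment": comp.value,
                "species": name, "value": self.states[:, j]}))
        records.append(pd.DataFrame({
            "time": self.times, "compartment": CompartmentId.TUMOR.value,
            "species": "diameter_cm", "value": self.diameter_cm}))
        return pd.concat(records, ignore_index=True)

    def summary(self) -> dict:
        return {
            "t_start": float(self.times[0]),
            "t_end": float(self.times[-1]),
            "n_points": int(self.times.size),
            "initial_diameter_cm": float(self.diameter_cm[0]),
            "final_diameter_cm": float(self.diameter_cm[-1]),
            "total_dose_mol": float(self.total_dose_mol),
        }


def _build_grid(t_span: float, grid_dt: float,
                dose_times: np.ndarray) -> np.ndarray:
    grid = np.arange(0.0, t_span + 0.5 * grid_dt, grid_dt)
    if grid[-1] < t_span:
        grid = np.append(grid, t_span)
    grid = np.union1d(grid, dose_times[dose_times <= t_span])
    return grid


def simulate(params: PatientParameters, init: ModelState, t_span: float,
             regimen: Regimen | None = None, *, grid_dt: float = 1.0,
             rtol: float = 1e-8, atol: np.ndarray | None = None,
             max_step: float = 5.0,
             stop_above_diameter_cm: float | None = None) -> Trajectory:
    """Integrate the model over ``[0, t_span]`` with bolus dosing events.

    At each dose time the central-compartment antibody amount jumps by
    ``dose * body_mass / MW`` (mol); the unmasked arm injects the same
    molecule with binding-competent fraction 1.  Output lands on a fixed
    grid of ``grid_dt`` days, with dose times inserted as grid points.
    If ``stop_above_diameter_cm`` is set, integration stops at the first
    grid time where the tumor diameter reaches it.
    """
    if t_span <= 0:
        raise ConfigurationError("t_span must be > 0")
    if not init.is_nonnegative():
        raise IntegrationError("negative entry in initial state", 0.0)
    regimen = regimen or Regimen(dose_mg_per_kg=0.0)
    p = params.to_vector()
    fopen = _effective_fopen(params, regimen)
    atol = default_atol() if atol is None else np.asarray(atol, dtype=float)

    dose_times = regimen.dose_times()
    dose_mol = (regimen.dose_mg_per_kg * params["body_mass_kg"] / 1000.0
                / params["mw_ab"])
    grid = _build_grid(t_span, grid_dt, dose_times)

    stop_cells = -1.0
    if stop_above_diameter_cm is not None:
        stop_cells = cells_from_diameter(stop_above_diameter_cm, params)

    # segment boundaries at dose times (state jumps there)
    boundaries = [0.0, *[t for t in dose_times if 0.0 < t < t_span], t_span]
    boundaries = np.unique(boundaries)

    y = init.y.copy()
    out_rows = [grid[:1].copy()]
    out_states = [y[None, :].copy()]
    stopped = False
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if stopped:
            break
        if np.any(np.isclose(dose_times, a)):
            y[_ode.I_AI_C] += dose_mol
            out_states[-1][-1] = y  # reflect the bolus at its grid point
        seg_mask = (grid >= a - 1e-9) & (grid <= b + 1e-9)
        seg = grid[seg_mask]
        out = np.empty((seg.size, _ode.N_STATE))
        n_done = _ode.integrate_grid(y, seg, p, fopen, rtol, atol,
                                     max_step, stop_cells, out)
        if n_done < 0:
            raise IntegrationError(
                "solver failed to converge", last_valid_time=float(seg[-n_done - 1]))
        y = out[n_done - 1].copy()
        if n_done < seg.size:
            stopped = True
        out_rows.append(seg[1:n_done])
        out_states.append(out[1:n_done])

    times = np.concatenate(out_rows)
    states = np.concatenate(out_states, axis=0)
    total_dose = dose_mol * np.sum(dose_times <= times[-1])
    return Trajectory(times, states, params, fopen,
                      dose_times=dose_times, total_dose_mol=total_dose)


_DEFAULT_PP = PatientParameters()
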