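"""Core ODE model: geometry, mask equilibrium, dynamics oracles, dosing."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from qspvct import model_core as mc
from qspvct import _ode


# ------------------------------------------------------------------ geometry

def test_tumor_diameter_zero_cells_is_zero():
    assert mc.tumor_diameter(0.0) == 0.0


def test_tumor_diameter_doubling_scales_cube_root(default_params):
    d1 = mc.tumor_diameter(1e9, default_params)
    d2 = mc.tumor_diameter(2e9, default_params)
    assert d2 == pytest.approx(d1 * 2 ** (1 / 3), rel=1e-12)


@pytest.mark.parametrize("diameter", [0.01, 0.5, 3.0, 12.0])
def test_diameter_cells_round_trip(diameter, default_params):
    cells = mc.cells_from_diameter(diameter, default_params)
    assert mc.tumor_diameter(cells, default_params) == pytest.approx(
        diameter, rel=1e-12)


def test_negative_cell_count_rejected():
    with pytest.raises(mc.ConfigurationError):
        mc.tumor_diameter(-1.0)


# ------------------------------------------------------------ mask equilibrium

def _mask_open_fraction_oracle(km: float) -> float:
    """Brute-force steady state of the full per-mask kinetics.

    Two independent masks, each opening at rate k_o and closing at k_c with
    km = k_o / k_c; states counted by number of open masks (0, 1, 2); the
    binding-competent fraction is P(>= 1 open)."""
    k_o, k_c = km, 1.0
    A = np.array([
        [-2 * k_o, k_c, 0.0],
        [2 * k_o, -(k_c + k_o), 2 * k_c],
        [0.0, k_o, -2 * k_c],
    ])
    sol = solve_ivp(lambda t, y: A @ y, (0, 2000.0), [1.0, 0.0, 0.0],
                    rtol=1e-12, atol=1e-14)
    p = sol.y[:, -1]
    return float(p[1] + p[2])


def test_unmasked_fraction_limits():
    assert mc.unmasked_fraction(0.0) == 0.0
    assert mc.unmasked_fraction(1e12) == pytest.approx(1.0, abs=1e-12)
    assert mc.unmasked_fraction(math.inf) == 1.0


def test_unmasked_fraction_strictly_increasing():
    km = np.logspace(-4, 3, 30)
    f = np.array([mc.unmasked_fraction(k) for k in km])
    assert np.all(np.diff(f) > 0)
    assert np.all((f >= 0) & (f <= 1))


def test_unmasked_fraction_matches_mask_kinetics_steady_state():
    # regression value at K_M = 1 from the brute-force equilibrium solve
    oracle = _mask_open_fraction_oracle(1.0)
    assert oracle == pytest.approx(0.75, abs=1e-9)
    assert mc.unmasked_fraction(1.0) == pytest.approx(oracle, abs=1e-9)
    for km in (0.05, 0.3, 4.0):
        assert mc.unmasked_fraction(km) == pytest.approx(
            _mask_open_fraction_oracle(km), abs=1e-8)


def test_unmasked_fraction_negative_km_rejected():
    with pytest.raises(mc.ConfigurationError):
        mc.unmasked_fraction(-0.1)


# ----------------------------------------------------------------- parameters

def test_missing_parameter_is_named():
    with pytest.raises(mc.ConfigurationError, match="growth_rate"):
        mc.PatientParameters({"tcc": 50.0}, complete=True)


def test_unknown_parameter_rejected():
    with pytest.raises(mc.ConfigurationError, match="no_such_rate"):
        mc.PatientParameters({"no_such_rate": 1.0})


@pytest.mark.parametrize("bad", [{"tcc": 0.5}, {"init_diameter_cm": 0.0},
                                 {"growth_rate": -0.1}])
def test_invalid_parameter_values_rejected(bad):
    with pytest.raises(mc.ConfigurationError):
        mc.PatientParameters(bad)


# ---------------------------------------------------------------- derivatives

def test_empty_system_is_absorbing(default_params):
    state = mc.ModelState()  # all zeros
    dy = mc.derivatives(state, 0.0, default_params, mc.Regimen())
    assert np.all(dy.y == 0.0)


def test_loss_only_dynamics_has_nonpositive_cancer_derivative(one_params):
    params = one_params.replace(growth_rate=0.0)
    state = mc.initial_state(1e9)
    state[("cd8_teff", mc.CompartmentId.TUMOR)] = 1e7
    dy = mc.derivatives(state, 0.0, params, mc.Regimen(dose_mg_per_kg=0.0))
    assert dy.y[_ode.I_C] <= 0.0


def test_negative_state_raises_integration_error(default_params):
    state = mc.ModelState()
    state.y[_ode.I_C] = -1.0
    with pytest.raises(mc.IntegrationError):
        mc.derivatives(state, 0.0, default_params, mc.Regimen())


def test_checkpoint_blockade_relieves_inhibition_monotonically(
        default_params):
    """More bound antibody in the tumor -> less negative CD8 balance."""
    base = mc.initial_state(5e9)
    base[("cd8_teff", mc.CompartmentId.TUMOR)] = 1e7
    regimen = mc.Regimen(arm="masked")
    derivs = []
    for ab in [0.0, 1e-12, 1e-10, 1e-8]:
        s = base.copy()
        s[("ab_cleaved", mc.CompartmentId.TUMOR)] = ab
        dy = mc.derivatives(s, 0.0, default_params, regimen)
        derivs.append(dy.y[_ode.I_TE_T])
    assert np.all(np.diff(derivs) > 0)  # exhaustion decreases with blockade


# ------------------------------------------------------------ dynamics oracles

def test_logistic_growth_matches_closed_form(immune_off_params):
    p = immune_off_params
    c0, g, k = 1e6, p["growth_rate"], p["c_max"]
    traj = mc.simulate(p, mc.initial_state(c0), 2000.0,
                       mc.Regimen(dose_mg_per_kg=0.0), grid_dt=20.0,
                       rtol=1e-10)
    t = traj.times
    expected = k * c0 * np.exp(g * t) / (k + c0 * (np.exp(g * t) - 1.0))
    np.testing.assert_allclose(traj.cancer_cells, expected, rtol=1e-6)


def test_single_bolus_exponential_decay(default_params):
    """With transport off, central antibody follows A0 exp(-k t)."""
    k = 0.31
    p = default_params.replace(q_peripheral=0.0, q_tdln=0.0,
                               k_perm_tumor=0.0, k_clear_ab=k)
    regimen = mc.Regimen(dose_mg_per_kg=10.0, interval_days=500.0,
                         duration_days=400.0, arm="masked")
    traj = mc.simulate(p, mc.ModelState(), 40.0, regimen, rtol=1e-10)
    a0 = regimen.dose_mg_per_kg * p["body_mass_kg"] / 1000.0 / p["mw_ab"]
    expected = a0 * np.exp(-k * traj.times)
    ai_c = traj.states[:, _ode.I_AI_C]
    np.testing.assert_allclose(ai_c, expected, rtol=1e-6)


def test_zero_dose_equals_dose_free_simulation(one_params):
    init = mc.initial_state(1e8)
    t1 = mc.simulate(one_params, init, 50.0,
                     mc.Regimen(dose_mg_per_kg=0.0))
    t2 = mc.simulate(one_params, init, 50.0, None)
    np.testing.assert_array_equal(t1.states, t2.states)


def test_invalid_t_span_rejected(default_params):
    with pytest.raises(mc.ConfigurationError):
        mc.simulate(default_params, mc.ModelState(), 0.0, mc.Regimen())


# --------------------------------------------------- conservation and cleavage

def _closed_config(params):
    return params.replace(k_clear_ab=0.0, k_cleave=0.0)


def test_antibody_mass_conserved_in_closed_configuration(one_params):
    p = _closed_config(one_params)
    init = mc.initial_state(mc.cells_from_diameter(3.0, p))
    regimen = mc.Regimen(dose_mg_per_kg=10.0, interval_days=14.0,
                         duration_days=400.0, arm="masked")
    traj = mc.simulate(p, init, 63.0, regimen, rtol=1e-10)
    dose_mol = (regimen.dose_mg_per_kg * p["body_mass_kg"] / 1000.0
                / p["mw_ab"])
    total = traj.total_antibody_mol()
    n_doses = np.searchsorted(regimen.dose_times(), traj.times,
                              side="right")
    expected = n_doses * dose_mol
    ok = expected > 0
    np.testing.assert_allclose(total[ok], expected[ok], rtol=1e-8)


def test_cumulative_cleaved_is_nondecreasing(small_cohort):
    for pt in small_cohort[0][:10]:
        traj = mc.simulate(pt.params, pt.pretreatment_state, 60.0,
                           mc.Regimen(arm="masked"))
        cum = traj.cumulative_cleaved_mol
        assert np.all(np.diff(cum) >= -1e-15)


def test_cleaved_exposure_monotone_in_cleavage_rate(one_params):
    """Tumor AUC of the cleaved species does not decrease with k_cvg."""
    aucs = []
    for k_cvg in [0.01, 0.03, 0.1, 0.3, 1.0]:
        p = one_params.replace(k_cleave=k_cvg)
        init = mc.initial_state(mc.cells_from_diameter(3.0, p))
        traj = mc.simulate(p, init, 60.0, mc.Regimen(arm="masked"))
        cleaved = traj.states[:, _ode.I_ACL_T]
        aucs.append(np.trapezoid(cleaved, traj.times))
    assert np.all(np.diff(aucs) >= 0)


def test_final_size_insensitive_to_cleavage_at_high_dose(one_params):
    """The spread of the final diameter across the k_cvg range shrinks as
    the dose grows (the reversible open fraction already saturates PD-L1)."""
    spreads = []
    init = mc.initial_state(mc.cells_from_diameter(3.0, one_params))
    for dose in [1.0, 3.0, 10.0]:
        finals = []
        for k_cvg in [0.01, 0.1, 1.0]:
            p = one_params.replace(k_cleave=k_cvg)
            traj = mc.simulate(p, init, 100.0,
                               mc.Regimen(dose_mg_per_kg=dose, arm="masked"))
            finals.append(traj.diameter_cm[-1])
        spreads.append(max(finals) - min(finals))
    assert spreads[-1] == min(spreads)
    assert np.all(np.diff(spreads) <= 0)


# ----------------------------------------------------------------- trajectory

def test_states_stay_nonnegative_under_treatment(small_cohort):
    for pt in small_cohort[0][:5]:
        traj = mc.simulate(pt.params, pt.pretreatment_state, 100.0,
                           mc.Regimen(arm="masked"))
        assert traj.states.min() >= -1e-9


def test_dose_times_are_grid_points(one_params):
    regimen = mc.Regimen(interval_days=14.0, duration_days=400.0)
    init = mc.initial_state(1e9)
    traj = mc.simulate(one_params, init, 60.0, regimen)
    for t in [0.0, 14.0, 28.0, 42.0, 56.0]:
        assert np.any(np.isclose(traj.times, t))


def test_mask_species_partition_and_occupancy_bounds(one_params):
    init = mc.initial_state(1e9)
    traj = mc.simulate(one_params, init, 60.0, mc.Regimen(arm="masked"))
    species = traj.mask_species_mol(mc.CompartmentId.TUMOR)
    total = (species[mc.PbTxSpecies.MASKED] + species[mc.PbTxSpecies.OPEN]
             + species[mc.PbTxSpecies.CLEAVED])
    free = (traj.states[:, _ode.I_AI_T] + traj.states[:, _ode.I_ACL_T])
    np.testing.assert_allclose(total, free, rtol=1e-12, atol=1e-30)
    occ = traj.pdl1_occupancy()
    assert np.all((occ >= 0) & (occ <= 1))
    for series in traj.synapse_occupancies().values():
        assert np.all((series >= 0) & (series <= 1))


def test_trajectory_export_long_format(one_params):
    traj = mc.simulate(one_params, mc.initial_state(1e9), 10.0,
                       mc.Regimen(dose_mg_per_kg=0.0))
    df = traj.to_frame()
    assert set(df.columns) == {"time", "compartment", "species", "value"}
    assert set(df["compartment"].unique()) <= {c.value
                                               for c in mc.CompartmentId}
    assert "diameter_cm" in set(df["species"])
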