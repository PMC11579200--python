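"""Clamped immune ratios, density estimation and inclusion selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qspvct import synthetic_data as sd
from qspvct import vp_selection as vs
from qspvct.model_core import ConfigurationError


# --------------------------------------------------------------- ratio clamp

def test_equal_macrophages_give_half():
    r = vs.compute_ratios(5.0, 5.0, 1.0, 1.0, 1.0, vs.RatioConfig(0.01))
    assert r.x1 == 0.5


def test_upper_clamp_applies():
    # M1/(M1+M2) = 0.999 with eps = 0.01 clamps to 0.99
    r = vs.compute_ratios(999.0, 1.0, 1.0, 1.0, 1.0, vs.RatioConfig(0.01))
    assert r.x1 == pytest.approx(0.99)


def test_lower_clamp_applies_at_zero_numerator():
    # CD4 = 0, CD8 > 0 with eps = 0.05 gives x3 = 0.05
    r = vs.compute_ratios(1.0, 1.0, 1.0, 2.0, 0.0, vs.RatioConfig(0.05))
    assert r.x3 == pytest.approx(0.05)


def test_negative_density_rejected():
    with pytest.raises(ConfigurationError):
        vs.compute_ratios(-1.0, 1.0, 1.0, 1.0, 1.0)


def test_invalid_eps_rejected():
    for eps in (0.0, 0.5, 0.7):
        with pytest.raises(ConfigurationError):
            vs.RatioConfig(eps)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1e12), min_size=5,
                max_size=5),
       st.floats(min_value=1e-4, max_value=0.49))
def test_clamp_invariant_over_random_densities(dens, eps):
    """Every ratio lies in [eps, 1 - eps], zeros and 0/0 included."""
    r = vs.compute_ratios(*dens, vs.RatioConfig(eps))
    for x in r.as_array():
        assert eps <= x <= 1.0 - eps


# ------------------------------------------------------------ eps diagnostic

def test_diagnostic_zero_when_clamp_inactive():
    samples = np.array([0.3, 0.4, 0.5])
    err = vs.epsilon_diagnostic(samples, np.array([0.01, 0.1]))
    np.testing.assert_array_equal(err, [0.0, 0.0])


def test_diagnostic_dips_to_zero_at_the_median():
    rng = np.random.default_rng(0)
    samples = rng.beta(0.8, 6.0, size=2001)
    med = np.median(samples)
    grid = np.array([med * 0.5, med, med * 1.5])
    err = vs.epsilon_diagnostic(samples, grid)
    assert err[0] == 0.0
    assert err[1] == pytest.approx(0.0, abs=1e-12)
    assert err[2] > 0.0  # above the median the clamp moves the median up


def test_diagnostic_symmetric_sample_enumeration():
    err = vs.epsilon_diagnostic(np.array([0.2, 0.5, 0.8]), np.array([0.3]))
    assert err[0] == 0.0  # clamped {0.3, 0.5, 0.7} keeps the median


def test_diagnostic_zero_median_undefined():
    err = vs.epsilon_diagnostic(np.array([0.0, 0.0, 0.9]), np.array([0.1]))
    assert np.isnan(err[0])


def test_diagnostic_empty_rejected():
    with pytest.raises(ConfigurationError):
        vs.epsilon_diagnostic(np.array([]), np.array([0.1]))


# ------------------------------------------------------------------ densities

def _ratio_array(x, n):
    out = np.full((n, 3), 0.5)
    out[:, 0] = x
    return out


def test_density_atom_for_identical_samples():
    samples = _ratio_array(0.4, 50)
    f = vs.fit_density(samples, (0,))
    at_atom = f.evaluate(_ratio_array(0.4, 1))[0]
    away = f.evaluate(_ratio_array(0.6, 1))[0]
    assert at_atom > away


def test_density_recovers_uniform_level():
    rng = np.random.default_rng(5)
    samples = _ratio_array(rng.uniform(0.2, 0.8, 5000), 5000)
    f = vs.fit_density(samples, (0,))
    # histogram oracle: the uniform density on [0.2, 0.8] is 1/0.6
    val = f.evaluate_ratio_density(_ratio_array(0.5, 1))[0]
    assert val == pytest.approx(1.0 / 0.6, rel=0.25)


def test_density_dimension_matches_constraints():
    rng = np.random.default_rng(6)
    samples = np.column_stack([rng.uniform(0.2, 0.8, 100) for _ in range(3)])
    assert vs.fit_density(samples, (1,)).ndim == 1
    assert vs.fit_density(samples, (0, 2)).ndim == 2
    assert vs.fit_density(samples, (0, 1, 2), mode="joint").ndim == 3


def test_density_minimum_samples_enforced():
    with pytest.raises(ConfigurationError):
        vs.fit_density(_ratio_array(0.5, 10), (0,), min_samples=20)


# -------------------------------------------------------- inclusion and beta

def _identical_model(n=200, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    samples = _ratio_array(rng.uniform(0.3, 0.7, n), n)
    f_ref = vs.fit_density(samples, (0,))
    f_pla = vs.fit_density(samples, (0,))
    model = vs.InclusionModel(f_ref, f_pla, beta=beta)
    return model, samples


def test_probability_is_clipped_product_of_beta_and_ratio():
    model, samples = _identical_model(beta=1.0)
    np.testing.assert_allclose(vs.inclusion_probability(samples, model), 1.0)
    model.beta = 0.8  # identical densities: ratio == 1, so p == beta
    np.testing.assert_allclose(vs.inclusion_probability(samples, model), 0.8)
    model.beta = 0.0
    np.testing.assert_allclose(vs.inclusion_probability(samples, model), 0.0)


def test_uncalibrated_model_rejected():
    model, samples = _identical_model(beta=None)
    with pytest.raises(RuntimeError):
        vs.inclusion_probability(samples, model)


def test_calibration_accepts_nearly_all_when_already_matched():
    """Plausible cohort drawn from the reference law: beta drives the mean
    inclusion probability toward 1."""
    model, samples = _identical_model(n=500)
    beta = vs.calibrate_beta(model, samples, samples, seed=42)
    p = vs.inclusion_probability(samples, model)
    assert p.mean() > 0.9
    assert beta > 0


def test_calibration_deterministic_and_no_worse_than_start():
    rng = np.random.default_rng(7)
    pla = _ratio_array(rng.beta(3, 2, 800), 800)
    ref = _ratio_array(rng.beta(2, 3, 800), 800)
    model = vs.InclusionModel(vs.fit_density(ref, (0,)),
                              vs.fit_density(pla, (0,)))
    b1 = vs.calibrate_beta(model, pla, ref, seed=1)
    model2 = vs.InclusionModel(vs.fit_density(ref, (0,)),
                               vs.fit_density(pla, (0,)))
    b2 = vs.calibrate_beta(model2, pla, ref, seed=1)
    assert b1 == b2
    ratio = model.density_ratio(pla)
    final = vs.annealing_objective(np.log(b1), ratio, pla, ref, (0,), 5.0)
    start = vs.annealing_objective(np.log(0.5 / ratio.mean()), ratio, pla,
                                   ref, (0,), 5.0)
    assert final >= start - 1e-12


def test_overclipping_beta_increases_mismatch_penalty():
    """Doubling beta into heavy clipping raises the KS penalty term."""
    rng = np.random.default_rng(8)
    pla = _ratio_array(rng.beta(4, 2, 2000), 2000)
    ref = _ratio_array(rng.beta(2, 4, 2000), 2000)
    model = vs.InclusionModel(vs.fit_density(ref, (0,)),
                              vs.fit_density(pla, (0,)))
    ratio = model.density_ratio(pla)
    lb = float(np.log(1.0 / np.percentile(ratio, 95)))  # little clipping
    lb2 = lb + np.log(16.0)                             # >50% clipped

    def penalty(l):
        p = np.clip(np.exp(l) * ratio, 0, 1)
        return vs._weighted_ks(pla[:, 0], p, ref[:, 0])

    assert np.mean(np.clip(np.exp(lb2) * ratio, 0, 1) >= 1) > 0.5
    assert penalty(lb2) > penalty(lb)


def test_greedy_mode_never_accepts_worse_objective():
    """With temperature 0 the annealing walk is a hill-climb, so the final
    objective equals the best objective seen."""
    rng = np.random.default_rng(9)
    pla = _ratio_array(rng.beta(3, 2, 500), 500)
    ref = _ratio_array(rng.beta(2, 3, 500), 500)
    cfg = vs.AnnealingConfig(t0=0.0, n_iter=200)
    model = vs.InclusionModel(vs.fit_density(ref, (0,)),
                              vs.fit_density(pla, (0,)))
    beta = vs.calibrate_beta(model, pla, ref, seed=2, cfg=cfg)
    ratio = model.density_ratio(pla)
    obj = vs.annealing_objective(np.log(beta), ratio, pla, ref, (0,), cfg.lam)
    # probe: no nearby beta on the walk's scale does much better
    probes = [obj]
    for d in (-0.5, -0.1, 0.1, 0.5):
        probes.append(vs.annealing_objective(np.log(beta) + d, ratio, pla,
                                             ref, (0,), cfg.lam))
    assert obj >= max(probes) - 0.05


# ------------------------------------------------------------------ selection

def test_select_all_when_probability_one():
    model, samples = _identical_model(n=300, beta=5.0)  # p clipped to 1
    cohort, idx, rate = vs.select_vps(list(range(300)), samples, model,
                                      seed=0, n_proposed=600)
    assert len(cohort) == 300
    assert rate == pytest.approx(50.0)  # plausible / proposed


def test_select_none_when_probability_zero():
    model, samples = _identical_model(n=300, beta=0.0)
    cohort, idx, rate = vs.select_vps(list(range(300)), samples, model,
                                      seed=0)
    assert cohort == [] and rate == 0.0


def test_selection_fraction_matches_bernoulli_probability():
    model, samples = _identical_model(n=10000, beta=0.5)  # p = 0.5 each
    cohort, idx, rate = vs.select_vps(list(range(10000)), samples, model,
                                      seed=3)
    assert 0.48 <= len(cohort) / 10000 <= 0.52


def test_empty_plausible_set_gives_empty_cohort():
    model, samples = _identical_model(beta=1.0)
    cohort, idx, rate = vs.select_vps([], np.empty((0, 3)), model, seed=0)
    assert cohort == [] and rate == 0.0


# ------------------------------------------------------ acceptance rate table

def test_rate_table_rejects_empty_subset():
    model, samples = _identical_model()
    with pytest.raises(ConfigurationError):
        vs.acceptance_rate_table(list(range(200)), samples, samples, 200,
                                 seed=0, subsets=[()])


def test_rate_table_statistically_equal_for_identical_cohorts():
    rng = np.random.default_rng(12)
    a = np.column_stack([rng.beta(2, 3, 2000) * 0.9 + 0.05
                         for _ in range(3)])
    b = np.column_stack([rng.beta(2, 3, 2000) * 0.9 + 0.05
                         for _ in range(3)])
    table = vs.acceptance_rate_table(list(range(len(a))), a, b, len(a),
                                     seed=5)
    rates = table["acceptance_pct"].to_numpy()
    assert rates.max() - rates.min() < 25.0
    assert rates.min() > 50.0  # matched cohorts admit most patients


def test_rate_table_penalizes_the_shifted_ratio():
    """A reference shifted away on x2 only makes the x2 constraint the
    stringent one."""
    spec = sd.OmicsTableSpec(n=3000, seed=21)
    ref, pla, _ = sd.make_shifted_cohorts(spec, "x2", 1.0)
    rr = vs.ratios_from_table(ref)
    pr = vs.ratios_from_table(pla)
    table = vs.acceptance_rate_table(list(range(len(pr))), pr, rr, len(pr),
                                     seed=6, subsets=[(0,), (1,)])
    x1_rate = table.loc[table["constraints"] == "x1",
                        "acceptance_pct"].item()
    x2_rate = table.loc[table["constraints"] == "x2",
                        "acceptance_pct"].item()
    assert x2_rate < x1_rate


def test_ratios_from_table_requires_columns():
    with pytest.raises(ConfigurationError):
        vs.ratios_from_table(pd.DataFrame({"M1": [1.0]}))
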