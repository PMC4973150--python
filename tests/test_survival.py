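"""Expected trajectories, the Pohar-Perme estimator and ICSS standardisation."""

import math

import numpy as np
import pytest

from conftest import flat_life_table
from stageweaver.records_io import LifeTable
from stageweaver.survival import (ICSSWeights, NetSurvivalEstimate,
                                  SurvivalSubject, age_standardise,
                                  expected_trajectory, icss_weights,
                                  net_survival_by_stage, pohar_perme)


def subject(fu_days, event, age=60.0, sex="male", dep=3, year=2008,
            stage="I"):
    return SurvivalSubject(follow_up_days=fu_days, event=event, age=age,
                           sex=sex, deprivation_quintile=dep,
                           diagnosis_year=year, stage=stage)


# --------------------------------------------------------------------------
# expected-mortality trajectories
# --------------------------------------------------------------------------

def test_zero_life_table_gives_unit_expected_survival(zero_life_table):
    traj = expected_trajectory(subject(1000, False), zero_life_table)
    assert np.all(traj.expected_survival == 1.0)


def test_constant_hazard_matches_closed_form():
    h = 0.07
    lt = flat_life_table(h)
    traj = expected_trajectory(subject(int(3 * 365.25), False), lt)
    t_years = np.arange(1, len(traj.cumulative_hazard) + 1) / 365.25
    assert np.allclose(traj.expected_survival, np.exp(-h * t_years),
                       atol=1e-6)


def test_attained_age_and_year_are_capped():
    """A 98-year-old followed 3 years uses the age-99 (and last-year) rates
    beyond the grid edge instead of falling off it."""
    ages = np.arange(15, 100)
    grid = np.tile((ages / 1000.0)[:, None, None, None], (1, 2, 6, 5))
    lt = LifeTable(ages, np.arange(2008, 2014), grid)
    traj = expected_trajectory(subject(int(3 * 365.25), False, age=98,
                                       year=2013), lt)
    daily = traj.daily_hazard * 365.25
    assert daily[0] == pytest.approx(0.098)
    assert daily[-1] == pytest.approx(0.099)  # capped at age 99, year 2013


def test_subject_below_grid_is_an_error():
    lt = flat_life_table(0.01, ages=(50, 99))
    with pytest.raises(ValueError, match="below the life-table grid"):
        pohar_perme([subject(100, True, age=40)], lt, (1.0,))


# --------------------------------------------------------------------------
# Pohar-Perme
# --------------------------------------------------------------------------

def test_equals_kaplan_meier_when_expected_hazard_zero(zero_life_table):
    """With S_P ≡ 1 all weights are 1 and the estimator must be exactly the
    Kaplan-Meier product-limit (independent oracle: lifelines)."""
    from lifelines import KaplanMeierFitter
    rng = np.random.default_rng(42)
    fu = rng.integers(30, 1827, size=120)
    ev = rng.random(120) < 0.6
    cohort = [subject(int(f), bool(e)) for f, e in zip(fu, ev)]
    est = pohar_perme(cohort, zero_life_table, (0.5, 1, 2, 3, 4, 5))
    km = KaplanMeierFitter().fit(fu, ev)
    for t, ns in zip(est.times, est.survival):
        assert ns == pytest.approx(float(km.predict(round(t * 365.25))),
                                   abs=1e-12)


def test_single_death_drops_to_zero(zero_life_table):
    est = pohar_perme([subject(365, True)], zero_life_table, (0.5, 1.0, 2.0))
    assert est.survival[0] == 1.0
    assert est.survival[1] == 0.0


# the 10-subject toy cohort: constant expected hazard 0.05/yr, fixed times
TOY = [(183, True), (366, True), (366, True), (731, True), (1279, True),
       (548, False), (914, False), (1461, False), (1827, False),
       (1827, False)]
# frozen from the independent scalar-loop evaluation of the weighted sums
TOY_NS1, TOY_VAR1 = 0.9461227605113237, 0.008951482779575677
TOY_NS5, TOY_VAR5 = 0.561803804744577, 0.039443197911672216


def toy_oracle(time_days):
    """Spreadsheet-style re-evaluation: explicit per-day scalar sums."""
    h = 0.05 / 365.25
    ns, cum_var = 1.0, 0.0
    for day in range(1, time_days + 1):
        sum_wY = sum_w_dN = sum_w2_dN = sum_wY_dLP = 0.0
        w = math.exp(h * (day - 1))
        for fu, event in TOY:
            if fu >= day:
                sum_wY += w
                sum_wY_dLP += w * h
            if event and fu == day:
                sum_w_dN += w
                sum_w2_dN += w * w
        if sum_wY > 0:
            ns *= 1.0 - (sum_w_dN - sum_wY_dLP) / sum_wY
            cum_var += sum_w2_dN / sum_wY ** 2
    return ns, ns * ns * cum_var


def test_toy_cohort_matches_hand_oracle():
    lt = flat_life_table(0.05)
    cohort = [subject(fu, ev) for fu, ev in TOY]
    est = pohar_perme(cohort, lt, (1.0, 5.0))
    ns1, var1 = toy_oracle(round(1 * 365.25))
    ns5, var5 = toy_oracle(round(5 * 365.25))
    # the oracle itself reproduces its frozen values
    assert ns1 == pytest.approx(TOY_NS1, abs=1e-12)
    assert ns5 == pytest.approx(TOY_NS5, abs=1e-12)
    assert est.survival[0] == pytest.approx(TOY_NS1, abs=1e-10)
    assert est.survival[1] == pytest.approx(TOY_NS5, abs=1e-10)
    assert est.variance[0] == pytest.approx(TOY_VAR1, abs=1e-10)
    assert est.variance[1] == pytest.approx(TOY_VAR5, abs=1e-10)


def test_recovers_constant_excess_hazard():
    """Additive constant hazards: the mean NS(5) over replicates approaches
    exp(−5·λ_E) (reduced-scale check; the full run lives in acceptance)."""
    lam_e, lam_p, reps, n = 0.10, 0.05, 40, 1500
    lt = flat_life_table(lam_p)
    rng = np.random.default_rng(1234)
    values = []
    for _ in range(reps):
        te = rng.exponential(1 / lam_e, n)
        tp = rng.exponential(1 / lam_p, n)
        td = np.minimum(te, tp)
        fu = np.minimum(td, 5.01)
        ev = td <= 5.0
        cohort = [subject(int(np.ceil(f * 365.25)), bool(e))
                  for f, e in zip(fu, ev)]
        values.append(pohar_perme(cohort, lt, (5.0,)).survival[0])
    target = math.exp(-5 * lam_e)
    mc_err = np.std(values, ddof=1) / math.sqrt(reps)
    assert abs(np.mean(values) - target) < 4 * mc_err + 1e-4


def test_invariant_to_calendar_relabelling(zero_life_table):
    lt = flat_life_table(0.03)
    cohort_a = [subject(fu, ev, year=2008) for fu, ev in TOY]
    cohort_b = [subject(fu, ev, year=2011) for fu, ev in TOY]
    est_a = pohar_perme(cohort_a, lt, (1.0, 5.0))
    est_b = pohar_perme(cohort_b, lt, (1.0, 5.0))
    assert np.allclose(est_a.survival, est_b.survival)


def test_empty_risk_set_truncates_with_warning(zero_life_table):
    cohort = [subject(200, True), subject(300, False)]
    with pytest.warns(UserWarning, match="risk set empty"):
        est = pohar_perme(cohort, zero_life_table, (1.0, 5.0))
    assert est.survival[0] == est.survival[1]  # carried forward


def test_empty_cohort_is_an_error(zero_life_table):
    with pytest.raises(ValueError, match="empty cohort"):
        pohar_perme([], zero_life_table, (1.0,))


# --------------------------------------------------------------------------
# ICSS age standardisation
# --------------------------------------------------------------------------

def _estimate(ns_values, variance=0.0):
    times = np.array([1.0, 5.0])
    ns = np.asarray(ns_values, dtype=float)
    return NetSurvivalEstimate(times=times, survival=ns,
                               variance=np.full(2, variance),
                               n_at_risk=np.array([10, 5]))


def test_icss_weights_resource():
    w = icss_weights()
    assert w.bands == ((15, 44), (45, 54), (55, 64), (65, 74), (75, 99))
    assert w.weights == (0.07, 0.12, 0.23, 0.29, 0.29)
    assert w.band_of(44.9) == 0
    assert w.band_of(75) == 4


def test_identical_bands_pass_through():
    est = {g: _estimate([0.9, 0.7]) for g in range(5)}
    std = age_standardise(est)
    assert np.allclose(std.survival, [0.9, 0.7])


def test_single_band_renormalises():
    std = age_standardise({2: _estimate([0.8, 0.5])})
    assert np.allclose(std.survival, [0.8, 0.5])


def test_two_band_arithmetic():
    w = ICSSWeights(((15, 59), (60, 99)), (0.5, 0.5))
    std = age_standardise({0: _estimate([0.8, 0.8]),
                           1: _estimate([0.6, 0.6])}, w)
    assert np.allclose(std.survival, 0.7)
    var = age_standardise({0: _estimate([0.8, 0.8], variance=0.04),
                           1: _estimate([0.6, 0.6], variance=0.08)}, w)
    assert np.allclose(var.variance, 0.25 * 0.04 + 0.25 * 0.08)


def test_standardised_value_within_band_envelope(zero_life_table):
    rng = np.random.default_rng(77)
    cohort = [subject(int(f), bool(e), age=float(a), stage="II")
              for f, e, a in zip(rng.integers(30, 1827, 300),
                                 rng.random(300) < 0.5,
                                 rng.uniform(20, 95, 300))]
    weights = icss_weights()
    by_band: dict = {}
    for s in cohort:
        by_band.setdefault(weights.band_of(s.age), []).append(s)
    bands = {g: pohar_perme(m, zero_life_table, (1.0, 5.0))
             for g, m in by_band.items()}
    std = age_standardise(bands, weights)
    lo = np.min([b.survival for b in bands.values()], axis=0)
    hi = np.max([b.survival for b in bands.values()], axis=0)
    assert np.all(std.survival >= lo - 1e-12)
    assert np.all(std.survival <= hi + 1e-12)


def test_all_bands_empty_is_an_error():
    with pytest.raises(ValueError):
        age_standardise({})


def test_net_survival_by_stage_includes_missing(zero_life_table):
    cohort = ([subject(500, True, stage="IV")] * 30
              + [subject(1500, False, stage="missing")] * 30)
    out = net_survival_by_stage(cohort, zero_life_table, (1.0,),
                                standardise=False)
    assert set(out) == {"IV", "missing"}
    assert out["missing"].survival[0] == 1.0


def test_ci_floored_at_zero():
    est = _estimate([0.05, 0.01], variance=0.01)
    lo, hi = est.ci()
    assert np.all(lo >= 0.0)
    assert hi[0] > 0.05
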