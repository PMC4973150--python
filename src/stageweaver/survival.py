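"""Stage-specific net survival: Pohar-Perme estimation and ICSS weighting.

Net survival is survival in the hypothetical world where the cancer is the
only cause of death.  Without cause-of-death data it is estimated in the
relative-survival framework: each subject's expected (general-population)
mortality is taken from a life table indexed by age, sex, calendar year and
deprivation quintile, and the non-parametric Pohar-Perme estimator weights
every subject's contribution to the at-risk set and the event count by the
inverse of their expected survival, removing the informative-censoring bias
of older estimators.

In counting-process form, with weights w_i(t) = 1/S_{Pi}(t),

    dLambda_E(t) = [ sum_i w_i dN_i(t) − sum_i w_i Y_i(t) dLambda_{Pi}(t) ]
                   / sum_i w_i Y_i(t)

and net survival is the product-integral NS(t) = prod_{s<=t} (1 − dLambda_E(s)),
evaluated here on a daily grid.  The product-integral form makes the
estimator collapse *exactly* to Kaplan-Meier when the expected hazard is
zero; on no-event days the daily factor differs from exp(−dLambda_E) by
O((h/365)^2), far below the discretisation tolerance.  The variance of the
cumulative excess hazard is the weighted martingale estimator
sum_s sum_i w_i^2 dN_i(s) / (sum_i w_i Y_i(s))^2, carried to the NS scale by
the delta method.

Age standardisation uses the International Cancer Survival Standard (ICSS)
five age bands (15-44, 45-54, 55-64, 65-74, 75-99), with weights
renormalised over the bands actually contributing subjects.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from importlib import resources as _ilr

import numpy as np

from .records_io import SEXES, LifeTable

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SurvivalSubject:
    """One subject of a net-survival analysis, on the follow-up time scale."""

    follow_up_days: int  # exit − entry, whole days
    event: bool  # True = death, False = censored
    age: float  # age at diagnosis, years
    sex: str
    deprivation_quintile: int
    diagnosis_year: int
    stage: str = "missing"

    def __post_init__(self):
        if self.follow_up_days < 0:
            raise ValueError("negative follow-up")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")


@dataclass(frozen=True)
class NetSurvivalEstimate:
    """Net survival on a time grid (years since diagnosis)."""

    times: np.ndarray  # years
    survival: np.ndarray  # NS(t); may exceed 1 in noise
    variance: np.ndarray  # var(NS(t)), delta method
    n_at_risk: np.ndarray

    def __post_init__(self):
        if np.any(self.variance < 0):
            raise ValueError("negative variance")

    def ci(self, level: float = 0.95):
        """Normal-scale confidence band, floored at 0."""
        from statistics import NormalDist
        z = NormalDist().inv_cdf(0.5 + level / 2)
        half = z * np.sqrt(self.variance)
        return np.maximum(self.survival - half, 0.0), self.survival + half

    def at(self, time_years: float) -> float:
        idx = int(np.argmin(np.abs(self.times - time_years)))
        return float(self.survival[idx])


@dataclass(frozen=True)
class ICSSWeights:
    """Age-band weights; bands partition 15-99 and weights sum to 1."""

    bands: tuple  # ((lo, hi), ...) inclusive integer ages
    weights: tuple

    def __post_init__(self):
        if len(self.bands) != len(self.weights):
            raise ValueError("bands and weights differ in length")
        if any(w < 0 for w in self.weights):
            raise ValueError("negative weight")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def band_of(self, age: float) -> int:
        for i, (lo, hi) in enumerate(self.bands):
            if lo <= age < hi + 1:
                return i
        raise ValueError(f"age {age} outside the standard's bands")


def icss_weights() -> ICSSWeights:
    """The ICSS-1 standard weights shipped as a resource."""
    ref = _ilr.files("stageweaver.resources").joinpath("icss_weights.csv")
    bands, weights = [], []
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            bands.append((int(row["age_lo"]), int(row["age_hi"])))
            weights.append(float(row["weight"]))
    return ICSSWeights(tuple(bands), tuple(weights))


# --------------------------------------------------------------------------
# expected-mortality trajectories
# --------------------------------------------------------------------------

def _daily_hazard_matrix(subjects, lt: LifeTable, n_days: int) -> np.ndarray:
    """Daily expected hazard for each subject over ``n_days`` of follow-up.

    Attained age and calendar year advance during follow-up in whole years
    of 365.25 days, capped at the life-table maxima; the annual hazard is
    spread uniformly over the days of the attained year.
    """
    n = len(subjects)
    day_years = (np.arange(n_days) / DAYS_PER_YEAR).astype(int)  # 0,0,...,1,...
    ages = np.array([int(s.age) for s in subjects])
    years = np.array([s.diagnosis_year for s in subjects])
    sex_idx = np.array([SEXES.index(s.sex) for s in subjects])
    dep_idx = np.array([s.deprivation_quintile - 1 for s in subjects])

    age_lo, age_hi = lt.age_range
    year_lo, year_hi = lt.year_range
    if np.any(ages < age_lo) or np.any(years < year_lo):
        raise ValueError("subject below the life-table grid")
    attained_age = np.clip(ages[:, None] + day_years[None, :], None, age_hi)
    attained_year = np.clip(years[:, None] + day_years[None, :], None, year_hi)
    ai = attained_age - age_lo
    yi = attained_year - year_lo
    annual = lt.hazard[ai, sex_idx[:, None], yi, dep_idx[:, None]]
    assert annual.shape == (n, n_days)
    return annual / DAYS_PER_YEAR


@dataclass(frozen=True)
class ExpectedTrajectory:
    """One subject's expected cumulative hazard and survival, daily grid."""

    daily_hazard: np.ndarray
    cumulative_hazard: np.ndarray  # Lambda_P at the *end* of each day
    expected_survival: np.ndarray  # S_P at the end of each day; S_P(0)=1 implied


def expected_trajectory(subject: SurvivalSubject, lt: LifeTable,
                        n_days: int | None = None) -> ExpectedTrajectory:
    n_days = subject.follow_up_days if n_days is None else n_days
    h = _daily_hazard_matrix([subject], lt, n_days)[0]
    cum = np.cumsum(h)
    return ExpectedTrajectory(h, cum, np.exp(-cum))


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

def pohar_perme(subjects, lt: LifeTable,
                time_grid_years=(1.0, 5.0)) -> NetSurvivalEstimate:
    """Pohar-Perme net survival for one stratum.

    Estimation runs on a daily grid to the last requested time; if the
    weighted risk set empties earlier the estimate is carried forward from
    the truncation day with a warning.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("empty cohort")
    times = np.asarray(sorted(time_grid_years), dtype=float)
    n_days = int(np.ceil(times[-1] * DAYS_PER_YEAR))

    fu = np.array([s.follow_up_days for s in subjects])
    event = np.array([s.event for s in subjects], dtype=bool)

    h = _daily_hazard_matrix(subjects, lt, n_days)  # (n, D)
    cum_prev = np.concatenate(
        [np.zeros((len(subjects), 1)), np.cumsum(h, axis=1)[:, :-1]], axis=1)
    w = np.exp(cum_prev)  # w_i(day d) = 1/S_P at the start of day d

    days = np.arange(1, n_days + 1)  # day d covers (d-1, d]
    at_risk = fu[:, None] >= days[None, :]  # (n, D)
    wY = w * at_risk
    sum_wY = wY.sum(axis=0)
    n_risk = at_risk.sum(axis=0)

    # events on day d: subjects with fu == d and an event
    event_day = np.where(event, fu, -1)
    in_range = (event_day >= 1) & (event_day <= n_days)
    w_at_event = w[np.arange(len(subjects)),
                   np.clip(event_day - 1, 0, n_days - 1)]
    sum_w_dN = np.zeros(n_days)
    sum_w2_dN = np.zeros(n_days)
    np.add.at(sum_w_dN, event_day[in_range] - 1, w_at_event[in_range])
    np.add.at(sum_w2_dN, event_day[in_range] - 1, w_at_event[in_range] ** 2)

    sum_wY_dLP = (wY * h).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        d_excess = np.where(sum_wY > 0,
                            (sum_w_dN - sum_wY_dLP) / sum_wY, 0.0)
        d_var = np.where(sum_wY > 0, sum_w2_dN / sum_wY ** 2, 0.0)
    if np.any(sum_wY == 0) and np.argmax(sum_wY == 0) < n_days - 1:
        first_empty = int(np.argmax(sum_wY == 0)) + 1
        warnings.warn(f"risk set empty from day {first_empty}; net survival "
                      f"carried forward", stacklevel=2)

    ns_daily = np.cumprod(1.0 - d_excess)
    var_lambda = np.cumsum(d_var)
    var_daily = ns_daily ** 2 * var_lambda

    idx = np.clip(np.round(times * DAYS_PER_YEAR).astype(int), 1, n_days) - 1
    return NetSurvivalEstimate(times=times, survival=ns_daily[idx],
                               variance=var_daily[idx],
                               n_at_risk=n_risk[idx])


def age_standardise(band_estimates: dict, weights: ICSSWeights | None = None
                    ) -> NetSurvivalEstimate:
    """ICSS-standardised net survival from per-age-band estimates.

    ``band_estimates`` maps band index → :class:`NetSurvivalEstimate`
    (bands without subjects are simply absent); weights are renormalised
    over the contributing bands.  NS_std = sum w_g NS_g,
    var_std = sum w_g^2 var_g.
    """
    weights = weights or icss_weights()
    if not band_estimates:
        raise ValueError("no age band contributed an estimate")
    idxs = sorted(band_estimates)
    total = sum(weights.weights[g] for g in idxs)
    if total <= 0:
        raise ValueError("contributing bands have zero total weight")
    times = band_estimates[idxs[0]].times
    ns = np.zeros_like(times, dtype=float)
    var = np.zeros_like(times, dtype=float)
    n_risk = np.zeros_like(times, dtype=float)
    for g in idxs:
        est = band_estimates[g]
        if not np.array_equal(est.times, times):
            raise ValueError("band estimates on different time grids")
        wg = weights.weights[g] / total
        ns += wg * est.survival
        var += wg ** 2 * est.variance
        n_risk += est.n_at_risk
    return NetSurvivalEstimate(times=times, survival=ns, variance=var,
                               n_at_risk=n_risk)


def net_survival_by_stage(subjects, lt: LifeTable,
                          time_grid_years=(1.0, 5.0),
                          standardise: bool = True,
                          weights: ICSSWeights | None = None) -> dict:
    """Per-stage (incl. missing) net survival, optionally ICSS-standardised."""
    weights = weights or icss_weights()
    by_stage: dict[str, list] = {}
    for s in subjects:
        by_stage.setdefault(s.stage, []).append(s)
    out = {}
    for stage, members in sorted(by_stage.items()):
        if not standardise:
            out[stage] = pohar_perme(members, lt, time_grid_years)
            continue
        bands: dict[int, list] = {}
        for s in members:
            bands.setdefault(weights.band_of(s.age), []).append(s)
        est = {g: pohar_perme(m, lt, time_grid_years)
               for g, m in bands.items()}
        out[stage] = age_standardise(est, weights)
    return out
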