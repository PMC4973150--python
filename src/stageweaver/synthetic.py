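"""Synthetic multi-source cohorts with known true stage.

The generator emulates the *structure* of the three routine data sources —
a cancer registry, a CAS-like central database and a clinical audit with
per-treatment records — including the pathologies that make staging hard in
real data: per-variable missingness, legacy not-assessable codes (Mx,
pM0), zero-coded components later contradicted by positive evidence,
conflicting duplicate treatment records straddling the ±30-day eligibility
window, heterogeneous raw code formats ("T2a", "2a", "pt2a"), and
survival times drawn from stage-specific excess hazards added to a
life-table population hazard.  Every tumour carries a truth record, so the
whole pipeline is testable without any external data.

All randomness flows from a single seeded generator; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import tnm_codes
from .derivation import SiteConfig, load_site_config
from .grouping import grouping_table
from .records_io import (AuditTreatmentRecord, CentralRecord, LifeTable,
                         RegistryRecord, records_to_frame)

FOLLOW_UP_END = date(2013, 12, 31)

_DEFAULT_EXCESS = {"I": 0.012, "II": 0.035, "III": 0.095, "IV": 0.40}

# Per-variable missingness (probability the emitted cell is blank given the
# record exists), loosely shaped on the completeness patterns of English
# audit/central staging data: pathological audit codes scarce for
# colorectal, clinical audit codes dominant for lung, integrated registry
# variables widespread in both.
DEFAULT_MISSINGNESS = {
    "colorectal": {
        "audit.pT": 0.70, "audit.pN": 0.70, "audit.pM": 0.90,
        "audit.cT": 0.60, "audit.cN": 0.60, "audit.cM": 0.57,
        "audit.serosal_involvement_or_perforation": 0.95,
        "audit.mri_T": 0.80, "audit.mri_N": 0.82,
        "audit.positive_node_count": 0.86,
        "audit.distant_metastasis": 0.85, "audit.liver_ct": 0.38,
        "audit.dukes_p": 0.60, "audit.dukes_c": 0.35,
        "central.pT": 0.51, "central.pN": 0.53, "central.pM": 0.93,
        "central.cT": 0.96, "central.cN": 0.96, "central.cM": 0.92,
        "central.iT": 0.35, "central.iN": 0.37, "central.iM": 0.57,
        "central.positive_node_count": 0.78,
        "central.pStage": 0.97, "central.cStage": 0.997,
        "central.iStage": 0.64, "central.dukes": 0.33,
    },
    "lung": {
        "audit.pT": 0.88, "audit.pN": 0.88, "audit.pM": 0.92,
        "audit.cT": 0.18, "audit.cN": 0.18, "audit.cM": 0.19,
        "audit.pStage": 0.87, "audit.cStage": 0.20,
        "central.pT": 0.91, "central.pN": 0.91, "central.pM": 0.94,
        "central.cT": 0.95, "central.cN": 0.95, "central.cM": 0.95,
        "central.iT": 0.45, "central.iN": 0.45, "central.iM": 0.44,
        "central.positive_node_count": 0.98,
        "central.pStage": 0.99, "central.cStage": 0.996,
        "central.iStage": 0.49,
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    site: str = "colorectal"
    n_tumours: int = 1000
    year_range: tuple = (2008, 2012)
    stage_distribution: tuple = (0.170, 0.285, 0.302, 0.243)  # I, II, III, IV
    missingness: dict | None = None  # overrides DEFAULT_MISSINGNESS[site]
    central_coverage: float = 0.97
    audit_coverage: float = 0.75
    zero_upgrade_prob: float = 0.10  # truth M1 emitted as cM0 + planted evidence
    mx_rate: float = 0.06  # M variables emitted as legacy "X"
    extra_record_dist: tuple = ((0, 0.55), (1, 0.30), (2, 0.15))
    extra_record_offset_sd: float = 28.0  # days; straddles the ±30 window
    conflict_upgrade_prob: float = 0.35  # extra records carry upgraded pT/pN/pM
    diagnosis_date_jitter_days: int = 4  # source-vs-registry diagnosis date
    corruption: dict = field(default_factory=dict)  # nhs_missing, nhs_error,
    #                                                 postcode_error rates
    excess_hazard: dict = field(default_factory=lambda: dict(_DEFAULT_EXCESS))
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.site not in DEFAULT_MISSINGNESS:
            problems.append(f"unknown site {self.site!r}")
        if self.n_tumours <= 0:
            problems.append("n_tumours must be positive")
        if abs(sum(self.stage_distribution) - 1.0) > 1e-9:
            problems.append("stage_distribution must sum to 1")
        for name in ("central_coverage", "audit_coverage", "zero_upgrade_prob",
                     "mx_rate", "conflict_upgrade_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} outside [0,1]")
        for key, v in (self.missingness or {}).items():
            if not 0.0 <= v <= 1.0:
                problems.append(f"missingness[{key!r}]={v} outside [0,1]")
        for key, v in self.corruption.items():
            if not 0.0 <= v <= 1.0:
                problems.append(f"corruption[{key!r}]={v} outside [0,1]")
        if abs(sum(p for _, p in self.extra_record_dist) - 1.0) > 1e-9:
            problems.append("extra_record_dist probabilities must sum to 1")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))

    @classmethod
    def clean(cls, site: str = "colorectal", n_tumours: int = 1000,
              seed: int = 0, **kw) -> "CohortConfig":
        """Conflict-free conditions: no missingness, no legacy codes, no
        duplicate-record conflicts, no corruption."""
        site_vars = DEFAULT_MISSINGNESS[site]
        return cls(site=site, n_tumours=n_tumours, seed=seed,
                   missingness={k: 0.0 for k in site_vars},
                   central_coverage=1.0, audit_coverage=1.0,
                   zero_upgrade_prob=0.0, mx_rate=0.0,
                   extra_record_dist=((0, 1.0),), conflict_upgrade_prob=0.0,
                   diagnosis_date_jitter_days=0, **kw)


@dataclass
class SyntheticCohort:
    registry: list
    central: list
    audit: list
    life_table: LifeTable
    truth: pd.DataFrame
    config: CohortConfig

    def write(self, out_dir) -> dict:
        """Emit the four CSVs plus the truth table; returns the paths."""
        import os
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name, records in (("registry", self.registry),
                              ("central", self.central),
                              ("audit", self.audit)):
            p = os.path.join(out_dir, f"{name}.csv")
            records_to_frame(records).to_csv(p, index=False)
            paths[name] = p
        lt_path = os.path.join(out_dir, "life_table.csv")
        self.life_table.write(lt_path)
        paths["life_table"] = lt_path
        truth_path = os.path.join(out_dir, "truth.csv")
        self.truth.to_csv(truth_path, index=False)
        paths["truth"] = truth_path
        return paths


# --------------------------------------------------------------------------
# population mortality
# --------------------------------------------------------------------------

def make_life_table(years=(2008, 2013), ages=(15, 99)) -> LifeTable:
    """Gompertz-shaped annual hazards with sex and deprivation gradients."""
    age_grid = np.arange(ages[0], ages[1] + 1)
    year_grid = np.arange(years[0], years[1] + 1)
    base = np.minimum(0.7, 3.2e-5 * np.exp(0.092 * age_grid))
    grid = np.empty((len(age_grid), 2, len(year_grid), 5))
    for si, sex_mult in enumerate((1.15, 0.85)):  # male, female
        for qi in range(5):
            dep_mult = 1.0 + 0.06 * (qi - 2)
            grid[:, si, :, qi] = (base * sex_mult * dep_mult)[:, None]
    return LifeTable(age_grid, year_grid, grid)


# --------------------------------------------------------------------------
# truth generation
# --------------------------------------------------------------------------

def _truth_tnm_pool(site: str, edition: str):
    """(T, N, M, stage) combinations eligible as invasive-tumour truths."""
    table = grouping_table(site, edition)
    pool = [(t, n, m, stage) for (t, n, m), stage in table.mapping.items()
            if stage is not None and t not in ("T0", "Tis")]
    return sorted(pool)


def _sample_population_death_day(rng, cum_daily_hazard: np.ndarray):
    """Inverse-sample a death day from a cumulative daily hazard; None if
    beyond the grid."""
    u = rng.random()
    target = -np.log(u)
    idx = np.searchsorted(cum_daily_hazard, target)
    return None if idx >= len(cum_daily_hazard) else int(idx) + 1


def generate_cohort(cfg: CohortConfig, annotate: bool = True) -> SyntheticCohort:
    """Generate linked registry/central/audit tables plus truth.

    Reproducible for a fixed ``cfg.seed``; with default conditions every
    chain step of the derivation algorithm is exercised for cohorts of a
    few hundred tumours or more.  ``annotate=False`` skips the
    expected-value/true-source presence walk (cheaper for large sweeps
    that only need stages and survival truth).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    site = cfg.site
    config = load_site_config(site)
    edition = config.default_edition
    missingness = dict(DEFAULT_MISSINGNESS[site])
    missingness.update(cfg.missingness or {})
    life_table = make_life_table()
    pool = _truth_tnm_pool(site, edition)
    pool_stages = np.array([p[3] for p in pool])
    stage_names = ("I", "II", "III", "IV")

    n = cfg.n_tumours
    stages = rng.choice(4, size=n, p=np.asarray(cfg.stage_distribution))
    ages = np.clip(np.round(rng.normal(71, 11, size=n)), 15, 99).astype(int)
    sexes = np.where(rng.random(n) < 0.53, "male", "female")
    deps = rng.integers(1, 6, size=n)
    year_lo, year_hi = cfg.year_range
    diag_days = rng.integers(0, (date(year_hi, 12, 31)
                                 - date(year_lo, 1, 1)).days + 1, size=n)

    registry, central, audit, truth_rows = [], [], [], []
    icd_codes = {"colorectal": ("C18", "C19"), "lung": ("C33", "C34")}[site]
    for i in range(n):
        stage = stage_names[stages[i]]
        choices = np.flatnonzero(pool_stages == stage)
        t, n_cat, m_cat, _ = pool[int(rng.choice(choices))]
        diagnosis = date(year_lo, 1, 1) + timedelta(days=int(diag_days[i]))
        birth = diagnosis - timedelta(days=int(round(ages[i] * 365.25 +
                                                     rng.integers(0, 365))))
        person = f"P{i:06d}"
        tumour = f"R{i:06d}"
        nhs = f"{4000000000 + i}"
        postcode = (f"{chr(65 + i % 26)}{chr(65 + (i // 26) % 26)}"
                    f"{1 + i % 9} {i % 10}{chr(65 + (i * 7) % 26)}"
                    f"{chr(65 + (i * 3) % 26)}")
        icd = str(rng.choice(icd_codes))

        # survival: stage-specific excess hazard + population hazard
        horizon = (FOLLOW_UP_END - diagnosis).days
        daily = _subject_daily_hazard(life_table, int(ages[i]), sexes[i],
                                      diagnosis.year, int(deps[i]), horizon)
        pop_day = _sample_population_death_day(rng, np.cumsum(daily))
        lam = cfg.excess_hazard[stage] / 365.25
        excess_day = int(np.ceil(rng.exponential(1.0 / lam))) if lam > 0 else None
        death_day = min(d for d in (pop_day, excess_day, horizon + 1)
                        if d is not None)
        if death_day <= horizon:
            vital, exit_date = "dead", diagnosis + timedelta(days=death_day)
        else:
            vital, exit_date = "alive", FOLLOW_UP_END

        registry.append(RegistryRecord(
            person_id=person, tumour_id=tumour, birth_date=birth,
            sex=str(sexes[i]), vital_status=vital,
            death_or_censor_date=exit_date,
            deprivation_quintile=int(deps[i]), icd10_site=icd,
            diagnosis_date=diagnosis, nhs_number=nhs, postcode=postcode))

        planted = False
        if rng.random() < cfg.central_coverage:
            central.append(_make_central(rng, cfg, missingness, person, i,
                                         icd, diagnosis, birth, sexes[i],
                                         postcode, nhs, t, n_cat, m_cat,
                                         stage))
        audit_recs = ()
        if rng.random() < cfg.audit_coverage:
            audit_recs, planted = _make_audit(rng, cfg, missingness, person,
                                              i, icd, diagnosis, birth,
                                              sexes[i], postcode, nhs, t,
                                              n_cat, m_cat, stage, edition)
            audit.extend(audit_recs)

        truth_rows.append(dict(
            tumour_id=tumour, person_id=person, site=site, stage=stage,
            T=t, N=n_cat, M=m_cat, age=int(ages[i]), sex=str(sexes[i]),
            deprivation_quintile=int(deps[i]),
            diagnosis_date=diagnosis.isoformat(),
            diagnosis_year=diagnosis.year,
            follow_up_days=(exit_date - diagnosis).days,
            event=int(vital == "dead"),
            zero_upgrade_planted=int(planted)))

    truth = pd.DataFrame(truth_rows)
    cohort = SyntheticCohort(registry=registry, central=central, audit=audit,
                             life_table=life_table, truth=truth, config=cfg)
    _apply_corruption(rng, cohort)
    if annotate:
        _annotate_true_sources(cohort, config, edition)
    return cohort


def _subject_daily_hazard(lt: LifeTable, age, sex, year, dep, n_days):
    day_years = (np.arange(n_days) / 365.25).astype(int)
    age_lo, age_hi = lt.age_range
    year_lo, year_hi = lt.year_range
    ai = np.clip(age + day_years, None, age_hi) - age_lo
    yi = np.clip(year + day_years, None, year_hi) - year_lo
    si = 0 if sex == "male" else 1
    return lt.hazard[ai, si, yi, dep - 1] / 365.25


# --------------------------------------------------------------------------
# degradation: emit raw source variables from the truth
# --------------------------------------------------------------------------

def _fmt(rng, category: str, basis: str) -> str:
    """Raw-format jitter: 'T2a' | '2a' | 't2a' | 'pT2a' etc."""
    style = rng.integers(0, 4)
    if style == 0:
        return category
    if style == 1:
        return category[1:]  # bare body
    if style == 2:
        return category.lower()
    prefix = {"clinical": "c", "pathological": "p", "integrated": "i"}[basis]
    return prefix + category


def _emit(rng, cfg, missingness, key, category, basis, component):
    """One raw staging cell, or None; applies missingness and Mx emission."""
    if rng.random() < missingness.get(key, 0.0):
        return None
    if component == "M" and rng.random() < cfg.mx_rate:
        return rng.choice(["X", "Mx", "MX"])
    return _fmt(rng, category, basis)


_DUKES_FROM_STAGE = {"I": "A", "II": "B", "III": "C", "IV": "D"}


def _emit_stage(rng, missingness, key, stage):
    if rng.random() < missingness.get(key, 0.0):
        return None
    text = stage
    if stage in ("I", "II", "III") and rng.random() < 0.3:
        text = stage + str(rng.choice(["A", "B"]))
    return text


def _make_central(rng, cfg, miss, person, i, icd, diagnosis, birth, sex,
                  postcode, nhs, t, n_cat, m_cat, stage) -> CentralRecord:
    jit = int(rng.integers(-cfg.diagnosis_date_jitter_days,
                           cfg.diagnosis_date_jitter_days + 1)) \
        if cfg.diagnosis_date_jitter_days else 0
    kw = dict(
        person_id=person, tumour_id=f"C{i:06d}", icd10_site=icd,
        diagnosis_date=diagnosis + timedelta(days=jit), nhs_number=nhs,
        birth_date=birth, sex=str(sex), postcode=postcode,
        pT=_emit(rng, cfg, miss, "central.pT", t, "pathological", "T"),
        pN=_emit(rng, cfg, miss, "central.pN", n_cat, "pathological", "N"),
        pM=_emit(rng, cfg, miss, "central.pM", m_cat, "pathological", "M"),
        cT=_emit(rng, cfg, miss, "central.cT", t, "clinical", "T"),
        cN=_emit(rng, cfg, miss, "central.cN", n_cat, "clinical", "N"),
        cM=_emit(rng, cfg, miss, "central.cM", m_cat, "clinical", "M"),
        iT=_emit(rng, cfg, miss, "central.iT", t, "integrated", "T"),
        iN=_emit(rng, cfg, miss, "central.iN", n_cat, "integrated", "N"),
        iM=_emit(rng, cfg, miss, "central.iM", m_cat, "integrated", "M"),
        pStage=_emit_stage(rng, miss, "central.pStage", stage),
        cStage=_emit_stage(rng, miss, "central.cStage", stage),
        iStage=_emit_stage(rng, miss, "central.iStage", stage),
    )
    if rng.random() >= miss.get("central.positive_node_count", 1.0):
        kw["positive_node_count"] = (int(rng.integers(1, 12))
                                     if n_cat != "N0" else 0)
    if cfg.site == "colorectal":
        if rng.random() >= miss.get("central.dukes", 1.0):
            kw["dukes"] = _DUKES_FROM_STAGE[stage]
    return CentralRecord(**kw)


def _next_rank_up(site, edition, component, category):
    table = tnm_codes.valid_codes(site, edition, component)
    rank = table[category]
    above = [c for c, r in table.items() if r == rank + 1]
    return above[0] if above else category


def _make_audit(rng, cfg, miss, person, i, icd, diagnosis, birth, sex,
                postcode, nhs, t, n_cat, m_cat, stage, edition):
    site = cfg.site
    # clinical codes are constant across the tumour's treatment records
    cT = _emit(rng, cfg, miss, "audit.cT", t, "clinical", "T")
    cN = _emit(rng, cfg, miss, "audit.cN", n_cat, "clinical", "N")
    cM = _emit(rng, cfg, miss, "audit.cM", m_cat, "clinical", "M")

    planted = False
    force_liver, force_flags = False, False
    if m_cat.startswith("M1") and rng.random() < cfg.zero_upgrade_prob:
        # miscoded zero contradicted by investigation evidence
        cM = _fmt(rng, "M0", "clinical")
        planted = True
        if rng.random() < 0.5:
            force_liver = True
        else:
            force_flags = True

    common = dict(person_id=person, tumour_id=f"A{i:06d}", icd10_site=icd,
                  diagnosis_date=diagnosis, nhs_number=nhs, birth_date=birth,
                  sex=str(sex), postcode=postcode, cT=cT, cN=cN, cM=cM)

    def pathological(upgraded: bool):
        def up(comp, cat):
            if upgraded and rng.random() < cfg.conflict_upgrade_prob:
                return _next_rank_up(site, edition, comp, cat)
            return cat
        return dict(
            pT=_emit(rng, cfg, miss, "audit.pT", up("T", t), "pathological", "T"),
            pN=_emit(rng, cfg, miss, "audit.pN", up("N", n_cat), "pathological", "N"),
            pM=_emit(rng, cfg, miss, "audit.pM", up("M", m_cat), "pathological", "M"))

    def extras():
        kw = {}
        if site == "colorectal":
            if rng.random() >= miss.get(
                    "audit.serosal_involvement_or_perforation", 1.0):
                kw["serosal_involvement_or_perforation"] = (
                    "positive" if t.startswith("T4") else "negative")
            if rng.random() >= miss.get("audit.mri_T", 1.0):
                kw["mri_T"] = _fmt(rng, t, "clinical")
            if rng.random() >= miss.get("audit.mri_N", 1.0):
                kw["mri_N"] = _fmt(rng, n_cat, "clinical")
            if rng.random() >= miss.get("audit.positive_node_count", 1.0):
                kw["positive_node_count"] = (int(rng.integers(1, 12))
                                             if n_cat != "N0" else 0)
            metastatic = m_cat.startswith("M1")
            if force_flags or (metastatic and rng.random() >= miss.get(
                    "audit.distant_metastasis", 1.0)):
                kw["distant_metastasis"] = frozenset(
                    {str(rng.choice(["liver", "lung", "peritoneum"]))})
            if force_liver or rng.random() >= miss.get("audit.liver_ct", 1.0):
                kw["liver_ct"] = "positive" if metastatic else "negative"
                if force_liver:
                    kw["liver_ct"] = "positive"
            if rng.random() >= miss.get("audit.dukes_p", 1.0):
                kw["dukes_p"] = _DUKES_FROM_STAGE[stage]
            if rng.random() >= miss.get("audit.dukes_c", 1.0):
                kw["dukes_c"] = _DUKES_FROM_STAGE[stage]
        else:
            if rng.random() >= miss.get("audit.pStage", 1.0):
                kw["pStage"] = _emit_stage(rng, {}, "", stage)
            if rng.random() >= miss.get("audit.cStage", 1.0):
                kw["cStage"] = _emit_stage(rng, {}, "", stage)
            kw["tnm_edition_flag"] = "7"
        return kw

    primary_offset = int(np.clip(round(rng.normal(5, 9)), -30, 30))
    records = [AuditTreatmentRecord(
        procedure_date=diagnosis + timedelta(days=primary_offset),
        **common, **pathological(upgraded=False), **extras())]

    n_extra = int(rng.choice([k for k, _ in cfg.extra_record_dist],
                             p=[p for _, p in cfg.extra_record_dist]))
    for _ in range(n_extra):
        offset = primary_offset
        while offset == primary_offset:
            offset = int(np.clip(round(rng.normal(10, cfg.extra_record_offset_sd)),
                                 -120, 120))
        # later/further records may reflect restaging: upgraded categories
        records.append(AuditTreatmentRecord(
            procedure_date=diagnosis + timedelta(days=offset),
            **common, **pathological(upgraded=abs(offset) > abs(primary_offset)),
            **extras()))
    return tuple(records), planted


def _apply_corruption(rng, cohort: SyntheticCohort) -> None:
    rates = cohort.config.corruption
    if not rates:
        return
    for name in ("central", "audit"):
        records = getattr(cohort, name)
        for idx, rec in enumerate(records):
            changes = {}
            if rng.random() < rates.get("nhs_missing", 0.0):
                changes["nhs_number"] = None
            elif rng.random() < rates.get("nhs_error", 0.0):
                changes["nhs_number"] = str(int(rec.nhs_number) + 7)
            if rng.random() < rates.get("postcode_error", 0.0):
                changes["postcode"] = (rec.postcode or "")[:-1] + "Z"
            if changes:
                records[idx] = replace(rec, **changes)


# --------------------------------------------------------------------------
# truth provenance: independent presence-walk over the chains
# --------------------------------------------------------------------------

def _expected_source(chain, central: CentralRecord | None, audit_recs,
                     diagnosis, site, edition):
    """Chain-first variable expected to fix the component; mirrors the
    derivation rules by a direct walk over emitted values (used as the
    oracle in tests)."""
    eligible = [r for r in audit_recs
                if r.procedure_date is not None
                and abs((r.procedure_date - diagnosis).days) <= 30]

    def rank_sum(rec):
        total = 0
        for comp, raw in (("T", rec.pT), ("N", rec.pN), ("M", rec.pM)):
            pr = tnm_codes.parse_code(raw, comp, "pathological", site, edition)
            total += tnm_codes.ordinal_rank(pr.value) if pr.is_valid else 1000
        return total

    order = {id(r): k for k, r in enumerate(audit_recs)}
    eligible.sort(key=lambda r: (abs((r.procedure_date - diagnosis).days),
                                 rank_sum(r), order[id(r)]))
    all_ordered = eligible + [r for r in audit_recs
                              if id(r) not in {id(e) for e in eligible}]
    pathological_vars = {"pT", "pN", "pM", "serosal_involvement_or_perforation",
                         "positive_node_count"}

    running = None  # (category, "source.variable")
    for step in chain.steps:
        if step.kind == "inference":
            continue
        if step.source == "central":
            recs = [central] if central is not None else []
        else:
            recs = eligible if step.variable in pathological_vars else all_ordered
        label = f"{step.source}.{step.variable}"
        if step.kind == "direct":
            # a pathologically confirmed M1 overrides a clinical M0
            override = (chain.component == "M" and running is not None
                        and running[0] == "M0"
                        and step.basis == "pathological")
            if running is not None and not override:
                continue
            for rec in recs:
                pr = tnm_codes.parse_code(getattr(rec, step.variable),
                                          chain.component, step.basis, site,
                                          edition)
                if pr.is_valid and (not override
                                    or tnm_codes.is_positive(pr.value)):
                    running = (pr.value.category, label)
                    break
        else:  # positive-evidence
            if running is not None and running[0] not in ("T0", "N0", "M0"):
                continue
            for rec in recs:
                v = getattr(rec, step.variable)
                if step.evidence == "t4" and v == "positive":
                    running = ("T4", label)
                    break
                if step.evidence == "m1":
                    if (bool(v) if isinstance(v, frozenset) else v == "positive"):
                        running = ("M1", label)
                        break
                if step.evidence == "n1_count" and v is not None and v > 0:
                    running = ("N1", label)
                    break
                if step.evidence == "identity":
                    pr = tnm_codes.parse_code(v, chain.component, step.basis,
                                              site, edition)
                    if pr.is_valid and tnm_codes.is_positive(pr.value):
                        running = (pr.value.category, label)
                        break
    return running


def _annotate_true_sources(cohort: SyntheticCohort, config: SiteConfig,
                           edition: str) -> None:
    central_by_person = {r.person_id: r for r in cohort.central}
    audit_by_person: dict[str, list] = {}
    for r in cohort.audit:
        audit_by_person.setdefault(r.person_id, []).append(r)
    cols = {comp: ([], []) for comp in ("T", "N", "M")}
    for row in cohort.truth.itertuples(index=False):
        central = central_by_person.get(row.person_id)
        audit = audit_by_person.get(row.person_id, [])
        diagnosis = date.fromisoformat(row.diagnosis_date)
        for comp in ("T", "N", "M"):
            hit = _expected_source(config.chains[comp], central, audit,
                                   diagnosis, cohort.config.site, edition)
            values, sources = cols[comp]
            values.append(hit[0] if hit else "")
            sources.append(hit[1] if hit else "")
    for comp in ("T", "N", "M"):
        values, sources = cols[comp]
        cohort.truth[f"expected_{comp}"] = values
        cohort.truth[f"true_source_{comp}"] = sources
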