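"""Source-record data model and CSV input/output.

Three delimited source tables feed the staging pipeline:

* ``registry``  — one row per tumour; person and basic tumour facts
  (the authoritative source for demographics, vital status, site).
* ``central``   — one row per tumour from a CAS-like central cancer
  database; clinical/pathological/integrated T, N, M codes, node counts,
  summary-stage variables, and (colorectal) a Dukes stage.
* ``audit``     — per-treatment-record rows from a clinical audit; detailed
  pathological/clinical TNM plus site-specific investigation variables
  (colorectal: serosal involvement, MRI results, liver CT, metastasis
  flags, node counts, Dukes; lung: summary stages and a TNM edition flag).

Raw staging codes are kept verbatim at this layer; their interpretation is
:mod:`stageweaver.tnm_codes`'s job.  Dates are ISO-8601.  Unparseable
*optional* fields become None/unknown with a logged warning; required
fields that fail to parse raise a row-level error naming the row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as _dc_fields
from datetime import date
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITES = ("colorectal", "lung")
SEXES = ("male", "female")
VITAL_STATUSES = ("alive", "dead", "censored")
TRISTATE = ("positive", "negative", "unknown")

# ICD-10 3-character topography prefixes admitted per configured site
SITE_ICD10 = {"colorectal": ("C18", "C19"), "lung": ("C33", "C34")}


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


class RowError(ValueError):
    """A required field on a specific data row failed to parse."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


# --------------------------------------------------------------------------
# record types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryRecord:
    person_id: str
    tumour_id: str
    birth_date: date
    sex: str
    vital_status: str
    death_or_censor_date: date
    deprivation_quintile: int
    icd10_site: str
    diagnosis_date: date
    nhs_number: str | None = None
    postcode: str | None = None
    morphology: str | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.vital_status not in VITAL_STATUSES:
            raise ValueError(f"bad vital_status {self.vital_status!r}")
        if not 1 <= int(self.deprivation_quintile) <= 5:
            raise ValueError(
                f"deprivation_quintile must be 1-5, got {self.deprivation_quintile}")
        if self.death_or_censor_date < self.diagnosis_date:
            raise ValueError("death_or_censor_date precedes diagnosis_date")


@dataclass(frozen=True)
class CentralRecord:
    """CAS-like central-database tumour row; raw codes uninterpreted."""

    person_id: str
    tumour_id: str
    icd10_site: str
    diagnosis_date: date
    nhs_number: str | None = None
    birth_date: date | None = None
    sex: str | None = None
    postcode: str | None = None
    cT: str | None = None
    cN: str | None = None
    cM: str | None = None
    pT: str | None = None
    pN: str | None = None
    pM: str | None = None
    iT: str | None = None
    iN: str | None = None
    iM: str | None = None
    positive_node_count: int | None = None
    pStage: str | None = None
    cStage: str | None = None
    iStage: str | None = None
    dukes: str | None = None  # colorectal only


@dataclass(frozen=True)
class AuditTreatmentRecord:
    """One clinical-audit treatment record (a tumour may carry several)."""

    person_id: str
    tumour_id: str
    icd10_site: str
    diagnosis_date: date
    nhs_number: str | None = None
    birth_date: date | None = None
    sex: str | None = None
    postcode: str | None = None
    procedure_date: date | None = None
    pT: str | None = None
    pN: str | None = None
    pM: str | None = None
    cT: str | None = None
    cN: str | None = None
    cM: str | None = None
    # colorectal-specific investigation variables
    serosal_involvement_or_perforation: str = "unknown"
    mri_T: str | None = None
    mri_N: str | None = None
    positive_node_count: int | None = None
    distant_metastasis: frozenset = field(default_factory=frozenset)
    liver_ct: str = "unknown"
    dukes_p: str | None = None
    dukes_c: str | None = None
    # lung-specific
    pStage: str | None = None
    cStage: str | None = None
    tnm_edition_flag: str | None = None


@dataclass(frozen=True)
class TumourBundle:
    """All linked records of one registry tumour."""

    registry: RegistryRecord
    central: CentralRecord | None = None
    audit: tuple = ()  # AuditTreatmentRecord, file order
    link_level: dict | None = None  # source -> hierarchy level used

    @property
    def site(self) -> str:
        for s, prefixes in SITE_ICD10.items():
            if self.registry.icd10_site[:3] in prefixes:
                return s
        raise ValueError(f"unconfigured site code {self.registry.icd10_site!r}")


# --------------------------------------------------------------------------
# schema dictionaries
# --------------------------------------------------------------------------

_LINK_OPTIONAL = ["nhs_number", "birth_date", "sex", "postcode"]

REQUIRED_COLUMNS = {
    "registry": ["person_id", "tumour_id", "birth_date", "sex", "vital_status",
                 "death_or_censor_date", "deprivation_quintile", "icd10_site",
                 "diagnosis_date"],
    "central": ["person_id", "tumour_id", "icd10_site", "diagnosis_date"],
    "audit": ["person_id", "tumour_id", "icd10_site", "diagnosis_date"],
}

_TNM_RAW = ["cT", "cN", "cM", "pT", "pN", "pM"]

OPTIONAL_COLUMNS = {
    ("registry", "colorectal"): ["nhs_number", "postcode", "morphology"],
    ("registry", "lung"): ["nhs_number", "postcode", "morphology"],
    ("central", "colorectal"): _LINK_OPTIONAL + _TNM_RAW + [
        "iT", "iN", "iM", "positive_node_count", "pStage", "cStage",
        "iStage", "dukes"],
    ("central", "lung"): _LINK_OPTIONAL + _TNM_RAW + [
        "iT", "iN", "iM", "positive_node_count", "pStage", "cStage", "iStage"],
    ("audit", "colorectal"): _LINK_OPTIONAL + ["procedure_date"] + _TNM_RAW + [
        "serosal_involvement_or_perforation", "mri_T", "mri_N",
        "positive_node_count", "distant_metastasis", "liver_ct",
        "dukes_p", "dukes_c", "tnm_edition_flag"],
    ("audit", "lung"): _LINK_OPTIONAL + ["procedure_date"] + _TNM_RAW + [
        "pStage", "cStage", "tnm_edition_flag"],
}

_RECORD_CLASS = {"registry": RegistryRecord, "central": CentralRecord,
                 "audit": AuditTreatmentRecord}


def _is_blank(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return str(v).strip() == ""


def _parse_date(v, *, row: int, column: str, required: bool) -> date | None:
    if _is_blank(v):
        if required:
            raise RowError(row, f"missing required date in column {column!r}")
        return None
    try:
        return date.fromisoformat(str(v).strip())
    except ValueError:
        if required:
            raise RowError(row, f"malformed date {v!r} in column {column!r}")
        logger.warning("row %d: unparseable optional date %r in %s; "
                       "treated as unknown", row, v, column)
        return None


def _parse_int(v, *, row: int, column: str) -> int | None:
    if _is_blank(v):
        return None
    try:
        return int(float(str(v).strip()))
    except ValueError:
        logger.warning("row %d: unparseable optional integer %r in %s; "
                       "treated as unknown", row, v, column)
        return None


def _parse_tristate(v, *, row: int, column: str) -> str:
    if _is_blank(v):
        return "unknown"
    text = str(v).strip().lower()
    mapping = {"positive": "positive", "yes": "positive", "1": "positive",
               "true": "positive", "negative": "negative", "no": "negative",
               "0": "negative", "false": "negative", "unknown": "unknown"}
    if text not in mapping:
        logger.warning("row %d: unparseable tri-state %r in %s; "
                       "treated as unknown", row, v, column)
        return "unknown"
    return mapping[text]


def _parse_text(v) -> str | None:
    return None if _is_blank(v) else str(v).strip()


def _parse_flagset(v) -> frozenset:
    if _is_blank(v):
        return frozenset()
    return frozenset(p.strip().lower() for p in str(v).split(";") if p.strip())


def read_source_table(path, schema: str, site: str) -> list:
    """Read one source CSV into typed records.

    Raises :class:`SchemaError` when a required column is absent, and
    :class:`RowError` (with the 1-based data-row number) when a required
    field fails to parse or violates an invariant.  Unknown columns are
    ignored with a warning; absent optional columns yield unknown fields.
    """
    if schema not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}")
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = REQUIRED_COLUMNS[schema]
    optional = OPTIONAL_COLUMNS[(schema, site)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table missing required column(s) "
                          f"{', '.join(missing)}")
    unknown = [c for c in df.columns if c not in required + optional]
    if unknown:
        logger.warning("%s table: ignoring unrecognised column(s) %s",
                       schema, ", ".join(unknown))

    records = []
    for i, raw in enumerate(df.to_dict("records"), start=1):
        records.append(_parse_row(raw, schema, site, row=i,
                                  columns=set(df.columns)))
    return records


def _parse_row(raw: dict, schema: str, site: str, *, row: int, columns: set):
    def get(col):
        return raw.get(col) if col in columns else None

    kw: dict = {}
    for col in ("person_id", "tumour_id", "icd10_site"):
        v = _parse_text(get(col))
        if v is None:
            raise RowError(row, f"missing required value in column {col!r}")
        kw[col] = v
    prefixes = SITE_ICD10[site]
    if kw["icd10_site"][:3] not in prefixes:
        raise RowError(row, f"icd10_site {kw['icd10_site']!r} outside the "
                            f"configured {site} set {prefixes}")
    kw["diagnosis_date"] = _parse_date(get("diagnosis_date"), row=row,
                                       column="diagnosis_date", required=True)
    kw["nhs_number"] = _parse_text(get("nhs_number"))
    kw["postcode"] = _parse_text(get("postcode"))

    if schema == "registry":
        kw["birth_date"] = _parse_date(get("birth_date"), row=row,
                                       column="birth_date", required=True)
        sex = _parse_text(get("sex"))
        if sex not in SEXES:
            raise RowError(row, f"sex must be one of {SEXES}, got {sex!r}")
        kw["sex"] = sex
        vs = _parse_text(get("vital_status"))
        if vs not in VITAL_STATUSES:
            raise RowError(row, f"bad vital_status {vs!r}")
        kw["vital_status"] = vs
        kw["death_or_censor_date"] = _parse_date(
            get("death_or_censor_date"), row=row,
            column="death_or_censor_date", required=True)
        dq = get("deprivation_quintile")
        try:
            dq = int(str(dq).strip())
        except (TypeError, ValueError):
            raise RowError(row, f"unparseable deprivation_quintile {dq!r}")
        if not 1 <= dq <= 5:
            raise RowError(row, f"deprivation_quintile {dq} outside 1-5")
        kw["deprivation_quintile"] = dq
        kw["morphology"] = _parse_text(get("morphology"))
        if kw["death_or_censor_date"] < kw["diagnosis_date"]:
            raise RowError(row, "death_or_censor_date precedes diagnosis_date")
        return RegistryRecord(**kw)

    kw["birth_date"] = _parse_date(get("birth_date"), row=row,
                                   column="birth_date", required=False)
    sex = _parse_text(get("sex"))
    kw["sex"] = sex if sex in SEXES else None

    for col in _TNM_RAW:
        kw[col] = _parse_text(get(col))

    if schema == "central":
        for col in ("iT", "iN", "iM", "pStage", "cStage", "iStage"):
            kw[col] = _parse_text(get(col))
        kw["positive_node_count"] = _parse_int(
            get("positive_node_count"), row=row, column="positive_node_count")
        if site == "colorectal":
            kw["dukes"] = _parse_text(get("dukes"))
        return CentralRecord(**kw)

    # audit
    kw["procedure_date"] = _parse_date(get("procedure_date"), row=row,
                                       column="procedure_date", required=False)
    kw["tnm_edition_flag"] = _parse_text(get("tnm_edition_flag"))
    if site == "colorectal":
        kw["serosal_involvement_or_perforation"] = _parse_tristate(
            get("serosal_involvement_or_perforation"), row=row,
            column="serosal_involvement_or_perforation")
        kw["mri_T"] = _parse_text(get("mri_T"))
        kw["mri_N"] = _parse_text(get("mri_N"))
        kw["positive_node_count"] = _parse_int(
            get("positive_node_count"), row=row, column="positive_node_count")
        kw["distant_metastasis"] = _parse_flagset(get("distant_metastasis"))
        kw["liver_ct"] = _parse_tristate(get("liver_ct"), row=row,
                                         column="liver_ct")
        kw["dukes_p"] = _parse_text(get("dukes_p"))
        kw["dukes_c"] = _parse_text(get("dukes_c"))
    else:
        kw["pStage"] = _parse_text(get("pStage"))
        kw["cStage"] = _parse_text(get("cStage"))
    return AuditTreatmentRecord(**kw)


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Flatten typed records to a DataFrame (dates ISO, flag sets ';'-joined)."""
    rows = []
    for r in records:
        d = {}
        for f in _dc_fields(r):
            v = getattr(r, f.name)
            if isinstance(v, date):
                v = v.isoformat()
            elif isinstance(v, frozenset):
                v = ";".join(sorted(v))
            d[f.name] = v
        rows.append(d)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# life tables
# --------------------------------------------------------------------------

class LifeTable:
    """Expected (general-population) mortality on a dense age×sex×year×quintile
    grid.

    Rates are stored internally as annual hazards.  Files may declare either
    convention through a first-line directive ``# rate: probability`` (the
    default: annual conditional probability of death, converted as
    h = −ln(1−q)) or ``# rate: hazard``.
    """

    def __init__(self, ages, years, hazard: np.ndarray):
        self.ages = np.asarray(sorted(ages), dtype=int)
        self.years = np.asarray(sorted(years), dtype=int)
        self.sexes = SEXES
        self.quintiles = (1, 2, 3, 4, 5)
        # hazard shape: (age, sex, year, quintile)
        expected = (len(self.ages), 2, len(self.years), 5)
        if hazard.shape != expected:
            raise ValueError(f"hazard grid shape {hazard.shape} != {expected}")
        if np.any(hazard < 0) or np.any(~np.isfinite(hazard)):
            raise ValueError("hazards must be finite and non-negative")
        self.hazard = hazard
        self._age_index = {a: i for i, a in enumerate(self.ages)}
        self._year_index = {y: i for i, y in enumerate(self.years)}

    @property
    def age_range(self):
        return int(self.ages[0]), int(self.ages[-1])

    @property
    def year_range(self):
        return int(self.years[0]), int(self.years[-1])

    def annual_hazard(self, age: int, sex: str, year: int,
                      quintile: int) -> float:
        """Annual mortality hazard at one exact grid cell (no capping here)."""
        try:
            ai = self._age_index[int(age)]
            yi = self._year_index[int(year)]
            si = SEXES.index(sex)
            qi = (1, 2, 3, 4, 5).index(int(quintile))
        except (KeyError, ValueError):
            raise KeyError(f"cell (age={age}, sex={sex}, year={year}, "
                           f"deprivation={quintile}) outside life-table grid")
        return float(self.hazard[ai, si, yi, qi])

    @classmethod
    def read(cls, path) -> "LifeTable":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
        convention = "probability"
        skip = 0
        if first.lstrip().startswith("#"):
            skip = 1
            directive = first.lstrip("#").strip().lower()
            if directive.startswith("rate:"):
                convention = directive.split(":", 1)[1].strip()
        if convention not in ("probability", "hazard"):
            raise SchemaError(f"unknown life-table rate convention "
                              f"{convention!r}")
        df = pd.read_csv(path, skiprows=skip)
        needed = ["age", "sex", "year", "deprivation", "rate"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise SchemaError(f"life table missing column(s) "
                              f"{', '.join(missing)}")
        ages = sorted(df["age"].unique())
        years = sorted(df["year"].unique())
        grid = np.full((len(ages), 2, len(years), 5), np.nan)
        ai = {a: i for i, a in enumerate(ages)}
        yi = {y: i for i, y in enumerate(years)}
        for row in df.itertuples(index=False):
            sex = str(row.sex).strip()
            if sex not in SEXES:
                raise SchemaError(f"life-table sex {sex!r} not in {SEXES}")
            q = int(row.deprivation)
            if not 1 <= q <= 5:
                raise SchemaError(f"life-table deprivation {q} outside 1-5")
            rate = float(row.rate)
            if convention == "probability":
                if not 0 <= rate < 1:
                    raise SchemaError(f"probability rate {rate} outside [0,1)")
                rate = -math.log1p(-rate)
            grid[ai[int(row.age)], SEXES.index(sex), yi[int(row.year)],
                 q - 1] = rate
        if np.isnan(grid).any():
            a, s, y, q = np.argwhere(np.isnan(grid))[0]
            raise SchemaError(
                f"life table has a gap: first missing cell (age={ages[a]}, "
                f"sex={SEXES[s]}, year={years[y]}, deprivation={q + 1})")
        return cls(ages, years, grid)

    def write(self, path, convention: str = "hazard") -> None:
        rows = []
        for a in self.ages:
            for si, sex in enumerate(SEXES):
                for y in self.years:
                    for q in self.quintiles:
                        h = self.hazard[self._age_index[a], si,
                                        self._year_index[y], q - 1]
                        rate = h if convention == "hazard" else -math.expm1(-h)
                        rows.append((a, sex, y, q, rate))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# rate: {convention}\n")
            pd.DataFrame(rows, columns=["age", "sex", "year", "deprivation",
                                        "rate"]).to_csv(fh, index=False)


# --------------------------------------------------------------------------
# derived-output table
# --------------------------------------------------------------------------

def write_derived_table(results: list, path) -> None:
    """Persist per-tumour derivation results.

    ``results`` is a list of ``(DerivedTNM, {strategy: StageResult})`` pairs.
    One row per tumour; per-component resolved category plus the provenance
    triple (source, variable, rule step) and the zero-upgrade flag; final
    stage, derivation path and imputed set per strategy.  The file
    round-trips losslessly through :func:`read_derived_table`.
    """
    if not results:
        raise ValueError("refusing to write an empty derived table")
    rows = []
    for derived, stages in results:
        row = {"tumour_id": derived.tumour_id, "site": derived.site,
               "edition": derived.edition}
        for comp in ("T", "N", "M"):
            c = derived.component(comp)
            row[f"{comp}_category"] = c.category or ""
            prov = c.provenance
            row[f"{comp}_source"] = prov.source if prov else ""
            row[f"{comp}_variable"] = prov.variable if prov else ""
            row[f"{comp}_step"] = prov.step if prov else ""
            row[f"{comp}_rule"] = prov.rule if prov else ""
            row[f"{comp}_zero_upgraded"] = int(c.zero_upgraded)
        for strategy in sorted(stages):
            s = stages[strategy]
            row[f"stage_{strategy}"] = s.stage
            row[f"path_{strategy}"] = s.path
            row[f"imputed_{strategy}"] = ";".join(sorted(s.imputed))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_derived_table(path) -> list:
    """Inverse of :func:`write_derived_table`."""
    from .derivation import DerivedComponent, DerivedTNM, Provenance
    from .grouping import StageResult

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    strategies = sorted(c[len("stage_"):] for c in df.columns
                        if c.startswith("stage_"))
    out = []
    for raw in df.to_dict("records"):
        comps = {}
        for comp in ("T", "N", "M"):
            prov = None
            if raw[f"{comp}_variable"]:
                prov = Provenance(source=raw[f"{comp}_source"],
                                  variable=raw[f"{comp}_variable"],
                                  step=int(raw[f"{comp}_step"]),
                                  rule=raw[f"{comp}_rule"])
            comps[comp] = DerivedComponent(
                component=comp,
                category=raw[f"{comp}_category"] or None,
                provenance=prov,
                zero_upgraded=bool(int(raw[f"{comp}_zero_upgraded"])))
        derived = DerivedTNM(tumour_id=raw["tumour_id"], site=raw["site"],
                             edition=raw["edition"], T=comps["T"],
                             N=comps["N"], M=comps["M"])
        stages = {}
        for strategy in strategies:
            imputed = frozenset(p for p in raw[f"imputed_{strategy}"].split(";")
                                if p)
            stages[strategy] = StageResult(stage=raw[f"stage_{strategy}"],
                                           strategy=strategy,
                                           path=raw[f"path_{strategy}"],
                                           imputed=imputed)
        out.append((derived, stages))
    return out
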