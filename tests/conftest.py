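"""Shared builders for hand-crafted tumours, bundles and life tables."""

from datetime import date, timedelta

import numpy as np
import pytest

from stageweaver.derivation import load_site_config
from stageweaver.records_io import (AuditTreatmentRecord, CentralRecord,
                                    LifeTable, RegistryRecord, TumourBundle)

DIAGNOSIS = date(2010, 6, 1)


def make_registry(person="P1", tumour="R1", site_code="C18",
                  diagnosis=DIAGNOSIS, **kw):
    defaults = dict(person_id=person, tumour_id=tumour,
                    birth_date=date(1940, 3, 15), sex="male",
                    vital_status="alive",
                    death_or_censor_date=date(2013, 12, 31),
                    deprivation_quintile=3, icd10_site=site_code,
                    diagnosis_date=diagnosis, nhs_number="4000000001",
                    postcode="AB1 2CD")
    defaults.update(kw)
    return RegistryRecord(**defaults)


_LINK_DEFAULTS = dict(nhs_number="4000000001", birth_date=date(1940, 3, 15),
                      sex="male", postcode="AB1 2CD")


def make_central(person="P1", tumour="C1", site_code="C18",
                 diagnosis=DIAGNOSIS, **kw):
    defaults = dict(person_id=person, tumour_id=tumour, icd10_site=site_code,
                    diagnosis_date=diagnosis, **_LINK_DEFAULTS)
    defaults.update(kw)
    return CentralRecord(**defaults)


def make_audit(person="P1", tumour="A1", site_code="C18",
               diagnosis=DIAGNOSIS, offset_days=0, **kw):
    defaults = dict(person_id=person, tumour_id=tumour, icd10_site=site_code,
                    diagnosis_date=diagnosis,
                    procedure_date=diagnosis + timedelta(days=offset_days),
                    **_LINK_DEFAULTS)
    defaults.update(kw)
    return AuditTreatmentRecord(**defaults)


def make_bundle(registry=None, central=None, audit=(), **registry_kw):
    return TumourBundle(registry=registry or make_registry(**registry_kw),
                        central=central, audit=tuple(audit))


def flat_life_table(annual_hazard=0.0, ages=(15, 99), years=(2008, 2013)):
    age_grid = np.arange(ages[0], ages[1] + 1)
    year_grid = np.arange(years[0], years[1] + 1)
    grid = np.full((len(age_grid), 2, len(year_grid), 5),
                   float(annual_hazard))
    return LifeTable(age_grid, year_grid, grid)


@pytest.fixture(scope="session")
def colorectal_config():
    return load_site_config("colorectal")


@pytest.fixture(scope="session")
def lung_config():
    return load_site_config("lung")


@pytest.fixture(scope="session")
def zero_life_table():
    return flat_life_table(0.0)
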