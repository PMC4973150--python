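"""Deterministic record linkage of audit/central records to registry tumours.

A two-part strategy: patients are matched through an ordered hierarchy of
identifier combinations (NHS number, date of birth, sex, postcode) — the
first level producing a *unique* registry candidate wins, ambiguous levels
fall through — and, within a matched patient, tumours are joined by
ICD-10 site group and diagnosis-date proximity.

The default eight-level hierarchy and the 90-day tumour date window are
configurable fixtures, not claims about any particular national linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records_io import TumourBundle

logger = logging.getLogger(__name__)

PATIENT_FIELDS = ("nhs_number", "birth_date", "sex", "postcode",
                  "postcode_district")

DEFAULT_HIERARCHY_LEVELS = (
    ("nhs_number", "birth_date", "sex", "postcode"),
    ("nhs_number", "birth_date", "sex"),
    ("nhs_number", "birth_date"),
    ("nhs_number", "sex", "postcode"),
    ("nhs_number",),
    ("birth_date", "sex", "postcode"),
    ("birth_date", "sex", "postcode_district"),
    ("birth_date", "postcode"),
)

DEFAULT_DATE_WINDOW_DAYS = 90


@dataclass(frozen=True)
class LinkHierarchy:
    """Ordered match levels; each level is a set of fields that must agree."""

    levels: tuple = DEFAULT_HIERARCHY_LEVELS

    def __post_init__(self):
        if not self.levels:
            raise ValueError("hierarchy needs at least one level")
        for level in self.levels:
            bad = set(level) - set(PATIENT_FIELDS)
            if bad:
                raise ValueError(f"unknown hierarchy field(s) {bad}")


@dataclass
class LinkageReport:
    """Residuals of a linkage pass."""

    unmatched_patients: list = field(default_factory=list)
    unbundled_tumours: list = field(default_factory=list)


def _postcode_district(postcode: str | None) -> str | None:
    if postcode is None:
        return None
    return postcode.split()[0] if postcode.strip() else None


def _key(record, level) -> tuple | None:
    """Match key for one record at one level; None when any field is absent."""
    parts = []
    for f in level:
        v = (_postcode_district(record.postcode) if f == "postcode_district"
             else getattr(record, f))
        if v is None:
            return None
        parts.append(v)
    return tuple(parts)


def link_patients(registry_records, source_records,
                  hierarchy: LinkHierarchy | None = None):
    """Match source patients to registry patients level by level.

    Returns ``(matches, report)`` where ``matches`` maps source person_id →
    (registry person_id, 1-based level).  Each source patient matches at
    most one registry patient; a level with several registry candidates is
    skipped for that patient (ambiguity falls through to later levels).
    """
    hierarchy = hierarchy or LinkHierarchy()
    registry_patients: dict[str, object] = {}
    for rec in registry_records:
        registry_patients.setdefault(rec.person_id, rec)
    source_patients: dict[str, object] = {}
    for rec in source_records:
        source_patients.setdefault(rec.person_id, rec)

    matches: dict[str, tuple[str, int]] = {}
    report = LinkageReport()
    for level_no, level in enumerate(hierarchy.levels, start=1):
        index: dict[tuple, list[str]] = {}
        for pid, rec in registry_patients.items():
            key = _key(rec, level)
            if key is not None:
                index.setdefault(key, []).append(pid)
        for pid, rec in source_patients.items():
            if pid in matches:
                continue
            key = _key(rec, level)
            if key is None:
                continue
            candidates = index.get(key, [])
            if len(candidates) == 1:
                matches[pid] = (candidates[0], level_no)
    report.unmatched_patients = sorted(set(source_patients) - set(matches))
    return matches, report


def _site_group(icd10: str) -> str:
    # tumour-level matching groups by the ICD-10 3-character topography prefix
    return icd10[:3]


def _assign_tumours(registry_by_person, source_tumours, matches,
                    window_days: int):
    """Greedy nearest-date assignment of source tumours to registry tumours."""
    candidates = []  # (|date diff|, source diagnosis date, src key, reg tumour id)
    for src_key, rec in source_tumours.items():
        link = matches.get(rec.person_id)
        if link is None:
            continue
        reg_pid, _level = link
        for reg in registry_by_person.get(reg_pid, []):
            if _site_group(reg.icd10_site) != _site_group(rec.icd10_site):
                continue
            delta = abs((rec.diagnosis_date - reg.diagnosis_date).days)
            if delta <= window_days:
                candidates.append((delta, rec.diagnosis_date,
                                   reg.diagnosis_date, src_key, reg.tumour_id))
    # nearest date first; among equal gaps the earlier source record, then
    # the earlier registry tumour, wins
    candidates.sort(key=lambda t: (t[0], t[1], t[2], str(t[3])))
    assignment: dict = {}
    taken_registry: set = set()
    for _delta, _sd, _rd, src_key, reg_tid in candidates:
        if src_key in assignment or reg_tid in taken_registry:
            continue
        assignment[src_key] = reg_tid
        taken_registry.add(reg_tid)
    return assignment


def link_tumours(registry_records, central_records, audit_records,
                 hierarchy: LinkHierarchy | None = None,
                 window_days: int = DEFAULT_DATE_WINDOW_DAYS):
    """Build one :class:`TumourBundle` per registry tumour.

    Patient matches are established per source; within each matched
    patient, a source tumour joins the registry tumour of the same site
    group whose diagnosis date is nearest within ``window_days`` (ties
    towards the earlier source record).  No source tumour joins two
    bundles; one registry tumour takes at most one central tumour and the
    treatment records of at most one audit tumour.

    Returns ``(bundles, report)``.
    """
    central_matches, central_rep = link_patients(registry_records,
                                                 central_records, hierarchy)
    audit_matches, audit_rep = link_patients(registry_records, audit_records,
                                             hierarchy)

    registry_by_person: dict[str, list] = {}
    for rec in registry_records:
        registry_by_person.setdefault(rec.person_id, []).append(rec)

    central_tumours = {(r.person_id, r.tumour_id): r for r in central_records}
    audit_tumours: dict[tuple, list] = {}
    for r in audit_records:
        audit_tumours.setdefault((r.person_id, r.tumour_id), []).append(r)
    audit_heads = {k: recs[0] for k, recs in audit_tumours.items()}

    central_assign = _assign_tumours(registry_by_person, central_tumours,
                                     central_matches, window_days)
    audit_assign = _assign_tumours(registry_by_person, audit_heads,
                                   audit_matches, window_days)

    central_by_reg = {reg: central_tumours[key]
                      for key, reg in central_assign.items()}
    audit_by_reg = {reg: tuple(audit_tumours[key])
                    for key, reg in audit_assign.items()}

    bundles = []
    for rec in registry_records:
        levels = {}
        central = central_by_reg.get(rec.tumour_id)
        if central is not None:
            levels["central"] = central_matches[central.person_id][1]
        audit = audit_by_reg.get(rec.tumour_id, ())
        if audit:
            levels["audit"] = audit_matches[audit[0].person_id][1]
        bundles.append(TumourBundle(registry=rec, central=central,
                                    audit=audit, link_level=levels or None))

    report = LinkageReport(
        unmatched_patients=sorted(
            {("central", p) for p in central_rep.unmatched_patients}
            | {("audit", p) for p in audit_rep.unmatched_patients}),
        unbundled_tumours=sorted(
            [("central",) + k for k in central_tumours
             if k not in central_assign]
            + [("audit",) + k for k in audit_tumours
               if k not in audit_assign]))
    return bundles, report
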