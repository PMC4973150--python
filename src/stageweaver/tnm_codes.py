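"""Parsing, validation and ordinal ranking of raw TNM and Dukes codes.

Raw staging codes arriving from registries, central cancer databases and
clinical audits are heterogeneous: blank cells, bare categories ("4a"),
prefixed categories ("pT4a"), legacy not-assessable codes ("Mx"), and codes
that are only valid under a particular edition of the TNM classification.
This module is the single point of truth for what a code means.

Key conventions
---------------
* ``X`` categories (TX/NX/MX, or a bare "x") mean "could not be assessed"
  and are returned as *not assessed*, never as valid values.  Mx was
  abolished in the Seventh Edition but remains common in routine data.
* A pathological ``M0`` (pM0) does not exist as a category: absence of
  distant metastasis generally cannot be established pathologically after
  resection of the primary tumour.  It is suppressed to *not assessed*.
* Validity is checked against closed per-(site, edition) code tables shipped
  as a CSV resource, so additional sites or editions are additive data
  changes.  A code valid in some edition for the site but not the declared
  one is rejected with an ``edition_conflict`` flag (optionally accepted
  when validating against the union of editions).
* ``ordinal_rank`` gives the total order used by "lowest category wins"
  rules; an unsuffixed code ranks immediately below its own "a" subcode
  (T2 < T2a < T2b).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from importlib import resources as _ilr

logger = logging.getLogger(__name__)

COMPONENTS = ("T", "N", "M")
BASES = ("clinical", "pathological", "integrated")
EDITIONS = ("5th", "6th", "7th")

VALID = "valid"
NOT_ASSESSED = "not_assessed"
INVALID = "invalid"


@dataclass(frozen=True)
class TNMValue:
    """One validated staging datum for a single component."""

    component: str  # T | N | M
    basis: str  # clinical | pathological | integrated
    category: str  # canonical code, e.g. "T4a"
    edition: str  # 5th | 6th | 7th | unknown
    site: str
    assessed: bool = True


@dataclass(frozen=True)
class ParseResult:
    status: str  # valid | not_assessed | invalid
    value: TNMValue | None = None
    reason: str | None = None
    edition_conflict: bool = False

    @property
    def is_valid(self) -> bool:
        return self.status == VALID


@dataclass(frozen=True)
class DukesValue:
    category: str  # A | B | C | D
    basis: str = "pathological"


def _load_code_tables() -> dict[tuple[str, str, str], dict[str, int]]:
    tables: dict[tuple[str, str, str], dict[str, int]] = {}
    ref = _ilr.files("stageweaver.resources").joinpath("valid_codes.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["site"], row["edition"], row["component"])
            tables.setdefault(key, {})[row["code"]] = int(row["rank"])
    return tables


_CODE_TABLES = _load_code_tables()


def sites() -> set[str]:
    return {site for site, _, _ in _CODE_TABLES}


def editions_for_site(site: str) -> set[str]:
    return {ed for s, ed, _ in _CODE_TABLES if s == site}


def valid_codes(site: str, edition: str, component: str) -> dict[str, int]:
    """Closed {canonical code: rank} table for one (site, edition, component)."""
    try:
        return dict(_CODE_TABLES[(site, edition, component)])
    except KeyError:
        raise KeyError(f"no code table for site={site!r} edition={edition!r} "
                       f"component={component!r}") from None


def _union_codes(site: str, component: str) -> set[str]:
    out: set[str] = set()
    for (s, _, c), table in _CODE_TABLES.items():
        if s == site and c == component:
            out.update(table)
    return out


_CODE_RE = re.compile(
    r"^(?P<prefix>[cpiy]?)(?P<letter>[tnm]?)(?P<body>is|x|[0-9](?:[a-c])?)$",
    re.IGNORECASE,
)


def parse_code(raw: object, component: str, basis: str, site: str,
               edition: str, accept_union: bool = False) -> ParseResult:
    """Canonicalise and validate one raw staging code.

    Never raises on data content: returns a ``ParseResult`` whose status is
    ``valid``, ``not_assessed`` (blank, X categories, suppressed pM0) or
    ``invalid`` (with a reason).  ``edition='unknown'`` validates against
    the union of editions shipped for the site.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if raw is None:
        return ParseResult(NOT_ASSESSED, reason="blank")
    text = str(raw).strip()
    if text == "" or text.lower() in {"na", "nan", "none", "unknown", "."}:
        return ParseResult(NOT_ASSESSED, reason="blank")

    m = _CODE_RE.match(text.replace(" ", ""))
    if m is None:
        return ParseResult(INVALID, reason=f"unrecognised code {text!r}")
    letter = m.group("letter").upper()
    if letter and letter != component:
        return ParseResult(INVALID,
                           reason=f"code {text!r} names component {letter}, "
                                  f"expected {component}")
    body = m.group("body").lower()
    if body == "x":
        return ParseResult(NOT_ASSESSED, reason="not assessable (X)")
    if body == "is":
        if component != "T":
            return ParseResult(INVALID, reason=f"'is' invalid for {component}")
        canonical = "Tis"
    else:
        canonical = f"{component}{body}"

    if component == "M" and basis == "pathological" and canonical == "M0":
        # pM0 cannot generally be established; suppressed, not an M value
        return ParseResult(NOT_ASSESSED, reason="pM0 suppressed")

    if edition == "unknown":
        if canonical in _union_codes(site, component):
            return ParseResult(VALID, TNMValue(component, basis, canonical,
                                               "unknown", site))
        return ParseResult(INVALID, reason=f"{canonical} unknown for {site}")

    table = valid_codes(site, edition, component)
    if canonical in table:
        return ParseResult(VALID, TNMValue(component, basis, canonical,
                                           edition, site))
    if canonical in _union_codes(site, component):
        # e.g. a Seventh-Edition-only subcode arriving in data declared Fifth
        logger.warning("classification conflict: %s not valid for %s %s "
                       "edition", canonical, site, edition)
        if accept_union:
            return ParseResult(VALID, TNMValue(component, basis, canonical,
                                               edition, site),
                               edition_conflict=True)
        return ParseResult(INVALID,
                           reason=f"{canonical} not valid under {edition} "
                                  f"edition for {site}",
                           edition_conflict=True)
    return ParseResult(INVALID, reason=f"{canonical} unknown for {site}")


def ordinal_rank(value: TNMValue) -> int:
    """Position of the category in the component's total order (0 = lowest)."""
    if not value.assessed:
        raise ValueError("not-assessed categories have no ordinal rank")
    edition = value.edition
    if edition == "unknown":
        # rank within the richest shipped edition that knows the code
        for ed in reversed(EDITIONS):
            table = _CODE_TABLES.get((value.site, ed, value.component))
            if table and value.category in table:
                return table[value.category]
        raise KeyError(f"{value.category} unknown for {value.site}")
    return valid_codes(value.site, edition, value.component)[value.category]


def is_zero(value: TNMValue) -> bool:
    """True for the component's lowest (negative) category: T0, N0, M0."""
    return value.category in ("T0", "N0", "M0")


def is_positive(value: TNMValue) -> bool:
    """True for any assessed category above the zero category (Tis counts)."""
    return not is_zero(value)


_DUKES_RE = re.compile(r"^(?:dukes\s*)?(?P<cat>[abd]|c[12]?)$", re.IGNORECASE)


def parse_dukes(raw: object, basis: str = "pathological") -> DukesValue | None:
    """Parse a Dukes stage; C1/C2 collapse to C; ``None`` when invalid/blank."""
    if raw is None:
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in {"na", "nan", "none", "unknown", "."}:
        return None
    m = _DUKES_RE.match(text)
    if m is None:
        return None
    cat = m.group("cat").upper()[0]
    return DukesValue(category=cat, basis=basis)
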