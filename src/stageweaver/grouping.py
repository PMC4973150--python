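"""Part 2 of the staging algorithm: grouped stage I-IV from resolved T/N/M.

Stage grouping evaluates components in the order M → N → T: distant
metastasis (any M1) is stage IV regardless of T and N; for colorectal any
node-positive tumour without distant metastasis is stage III regardless of
T; remaining stages follow the edition's grouping truth table (shipped as
a CSV resource; sub-stages IA/IIB/... collapsed to their numerals).

Two strategies handle missing components:

* ``restrictive``      — all three components must be present and assessed,
  otherwise the stage is missing; grouped summary-stage variables are
  ignored because their T/N/M basis cannot be verified.
* ``non_restrictive``  — missing N and/or M are interpreted as N0/M0 and the
  tumour graded from the remaining information; if the components still
  cannot be graded the algorithm falls back to summary-stage variables
  (audit pathological, audit clinical, central pathological, clinical,
  integrated) and finally, for colorectal, to the Dukes classification.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources as _ilr

from .derivation import DerivedTNM, SiteConfig
from .records_io import TumourBundle
from .tnm_codes import DukesValue, parse_dukes

RESTRICTIVE = "restrictive"
NON_RESTRICTIVE = "non_restrictive"
STRATEGIES = (RESTRICTIVE, NON_RESTRICTIVE)

MISSING = "missing"
STAGES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class StageResult:
    stage: str  # I | II | III | IV | missing
    strategy: str
    path: str  # components | components-with-imputed-zeros |
    #            summary-stage(source,basis) | dukes(source,basis) | missing
    imputed: frozenset = field(default_factory=frozenset)  # subset of {N->0, M->0}

    def __post_init__(self):
        if self.path == "components" and self.imputed:
            raise ValueError("components path cannot carry imputations")
        if self.strategy == RESTRICTIVE and not (
                self.path in ("components", MISSING)):
            raise ValueError("restrictive strategy admits only the "
                             "components path")


class GroupingTable:
    """Total (T, N, M) → stage mapping for one site and edition."""

    def __init__(self, site: str, edition: str, mapping: dict):
        self.site = site
        self.edition = edition
        self.mapping = mapping  # (T, N, M) -> "I".."IV" | None

    def stage_of(self, t: str, n: str, m: str) -> str | None:
        try:
            return self.mapping[(t, n, m)]
        except KeyError:
            raise KeyError(f"({t}, {n}, {m}) outside the {self.site} "
                           f"{self.edition} grouping table") from None

    @property
    def categories(self):
        ts = {k[0] for k in self.mapping}
        ns = {k[1] for k in self.mapping}
        ms = {k[2] for k in self.mapping}
        return ts, ns, ms


def _load_grouping_tables() -> dict:
    tables: dict[tuple[str, str], dict] = {}
    ref = _ilr.files("stageweaver.resources").joinpath("grouping_tables.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["site"], row["edition"])
            tables.setdefault(key, {})[(row["t"], row["n"], row["m"])] = \
                row["stage"] or None
    return {key: GroupingTable(site, ed, mapping)
            for (site, ed), mapping in tables.items()
            for key in [(site, ed)]}


_GROUPING_TABLES = _load_grouping_tables()


def grouping_table(site: str, edition: str) -> GroupingTable:
    if edition == "unknown":
        # grade under the richest shipped edition that covers the codes
        candidates = sorted(ed for s, ed in _GROUPING_TABLES if s == site)
        edition = candidates[-1]
    try:
        return _GROUPING_TABLES[(site, edition)]
    except KeyError:
        raise KeyError(f"no grouping table for {site} {edition}") from None


def group_from_components(derived: DerivedTNM, strategy: str,
                          table: GroupingTable | None = None,
                          dominance_relaxation: bool = False) -> StageResult:
    """Grade the resolved components under one strategy.

    Under ``restrictive`` all three components must be present; with the
    optional ``dominance_relaxation`` (off by default) an assessed M1 alone
    still grades stage IV.  Under ``non_restrictive`` missing N/M are
    imputed to N0/M0 (every applied imputation recorded in ``imputed``),
    and a tumour whose T remains missing is graded when the
    node/metastasis dominance already fixes the stage (metastatic disease;
    colorectal node-positive), else left missing on this path.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if table is None:
        table = grouping_table(derived.site, derived.edition)
    t, n, m = derived.T.category, derived.N.category, derived.M.category

    if strategy == RESTRICTIVE:
        if t is None or n is None or m is None:
            if dominance_relaxation and m is not None and m != "M0":
                return StageResult("IV", strategy, "components")
            return StageResult(MISSING, strategy, MISSING)
        stage = table.stage_of(t, n, m)
        if stage is None:
            return StageResult(MISSING, strategy, MISSING)
        return StageResult(stage, strategy, "components")

    imputed = set()
    if n is None:
        n = "N0"
        imputed.add("N->0")
    if m is None:
        m = "M0"
        imputed.add("M->0")
    if t is not None:
        stage = table.stage_of(t, n, m)
    elif m != "M0":
        stage = "IV"  # metastatic disease dominates regardless of T
    elif _node_dominates(derived.site, n):
        stage = "III"
    else:
        stage = None
    if stage is None:
        return StageResult(MISSING, strategy, MISSING)
    used = frozenset(imputed)
    path = "components-with-imputed-zeros" if used else "components"
    return StageResult(stage, strategy, path, imputed=used)


def _node_dominates(site: str, n: str) -> bool:
    """Nodal categories that fix stage III regardless of T (given M0):
    any node-positive disease for colorectal; mediastinal/supraclavicular
    involvement (N2/N3) for lung, where N1 still needs T."""
    if site == "colorectal":
        return n != "N0"
    return n in ("N2", "N3")


def map_dukes_to_stage(dukes: DukesValue) -> str:
    """Standard Dukes/TNM correspondence: A→I, B→II, C→III, D→IV."""
    try:
        return {"A": "I", "B": "II", "C": "III", "D": "IV"}[dukes.category]
    except KeyError:
        raise ValueError(f"invalid Dukes category {dukes.category!r}") from None


_SUMMARY_RE = re.compile(
    r"^(?:stage)?(?P<num>IV|III|II|I|[1-4])(?P<sub>[A-C]?)$", re.IGNORECASE)

_ARABIC = {"1": "I", "2": "II", "3": "III", "4": "IV"}


def parse_summary_stage(raw: object) -> str | None:
    """Parse a grouped-stage text to I-IV; sub-stages collapse; else None.

    '0' / in-situ stages are not usable for a malignant-tumour cohort.
    """
    if raw is None:
        return None
    text = str(raw).strip()
    if not text:
        return None
    m = _SUMMARY_RE.match(text.upper().replace(" ", ""))
    if m is None:
        return None
    num = m.group("num")
    return _ARABIC.get(num, num)


def _fallback_steps(bundle: TumourBundle):
    """Summary-stage then Dukes variables in fallback priority order."""
    audit = bundle.audit
    central = bundle.central

    def audit_first(attr):
        for rec in audit:
            v = getattr(rec, attr, None)
            if v is not None:
                return v
        return None

    yield ("summary-stage", "audit", "pathological", audit_first("pStage"))
    yield ("summary-stage", "audit", "clinical", audit_first("cStage"))
    if central is not None:
        yield ("summary-stage", "central", "pathological", central.pStage)
        yield ("summary-stage", "central", "clinical", central.cStage)
        yield ("summary-stage", "central", "integrated", central.iStage)
    yield ("dukes", "audit", "pathological", audit_first("dukes_p"))
    yield ("dukes", "audit", "clinical", audit_first("dukes_c"))
    if central is not None:
        yield ("dukes", "central", "unspecified", central.dukes)


def apply_fallbacks(derived: DerivedTNM, bundle: TumourBundle,
                    strategy: str) -> StageResult:
    """Stage from summary-stage/Dukes variables when components failed.

    The restrictive strategy ignores grouped-stage variables entirely.
    """
    if strategy == RESTRICTIVE:
        return StageResult(MISSING, strategy, MISSING)
    for kind, source, basis, raw in _fallback_steps(bundle):
        if raw is None:
            continue
        if kind == "summary-stage":
            stage = parse_summary_stage(raw)
        else:
            dukes = parse_dukes(raw, basis if basis != "unspecified"
                                else "pathological")
            stage = None if dukes is None else map_dukes_to_stage(dukes)
        if stage is not None:
            return StageResult(stage, strategy, f"{kind}({source},{basis})")
    return StageResult(MISSING, strategy, MISSING)


def stage_tumour(derived: DerivedTNM, bundle: TumourBundle, strategy: str,
                 table: GroupingTable | None = None) -> StageResult:
    """Full part-2 grading: components first, then strategy-specific fallbacks."""
    result = group_from_components(derived, strategy, table)
    if result.stage != MISSING:
        return result
    return apply_fallbacks(derived, bundle, strategy)
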