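"""Part 1 of the staging algorithm: resolve one overall T, N and M per tumour.

Each component is resolved by walking a prioritised chain of source
variables (shipped as the ``chains.yaml`` resource).  Pathological variables
outrank clinical ones for T and N; for M the clinical value is preferred
because distant metastasis is rarely evaluable at resection of the primary,
with one exception: a pathologically confirmed M1 from any source overrides
an earlier clinical M0.  "Integrated" registry variables of undocumented
origin sit last.  Evidence-type variables (serosal involvement, MRI
results, node counts, organ metastasis flags, liver CT) may *impose* a
positive category when the running value is missing or zero, but negative
or unknown evidence never sets a zero and never stops the walk.

For colorectal tumours a single tumour may carry several audit treatment
records with conflicting pathological codes; only records dated within ±30
days of diagnosis contribute pathological information, nearest-first, with
equal-dated ties broken towards the lowest TNM categories, and later
records consulted per variable only where earlier ones are missing.

If M is still missing after the whole chain but there is indirect evidence
of a clinical examination — information on both clinical T and clinical N —
M is assumed to be M0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from importlib import resources as _ilr

import yaml

from . import tnm_codes
from .records_io import AuditTreatmentRecord, TumourBundle
from .tnm_codes import ParseResult, TNMValue, is_positive, ordinal_rank, parse_code

logger = logging.getLogger(__name__)

AUDIT_WINDOW_DAYS = 30  # eligibility window for pathological audit data

RULE_DIRECT = "direct"
RULE_EVIDENCE = "positive-evidence"
RULE_PM1_OVERRIDE = "pathological-confirmation"
RULE_CLINICAL_EXAM = "clinical examination"


@dataclass(frozen=True)
class ChainStep:
    source: str  # audit | central | derived
    variable: str
    kind: str  # direct | positive-evidence | inference
    basis: str  # clinical | pathological | integrated
    evidence: str | None = None  # t4 | m1 | n1_count | identity


@dataclass(frozen=True)
class PriorityChain:
    component: str
    steps: tuple  # of ChainStep

    def __post_init__(self):
        if not any(s.kind == "direct" for s in self.steps):
            raise ValueError(f"{self.component} chain has no direct step")


@dataclass(frozen=True)
class Provenance:
    source: str
    variable: str
    step: int  # 1-based position in the chain
    rule: str


@dataclass(frozen=True)
class DerivedComponent:
    component: str
    category: str | None
    provenance: Provenance | None
    zero_upgraded: bool = False

    def __post_init__(self):
        if (self.category is None) != (self.provenance is None):
            raise ValueError("category and provenance must be jointly "
                             "present or jointly absent")


@dataclass(frozen=True)
class DerivedTNM:
    tumour_id: str
    site: str
    edition: str
    T: DerivedComponent
    N: DerivedComponent
    M: DerivedComponent

    def component(self, name: str) -> DerivedComponent:
        return {"T": self.T, "N": self.N, "M": self.M}[name]


@dataclass(frozen=True)
class SiteConfig:
    site: str
    default_edition: str
    chains: dict  # component -> PriorityChain
    accept_union: bool = False
    m0_inference: str = "presence"  # presence | selected


def load_site_config(site: str, accept_union: bool = False,
                     m0_inference: str = "presence") -> SiteConfig:
    """Load the shipped priority-chain configuration for a site."""
    ref = _ilr.files("stageweaver.resources").joinpath("chains.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if site not in cfg:
        raise KeyError(f"no chain configuration for site {site!r}")
    entry = cfg[site]
    chains = {}
    for comp in ("T", "N", "M"):
        steps = tuple(ChainStep(source=s["source"], variable=s["variable"],
                                kind=s["kind"], basis=s["basis"],
                                evidence=s.get("evidence"))
                      for s in entry[comp])
        chains[comp] = PriorityChain(component=comp, steps=steps)
    return SiteConfig(site=site, default_edition=str(entry["default_edition"]),
                      chains=chains, accept_union=accept_union,
                      m0_inference=m0_inference)


# --------------------------------------------------------------------------
# audit treatment-record selection
# --------------------------------------------------------------------------

def _pathological_rank_sum(rec: AuditTreatmentRecord, site: str,
                           edition: str) -> int:
    """Tie-break key: sum of ordinal ranks of present pT/pN/pM, missing last."""
    missing_penalty = 1000
    total = 0
    for comp, raw in (("T", rec.pT), ("N", rec.pN), ("M", rec.pM)):
        pr = parse_code(raw, comp, "pathological", site, edition)
        if pr.is_valid:
            total += ordinal_rank(pr.value)
        else:
            total += missing_penalty
    return total


def select_audit_records(records, diagnosis_date: date, site: str,
                         edition: str,
                         window_days: int = AUDIT_WINDOW_DAYS) -> list:
    """Order the treatment records eligible to contribute pathological data.

    Records with a procedure date within ``window_days`` (inclusive) of
    diagnosis are kept, nearest-first; equal-dated records are ordered by
    ascending total TNM rank (lowest categories first).  Records without a
    procedure date are excluded (they cannot be placed relative to
    diagnosis, so they never contribute pathological information).
    """
    eligible = []
    for idx, rec in enumerate(records):
        if rec.procedure_date is None:
            continue
        delta = abs((rec.procedure_date - diagnosis_date).days)
        if delta <= window_days:
            eligible.append((delta, rec, idx))
    eligible.sort(key=lambda t: (t[0],
                                 _pathological_rank_sum(t[1], site, edition),
                                 t[2]))
    return [rec for _, rec, _ in eligible]


# --------------------------------------------------------------------------
# variable accessors
# --------------------------------------------------------------------------

class BundleContext:
    """Resolves (source, variable) chain references against one bundle.

    Pathological audit variables (pT/pN/pM, serosal involvement, node
    counts) are read from the date-eligible treatment records only;
    clinical codes and diagnostic-investigation variables (MRI, liver CT,
    metastasis flags) are read across all treatment records, eligible ones
    first.
    """

    _AUDIT_PATHOLOGICAL = {"pT", "pN", "pM",
                           "serosal_involvement_or_perforation",
                           "positive_node_count"}

    def __init__(self, bundle: TumourBundle, config: SiteConfig,
                 edition: str):
        self.bundle = bundle
        self.config = config
        self.edition = edition
        self.eligible = select_audit_records(
            bundle.audit, bundle.registry.diagnosis_date, config.site, edition)
        in_eligible = {id(r) for r in self.eligible}
        self.all_ordered = self.eligible + [r for r in bundle.audit
                                            if id(r) not in in_eligible]

    def _audit_records_for(self, variable: str) -> list:
        if variable in self._AUDIT_PATHOLOGICAL:
            return self.eligible
        return self.all_ordered

    def direct_value(self, step: ChainStep, component: str) -> ParseResult:
        """First valid, assessed code for a direct chain step."""
        site, ed, union = self.config.site, self.edition, self.config.accept_union
        if step.source == "central":
            if self.bundle.central is None:
                return ParseResult(tnm_codes.NOT_ASSESSED, reason="no record")
            raw = getattr(self.bundle.central, step.variable)
            return parse_code(raw, component, step.basis, site, ed,
                              accept_union=union)
        best = ParseResult(tnm_codes.NOT_ASSESSED, reason="no record")
        for rec in self._audit_records_for(step.variable):
            pr = parse_code(getattr(rec, step.variable), component, step.basis,
                            site, ed, accept_union=union)
            if pr.is_valid:
                return pr
            if pr.status == tnm_codes.INVALID and best.status != tnm_codes.INVALID:
                best = pr
        return best

    def evidence_value(self, step: ChainStep, component: str) -> TNMValue | None:
        """Positive category imposed by an evidence step, or None."""
        site, ed = self.config.site, self.edition
        mapping = step.evidence
        if mapping == "t4":
            for rec in self._audit_records_for(step.variable):
                if getattr(rec, step.variable) == "positive":
                    return TNMValue("T", step.basis, "T4", ed, site)
            return None
        if mapping == "m1":
            for rec in self._audit_records_for(step.variable):
                v = getattr(rec, step.variable)
                positive = bool(v) if isinstance(v, frozenset) else v == "positive"
                if positive:
                    return TNMValue("M", step.basis, "M1", ed, site)
            return None
        if mapping == "n1_count":
            if step.source == "central":
                counts = [] if self.bundle.central is None else \
                    [self.bundle.central.positive_node_count]
            else:
                counts = [r.positive_node_count
                          for r in self._audit_records_for(step.variable)]
            if any(c is not None and c > 0 for c in counts):
                # counts cannot separate node-positive categories; lowest wins
                return TNMValue("N", step.basis, "N1", ed, site)
            return None
        if mapping == "identity":
            for rec in self._audit_records_for(step.variable):
                pr = parse_code(getattr(rec, step.variable), component,
                                step.basis, site, ed,
                                accept_union=self.config.accept_union)
                if pr.is_valid and is_positive(pr.value):
                    return pr.value
            return None
        raise ValueError(f"unknown evidence mapping {mapping!r} "
                         f"for variable {step.variable!r}")

    def has_clinical(self, component: str) -> bool:
        """Any valid, assessed clinical-basis code for the component?"""
        chain = self.config.chains[component]
        for step in chain.steps:
            if step.kind == "direct" and step.basis == "clinical":
                if self.direct_value(step, component).is_valid:
                    return True
        return False


# --------------------------------------------------------------------------
# chain walk
# --------------------------------------------------------------------------

def resolve_component(bundle: TumourBundle, chain: PriorityChain,
                      ctx: BundleContext) -> DerivedComponent:
    """Walk one priority chain and fix the component with provenance.

    A direct step with a valid assessed code populates the component, after
    which later direct steps are ignored, except that for M a pathological
    M1 overrides a clinical M0.  Positive-evidence steps act only while the
    running value is missing or zero, and only on positive evidence.
    """
    comp = chain.component
    running: TNMValue | None = None
    prov: Provenance | None = None
    zero_upgraded = False

    for idx, step in enumerate(chain.steps, start=1):
        if step.kind == "inference":
            continue  # applied afterwards by infer_m0_from_clinical_exam
        if step.kind == "direct":
            pr = ctx.direct_value(step, comp)
            if not pr.is_valid:
                continue
            if running is None:
                running = pr.value
                prov = Provenance(step.source, step.variable, idx, RULE_DIRECT)
            elif (comp == "M" and running.category == "M0"
                  and running.basis == "clinical"
                  and step.basis == "pathological"
                  and is_positive(pr.value)):
                running = pr.value
                prov = Provenance(step.source, step.variable, idx,
                                  RULE_PM1_OVERRIDE)
        elif step.kind == "positive-evidence":
            if running is not None and is_positive(running):
                continue
            value = ctx.evidence_value(step, comp)
            if value is None:
                continue
            zero_upgraded = running is not None  # replaced an explicit zero
            running = value
            prov = Provenance(step.source, step.variable, idx, RULE_EVIDENCE)
        else:
            raise ValueError(f"unknown step kind {step.kind!r}")

    if running is None:
        return DerivedComponent(comp, None, None)
    return DerivedComponent(comp, running.category, prov,
                            zero_upgraded=zero_upgraded)


def infer_m0_from_clinical_exam(derived: DerivedTNM,
                                ctx: BundleContext) -> DerivedTNM:
    """Assume M0 when M is missing but a clinical examination is evidenced.

    Indirect evidence of a clinical examination means information on *both*
    clinical T and clinical N.  In the default ``presence`` mode any valid
    clinical-basis T and N codes anywhere in the bundle qualify; in
    ``selected`` mode the resolved T and N must themselves have come from
    clinical-basis variables.
    """
    if derived.M.category is not None:
        return derived
    if ctx.config.m0_inference == "selected":
        def from_clinical(c: DerivedComponent) -> bool:
            if c.provenance is None:
                return False
            chain = ctx.config.chains[c.component]
            return chain.steps[c.provenance.step - 1].basis == "clinical"
        ok = from_clinical(derived.T) and from_clinical(derived.N)
    else:
        ok = ctx.has_clinical("T") and ctx.has_clinical("N")
    if not ok:
        return derived
    chain = ctx.config.chains["M"]
    idx = next((i for i, s in enumerate(chain.steps, start=1)
                if s.kind == "inference"), len(chain.steps))
    m = DerivedComponent("M", "M0",
                         Provenance("derived", "clinical_examination", idx,
                                    RULE_CLINICAL_EXAM))
    return DerivedTNM(derived.tumour_id, derived.site, derived.edition,
                      derived.T, derived.N, m)


_EDITION_FLAGS = {"5": "5th", "5th": "5th", "6": "6th", "6th": "6th",
                  "7": "7th", "7th": "7th"}


def edition_for_bundle(bundle: TumourBundle, config: SiteConfig) -> str:
    """Per-tumour TNM edition: the audit's edition flag when present."""
    for rec in bundle.audit:
        flag = rec.tnm_edition_flag
        if flag is not None:
            ed = _EDITION_FLAGS.get(str(flag).strip().lower())
            if ed is not None and ed in tnm_codes.editions_for_site(config.site):
                return ed
            logger.warning("tumour %s: unrecognised TNM edition flag %r; "
                           "using site default %s", bundle.registry.tumour_id,
                           flag, config.default_edition)
            break
    return config.default_edition


def derive_tnm(bundle: TumourBundle, config: SiteConfig) -> DerivedTNM:
    """Resolve the full T/N/M triple for one tumour, with provenance."""
    edition = edition_for_bundle(bundle, config)
    ctx = BundleContext(bundle, config, edition)
    comps = {comp: resolve_component(bundle, config.chains[comp], ctx)
             for comp in ("T", "N", "M")}
    derived = DerivedTNM(tumour_id=bundle.registry.tumour_id,
                         site=config.site, edition=edition,
                         T=comps["T"], N=comps["N"], M=comps["M"])
    derived = infer_m0_from_clinical_exam(derived, ctx)
    for comp in ("T", "N", "M"):
        c = derived.component(comp)
        if c.provenance is not None:
            logger.debug("tumour %s %s=%s from %s.%s (step %d, %s)",
                         derived.tumour_id, comp, c.category,
                         c.provenance.source, c.provenance.variable,
                         c.provenance.step, c.provenance.rule)
    return derived
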