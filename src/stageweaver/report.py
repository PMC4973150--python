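"""Cohort-level accounting tables: variable completeness/contribution and
stage distribution by year and strategy.

Percentages are printed to one decimal place, rounded half away from zero.
Completeness counts tumours with usable information in a variable;
contribution counts tumours whose *final* component came from it — the two
differ where positive evidence replaced an explicit zero (the zero is
complete in its own variable but the evidence variable contributes).
Conservation identities (contributions + missing = cohort; stage I-IV sum
to the observed count) are asserted on every run, not just in tests.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .derivation import BundleContext, SiteConfig, edition_for_bundle
from .grouping import MISSING, STAGES


def percent(count: float, denominator: float) -> float:
    """count/denominator as a percentage, 1 d.p., half away from zero."""
    if denominator == 0:
        return float("nan")
    ratio = Decimal(int(count)) * 100 / Decimal(int(denominator))
    sign = -1 if ratio < 0 else 1
    return sign * float(abs(ratio).quantize(Decimal("0.1"),
                                            rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# sources of valid components: completeness and contribution
# --------------------------------------------------------------------------

def _variable_complete(ctx: BundleContext, step, component) -> bool:
    """Does this bundle hold usable information in one chain variable?"""
    if step.kind == "direct" or step.evidence == "identity":
        return ctx.direct_value(step, component).is_valid
    records = (ctx._audit_records_for(step.variable)
               if step.source == "audit"
               else ([ctx.bundle.central] if ctx.bundle.central else []))
    if step.evidence == "t4":
        return any(getattr(r, step.variable) != "unknown" for r in records)
    if step.evidence == "m1":
        for r in records:
            v = getattr(r, step.variable)
            if (bool(v) if isinstance(v, frozenset) else v != "unknown"):
                return True
        return False
    if step.evidence == "n1_count":
        return any(getattr(r, step.variable) is not None for r in records)
    raise ValueError(f"unhandled step {step}")


def contribution_table(derived_list, bundles, config: SiteConfig) -> pd.DataFrame:
    """Per (component, source, variable): completeness and contribution.

    ``derived_list`` and ``bundles`` must be aligned (one entry per
    tumour).  Percentages are of the cohort size.
    """
    if not derived_list:
        raise ValueError("empty cohort")
    if len(derived_list) != len(bundles):
        raise ValueError("derived results and bundles are not aligned")
    n = len(derived_list)

    complete: dict[tuple, int] = {}
    contrib: dict[tuple, int] = {}
    missing = {comp: 0 for comp in ("T", "N", "M")}
    for derived, bundle in zip(derived_list, bundles):
        edition = derived.edition
        ctx = BundleContext(bundle, config, edition)
        for comp in ("T", "N", "M"):
            chain = config.chains[comp]
            for step in chain.steps:
                if step.kind == "inference":
                    continue
                key = (comp, step.source, step.variable)
                complete.setdefault(key, 0)
                if _variable_complete(ctx, step, comp):
                    complete[key] += 1
            c = derived.component(comp)
            if c.category is None:
                missing[comp] += 1
            else:
                key = (comp, c.provenance.source, c.provenance.variable)
                contrib[key] = contrib.get(key, 0) + 1

    rows = []
    for comp in ("T", "N", "M"):
        chain = config.chains[comp]
        total_contrib = 0
        for step in chain.steps:
            key = (comp, step.source, step.variable)
            if step.kind == "inference":
                c = contrib.get(key, 0)
                rows.append(dict(component=comp, source=step.source,
                                 variable=step.variable,
                                 completeness_count=None,
                                 completeness_pct=None,
                                 contribution_count=c,
                                 contribution_pct=percent(c, n)))
            else:
                c = contrib.get(key, 0)
                rows.append(dict(component=comp, source=step.source,
                                 variable=step.variable,
                                 completeness_count=complete[key],
                                 completeness_pct=percent(complete[key], n),
                                 contribution_count=c,
                                 contribution_pct=percent(c, n)))
            total_contrib += c
        rows.append(dict(component=comp, source="", variable="missing",
                         completeness_count=None, completeness_pct=None,
                         contribution_count=missing[comp],
                         contribution_pct=percent(missing[comp], n)))
        # conservation: every non-missing component has exactly one provenance
        assert total_contrib + missing[comp] == n, \
            f"{comp}: contributions {total_contrib} + missing " \
            f"{missing[comp]} != cohort {n}"
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stage distribution by year and strategy
# --------------------------------------------------------------------------

def distribution_table(results) -> pd.DataFrame:
    """Stage distribution table from ``(year, StageResult)`` pairs.

    Rows per (strategy, year incl. a pooled 'total'): missing and observed
    counts as percentages of the cohort, stage I-IV counts as percentages
    of the *observed* stage data.
    """
    results = list(results)
    if not results:
        raise ValueError("no stage results")
    frame = pd.DataFrame(
        [(str(year), r.strategy, r.stage) for year, r in results],
        columns=["year", "strategy", "stage"])
    years = sorted(frame["year"].unique()) + ["total"]
    rows = []
    for strategy in sorted(frame["strategy"].unique()):
        sub_all = frame[frame["strategy"] == strategy]
        for year in years:
            sub = sub_all if year == "total" else sub_all[sub_all["year"] == year]
            total = len(sub)
            observed = int((sub["stage"] != MISSING).sum())
            n_missing = total - observed
            rows.append(dict(strategy=strategy, year=year, row="missing",
                             count=n_missing, pct=percent(n_missing, total)))
            rows.append(dict(strategy=strategy, year=year, row="observed",
                             count=observed, pct=percent(observed, total)))
            stage_counts = {s: int((sub["stage"] == s).sum()) for s in STAGES}
            assert sum(stage_counts.values()) == observed, \
                "stage I-IV counts do not sum to the observed count"
            for s in STAGES:
                rows.append(dict(strategy=strategy, year=year, row=s,
                                 count=stage_counts[s],
                                 pct=percent(stage_counts[s], observed)))
            rows.append(dict(strategy=strategy, year=year, row="total",
                             count=total, pct=None))
    return pd.DataFrame(rows)
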