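"""End-to-end orchestration: link → derive → group → report → survival.

Driven by a YAML/JSON config that either names the four input CSVs or
embeds a ``simulate`` block for a synthetic cohort.  Every artefact is a
CSV under the output directory; a line-oriented log records one provenance
decision per derived component.
"""

from __future__ import annotations

import json
import logging
import os
from datetime import date

import pandas as pd
import yaml

from . import grouping, report, survival
from .derivation import derive_tnm, load_site_config
from .linkage import DEFAULT_DATE_WINDOW_DAYS, LinkHierarchy, link_tumours
from .records_io import LifeTable, read_source_table, write_derived_table
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    cfg = (json.loads(text) if str(path).endswith(".json")
           else yaml.safe_load(text))
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _strategies(cfg: dict):
    wanted = cfg.get("strategies", "both")
    if wanted in ("both", None):
        return list(grouping.STRATEGIES)
    if isinstance(wanted, str):
        wanted = [wanted]
    out = [w.replace("-", "_") for w in wanted]
    bad = set(out) - set(grouping.STRATEGIES)
    if bad:
        raise ConfigError(f"unknown strategy {sorted(bad)}")
    return out


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the full pipeline; returns a dict of artefact paths/frames.

    ``config`` is a mapping or a path to a YAML/JSON file.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    site = config.get("site")
    if site is None:
        raise ConfigError("config must name a site")
    out_dir = out_dir or config.get("out_dir") or "."
    os.makedirs(out_dir, exist_ok=True)
    strategies = _strategies(config)
    want_survival = "survival" in config

    life_table = None
    if "simulate" in config:
        sim = dict(config["simulate"])
        sim.setdefault("site", site)
        cohort = generate_cohort(CohortConfig(**sim), annotate=False)
        registry, central, audit = cohort.registry, cohort.central, cohort.audit
        life_table = cohort.life_table
    elif "inputs" in config:
        inputs = config["inputs"]
        for key in ("registry", "central", "audit"):
            if key not in inputs:
                raise ConfigError(f"inputs must name a {key} table")
        if want_survival and "life_table" not in inputs:
            raise ConfigError("survival requested but no life table supplied")
        registry = read_source_table(inputs["registry"], "registry", site)
        central = read_source_table(inputs["central"], "central", site)
        audit = read_source_table(inputs["audit"], "audit", site)
        if "life_table" in inputs:
            life_table = LifeTable.read(inputs["life_table"])
    else:
        raise ConfigError("config needs an 'inputs' or 'simulate' section")
    if want_survival and life_table is None:
        raise ConfigError("survival requested but no life table supplied")

    link_cfg = config.get("linkage", {})
    hierarchy = LinkHierarchy(tuple(tuple(lv) for lv in link_cfg["levels"])) \
        if "levels" in link_cfg else None
    bundles, link_report = link_tumours(
        registry, central, audit, hierarchy,
        window_days=link_cfg.get("window_days", DEFAULT_DATE_WINDOW_DAYS))

    site_config = load_site_config(
        site, accept_union=bool(config.get("accept_union", False)),
        m0_inference=config.get("m0_inference", "presence"))

    derived_list, results, log_lines = [], [], []
    for bundle in bundles:
        derived = derive_tnm(bundle, site_config)
        stages = {s: grouping.stage_tumour(derived, bundle, s)
                  for s in strategies}
        derived_list.append(derived)
        results.append((derived, stages))
        for comp in ("T", "N", "M"):
            c = derived.component(comp)
            if c.provenance is None:
                log_lines.append(f"{derived.tumour_id}\tderive\t{comp}=missing")
            else:
                log_lines.append(
                    f"{derived.tumour_id}\tderive\t{comp}={c.category}\t"
                    f"{c.provenance.source}.{c.provenance.variable}\t"
                    f"step={c.provenance.step}\t{c.provenance.rule}")
        for s, res in stages.items():
            log_lines.append(f"{derived.tumour_id}\tgroup\t{s}={res.stage}\t"
                             f"path={res.path}")

    artefacts = {}
    derived_path = os.path.join(out_dir, "derived_stage.csv")
    write_derived_table(results, derived_path)
    artefacts["derived"] = derived_path

    contribution = report.contribution_table(derived_list, bundles, site_config)
    contribution_path = os.path.join(out_dir, "contribution_table.csv")
    contribution.to_csv(contribution_path, index=False)
    artefacts["contribution"] = contribution_path

    year_of = {b.registry.tumour_id: b.registry.diagnosis_date.year
               for b in bundles}
    pairs = [(year_of[d.tumour_id], stages[s])
             for d, stages in results for s in stages]
    distribution = report.distribution_table(pairs)
    distribution_path = os.path.join(out_dir, "stage_distribution.csv")
    distribution.to_csv(distribution_path, index=False)
    artefacts["distribution"] = distribution_path

    residual_path = os.path.join(out_dir, "linkage_residuals.csv")
    pd.DataFrame({"unmatched": [repr(u) for u in
                                link_report.unmatched_patients]
                  + [repr(u) for u in link_report.unbundled_tumours]}
                 ).to_csv(residual_path, index=False)
    artefacts["linkage_residuals"] = residual_path

    if want_survival:
        surv_cfg = config["survival"] or {}
        horizons = tuple(float(h) for h in surv_cfg.get("horizons", (1, 5)))
        standardise = bool(surv_cfg.get("standardise", True))
        rows = []
        for strategy in strategies:
            subjects = []
            for bundle, (_, stages) in zip(bundles, results):
                reg = bundle.registry
                age = (reg.diagnosis_date - reg.birth_date).days / 365.25
                subjects.append(survival.SurvivalSubject(
                    follow_up_days=(reg.death_or_censor_date
                                    - reg.diagnosis_date).days,
                    event=reg.vital_status == "dead",
                    age=age, sex=reg.sex,
                    deprivation_quintile=reg.deprivation_quintile,
                    diagnosis_year=reg.diagnosis_date.year,
                    stage=stages[strategy].stage))
            estimates = survival.net_survival_by_stage(
                subjects, life_table, horizons, standardise=standardise)
            for stage, est in estimates.items():
                lo, hi = est.ci()
                for k, t in enumerate(est.times):
                    rows.append(dict(strategy=strategy, stage=stage,
                                     time_years=float(t),
                                     net_survival=float(est.survival[k]),
                                     variance=float(est.variance[k]),
                                     ci_low=float(lo[k]),
                                     ci_high=float(hi[k]),
                                     n=int(est.n_at_risk[k])))
        survival_path = os.path.join(out_dir, "net_survival.csv")
        pd.DataFrame(rows).to_csv(survival_path, index=False)
        artefacts["survival"] = survival_path

    log_path = os.path.join(out_dir, "pipeline_log.tsv")
    with open(log_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    artefacts["log"] = log_path
    return artefacts
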