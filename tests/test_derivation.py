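"""Chain walking, treatment-record selection, evidence rules and provenance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import DIAGNOSIS, make_audit, make_bundle, make_central
from stageweaver.derivation import (BundleContext, derive_tnm,
                                    edition_for_bundle,
                                    infer_m0_from_clinical_exam,
                                    load_site_config, select_audit_records)
from stageweaver.linkage import link_tumours
from stageweaver.synthetic import CohortConfig, generate_cohort


# --------------------------------------------------------------------------
# treatment-record selection
# --------------------------------------------------------------------------

def test_window_is_inclusive_of_day_30(colorectal_config):
    records = [make_audit(offset_days=d, pT="T2")
               for d in (-31, -30, 0, 30, 31)]
    kept = select_audit_records(records, DIAGNOSIS, "colorectal", "5th")
    assert [(r.procedure_date - DIAGNOSIS).days for r in kept] == [0, -30, 30]


def test_equal_dates_tie_broken_to_lowest_tnm(colorectal_config):
    high = make_audit(offset_days=5, pT="T3", pN="N1")
    low = make_audit(offset_days=5, pT="T2", pN="N0")
    kept = select_audit_records([high, low], DIAGNOSIS, "colorectal", "5th")
    assert kept[0] is low


def test_missing_component_ranks_last_in_tie(colorectal_config):
    partial = make_audit(offset_days=5, pT="T1")  # pN, pM missing
    complete = make_audit(offset_days=5, pT="T3", pN="N2", pM="M1")
    kept = select_audit_records([partial, complete], DIAGNOSIS,
                                "colorectal", "5th")
    assert kept[0] is complete


def test_undated_records_never_contribute_pathology(colorectal_config):
    undated = make_audit(pT="T4", procedure_date=None)
    kept = select_audit_records([undated], DIAGNOSIS, "colorectal", "5th")
    assert kept == []
    # ... but their clinical codes are still readable
    derived = derive_tnm(
        make_bundle(audit=[make_audit(cT="T2", procedure_date=None)]),
        colorectal_config)
    assert derived.T.category == "T2"
    assert derived.T.provenance.variable == "cT"


def test_later_record_fills_only_missing_variables(colorectal_config):
    """The nearest record fixes pT; its missing pN is taken from the next."""
    nearest = make_audit(offset_days=2, pT="T2")
    later = make_audit(offset_days=10, pT="T4", pN="N1")
    bundle = make_bundle(audit=[later, nearest])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.T.category == "T2"
    assert derived.N.category == "N1"
    assert derived.N.provenance.variable == "pN"


# --------------------------------------------------------------------------
# chain order and the documented exceptions
# --------------------------------------------------------------------------

def test_pathological_beats_clinical_for_t_and_n(colorectal_config):
    bundle = make_bundle(central=make_central(pT="T3", cT="T1", pN="N2",
                                              cN="N0"))
    derived = derive_tnm(bundle, colorectal_config)
    assert (derived.T.category, derived.N.category) == ("T3", "N2")
    assert derived.T.provenance.variable == "pT"


def test_audit_beats_central(colorectal_config):
    bundle = make_bundle(central=make_central(pT="T4"),
                         audit=[make_audit(pT="T1")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.T.provenance.source == "audit"
    assert derived.T.category == "T1"


def test_cm_prioritised_over_pm(colorectal_config):
    bundle = make_bundle(audit=[make_audit(cM="M0", pM="M1")])
    # pathological confirmation of metastasis overrides the clinical zero
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.category == "M1"
    assert derived.M.provenance.rule == "pathological-confirmation"

    # ... but a clinical M1 is simply taken at its own step
    bundle = make_bundle(audit=[make_audit(cM="M1", pM="M1")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.provenance.variable == "cM"
    assert derived.M.provenance.rule == "direct"


def test_pm1_override_reaches_across_sources(colorectal_config):
    bundle = make_bundle(audit=[make_audit(cM="M0")],
                         central=make_central(pM="M1"))
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.category == "M1"
    assert derived.M.provenance.source == "central"


def test_integrated_used_only_when_all_else_exhausted(colorectal_config):
    bundle = make_bundle(central=make_central(iT="T2", iN="N0", iM="M0"))
    derived = derive_tnm(bundle, colorectal_config)
    for comp, var in (("T", "iT"), ("N", "iN"), ("M", "iM")):
        c = derived.component(comp)
        assert c.provenance.variable == var
        assert c.provenance.rule == "direct"
    # any higher-priority variable displaces the integrated one
    bundle = make_bundle(central=make_central(iT="T2", cT="T3"))
    assert derive_tnm(bundle, colorectal_config).T.provenance.variable == "cT"


def test_empty_bundle_gives_all_missing(colorectal_config):
    derived = derive_tnm(make_bundle(), colorectal_config)
    assert all(derived.component(c).category is None for c in "TNM")


def test_lung_chain_from_audit_clinical_only(lung_config):
    bundle = make_bundle(site_code="C34",
                         audit=[make_audit(site_code="C34", cT="T2a",
                                           cN="N1", cM="M0",
                                           tnm_edition_flag="7")])
    derived = derive_tnm(bundle, lung_config)
    assert (derived.T.category, derived.N.category, derived.M.category) == \
        ("T2a", "N1", "M0")
    assert all(derived.component(c).provenance.source == "audit"
               for c in "TNM")
    assert derived.edition == "7th"


def test_lung_edition_flag_respected(lung_config):
    bundle = make_bundle(site_code="C34",
                         audit=[make_audit(site_code="C34", cT="T2",
                                           tnm_edition_flag="6")])
    assert edition_for_bundle(bundle, lung_config) == "6th"


# --------------------------------------------------------------------------
# positive-evidence rules
# --------------------------------------------------------------------------

def test_metastasis_flag_upgrades_missing_cm(colorectal_config):
    bundle = make_bundle(audit=[make_audit(
        distant_metastasis=frozenset({"liver"}))])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.category == "M1"
    assert derived.M.provenance.variable == "distant_metastasis"
    assert derived.M.provenance.rule == "positive-evidence"
    assert not derived.M.zero_upgraded  # nothing was zero, it was missing


def test_positive_evidence_replaces_explicit_zero(colorectal_config):
    bundle = make_bundle(audit=[make_audit(cM="M0", liver_ct="positive")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.category == "M1"
    assert derived.M.provenance.variable == "liver_ct"
    assert derived.M.zero_upgraded


def test_negative_evidence_never_sets_zero(colorectal_config):
    """No evidence of metastasis does not mean M0; the walk continues."""
    bundle = make_bundle(audit=[make_audit(liver_ct="negative")],
                         central=make_central(iM="M1"))
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.category == "M1"
    assert derived.M.provenance.variable == "iM"


def test_serosal_involvement_imposes_t4(colorectal_config):
    bundle = make_bundle(audit=[make_audit(
        serosal_involvement_or_perforation="positive")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.T.category == "T4"
    assert derived.T.provenance.variable == \
        "serosal_involvement_or_perforation"


def test_node_count_imposes_lowest_node_positive(colorectal_config):
    bundle = make_bundle(audit=[make_audit(positive_node_count=7)])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.N.category == "N1"  # counts cannot separate N1 from N2
    zero = make_bundle(audit=[make_audit(positive_node_count=0)])
    assert derive_tnm(zero, colorectal_config).N.category is None


def test_mri_identity_evidence(colorectal_config):
    bundle = make_bundle(audit=[make_audit(mri_T="T3", mri_N="N2")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.T.category == "T3"
    assert derived.N.category == "N2"
    assert derived.T.provenance.rule == "positive-evidence"


def test_evidence_never_downgrades(colorectal_config):
    """A positive direct value is never touched by later evidence steps."""
    bundle = make_bundle(audit=[make_audit(cM="M1", liver_ct="positive")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.provenance.variable == "cM"


# --------------------------------------------------------------------------
# the clinical-examination M0 inference
# --------------------------------------------------------------------------

def test_m0_inferred_when_ct_and_cn_present(colorectal_config):
    bundle = make_bundle(audit=[make_audit(cT="T2", cN="N1")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.category == "M0"
    assert derived.M.provenance.rule == "clinical examination"
    assert derived.M.provenance.variable == "clinical_examination"


def test_no_inference_without_clinical_t(colorectal_config):
    """Pathological T plus clinical N is not evidence of a full clinical
    examination: M stays missing."""
    bundle = make_bundle(audit=[make_audit(pT="T2", cN="N1")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.T.category == "T2"
    assert derived.M.category is None


def test_inference_requires_m_missing(colorectal_config):
    bundle = make_bundle(audit=[make_audit(cT="T2", cN="N1", cM="M1")])
    derived = derive_tnm(bundle, colorectal_config)
    assert derived.M.category == "M1"


def test_strict_mode_requires_selected_clinical_components():
    config = load_site_config("colorectal", m0_inference="selected")
    # T resolved pathologically although cT exists -> strict mode refuses
    bundle = make_bundle(audit=[make_audit(pT="T3", cT="T2", cN="N1")])
    derived = derive_tnm(bundle, config)
    assert derived.T.provenance.variable == "pT"
    assert derived.M.category is None
    # presence mode (default) accepts the same bundle
    default = load_site_config("colorectal")
    assert derive_tnm(bundle, default).M.category == "M0"


# --------------------------------------------------------------------------
# properties
# --------------------------------------------------------------------------

def test_derivation_is_deterministic(colorectal_config):
    cohort = generate_cohort(CohortConfig(n_tumours=60, seed=31),
                             annotate=False)
    bundles, _ = link_tumours(cohort.registry, cohort.central, cohort.audit)
    first = [derive_tnm(b, colorectal_config) for b in bundles]
    second = [derive_tnm(b, colorectal_config) for b in bundles]
    assert first == second


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), site=st.sampled_from(["colorectal",
                                                          "lung"]))
def test_provenance_matches_independent_walk(seed, site):
    """The full derivation agrees, tumour by tumour, with the generator's
    independent presence-walk over the chains (value and source), the
    clinical-examination inference being the only step the walk omits."""
    cohort = generate_cohort(CohortConfig(site=site, n_tumours=40, seed=seed))
    bundles, _ = link_tumours(cohort.registry, cohort.central, cohort.audit)
    config = load_site_config(site)
    truth = cohort.truth.set_index("tumour_id")
    for bundle in bundles:
        derived = derive_tnm(bundle, config)
        row = truth.loc[bundle.registry.tumour_id]
        for comp in "TNM":
            c = derived.component(comp)
            got_source = (f"{c.provenance.source}.{c.provenance.variable}"
                          if c.provenance else "")
            got_value = c.category or ""
            if got_source == "derived.clinical_examination":
                assert row[f"true_source_{comp}"] == ""
                continue
            assert got_source == row[f"true_source_{comp}"]
            assert got_value == row[f"expected_{comp}"]


def test_provenance_is_unique_per_resolved_component(colorectal_config):
    cohort = generate_cohort(CohortConfig(n_tumours=120, seed=33),
                             annotate=False)
    bundles, _ = link_tumours(cohort.registry, cohort.central, cohort.audit)
    for bundle in bundles:
        derived = derive_tnm(bundle, colorectal_config)
        for comp in "TNM":
            c = derived.component(comp)
            assert (c.category is None) == (c.provenance is None)
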