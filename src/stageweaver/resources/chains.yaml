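# Priority chains for resolving one overall T, N and M per tumour.
# Step order is priority order; the walk stops looking once a component is
# populated, except that (a) later positive-evidence steps may replace a
# zero-valued component and (b) a pathological M1 overrides a clinical M0.
# kinds: direct | positive-evidence | inference
# evidence mappings: t4 (positive -> T4), m1 (positive -> M1),
#                    n1_count (count > 0 -> N1), identity (valid code carried over)
colorectal:
  default_edition: "5th"
  T:
    - {source: audit,   variable: pT,                                kind: direct,            basis: pathological}
    - {source: audit,   variable: serosal_involvement_or_perforation, kind: positive-evidence, basis: pathological, evidence: t4}
    - {source: central, variable: pT,                                kind: direct,            basis: pathological}
    - {source: audit,   variable: cT,                                kind: direct,            basis: clinical}
    - {source: audit,   variable: mri_T,                             kind: positive-evidence, basis: clinical, evidence: identity}
    - {source: central, variable: cT,                                kind: direct,            basis: clinical}
    - {source: central, variable: iT,                                kind: direct,            basis: integrated}
  N:
    - {source: audit,   variable: pN,                                kind: direct,            basis: pathological}
    - {source: audit,   variable: positive_node_count,               kind: positive-evidence, basis: pathological, evidence: n1_count}
    - {source: central, variable: pN,                                kind: direct,            basis: pathological}
    - {source: central, variable: positive_node_count,               kind: positive-evidence, basis: pathological, evidence: n1_count}
    - {source: audit,   variable: cN,                                kind: direct,            basis: clinical}
    - {source: audit,   variable: mri_N,                             kind: positive-evidence, basis: clinical, evidence: identity}
    - {source: central, variable: cN,                                kind: direct,            basis: clinical}
    - {source: central, variable: iN,                                kind: direct,            basis: integrated}
  M:
    - {source: audit,   variable: cM,                                kind: direct,            basis: clinical}
    - {source: audit,   variable: distant_metastasis,                kind: positive-evidence, basis: clinical, evidence: m1}
    - {source: audit,   variable: liver_ct,                          kind: positive-evidence, basis: clinical, evidence: m1}
    - {source: central, variable: cM,                                kind: direct,            basis: clinical}
    - {source: audit,   variable: pM,                                kind: direct,            basis: pathological}
    - {source: central, variable: pM,                                kind: direct,            basis: pathological}
    - {source: central, variable: iM,                                kind: direct,            basis: integrated}
    - {source: derived, variable: clinical_examination,              kind: inference,         basis: clinical}
lung:
  default_edition: "7th"
  T:
    - {source: audit,   variable: pT,                                kind: direct,            basis: pathological}
    - {source: central, variable: pT,                                kind: direct,            basis: pathological}
    - {source: audit,   variable: cT,                                kind: direct,            basis: clinical}
    - {source: central, variable: cT,                                kind: direct,            basis: clinical}
    - {source: central, variable: iT,                                kind: direct,            basis: integrated}
  N:
    - {source: audit,   variable: pN,                                kind: direct,            basis: pathological}
    - {source: central, variable: pN,                                kind: direct,            basis: pathological}
    - {source: central, variable: positive_node_count,               kind: positive-evidence, basis: pathological, evidence: n1_count}
    - {source: audit,   variable: cN,                                kind: direct,            basis: clinical}
    - {source: central, variable: cN,                                kind: direct,            basis: clinical}
    - {source: central, variable: iN,                                kind: direct,            basis: integrated}
  M:
    - {source: audit,   variable: cM,                                kind: direct,            basis: clinical}
    - {source: central, variable: cM,                                kind: direct,            basis: clinical}
    - {source: audit,   variable: pM,                                kind: direct,            basis: pathological}
    - {source: central, variable: pM,                                kind: direct,            basis: pathological}
    - {source: central, variable: iM,                                kind: direct,            basis: integrated}
    - {source: derived, variable: clinical_examination,              kind: inference,         basis: clinical}
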