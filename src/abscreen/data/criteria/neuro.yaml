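# Screening-1 criteria for a systematic review of treatment effectiveness
# in hereditary peripheral neuropathies.
criteria:
  - key: disease
    instruction: >-
      If the condition studied was hereditary peripheral neuropathy
      confirmed genetically with known neuropathy genes or by pedigree
      where a significant proportion is genetically confirmed, then return
      true. Otherwise, return false.
  - key: treatment
    instruction: >-
      If the study focuses on pharmacological therapies or genotype-related
      dietary changes specifically targeting the neuropathy, return true.
      Nonpharmacological interventions such as physiotherapy, surgery, and
      genetic counseling should be excluded, return false.
  - key: human
    instruction: >-
      If the study involves human participants, return true. Otherwise,
      return false.
  - key: genetic
    instruction: >-
      If the study involves patients who are genetically confirmed to have
      mutations in known neuropathy genes, or are familial relatives of
      someone who was genetically diagnosed, or have been diagnosed through
      accepted pathological diagnostic criteria strongly linked to genetic
      variants (such as TTR amyloidosis), then return true. Studies
      including patients diagnosed only on a symptomatic basis without
      genetic confirmation or acceptable pathological criteria are
      excluded, and returned as false.
  - key: results
    instruction: >-
      If the study reports results from interventions that were explored in
      databases such as ClinicalTrials.gov, CENTRAL, EudraCT, ICTRP, and
      CRD with filters ensuring only interventional studies with results
      available were included, then return true. Additionally, studies
      should present results for genetically confirmed cohorts separately
      if the cohort includes both diagnosed and undiagnosed patients.
      Otherwise, return false.
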