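# Screening-1 criteria for a systematic review of full economic evaluations
# in musculo-skeletal physiotherapy.
criteria:
  - key: population
    instruction: >-
      If the study population comprises patients with musculoskeletal
      conditions, with no majority having another primary disease or
      intellectual disabilities, then return true. Otherwise, return false.
  - key: intervention
    instruction: >-
      If the treatment involves physiotherapy (techniques like exercises,
      manual therapy, education, and modalities such as heat, cold,
      ultrasound, and electrical stimulation to aid in patient recovery,
      pain reduction, mobility enhancement, and injury prevention), or at
      least one of the intervention/control group treatments was provided
      exclusively by physiotherapists, then return true. However, if the
      treatment of interest was offered by an interdisciplinary team,
      non-health care professionals, or mostly by a different profession to
      physiotherapists, then return false.
  - key: physio_plus_other
    instruction: >-
      In case at least one of the intervention/control group treatments was
      provided exclusively by physiotherapists, if the intervention includes
      physiotherapy and another treatment and the other treatment is
      provided in a comparator group, then return true.
  - key: e_interventions
    instruction: >-
      If the study evaluates the economic aspects of E-interventions,
      digital interventions or eHealth interventions, then return false.
      Otherwise, return true.
  - key: control_group
    instruction: >-
      If there is a control group of any type - for example, wait and see,
      usual care, placebo, or alternative treatments, then return true.
      Otherwise, return false.
  - key: outcome
    instruction: >-
      If the outcome of the study involves or allows a full economic
      evaluation, potentially including cost-effectiveness ratios and
      cost-utility ratios or if the study provides information on the costs
      and clinical effects of a treatment then return true. Otherwise,
      return false.
  - key: study_type
    instruction: >-
      If the article is not a conference abstract, review, study without
      results (like a protocol), or model-based study, then return true.
      Otherwise, return false.
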