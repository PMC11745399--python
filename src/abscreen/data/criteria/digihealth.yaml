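# Screening-1 criteria for a systematic review of the cost-effectiveness
# of AI applications in healthcare.
criteria:
  - key: ai_functionality
    instruction: >-
      Return true if the study provides a comprehensive description of an
      AI functionality used in healthcare; otherwise, return false.
  - key: economic_evaluation
    instruction: >-
      Return true if the study evaluates the economic efficiency and
      outcomes of an AI application in healthcare, specifically assessing
      cost-effectiveness or return on investment; otherwise, return false.
  - key: quantitative_outcomes
    instruction: >-
      Return true if the study reports quantitative outcomes in at least
      one healthcare system, showing measurable impacts such as patient
      recovery times, treatment efficacy, or cost savings; otherwise,
      return false.
  - key: ai_relevance
    instruction: >-
      Return false if the title of the study does not explicitly cover a
      topic related to AI in healthcare, indicating the study is not
      primarily focused on AI applications within healthcare; otherwise,
      return true.
  - key: ai_application
    instruction: >-
      Return false if the abstract does not contain a description of an AI
      application in healthcare, indicating a lack of focus on how AI
      technologies are implemented or their functional roles within
      healthcare; otherwise, return true.
  - key: economic_details
    instruction: >-
      Return false if the abstract or full text does not elaborate on the
      quantitative economic outcomes in one healthcare system, failing to
      provide specific economic data or analysis related to the AI
      application; otherwise, return true.
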