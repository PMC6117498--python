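# Group definitions used in the patient-interest comparisons.
# Disease names are matched case-insensitively after trimming; keys absent from a
# scheme (e.g. diabetes under mild_vs_serious) leave the document ungrouped.
acute_vs_chronic:
  field: disease
  mapping:
    influenza: acute
    infantile pneumonia: acute
    infantile diarrhea: acute
    hyperthyroidism: acute
    hypertension: chronic
    diabetes: chronic
    infertility: chronic
mild_vs_serious:
  field: disease
  mapping:
    influenza: mild
    liver cancer: serious
    gastric cancer: serious
high_vs_low_hospital:
  field: hospital_level
  mapping:
    A: high
    B: low
    C: low
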