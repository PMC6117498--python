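# Physician-review topic taxonomy: 3 domains, 9 topics.
# Keywords are the English glosses of each topic's indicative vocabulary and are
# optional metadata; classification itself is driven by the labeled topic model.
labels:
  - id: ME
    name: Medical ethics
    domain: physician-related
    keywords: [kind, good, attitude, medical ethics, patient, considerate, noble,
               careful, polite, respect, indifference, unfriendly]
  - id: MC
    name: Medical competence
    domain: physician-related
    keywords: [good, medical skill, curative effect, turn for the better,
               improved significantly, recovered, exacerbation, aggravation]
  - id: MAP
    name: Medical advice and prescription
    domain: physician-related
    keywords: [treatment, drug, antibiotics, surgery, insulin, take the medicine,
               injection, oral drugs, infusion, chemotherapy]
  - id: CS
    name: Communication skills
    domain: physician-related
    keywords: [patiently answering question, explicate, cannot understand,
               state of illness, problem, ask, detailed, explain, analyze]
  - id: F
    name: Financing
    domain: system-related
    keywords: [expenses, money, expensive, spend money, cheap, registration fee,
               waste money, inexpensive, price, affordable price]
  - id: OP
    name: Operation process
    domain: system-related
    keywords: [difficult, make an appointment, see a doctor, flow, service, ward,
               consulting, wait in line, beds, reexamination, online consulting]
  - id: PP
    name: Patient profile
    domain: patient-related
    keywords: [gender, height, age, born, weight, address, habits, allergic, hair]
  - id: S
    name: Symptoms
    domain: patient-related
    keywords: [cough, symptoms, have a fever, abnormal, virus, high blood pressure,
               diarrhea, serious, catch a cold, swelling, lymph node]
  - id: DAP
    name: Diagnosis and pathogenesis
    domain: patient-related
    keywords: [pathogenesis, influencing factor, pneumonia, diabetes, blood pressure,
               fallopian tubes, cause, infertility, congenital, gastric cancer]
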