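# Default synthetic-corpus specification: a hand-search universe of 8238
# citations across 27 general-medical journals with 22 relevant articles
# (prevalence 0.27 %), plus two planted discriminative term signals whose
# per-class occurrence rates are anchored to the published single-term
# performance table (a title/abstract token family hit in 75 % of relevant
# vs 2.8 % of non-relevant records, and a MeSH descriptor at 50 % vs 0.7 %).
# Per-journal dev/val columns record the published randomization realization;
# the generator uses total = dev_total + val_total and the relevant column.
journals:
  - {name: "Annals of internal medicine", dev_total: 282, dev_relevant: 0, val_total: 312, val_relevant: 0}
  - {name: "Anthropology and Medicine", dev_total: 9, dev_relevant: 0, val_total: 16, val_relevant: 0}
  - {name: "Archives of internal medicine", dev_total: 269, dev_relevant: 1, val_total: 245, val_relevant: 0}
  - {name: "BMC Health Services Research", dev_total: 182, dev_relevant: 1, val_total: 190, val_relevant: 0}
  - {name: "BMC Medical Ethics", dev_total: 13, dev_relevant: 0, val_total: 11, val_relevant: 0}
  - {name: "BMC Medical Informatics and Decision Making", dev_total: 34, dev_relevant: 0, val_total: 43, val_relevant: 0}
  - {name: "BMC Medicine", dev_total: 80, dev_relevant: 0, val_total: 59, val_relevant: 0}
  - {name: "British Medical Journal", dev_total: 1311, dev_relevant: 0, val_total: 1293, val_relevant: 0}
  - {name: "Culture, Medicine, and Psychiatry", dev_total: 19, dev_relevant: 0, val_total: 8, val_relevant: 0}
  - {name: "Current medical research and opinion", dev_total: 123, dev_relevant: 2, val_total: 147, val_relevant: 1}
  - {name: "Health Economics", dev_total: 54, dev_relevant: 1, val_total: 63, val_relevant: 0}
  - {name: "Health Expectations", dev_total: 45, dev_relevant: 0, val_total: 55, val_relevant: 1}
  - {name: "Implementation Science", dev_total: 68, dev_relevant: 0, val_total: 65, val_relevant: 0}
  - {name: "International Journal of technology assessment in health care", dev_total: 28, dev_relevant: 0, val_total: 34, val_relevant: 1}
  - {name: "Journal of general internal medicine", dev_total: 161, dev_relevant: 0, val_total: 150, val_relevant: 1}
  - {name: "JAMA : the journal of the American Medical Association", dev_total: 504, dev_relevant: 0, val_total: 503, val_relevant: 0}
  - {name: "Journal of Clinical Epidemiology", dev_total: 99, dev_relevant: 0, val_total: 98, val_relevant: 1}
  - {name: "Medical Anthropology Quarterly", dev_total: 11, dev_relevant: 0, val_total: 15, val_relevant: 0}
  - {name: "Medical Care", dev_total: 86, dev_relevant: 1, val_total: 90, val_relevant: 0}
  - {name: "Medical Decision Making", dev_total: 43, dev_relevant: 0, val_total: 46, val_relevant: 1}
  - {name: "The patient", dev_total: 15, dev_relevant: 1, val_total: 11, val_relevant: 1}
  - {name: "Patient Education and Counseling", dev_total: 182, dev_relevant: 1, val_total: 196, val_relevant: 0}
  - {name: "Patient Preference and Adherence", dev_total: 32, dev_relevant: 2, val_total: 37, val_relevant: 2}
  - {name: "Quality of life research", dev_total: 85, dev_relevant: 0, val_total: 101, val_relevant: 0}
  - {name: "Social Science and Medicine", dev_total: 250, dev_relevant: 1, val_total: 215, val_relevant: 0}
  - {name: "Sociology of Health and Illness", dev_total: 45, dev_relevant: 0, val_total: 24, val_relevant: 0}
  - {name: "Value in Health", dev_total: 92, dev_relevant: 1, val_total: 89, val_relevant: 1}
prevalence: 0.0026705511046370477   # 22 / 8238
exact_counts: true
planted_terms:
  - pattern: preferen
    field_class: tiab
    rate_relevant: 0.75
    rate_irrelevant: 0.028
    variants: [preference, preferences]
  - pattern: Patient Preference
    field_class: mesh
    rate_relevant: 0.50
    rate_irrelevant: 0.007
vocab_size: 5000
tokens_per_abstract: 150
tokens_per_title: 10
mesh_per_record: 10
zipf_exponent: 1.1
year: 2011
language: eng
seed: 0
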