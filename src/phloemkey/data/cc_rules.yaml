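# Decision table for the eleven companion-cell subtypes.
#
# Per label:
#   major     - one of ORDINARY, TRANSFER, INTERMEDIARY, PF_CC
#   canonical - the archetypal trait vector of the subtype ("?" = not scored)
#   match     - allowed token set per trait; a trait not listed accepts any
#               value, and an UNKNOWN observation never constrains a rule.
#
# Grades: "-" absent, "+" sparse, "++" moderate, "+++" abundant.
# The MIC pair shares broad grade sets; the classifier narrows it by grade
# band (both <= "+" -> MIC_A, both >= "+++" -> MIC_B, mixed -> ambiguous).

OC_A:
  major: ORDINARY
  canonical:
    pf_grade: "-"
    pd_branching: "?"
    cwi_grade: "-"
    cwi_morphology: "none"
    plastid: "leucoplast"
    starch_in_leucoplasts: "?"
    rfo_evidence: "not_detected"
  match:
    pf_grade: ["-"]
    cwi_grade: ["-"]
    cwi_morphology: ["none"]
    plastid: ["leucoplast"]
    rfo_evidence: ["not_detected"]

OC_B:
  major: ORDINARY
  canonical:
    pf_grade: "-"
    pd_branching: "?"
    cwi_grade: "-"
    cwi_morphology: "none"
    plastid: "chloroplast"
    starch_in_leucoplasts: "no"
    rfo_evidence: "not_detected"
  match:
    pf_grade: ["-"]
    cwi_grade: ["-"]
    cwi_morphology: ["none"]
    plastid: ["chloroplast"]
    rfo_evidence: ["not_detected"]

TC_A:
  major: TRANSFER
  canonical:
    pf_grade: "-"
    pd_branching: "?"
    cwi_grade: "+++"
    cwi_morphology: "reticulate"
    plastid: "chloroplast"
    starch_in_leucoplasts: "no"
    rfo_evidence: "not_detected"
  match:
    pf_grade: ["-"]
    cwi_grade: ["++", "+++"]
    cwi_morphology: ["reticulate"]
    plastid: ["chloroplast"]
    rfo_evidence: ["not_detected"]

TC_B:
  major: TRANSFER
  canonical:
    pf_grade: "-"
    pd_branching: "?"
    cwi_grade: "++"
    cwi_morphology: "reticulate"
    plastid: "leucoplast"
    starch_in_leucoplasts: "?"
    rfo_evidence: "not_detected"
  match:
    pf_grade: ["-"]
    cwi_grade: ["++", "+++"]
    cwi_morphology: ["reticulate"]
    plastid: ["leucoplast"]
    rfo_evidence: ["not_detected"]

TC_C:
  major: TRANSFER
  canonical:
    pf_grade: "-"
    pd_branching: "?"
    cwi_grade: "+++"
    cwi_morphology: "flange"
    plastid: "leucoplast"
    starch_in_leucoplasts: "?"
    rfo_evidence: "not_detected"
  match:
    pf_grade: ["-"]
    cwi_grade: ["++", "+++"]
    cwi_morphology: ["flange"]
    plastid: ["leucoplast"]
    rfo_evidence: ["not_detected"]

IC:
  major: INTERMEDIARY
  canonical:
    pf_grade: "+++"
    pd_branching: "asymmetric"
    cwi_grade: "-"
    cwi_morphology: "none"
    plastid: "leucoplast"
    starch_in_leucoplasts: "no"
    rfo_evidence: "detected"
  match:
    pf_grade: ["++", "+++"]
    pd_branching: ["asymmetric"]
    cwi_grade: ["-"]
    cwi_morphology: ["none"]
    plastid: ["leucoplast"]
    starch_in_leucoplasts: ["no"]
    rfo_evidence: ["detected"]

ICL:
  major: INTERMEDIARY
  canonical:
    pf_grade: "+++"
    pd_branching: "asymmetric"
    cwi_grade: "-"
    cwi_morphology: "none"
    plastid: "leucoplast"
    starch_in_leucoplasts: "yes"
    rfo_evidence: "?"
  match:
    pf_grade: ["++", "+++"]
    pd_branching: ["asymmetric"]
    cwi_grade: ["-"]
    cwi_morphology: ["none"]
    plastid: ["leucoplast"]
    starch_in_leucoplasts: ["yes"]

CC_A:
  major: PF_CC
  canonical:
    pf_grade: "++"
    pd_branching: "symmetric"
    cwi_grade: "-"
    cwi_morphology: "none"
    plastid: "leucoplast"
    starch_in_leucoplasts: "no"
    rfo_evidence: "not_detected"
  match:
    pf_grade: ["++", "+++"]
    pd_branching: ["symmetric"]
    cwi_grade: ["-"]
    cwi_morphology: ["none"]
    plastid: ["leucoplast"]
    rfo_evidence: ["not_detected"]

CC_B:
  major: PF_CC
  canonical:
    pf_grade: "++"
    pd_branching: "asymmetric"
    cwi_grade: "-"
    cwi_morphology: "none"
    plastid: "chloroplast"
    starch_in_leucoplasts: "no"
    rfo_evidence: "not_detected"
  match:
    pf_grade: ["++", "+++"]
    pd_branching: ["asymmetric", "single"]
    cwi_grade: ["-"]
    cwi_morphology: ["none"]
    plastid: ["chloroplast"]
    rfo_evidence: ["not_detected"]

MIC_A:
  major: PF_CC
  canonical:
    pf_grade: "+"
    pd_branching: "asymmetric"
    cwi_grade: "+"
    cwi_morphology: "reticulate"
    plastid: "leucoplast"
    starch_in_leucoplasts: "?"
    rfo_evidence: "detected"
  match:
    pf_grade: ["+", "++", "+++"]
    pd_branching: ["asymmetric"]
    cwi_grade: ["+", "++", "+++"]
    cwi_morphology: ["reticulate"]
    plastid: ["leucoplast"]

MIC_B:
  major: PF_CC
  canonical:
    pf_grade: "+++"
    pd_branching: "asymmetric"
    cwi_grade: "+++"
    cwi_morphology: "reticulate"
    plastid: "leucoplast"
    starch_in_leucoplasts: "?"
    rfo_evidence: "not_detected"
  match:
    pf_grade: ["+", "++", "+++"]
    pd_branching: ["asymmetric"]
    cwi_grade: ["+", "++", "+++"]
    cwi_morphology: ["reticulate"]
    plastid: ["leucoplast"]
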