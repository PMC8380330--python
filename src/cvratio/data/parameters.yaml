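# The 25 clinical-chemical and hematological parameters of the blood screen.
# Each entry carries the vertebrate trait (VT) ontology term used to select
# project data sets in the Mouse Phenome Database; MCV has no VT term.
# Derived red-blood-cell quantities (hematocrit, MCH, MCHC) are deliberately
# absent: they are computed from directly measured parameters.
parameters:
  - {key: cholesterol, display_name: Cholesterol, vt_term: "VT:0000180"}
  - {key: creatinine, display_name: Creatinine, vt_term: "VT:0005328"}
  - {key: glucose, display_name: Glucose, vt_term: "VT:0000188"}
  - {key: total_protein, display_name: Total protein, vt_term: "VT:0005567"}
  - {key: triglycerides, display_name: Triglycerides, vt_term: "VT:0002644"}
  - {key: urea, display_name: Urea, vt_term: "VT:0005265"}
  - {key: uric_acid, display_name: Uric acid, vt_term: "VT:0010302"}
  - {key: ferritin, display_name: Ferritin, vt_term: "VT:0010513"}
  - {key: transferrin, display_name: Transferrin, vt_term: "VT:0010514"}
  - {key: calcium, display_name: Calcium, vt_term: "VT:0001562"}
  - {key: chloride, display_name: Chloride, vt_term: "VT:0003018"}
  - {key: phosphorus, display_name: Phosphorus, vt_term: "VT:0001565"}
  - {key: potassium, display_name: Potassium, vt_term: "VT:0002668"}
  - {key: sodium, display_name: Sodium, vt_term: "VT:0001776"}
  - {key: alt, display_name: Alanine aminotransferase (ALT), vt_term: "VT:0001573"}
  - {key: ast, display_name: Aspartate aminotransferase (AST), vt_term: "VT:0000203"}
  - {key: alpha_amylase, display_name: "α-Amylase", vt_term: "VT:0010475"}
  - {key: ap, display_name: Alkaline phosphatase (AP), vt_term: "VT:0000202"}
  - {key: ck, display_name: Creatine kinase (CK), vt_term: "VT:1000047"}
  - {key: lipase, display_name: Lipase, vt_term: "VT:0010478"}
  - {key: hemoglobin, display_name: Hemoglobin, vt_term: "VT:0001588"}
  - {key: mcv, display_name: Mean corpuscular volume (MCV), vt_term: null}
  - {key: rbc, display_name: Red blood cell count (RBC), vt_term: "VT:0001586"}
  - {key: wbc, display_name: White blood cell count (WBC), vt_term: "VT:0000217"}
  - {key: platelets, display_name: Platelets, vt_term: "VT:0003179"}
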