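# Pseudo-report templates. Concise templates state the findings for one
# class; wordy frames wrap the joined findings in distractor clauses.
# "benign" frames negate their disease mention within a short scope;
# "misleading" frames leave a history mention of the {distractor} class
# outside any negation scope (out-of-window negation or an unnegated
# prior-specimen clause), emulating the reports on which rule-based
# concept extraction realistically fails.
classes:
  celiac_disease:
    mention: "villous atrophy with crypt hyperplasia and increased intraepithelial lymphocytes"
    short: "villous atrophy"
    concise:
      - "Duodenal biopsy : fragments of duodenal mucosa showing {mention} ."
      - "Sections show {mention} , consistent with celiac disease ."
      - "Duodenal mucosa with {mention} ; findings compatible with gluten-sensitive enteropathy ."
  sclc:
    mention: "small cell carcinoma"
    concise:
      - "Lung biopsy : infiltration by {mention} with extensive crush artifact ."
      - "Sections show {mention} ; neuroendocrine markers are positive ."
      - "Core biopsy involved by {mention} ."
  luad:
    mention: "adenocarcinoma"
    concise:
      - "Lung biopsy : invasive {mention} with acinar growth pattern ."
      - "Sections show moderately differentiated {mention} of the lung ."
      - "Core biopsy involved by pulmonary {mention} ."
  lusc:
    mention: "squamous cell carcinoma"
    concise:
      - "Lung biopsy : infiltrating {mention} with keratinization ."
      - "Sections show poorly differentiated {mention} ."
      - "Core biopsy involved by {mention} of the lung ."
  adenocarcinoma:
    mention: "adenocarcinoma"
    concise:
      - "Colon biopsy : invasive {mention} arising in a polyp ."
      - "Sections show moderately differentiated colonic {mention} ."
      - "Colonic mucosa infiltrated by {mention} ."
  hgd:
    mention: "high-grade dysplasia"
    concise:
      - "Colon biopsy : adenomatous epithelium with focal {mention} ."
      - "Sections show {mention} within a tubular adenoma ."
      - "Polypectomy specimen with {mention} ."
  lgd:
    mention: "low-grade dysplasia"
    concise:
      - "Colon biopsy : tubular adenoma with {mention} ."
      - "Sections show adenomatous change with {mention} ."
      - "Polypectomy specimen with {mention} ."
  hyperplastic_polyp:
    mention: "hyperplastic polyp"
    concise:
      - "Colon biopsy : {mention} with serrated crypts ."
      - "Sections show a {mention} of the distal colon ."
      - "Polypectomy specimen consistent with {mention} ."
  normal:
    mention: "within normal limits"
    concise:
      - "Fragments of mucosa {mention} . No evidence of dysplasia or malignancy ."
      - "Benign tissue , {mention} , architecture preserved ."
      - "Unremarkable mucosa , {mention} ; no significant abnormality ."
wordy_frames:
  benign:
    - "Clinical history : family history of gastrointestinal malignancy ; prior endoscopies were non-contributory for the referring clinician . Immunohistochemical stains were reviewed . {findings} There is no evidence of {distractor} elsewhere . Correlation with clinical findings is advised ."
    - "Received in formalin , multiple tissue fragments ; the patient reports longstanding reflux symptoms treated medically . {findings} Negative for {distractor} in the sampled material . Immunostains support the above interpretation ."
  misleading:
    - "Clinical note : the patient 's prior resection specimen demonstrated {distractor} , currently status post therapy . Immunohistochemistry was repeated for confirmation . {findings} Correlation with the previous material is recommended ."
    - "There is no definite convincing morphological or immunophenotypic evidence of residual {distractor} in these fragments . {findings} Additional levels were examined ; family history is notable for gastrointestinal disease ."
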