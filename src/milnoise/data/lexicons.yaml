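# Concept lexicons for the rule-based report labeler, one per use case.
# priority orders classes for single-label conflict resolution (diseases
# before normal; among diseases, configured severity order).
celiac:
  scheme: binary
  default_class: normal
  priority: [celiac_disease, normal]
  negation_cues: ["no evidence of", "negative for", "absence of", "free of", "without", "no"]
  negation_window: 5
  triggers:
    celiac_disease:
      - villous atrophy
      - crypt hyperplasia
      - intraepithelial lymphocytes
      - celiac disease
      - gluten-sensitive enteropathy
    normal:
      - normal limits
      - unremarkable
      - benign tissue
lung:
  scheme: multiclass
  default_class: normal
  priority: [sclc, lusc, luad, normal]
  negation_cues: ["no evidence of", "negative for", "absence of", "free of", "without", "no"]
  negation_window: 5
  triggers:
    sclc:
      - small cell carcinoma
    luad:
      - adenocarcinoma
    lusc:
      - squamous cell carcinoma
    normal:
      - normal limits
      - unremarkable
      - benign tissue
colon:
  scheme: multilabel
  default_class: normal
  priority: [adenocarcinoma, hgd, lgd, hyperplastic_polyp, normal]
  negation_cues: ["no evidence of", "negative for", "absence of", "free of", "without", "no"]
  negation_window: 5
  triggers:
    adenocarcinoma:
      - adenocarcinoma
    hgd:
      - high-grade dysplasia
    lgd:
      - low-grade dysplasia
    hyperplastic_polyp:
      - hyperplastic polyp
    normal:
      - normal limits
      - unremarkable
      - benign tissue
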