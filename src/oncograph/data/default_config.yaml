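cancer_type_weights:
  breast: 0.1
  cholangiocarcinoma: 0.04
  colorectal: 0.13
  glioma: 0.05
  lung: 0.22
  lymphoma: 0.03
  melanoma: 0.1
  ovarian: 0.07
  pancreatic: 0.08
  prostate: 0.08
  unknown primary: 0.1
censoring_rate: 0.3
frac_female: 0.514
frac_hispanic: 0.035
frac_unknown_primary: 0.1
frac_white: 0.887
gene_prevalence:
  breast:
    BRCA1: 0.08
    BRCA2: 0.08
    ERBB2: 0.15
    PIK3CA: 0.3
    TP53: 0.35
  cholangiocarcinoma:
    FGFR2: 0.15
    IDH1: 0.2
    KRAS: 0.2
    TP53: 0.3
  colorectal:
    APC: 0.6
    BRAF: 0.08
    KRAS: 0.4
    PIK3CA: 0.15
    TP53: 0.5
  glioma:
    EGFR: 0.25
    IDH1: 0.4
    PTEN: 0.2
    TP53: 0.4
  lung:
    ALK: 0.06
    CHEK2: 0.05
    EGFR: 0.28
    KRAS: 0.25
    MET: 0.05
    TP53: 0.45
  lymphoma:
    DNMT3A: 0.1
    MYC: 0.15
    TP53: 0.2
  melanoma:
    BRAF: 0.45
    CDKN2A/B: 0.3
    NRAS: 0.2
    TP53: 0.25
  ovarian:
    BRCA1: 0.15
    BRCA2: 0.1
    TP53: 0.7
  pancreatic:
    CDKN2A/B: 0.3
    KRAS: 0.85
    SMAD4: 0.2
    TP53: 0.6
  prostate:
    ATM: 0.08
    BRCA2: 0.1
    PTEN: 0.25
    TP53: 0.3
  unknown primary:
    CDKN2A/B: 0.15
    EGFR: 0.08
    KRAS: 0.2
    TP53: 0.4
mean_age_first_test: 62.0
mean_age_initial_dx: 58.0
n_patients: 2593
report_date_end: '2020-06-30'
report_date_start: '2016-01-01'
stage_weights:
  I: 0.2
  II: 0.25
  III: 0.25
  IV: 0.3
structured_dx_coverage: 0.46
study_end: '2021-06-30'
survival_model:
  gene_hazard_multiplier:
    TP53: 3.5
  stage_scale:
    I: 4500.0
    II: 3200.0
    III: 2000.0
    IV: 1100.0
  stage_shape:
    I: 1.3
    II: 1.3
    III: 1.3
    IV: 1.3
treatment_affinity:
  '*|breast':
    cyclophosphamide: 0.15
    letrozole: 0.25
    paclitaxel: 0.3
  '*|cholangiocarcinoma':
    cisplatin: 0.35
    gemcitabine: 0.5
  '*|colorectal':
    cetuximab: 0.1
    fluorouracil: 0.4
    irinotecan: 0.15
    oxaliplatin: 0.3
  '*|glioma':
    temozolomide: 0.6
  '*|lung':
    carboplatin: 0.3
    docetaxel: 0.1
    pembrolizumab: 0.25
    pemetrexed: 0.22
  '*|lymphoma':
    cyclophosphamide: 0.4
    doxorubicin: 0.35
  '*|melanoma':
    ipilimumab: 0.2
    nivolumab: 0.2
    pembrolizumab: 0.4
  '*|ovarian':
    carboplatin: 0.5
    paclitaxel: 0.4
  '*|pancreatic':
    fluorouracil: 0.25
    gemcitabine: 0.45
    oxaliplatin: 0.2
  '*|prostate':
    abiraterone: 0.35
    docetaxel: 0.2
    enzalutamide: 0.25
  '*|unknown primary':
    carboplatin: 0.4
    paclitaxel: 0.3
  ALK|lung:
    alectinib: 0.55
    brigatinib: 0.06
    ceritinib: 0.04
    crizotinib: 0.2
    lorlatinib: 0.08
  BRAF|melanoma:
    dabrafenib: 0.35
    trametinib: 0.3
    vemurafenib: 0.25
  BRCA1|ovarian:
    olaparib: 0.35
  BRCA2|ovarian:
    olaparib: 0.35
  EGFR|glioma:
    erlotinib: 0.1
  EGFR|lung:
    afatinib: 0.08
    erlotinib: 0.15
    gefitinib: 0.1
    osimertinib: 0.55
  ERBB2|breast:
    trastuzumab: 0.55
  FGFR2|cholangiocarcinoma:
    pemigatinib: 0.4
  IDH1|cholangiocarcinoma:
    ivosidenib: 0.4
  MET|lung:
    crizotinib: 0.35
variant_mappable_frac: 0.195
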