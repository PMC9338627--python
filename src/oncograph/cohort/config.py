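"""Cohort generator configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import yaml

from ..errors import ConfigurationError

CANCER_TYPES = [
    "lung", "colorectal", "melanoma", "breast", "pancreatic", "prostate",
    "ovarian", "glioma", "cholangiocarcinoma", "lymphoma", "unknown primary",
]

UNKNOWN_PRIMARY = "unknown primary"

#: cancer-type label -> dictionary disease surface form
DISEASE_LABEL = {
    "lung": "lung adenocarcinoma",
    "colorectal": "colorectal carcinoma",
    "melanoma": "melanoma",
    "breast": "breast carcinoma",
    "pancreatic": "pancreatic adenocarcinoma",
    "prostate": "prostate carcinoma",
    "ovarian": "ovarian carcinoma",
    "glioma": "glioma",
    "cholangiocarcinoma": "cholangiocarcinoma",
    "lymphoma": "lymphoma",
    "unknown primary": "carcinoma of unknown primary",
}


def _default_type_weights():
    return {
        "lung": 0.22, "colorectal": 0.13, "melanoma": 0.10, "breast": 0.10,
        "pancreatic": 0.08, "prostate": 0.08, "ovarian": 0.07, "glioma": 0.05,
        "cholangiocarcinoma": 0.04, "lymphoma": 0.03, "unknown primary": 0.10,
    }


def _default_gene_prevalence():
    return {
        "lung": {"TP53": 0.45, "EGFR": 0.28, "KRAS": 0.25, "ALK": 0.06,
                 "MET": 0.05, "CHEK2": 0.05},
        "colorectal": {"APC": 0.60, "TP53": 0.50, "KRAS": 0.40,
                       "PIK3CA": 0.15, "BRAF": 0.08},
        "melanoma": {"BRAF": 0.45, "TP53": 0.25, "NRAS": 0.20,
                     "CDKN2A/B": 0.30},
        "breast": {"PIK3CA": 0.30, "TP53": 0.35, "BRCA1": 0.08,
                   "BRCA2": 0.08, "ERBB2": 0.15},
        "pancreatic": {"KRAS": 0.85, "TP53": 0.60, "SMAD4": 0.20,
                       "CDKN2A/B": 0.30},
        "prostate": {"TP53": 0.30, "PTEN": 0.25, "ATM": 0.08, "BRCA2": 0.10},
        "ovarian": {"TP53": 0.70, "BRCA1": 0.15, "BRCA2": 0.10},
        "glioma": {"IDH1": 0.40, "TP53": 0.40, "EGFR": 0.25, "PTEN": 0.20},
        "cholangiocarcinoma": {"FGFR2": 0.15, "IDH1": 0.20, "TP53": 0.30,
                               "KRAS": 0.20},
        "lymphoma": {"TP53": 0.20, "MYC": 0.15, "DNMT3A": 0.10},
        "unknown primary": {"TP53": 0.40, "KRAS": 0.20, "EGFR": 0.08,
                            "CDKN2A/B": 0.15},
    }


def _default_treatment_affinity():
    # "*" keys are background (mutation-agnostic) therapy for a cancer type
    return {
        ("EGFR", "lung"): {"osimertinib": 0.55, "erlotinib": 0.15,
                           "gefitinib": 0.10, "afatinib": 0.08},
        ("ALK", "lung"): {"alectinib": 0.55, "crizotinib": 0.20,
                          "lorlatinib": 0.08, "brigatinib": 0.06,
                          "ceritinib": 0.04},
        ("MET", "lung"): {"crizotinib": 0.35},
        ("BRAF", "melanoma"): {"dabrafenib": 0.35, "vemurafenib": 0.25,
                               "trametinib": 0.30},
        ("ERBB2", "breast"): {"trastuzumab": 0.55},
        ("BRCA1", "ovarian"): {"olaparib": 0.35},
        ("BRCA2", "ovarian"): {"olaparib": 0.35},
        ("IDH1", "cholangiocarcinoma"): {"ivosidenib": 0.40},
        ("FGFR2", "cholangiocarcinoma"): {"pemigatinib": 0.40},
        ("EGFR", "glioma"): {"erlotinib": 0.10},
        ("*", "lung"): {"carboplatin": 0.30, "pemetrexed": 0.22,
                        "pembrolizumab": 0.25, "docetaxel": 0.10},
        ("*", "colorectal"): {"fluorouracil": 0.40, "oxaliplatin": 0.30,
                              "irinotecan": 0.15, "cetuximab": 0.10},
        ("*", "melanoma"): {"pembrolizumab": 0.40, "ipilimumab": 0.20,
                            "nivolumab": 0.20},
        ("*", "breast"): {"paclitaxel": 0.30, "letrozole": 0.25,
                          "cyclophosphamide": 0.15},
        ("*", "pancreatic"): {"gemcitabine": 0.45, "oxaliplatin": 0.20,
                              "fluorouracil": 0.25},
        ("*", "prostate"): {"abiraterone": 0.35, "enzalutamide": 0.25,
                            "docetaxel": 0.20},
        ("*", "ovarian"): {"carboplatin": 0.50, "paclitaxel": 0.40},
        ("*", "glioma"): {"temozolomide": 0.60},
        ("*", "cholangiocarcinoma"): {"gemcitabine": 0.50, "cisplatin": 0.35},
        ("*", "lymphoma"): {"cyclophosphamide": 0.40, "doxorubicin": 0.35},
        ("*", "unknown primary"): {"carboplatin": 0.40, "paclitaxel": 0.30},
    }


@dataclass
class SurvivalModel:
    """Per-stage Weibull baselines (days) plus per-gene hazard multipliers."""

    stage_scale: dict = field(default_factory=lambda: {
        "I": 4500.0, "II": 3200.0, "III": 2000.0, "IV": 1100.0})
    stage_shape: dict = field(default_factory=lambda: {
        "I": 1.3, "II": 1.3, "III": 1.3, "IV": 1.3})
    gene_hazard_multiplier: dict = field(
        default_factory=lambda: {"TP53": 3.5})


@dataclass
class CohortConfig:
    n_patients: int = 2593
    cancer_type_weights: dict = field(default_factory=_default_type_weights)
    frac_unknown_primary: float = 0.10
    frac_female: float = 0.514
    frac_white: float = 0.887
    frac_hispanic: float = 0.035
    mean_age_first_test: float = 62.0
    mean_age_initial_dx: float = 58.0
    structured_dx_coverage: float = 0.46
    gene_prevalence: dict = field(default_factory=_default_gene_prevalence)
    treatment_affinity: dict = field(
        default_factory=_default_treatment_affinity)
    variant_mappable_frac: float = 0.195
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    censoring_rate: float = 0.30
    report_date_start: dt.date = dt.date(2016, 1, 1)
    report_date_end: dt.date = dt.date(2020, 6, 30)
    study_end: dt.date = dt.date(2021, 6, 30)
    stage_weights: dict = field(default_factory=lambda: {
        "I": 0.20, "II": 0.25, "III": 0.25, "IV": 0.30})

    def validate(self) -> None:
        def _prob(name, value):
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(name, f"probability {value} not in [0,1]")

        if self.n_patients < 0:
            raise ConfigurationError("n_patients", "must be >= 0")
        for name in ("frac_unknown_primary", "frac_female", "frac_white",
                     "frac_hispanic", "structured_dx_coverage",
                     "variant_mappable_frac", "censoring_rate"):
            _prob(name, getattr(self, name))
        total = sum(self.cancer_type_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                "cancer_type_weights", f"weights sum to {total}, expected 1")
        for ct, w in self.cancer_type_weights.items():
            _prob(f"cancer_type_weights[{ct}]", w)
        for ct, genes in self.gene_prevalence.items():
            for g, p in genes.items():
                _prob(f"gene_prevalence[{ct}][{g}]", p)
        for key, drugs in self.treatment_affinity.items():
            for d, p in drugs.items():
                _prob(f"treatment_affinity[{key}][{d}]", p)
        for stage, m in self.survival_model.stage_scale.items():
            if m <= 0:
                raise ConfigurationError(
                    f"survival_model.stage_scale[{stage}]", "must be > 0")
        for gene, m in self.survival_model.gene_hazard_multiplier.items():
            if m <= 0:
                raise ConfigurationError(
                    f"survival_model.gene_hazard_multiplier[{gene}]",
                    "must be > 0")
        if self.report_date_end < self.report_date_start:
            raise ConfigurationError(
                "report_date_end", "must be >= report_date_start")
        swsum = sum(self.stage_weights.values())
        if abs(swsum - 1.0) > 1e-9:
            raise ConfigurationError(
                "stage_weights", f"weights sum to {swsum}, expected 1")

    # ---- YAML round trip --------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["treatment_affinity"] = {
            f"{g}|{ct}": drugs
            for (g, ct), drugs in self.treatment_affinity.items()
        }
        for k in ("report_date_start", "report_date_end", "study_end"):
            data[k] = data[k].isoformat()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "treatment_affinity" in data:
            ta = {}
            for key, drugs in data["treatment_affinity"].items():
                gene, _, ct = key.partition("|")
                ta[(gene, ct)] = drugs
            data["treatment_affinity"] = ta
        if "survival_model" in data and isinstance(data["survival_model"], dict):
            data["survival_model"] = SurvivalModel(**data["survival_model"])
        for k in ("report_date_start", "report_date_end", "study_end"):
            if k in data and isinstance(data[k], str):
                data[k] = dt.date.fromisoformat(data[k])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def default_config() -> CohortConfig:
    cfg = CohortConfig()
    cfg.validate()
    return cfg
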