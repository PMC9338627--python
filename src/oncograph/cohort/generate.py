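"""Reproducible synthetic precision-oncology cohorts.

The generator plants known structure so downstream stages can be tested by
parameter recovery: configured demographic marginals, partial structured
diagnosis coverage, a configurable fraction of dictionary-covered variant
nomenclature, gene-and-cancer-conditional drug affinities, and per-gene
survival hazard multipliers (mutants of a penalized gene die faster).
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np

from .config import CohortConfig, DISEASE_LABEL
from .records import (
    DiagnosisRecord, GeneticReport, MedicationRecord, NoteSentence,
    PatientRecord, ReportFinding, SyntheticCohort,
)

_FIRST_NAMES = [
    "Alice", "Benjamin", "Carla", "David", "Elena", "Frank", "Grace",
    "Henry", "Irene", "James", "Karen", "Liam", "Maria", "Noah", "Olivia",
    "Peter", "Quinn", "Rachel", "Samuel", "Teresa", "Umar", "Victoria",
    "Walter", "Xenia", "Yusuf", "Zoe", "Andre", "Bianca", "Carlos",
    "Diana", "Emil", "Fatima", "Gustav", "Hana", "Ivan", "Julia", "Kenji",
    "Lucia", "Marco", "Nadia", "Oscar", "Priya", "Rosa", "Stefan", "Tomas",
    "Ursula", "Vera", "Wendell", "Yara", "Zachary",
]
_LAST_NAMES = [
    "Anderson", "Baker", "Carter", "Dawson", "Ellis", "Foster", "Garcia",
    "Huang", "Ibrahim", "Jensen", "Kim", "Lopez", "Murphy", "Nguyen",
    "Olsen", "Park", "Quintero", "Rivera", "Schmidt", "Tanaka", "Ueda",
    "Vasquez", "Weber", "Xu", "Young", "Zimmerman", "Abe", "Bauer",
    "Costa", "Dubois", "Eriksen", "Fischer", "Gupta", "Hansen", "Ito",
    "Johansson", "Kowalski", "Larsen", "Moreau", "Novak", "Okafor",
    "Petrov", "Rossi", "Silva", "Tran", "Umeda", "Villanueva", "Wagner",
    "Yamada", "Zhang",
]

_PANELS = ["FoundationOne CDx", "FoundationOne Heme"]

_UNMAPPABLE_TEMPLATES = [
    "{gene} deletion exon {n}",
    "{gene} amplification",
    "{gene} rearrangement",
    "{gene} splice site {n}-1G>A",
    "{gene} truncation intron {n}",
    "{partner}-{gene} fusion",
]
_FUSION_PARTNERS = ["CD74", "EML4", "KIF5B", "TPM3"]

_NONCANCER_DX = [
    "hypertension", "type 2 diabetes mellitus", "hyperlipidemia",
    "atrial fibrillation", "chronic kidney disease", "asthma",
    "osteoarthritis", "depression", "hypothyroidism",
]

#: discordance rate between report and warehouse primary-cancer diagnosis
_WAREHOUSE_DISCORDANT = 0.05
#: probability a warehouse-covered patient has a cancer code in the warehouse
_WAREHOUSE_HAS_CANCER_DX = 0.55
#: probability a warehouse drug is also mentioned in a note
_NOTE_ECHO = 0.30
#: probability a note mention uses the brand (vs chemical) name
_BRAND_IN_NOTE = 0.40


def _mappable_variants_by_gene():
    """Gene -> dictionary-covered variant surfaces, from the bundled fixture."""
    from ..normalize import ConceptDictionary

    d = ConceptDictionary.bundled()
    by_gene: dict[str, list[str]] = {}
    for (cls_, _), entry in sorted(d.entries.items()):
        if cls_ != "variant":
            continue
        gene = entry.preferred_term.rsplit(" ", 1)[0]
        by_gene.setdefault(gene, []).append(entry.preferred_term)
    for v in by_gene.values():
        v.sort()
    return by_gene


def _brand_by_chemical():
    from ..normalize import ConceptDictionary

    d = ConceptDictionary.bundled()
    # brand entries point at their chemical; keep the folded display form
    brands: dict[str, str] = {}
    for (cls_, surface), entry in sorted(d.entries.items()):
        if cls_ == "drug" and entry.brand_of:
            brands.setdefault(entry.brand_of, surface.capitalize())
    return brands


def _truncated_normal(rng, mean, sd, low, high):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x
    return min(max(mean, low), high)


def _conditional_weibull(rng, scale, shape, multiplier, t0):
    """Draw T from Weibull(scale, shape) with hazard multiplied by
    `multiplier`, conditional on T > t0 (left truncation)."""
    u = rng.uniform()
    u = max(u, 1e-300)
    base = (t0 / scale) ** shape if t0 > 0 else 0.0
    return scale * (base - math.log(u) / multiplier) ** (1.0 / shape)


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Generate a cohort; identical (config, seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(seed)

    variant_pool = _mappable_variants_by_gene()
    brand_of = _brand_by_chemical()
    cancer_types = sorted(config.cancer_type_weights)
    weights = np.array([config.cancer_type_weights[c] for c in cancer_types])
    weights = weights / weights.sum()
    stages = sorted(config.stage_weights)
    stage_w = np.array([config.stage_weights[s] for s in stages])
    stage_w = stage_w / stage_w.sum()
    window_days = (config.report_date_end - config.report_date_start).days

    patients, reports, findings = [], [], []
    diagnoses, medications, notes = [], [], []
    used_name_dob: set[tuple[str, str, str]] = set()

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        clinic = f"C{1000000 + i}"

        sex = "F" if rng.uniform() < config.frac_female else "M"
        race = "White" if rng.uniform() < config.frac_white else str(
            rng.choice(["Black", "Asian", "Other"]))
        eth = ("Hispanic" if rng.uniform() < config.frac_hispanic
               else "Not Hispanic")

        receipt = config.report_date_start + dt.timedelta(
            days=int(rng.integers(0, window_days + 1)))
        age_test = _truncated_normal(
            rng, config.mean_age_first_test, 11.0, 19.0, 95.0)
        dob = receipt - dt.timedelta(days=int(round(age_test * 365.25)))
        gap_years = max(0.0, rng.normal(
            config.mean_age_first_test - config.mean_age_initial_dx, 0.8))
        gap_years = min(gap_years, age_test - 19.0)
        dx_date = receipt - dt.timedelta(days=int(round(gap_years * 365.25)))

        # unique (first, last, dob) so name+dob linkage is never ambiguous
        while True:
            first = str(rng.choice(_FIRST_NAMES))
            last = str(rng.choice(_LAST_NAMES))
            key = (first.casefold(), last.casefold(), dob.isoformat())
            if key not in used_name_dob:
                used_name_dob.add(key)
                break

        ctype = cancer_types[int(rng.choice(len(cancer_types), p=weights))]
        disease = DISEASE_LABEL.get(ctype, ctype)
        stage = stages[int(rng.choice(len(stages), p=stage_w))]

        # ---- genetic report & findings ---------------------------------
        has_clinic_on_report = rng.uniform() >= 0.10
        reports.append(GeneticReport(
            report_id=f"R{i + 1:05d}", patient_id=pid,
            clinic_number=clinic if has_clinic_on_report else "",
            first_name=first, last_name=last, dob=dob,
            panel=_PANELS[int(rng.integers(0, len(_PANELS)))],
            receipt_date=receipt,
        ))

        genes = []
        prevalence = config.gene_prevalence.get(ctype, {})
        for gene in sorted(prevalence):
            if rng.uniform() < prevalence[gene]:
                genes.append(gene)
        for gene in genes:
            pool = variant_pool.get(gene, [])
            if pool and rng.uniform() < config.variant_mappable_frac:
                variant = pool[int(rng.integers(0, len(pool)))]
            else:
                tmpl = _UNMAPPABLE_TEMPLATES[
                    int(rng.integers(0, len(_UNMAPPABLE_TEMPLATES)))]
                variant = tmpl.format(
                    gene=gene, n=int(rng.integers(1, 20)),
                    partner=_FUSION_PARTNERS[
                        int(rng.integers(0, len(_FUSION_PARTNERS)))],
                )
            findings.append(ReportFinding(
                report_id=f"R{i + 1:05d}", patient_id=pid,
                gene=gene, variant=variant,
            ))

        # ---- diagnoses ---------------------------------------------------
        diagnoses.append(DiagnosisRecord(
            patient_id=pid, disease=disease, date=dx_date, stage=stage,
            source="report",
        ))
        covered = rng.uniform() < config.structured_dx_coverage
        if covered:
            has_cancer_code = rng.uniform() < _WAREHOUSE_HAS_CANCER_DX
            if has_cancer_code:
                wh_disease = disease
                if rng.uniform() < _WAREHOUSE_DISCORDANT:
                    others = [DISEASE_LABEL[c] for c in cancer_types
                              if DISEASE_LABEL[c] != disease]
                    wh_disease = others[int(rng.integers(0, len(others)))]
                diagnoses.append(DiagnosisRecord(
                    patient_id=pid, disease=wh_disease, date=dx_date,
                    stage=stage, source="warehouse",
                ))
            # covered patients always carry at least one warehouse code
            n_noncancer = int(rng.poisson(1.5))
            if not has_cancer_code:
                n_noncancer = max(n_noncancer, 1)
            for _ in range(n_noncancer):
                dx = _NONCANCER_DX[int(rng.integers(0, len(_NONCANCER_DX)))]
                offset = int(rng.integers(0, 365 * 3))
                diagnoses.append(DiagnosisRecord(
                    patient_id=pid, disease=dx,
                    date=dx_date + dt.timedelta(days=offset), stage="",
                    source="warehouse",
                ))

        # ---- medications -------------------------------------------------
        drug_probs: dict[str, float] = {}
        for key_gene in ["*"] + genes:
            affinity = config.treatment_affinity.get((key_gene, ctype), {})
            for drug in sorted(affinity):
                drug_probs[drug] = max(drug_probs.get(drug, 0.0),
                                       affinity[drug])
        for drug in sorted(drug_probs):
            if rng.uniform() >= drug_probs[drug]:
                continue
            drug_date = receipt + dt.timedelta(days=int(rng.integers(5, 301)))
            in_note = not covered or rng.uniform() < _NOTE_ECHO
            if covered:
                medications.append(MedicationRecord(
                    patient_id=pid, drug=drug, date=drug_date,
                    source="warehouse",
                ))
            if in_note:
                display = drug
                if (rng.uniform() < _BRAND_IN_NOTE
                        and drug in brand_of):
                    display = brand_of[drug]
                notes.append(NoteSentence(
                    patient_id=pid, date=drug_date,
                    text=f"Patient was started on {display} for "
                         f"treatment of {disease}.",
                ))
        if rng.uniform() < 0.2:
            notes.append(NoteSentence(
                patient_id=pid, date=receipt,
                text="Patient is tolerating therapy well with no new "
                     "complaints.",
            ))

        # ---- survival ----------------------------------------------------
        model = config.survival_model
        scale = model.stage_scale.get(stage, 2000.0)
        shape = model.stage_shape.get(stage, 1.1)
        mult = 1.0
        for gene in genes:
            mult *= model.gene_hazard_multiplier.get(gene, 1.0)
        t0 = (receipt - dx_date).days
        t_death = _conditional_weibull(rng, scale, shape, mult, t0)
        c_admin = (config.study_end - dx_date).days
        c_ltfu = math.inf
        if rng.uniform() < config.censoring_rate:
            c_ltfu = t0 + rng.uniform() * max(c_admin - t0, 1)
        censor_at = min(c_admin, c_ltfu)
        if t_death <= censor_at:
            death = dx_date + dt.timedelta(days=int(round(t_death)))
            last_contact = death
        else:
            death = None
            last_contact = dx_date + dt.timedelta(days=int(round(censor_at)))

        patients.append(PatientRecord(
            patient_id=pid, clinic_number=clinic, first_name=first,
            last_name=last, dob=dob, sex=sex, race=race, ethnicity=eth,
            death_date=death, last_contact_date=last_contact,
        ))

    cohort = SyntheticCohort(
        patients=patients, reports=reports, findings=findings,
        diagnoses=diagnoses, medications=medications, note_sentences=notes,
    )
    cohort.check_invariants()
    return cohort
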