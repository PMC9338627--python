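import datetime as dt

import pytest

from oncograph.cohort import (
    DiagnosisRecord, GeneticReport, MedicationRecord, PatientRecord,
    ReportFinding, SyntheticCohort, default_config, generate_cohort,
)
from oncograph.integrate import build_bundles, derive_all_relations
from oncograph.normalize import ConceptDictionary


@pytest.fixture(scope="session")
def bundled_dict():
    return ConceptDictionary.bundled()


@pytest.fixture(scope="session")
def small_config():
    cfg = default_config()
    cfg.n_patients = 150
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=7)


@pytest.fixture(scope="session")
def small_bundles(small_cohort, bundled_dict):
    bundles, unlinked = build_bundles(small_cohort, bundled_dict)
    assert not unlinked
    return bundles


@pytest.fixture(scope="session")
def small_relations(small_bundles, bundled_dict):
    return derive_all_relations(small_bundles, 365, bundled_dict)


def _patient(pid, clinic, first, last, dob, sex="F", death=None,
             last_contact=None):
    return PatientRecord(
        patient_id=pid, clinic_number=clinic, first_name=first,
        last_name=last, dob=dt.date.fromisoformat(dob), sex=sex,
        race="White", ethnicity="Not Hispanic", death_date=death,
        last_contact_date=last_contact,
    )


@pytest.fixture(scope="session")
def two_patient_cohort():
    """Two hand-built patients: a lung adenocarcinoma case with EGFR, TP53
    and CHEK2 findings given osimertinib 30 days after the test, and a
    melanoma case with five findings given pembrolizumab after the test."""
    test1 = dt.date(2018, 6, 1)
    test2 = dt.date(2019, 3, 1)
    patients = [
        _patient("PT1", "CN100", "Alice", "Anderson", "1955-02-10",
                 last_contact=dt.date(2021, 6, 30)),
        _patient("PT2", "CN200", "Bruno", "Baker", "1948-11-03", sex="M",
                 last_contact=dt.date(2021, 6, 30)),
    ]
    reports = [
        GeneticReport("R1", "PT1", "CN100", "Alice", "Anderson",
                      dt.date(1955, 2, 10), "FoundationOne CDx", test1),
        GeneticReport("R2", "PT2", "CN200", "Bruno", "Baker",
                      dt.date(1948, 11, 3), "FoundationOne CDx", test2),
    ]
    findings = [
        ReportFinding("R1", "PT1", "EGFR", "EGFR L858R"),
        ReportFinding("R1", "PT1", "TP53", "TP53 R175H"),
        ReportFinding("R1", "PT1", "CHEK2", "CHEK2 I157T"),
        ReportFinding("R2", "PT2", "EGFR", "EGFR T790M"),
        ReportFinding("R2", "PT2", "TP53", "TP53 R273H"),
        ReportFinding("R2", "PT2", "DNMT3A", "DNMT3A R882H"),
        ReportFinding("R2", "PT2", "CDKN2A/B", "CDKN2A/B A148T"),
        ReportFinding("R2", "PT2", "RAF1", "RAF1 S257L"),
    ]
    diagnoses = [
        DiagnosisRecord("PT1", "lung adenocarcinoma",
                        test1 - dt.timedelta(days=100), "IV", "report"),
        DiagnosisRecord("PT2", "melanoma",
                        test2 - dt.timedelta(days=50), "III", "report"),
    ]
    medications = [
        MedicationRecord("PT1", "osimertinib",
                         test1 + dt.timedelta(days=30), "warehouse"),
        MedicationRecord("PT2", "pembrolizumab",
                         test2 + dt.timedelta(days=40), "warehouse"),
    ]
    return SyntheticCohort(
        patients=patients, reports=reports, findings=findings,
        diagnoses=diagnoses, medications=medications, note_sentences=[],
    )


@pytest.fixture(scope="session")
def two_patient_bundles(two_patient_cohort, bundled_dict):
    bundles, unlinked = build_bundles(two_patient_cohort, bundled_dict)
    assert not unlinked
    return bundles


@pytest.fixture(scope="session")
def two_patient_relations(two_patient_bundles, bundled_dict):
    return derive_all_relations(two_patient_bundles, 365, bundled_dict)
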