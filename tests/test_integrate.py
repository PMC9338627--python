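import datetime as dt

import pytest

from oncograph.cohort import DiagnosisRecord, GeneticReport, PatientRecord
from oncograph.errors import AmbiguousLinkError
from oncograph.integrate import (
    OBJECT_PROPERTIES, PatientBundle, Relation, derive_relations,
    link_records, read_relations, resolve_diseases, write_relations,
)
from oncograph.normalize import normalize_drug, map_term, normalize_variant


def _patient(pid, clinic, first="Ann", last="Ames", dob="1960-01-01"):
    return PatientRecord(pid, clinic, first, last,
                         dt.date.fromisoformat(dob), "F", "White",
                         "Not Hispanic", None, None)


def _report(rid, clinic, first="Ann", last="Ames", dob="1960-01-01",
            receipt="2018-01-01"):
    return GeneticReport(rid, "", clinic, first, last,
                         dt.date.fromisoformat(dob) if dob else None,
                         "FoundationOne CDx", dt.date.fromisoformat(receipt))


class TestLinkRecords:
    def test_clinic_number_dominates_name(self):
        patients = [_patient("P1", "C1", "Ann", "Ames")]
        reports = [_report("R1", "C1", "Zoe", "Zimmer")]
        bundles, unlinked = link_records(reports, patients)
        assert [b.patient_id for b in bundles] == ["P1"]
        assert unlinked == []

    def test_name_dob_fallback(self):
        patients = [_patient("P1", "C1")]
        reports = [_report("R1", "", "ANN", "ames")]  # case-insensitive
        bundles, unlinked = link_records(reports, patients)
        assert [b.patient_id for b in bundles] == ["P1"]

    def test_dob_mismatch_unlinked(self):
        patients = [_patient("P1", "C1", dob="1960-01-01")]
        reports = [_report("R1", "", dob="1961-01-01")]
        bundles, unlinked = link_records(reports, patients)
        assert bundles == []
        assert [r.report_id for r in unlinked] == ["R1"]

    def test_ambiguous_match_raises(self):
        patients = [_patient("P1", "C1"), _patient("P2", "C2")]
        reports = [_report("R1", "")]  # same name+dob as both
        with pytest.raises(AmbiguousLinkError) as exc:
            link_records(reports, patients)
        assert set(exc.value.candidates) == {"P1", "P2"}

    def test_earliest_receipt_is_index_date(self):
        patients = [_patient("P1", "C1")]
        reports = [_report("R1", "C1", receipt="2018-05-01"),
                   _report("R2", "C1", receipt="2017-03-01")]
        bundles, _ = link_records(reports, patients)
        assert bundles[0].index_test_date == dt.date(2017, 3, 1)


class TestResolveDiseases:
    def test_report_is_gold_standard(self, bundled_dict):
        rep = [DiagnosisRecord("P1", "lung adenocarcinoma",
                               dt.date(2018, 1, 1), "III", "report")]
        wh = [DiagnosisRecord("P1", "melanoma", dt.date(2018, 2, 1), "II",
                              "warehouse")]
        entries = resolve_diseases(rep, wh, bundled_dict)
        active = [e for e in entries if not e.superseded]
        assert [e.name for e in active] == ["lung adenocarcinoma"]
        superseded = [e for e in entries if e.superseded]
        assert [e.name for e in superseded] == ["melanoma"]

    def test_concordant_sources_merge(self, bundled_dict):
        rep = [DiagnosisRecord("P1", "melanoma", dt.date(2018, 1, 1), "",
                               "report")]
        wh = [DiagnosisRecord("P1", "Melanoma", dt.date(2018, 2, 1), "III",
                              "warehouse")]
        entries = resolve_diseases(rep, wh, bundled_dict)
        assert len(entries) == 1
        e = entries[0]
        assert e.sources == ("report", "warehouse")
        assert e.date == dt.date(2018, 2, 1)  # warehouse date preferred
        assert e.stage == "III"

    def test_noncancer_filtered(self, bundled_dict):
        wh = [DiagnosisRecord("P1", "hypertension", dt.date(2018, 1, 1), "",
                              "warehouse")]
        assert resolve_diseases([], wh, bundled_dict) == []

    def test_warehouse_only_cancer_retained(self, bundled_dict):
        wh = [DiagnosisRecord("P1", "glioma", dt.date(2018, 1, 1), "II",
                              "warehouse")]
        entries = resolve_diseases([], wh, bundled_dict)
        assert len(entries) == 1 and not entries[0].superseded


def _bundle(bundled_dict, *, dx_offset=-100, drug_offset=30,
            drug="osimertinib", genes=("EGFR", "TP53", "CHEK2"),
            disease="lung adenocarcinoma", test=dt.date(2018, 6, 1)):
    b = PatientBundle(patient_id="PX", index_test_date=test)
    for g in genes:
        gene_m = map_term(g, "gene", bundled_dict)
        var_m = normalize_variant(f"{g} amplification", g, bundled_dict)
        b.findings.append((gene_m, var_m))
    from oncograph.integrate import DiseaseEntry

    b.diseases = [DiseaseEntry(
        concept=map_term(disease, "disease", bundled_dict),
        date=test + dt.timedelta(days=dx_offset), stage="IV",
        sources=("report",))]
    b.drugs = [(normalize_drug(drug, bundled_dict),
                test + dt.timedelta(days=drug_offset), "warehouse")]
    return b


class TestDeriveRelations:
    def test_two_patient_reference_counts(self, two_patient_bundles,
                                          bundled_dict):
        b1 = next(b for b in two_patient_bundles if b.patient_id == "PT1")
        rels = derive_relations(b1, 365, bundled_dict)
        by_pred = {}
        for r in rels:
            by_pred.setdefault(r.predicate, []).append(r)
        assert len(by_pred["HasMutGene"]) == 3
        assert len(by_pred["HasVariant"]) == 3
        assert len(by_pred["AssociatedWithVariant"]) == 3
        assert len(by_pred["HasDisease"]) == 1
        assert len(by_pred["AssociatedWithGene"]) == 3
        assert [r.object for r in by_pred["TreatedBy"]] == ["osimertinib"]
        assert [(r.subject, r.object) for r in by_pred["MayTargetedBy"]] \
            == [("EGFR", "osimertinib")]
        assert len(by_pred["MayTreatedBy"]) == 1

    def test_nontargeted_drug_no_treatedby(self, two_patient_bundles,
                                           bundled_dict):
        b2 = next(b for b in two_patient_bundles if b.patient_id == "PT2")
        rels = derive_relations(b2, 365, bundled_dict)
        preds = {r.predicate for r in rels}
        assert "TreatedBy" not in preds  # immunotherapy is not targeted
        assert ("melanoma", "pembrolizumab") in {
            (r.subject, r.object) for r in rels
            if r.predicate == "MayTreatedBy"}

    def test_drug_outside_window(self, bundled_dict):
        b = _bundle(bundled_dict, drug_offset=400)
        rels = derive_relations(b, 365, bundled_dict)
        preds = {r.predicate for r in rels}
        assert "TreatedBy" not in preds and "MayTargetedBy" not in preds
        assert "MayTreatedBy" in preds  # no upper bound on disease-drug

    def test_drug_on_boundary_included(self, bundled_dict):
        b = _bundle(bundled_dict, drug_offset=365)
        preds = {r.predicate for r in derive_relations(b, 365, bundled_dict)}
        assert "TreatedBy" in preds

    def test_drug_on_test_day_excluded(self, bundled_dict):
        b = _bundle(bundled_dict, drug_offset=0)
        preds = {r.predicate for r in derive_relations(b, 365, bundled_dict)}
        assert "TreatedBy" not in preds

    def test_diagnosis_outside_window(self, bundled_dict):
        b = _bundle(bundled_dict, dx_offset=-400)
        preds = {r.predicate for r in derive_relations(b, 365, bundled_dict)}
        assert "HasDisease" not in preds and "AssociatedWithGene" not in preds

    def test_post_test_diagnosis_still_anchors_maytreatedby(
            self, bundled_dict):
        b = _bundle(bundled_dict, dx_offset=10, drug_offset=30)
        rels = derive_relations(b, 365, bundled_dict)
        preds = {r.predicate for r in rels}
        assert "HasDisease" not in preds
        assert "MayTreatedBy" in preds

    def test_repeat_prescription_counted_once(self, bundled_dict):
        b = _bundle(bundled_dict)
        b.drugs.append((b.drugs[0][0],
                        b.index_test_date + dt.timedelta(days=60),
                        "notes"))
        rels = derive_relations(b, 365, bundled_dict)
        may_treated = [r for r in rels if r.predicate == "MayTreatedBy"]
        assert len(may_treated) == 1

    def test_missing_drug_date_skipped_not_crash(self, bundled_dict, caplog):
        b = _bundle(bundled_dict)
        b.drugs.append((normalize_drug("erlotinib", bundled_dict), None,
                        "notes"))
        rels = derive_relations(b, 365, bundled_dict)
        assert all(r.object != "erlotinib" for r in rels)

    def test_monotone_window(self, small_bundles, bundled_dict):
        for b in small_bundles[:40]:
            small = {r.key() for r in derive_relations(b, 180, bundled_dict)}
            large = {r.key() for r in derive_relations(b, 720, bundled_dict)}
            assert small <= large

    def test_window_zero(self, bundled_dict):
        b = _bundle(bundled_dict, dx_offset=0, drug_offset=30)
        rels = derive_relations(b, 0, bundled_dict)
        preds = {r.predicate for r in rels}
        assert "TreatedBy" not in preds and "MayTargetedBy" not in preds
        assert "HasDisease" in preds  # same-day diagnosis survives

    def test_no_duplicates_brute_force(self, small_bundles, small_relations):
        keys = [r.key() for r in small_relations]
        assert len(keys) == len(set(keys))

    def test_domain_range_validity(self, small_relations):
        for r in small_relations:
            dom, rng = OBJECT_PROPERTIES[r.predicate]
            assert (r.subject_class, r.object_class) == (dom, rng)

    def test_invalid_domain_range_rejected(self):
        with pytest.raises(ValueError, match="requires"):
            Relation("Patient", "P1", "AssociatedWithGene", "Gene", "EGFR",
                     "P1")

    def test_boundary_perturbation_changes_only_that_drug(self, bundled_dict):
        b = _bundle(bundled_dict, drug_offset=365)
        b.drugs.append((normalize_drug("carboplatin", bundled_dict),
                        b.index_test_date + dt.timedelta(days=50),
                        "warehouse"))
        before = {r.key() for r in derive_relations(b, 365, bundled_dict)}
        # push the targeted drug across the boundary
        b.drugs[0] = (b.drugs[0][0],
                      b.index_test_date + dt.timedelta(days=366),
                      b.drugs[0][2])
        after = {r.key() for r in derive_relations(b, 365, bundled_dict)}
        changed = before ^ after
        assert changed
        assert all("osimertinib" in k for k in
                   {str(c) for c in changed})


def test_relation_table_round_trip(small_relations, tmp_path):
    path = tmp_path / "relations.tsv"
    write_relations(small_relations, path)
    back = read_relations(path)
    assert back == small_relations
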