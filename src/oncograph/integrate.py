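"""Link per-source records into per-patient bundles and derive typed
relations under the temporal validity rules.

Relation derivation windows (defaults, in days):

* Disease--Gene: diagnosis valid in the closed window ``[test - w, test]``.
* Drug--Gene: prescription valid in the half-open window ``(test, test + w]``
  and restricted to targeted therapies.
* Disease--Drug: prescription valid any time on/after the diagnosis date,
  any drug category, counted once per patient.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional

from .errors import AmbiguousLinkError
from .normalize import (
    ConceptDictionary, ConceptMapping, extract_drug_mentions, map_term,
    normalize_drug, normalize_variant,
)

log = logging.getLogger(__name__)

#: object property -> (domain class, range class); property names are part of
#: the persisted schema and must not be altered
OBJECT_PROPERTIES = {
    "HasMutGene": ("Patient", "Gene"),
    "HasVariant": ("Patient", "Variant"),
    "HasDisease": ("Patient", "Disease"),
    "TreatedBy": ("Patient", "Drug"),
    "AssociatedWithGene": ("Disease", "Gene"),
    "AssociatedWithVariant": ("Gene", "Variant"),
    "MayTreatedBy": ("Disease", "Drug"),
    "MayTargetedBy": ("Gene", "Drug"),
    "HasContraindicationWith": ("Drug", "Disease"),
}

TARGETED_CATEGORY = "targeted therapy"


@dataclass(frozen=True)
class Relation:
    subject_class: str
    subject: str
    predicate: str
    object_class: str
    object: str
    patient_id: str
    evidence_dates: Optional[tuple[Optional[dt.date], Optional[dt.date]]] = None

    def __post_init__(self):
        dom, rng = OBJECT_PROPERTIES[self.predicate]
        if (self.subject_class, self.object_class) != (dom, rng):
            raise ValueError(
                f"{self.predicate} requires ({dom}, {rng}), got "
                f"({self.subject_class}, {self.object_class})")

    def key(self):
        return (self.patient_id, self.subject_class, self.subject,
                self.predicate, self.object_class, self.object)


@dataclass
class DiseaseEntry:
    concept: ConceptMapping
    date: Optional[dt.date]
    stage: str
    sources: tuple
    superseded: bool = False

    @property
    def name(self) -> str:
        return self.concept.preferred_term or self.concept.raw_term


@dataclass
class PatientBundle:
    patient_id: str
    dob: Optional[dt.date] = None
    sex: str = ""
    race: str = ""
    ethnicity: str = ""
    death_date: Optional[dt.date] = None
    last_contact_date: Optional[dt.date] = None
    index_test_date: Optional[dt.date] = None
    reports: list = field(default_factory=list)
    findings: list = field(default_factory=list)  # (gene map, variant map)
    diseases: list = field(default_factory=list)  # DiseaseEntry
    drugs: list = field(default_factory=list)  # (drug map, date, source)

    def active_diseases(self):
        return [d for d in self.diseases if not d.superseded]

    def mutated_genes(self):
        seen, out = set(), []
        for gene_m, _ in self.findings:
            name = gene_m.preferred_term or gene_m.raw_term
            if name not in seen:
                seen.add(name)
                out.append(name)
        return out


def variant_label(gene: str, mapping: ConceptMapping) -> str:
    """Stable display label for a variant concept; keeps gene context so
    labels do not collide across genes."""
    if mapping.status == "mapped":
        return mapping.preferred_term
    if mapping.status == "hgvs_normalized":
        return f"{gene} {mapping.preferred_term}"
    return mapping.raw_term


def link_records(reports, ehr_patients):
    """Link genetic reports to patients by clinic number, falling back to
    exact (case-folded name, date of birth) match.

    Returns ``(bundles, unlinked_reports)``; bundles carry demographics and
    the earliest report receipt date as the index test date.
    """
    by_clinic: dict[str, list] = {}
    by_name_dob: dict[tuple, list] = {}
    for p in ehr_patients:
        if p.clinic_number:
            by_clinic.setdefault(p.clinic_number, []).append(p)
        key = (p.first_name.casefold(), p.last_name.casefold(), p.dob)
        by_name_dob.setdefault(key, []).append(p)

    linked: dict[str, list] = {}
    unlinked = []
    for r in reports:
        if r.clinic_number:
            candidates = by_clinic.get(r.clinic_number, [])
        else:
            key = (r.first_name.casefold(), r.last_name.casefold(), r.dob)
            candidates = by_name_dob.get(key, [])
        if len(candidates) > 1:
            raise AmbiguousLinkError(
                r.report_id, [p.patient_id for p in candidates])
        if not candidates:
            unlinked.append(r)
            continue
        linked.setdefault(candidates[0].patient_id, []).append(r)

    patients_by_id = {p.patient_id: p for p in ehr_patients}
    bundles = []
    for pid, reps in linked.items():
        p = patients_by_id[pid]
        bundles.append(PatientBundle(
            patient_id=pid, dob=p.dob, sex=p.sex, race=p.race,
            ethnicity=p.ethnicity, death_date=p.death_date,
            last_contact_date=p.last_contact_date,
            index_test_date=min(r.receipt_date for r in reps),
            reports=sorted(reps, key=lambda r: (r.receipt_date, r.report_id)),
        ))
    bundles.sort(key=lambda b: b.patient_id)
    return bundles, unlinked


def _is_cancer(mapping: ConceptMapping, dictionary: ConceptDictionary) -> bool:
    if mapping.preferred_term is None:
        return False
    entry = dictionary.lookup("disease", mapping.preferred_term)
    return bool(entry and entry.is_cancer)


def resolve_diseases(report_dx, warehouse_dx, dictionary: ConceptDictionary):
    """Merge diagnosis records from the two sources.

    Non-cancer (or unmappable) diagnoses are dropped.  When the two sources
    disagree on a cancer, the genetic report wins and the warehouse entry is
    kept but marked superseded.  Dates and stages prefer the warehouse record
    when present.
    """
    entries: list[DiseaseEntry] = []

    def _prepare(records):
        out = []
        for rec in records:
            m = map_term(rec.disease, "disease", dictionary)
            if not _is_cancer(m, dictionary):
                continue
            out.append((m, rec))
        return out

    rep = _prepare(report_dx)
    wh = _prepare(warehouse_dx)
    rep_cuis = {m.cui for m, _ in rep}

    for m, rec in rep:
        entry = DiseaseEntry(
            concept=m, date=rec.date, stage=rec.stage, sources=("report",))
        for wm, wrec in wh:
            if wm.cui == m.cui:
                entry.sources = ("report", "warehouse")
                if wrec.date is not None:
                    entry.date = wrec.date
                if wrec.stage:
                    entry.stage = wrec.stage
        entries.append(entry)

    for wm, wrec in wh:
        if wm.cui in rep_cuis:
            continue  # merged above
        superseded = bool(rep)  # report is the gold standard when it speaks
        entries.append(DiseaseEntry(
            concept=wm, date=wrec.date, stage=wrec.stage,
            sources=("warehouse",), superseded=superseded))
    return entries


def build_bundles(cohort, dictionary: ConceptDictionary,
                  include_note_mentions: bool = True):
    """Full linkage + normalization pipeline from a cohort to bundles.

    Returns ``(bundles, unlinked_reports)``.
    """
    bundles, unlinked = link_records(cohort.reports, cohort.patients)
    by_id = {b.patient_id: b for b in bundles}

    findings_by_pid: dict[str, list] = {}
    for f in cohort.findings:
        findings_by_pid.setdefault(f.patient_id, []).append(f)
    dx_by_pid: dict[str, dict[str, list]] = {}
    for d in cohort.diagnoses:
        dx_by_pid.setdefault(d.patient_id, {}).setdefault(
            d.source, []).append(d)
    meds_by_pid: dict[str, list] = {}
    for m in cohort.medications:
        meds_by_pid.setdefault(m.patient_id, []).append(
            (m.drug, m.date, m.source))
    if include_note_mentions:
        mentions = extract_drug_mentions(
            [(n.patient_id, n.date, n.text) for n in cohort.note_sentences],
            dictionary)
        for rec in mentions:
            meds_by_pid.setdefault(rec["patient_id"], []).append(
                (rec["drug"], rec["date"], rec["source"]))

    for pid, b in by_id.items():
        for f in findings_by_pid.get(pid, []):
            gene_m = map_term(f.gene, "gene", dictionary)
            var_m = normalize_variant(f.variant, f.gene, dictionary)
            b.findings.append((gene_m, var_m))
        dx = dx_by_pid.get(pid, {})
        b.diseases = resolve_diseases(
            dx.get("report", []), dx.get("warehouse", []), dictionary)
        for drug_raw, date, source in meds_by_pid.get(pid, []):
            b.drugs.append((normalize_drug(drug_raw, dictionary),
                            date, source))
        b.drugs.sort(key=lambda t: (t[1] or dt.date.min,
                                    t[0].preferred_term or t[0].raw_term,
                                    t[2]))
    return bundles, unlinked


def derive_relations(bundle: PatientBundle, window_days: int = 365,
                     dictionary: Optional[ConceptDictionary] = None):
    """Derive the per-patient relation set under the temporal rules; the
    output is deduplicated on (subject, predicate, object)."""
    if dictionary is None:
        dictionary = ConceptDictionary.bundled()
    relations: list[Relation] = []
    seen = set()

    def emit(rel: Relation):
        if rel.key() not in seen:
            seen.add(rel.key())
            relations.append(rel)

    pid = bundle.patient_id
    t = bundle.index_test_date

    genes = bundle.mutated_genes()
    for gene_m, var_m in bundle.findings:
        gene = gene_m.preferred_term or gene_m.raw_term
        var = variant_label(gene_m.raw_term, var_m)
        emit(Relation("Patient", pid, "HasMutGene", "Gene", gene, pid))
        emit(Relation("Patient", pid, "HasVariant", "Variant", var, pid))
        emit(Relation("Gene", gene, "AssociatedWithVariant", "Variant",
                      var, pid))

    in_window_dx = []
    for entry in bundle.active_diseases():
        if entry.date is None:
            log.warning("patient %s: diagnosis %s has no date; skipped",
                        pid, entry.name)
            continue
        if (t is not None
                and t - dt.timedelta(days=window_days) <= entry.date <= t):
            in_window_dx.append(entry)
            emit(Relation("Patient", pid, "HasDisease", "Disease",
                          entry.name, pid, (entry.date, t)))
            for gene in genes:
                emit(Relation("Disease", entry.name, "AssociatedWithGene",
                              "Gene", gene, pid, (entry.date, t)))

    for drug_m, date, source in bundle.drugs:
        drug = drug_m.preferred_term or drug_m.raw_term
        if date is None:
            log.warning("patient %s: drug %s has no date; skipped", pid, drug)
            continue
        entry = dictionary.lookup("drug", drug)
        targeted = bool(entry and entry.drug_category == TARGETED_CATEGORY)
        if (t is not None and targeted
                and t < date <= t + dt.timedelta(days=window_days)):
            emit(Relation("Patient", pid, "TreatedBy", "Drug", drug, pid,
                          (t, date)))
            targets = set(entry.targets) if entry else set()
            for gene in genes:
                if gene in targets:
                    emit(Relation("Gene", gene, "MayTargetedBy", "Drug",
                                  drug, pid, (t, date)))
        for dx_entry in bundle.active_diseases():
            if dx_entry.date is not None and date >= dx_entry.date:
                emit(Relation("Disease", dx_entry.name, "MayTreatedBy",
                              "Drug", drug, pid, (dx_entry.date, date)))
    return relations


def derive_all_relations(bundles, window_days: int = 365,
                         dictionary: Optional[ConceptDictionary] = None):
    if dictionary is None:
        dictionary = ConceptDictionary.bundled()
    out = []
    for b in bundles:
        out.extend(derive_relations(b, window_days, dictionary))
    return out


# ---- relation table persistence -------------------------------------------

RELATION_COLUMNS = ["subject_class", "subject", "predicate", "object_class",
                    "object", "patient_id", "date_start", "date_end"]


def write_relations(relations, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RELATION_COLUMNS)
        for r in relations:
            d0, d1 = r.evidence_dates or (None, None)
            w.writerow([
                r.subject_class, r.subject, r.predicate, r.object_class,
                r.object, r.patient_id,
                d0.isoformat() if d0 else "", d1.isoformat() if d1 else "",
            ])


def read_relations(path):
    import csv

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            dates = None
            if row["date_start"] or row["date_end"]:
                dates = (
                    dt.date.fromisoformat(row["date_start"])
                    if row["date_start"] else None,
                    dt.date.fromisoformat(row["date_end"])
                    if row["date_end"] else None,
                )
            out.append(Relation(
                row["subject_class"], row["subject"], row["predicate"],
                row["object_class"], row["object"], row["patient_id"],
                dates))
    return out
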