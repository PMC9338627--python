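"""Materialize entity tables and relations as a typed RDF graph.

IRIs are deterministic: ``namespace + Class + "/" + local`` where the local
identifier is the concept's CUI when present, the slugified name otherwise,
and the patient identifier for patients.  Rebuilding from the same inputs
yields the identical triple set.
"""

from __future__ import annotations

import datetime as dt
import re

from ..errors import ReferentialIntegrityError
from ..normalize import ConceptDictionary
from .model import A, IRI, KnowledgeGraph, Literal, XSD_DATE
from .schema import DEFAULT_SCHEMA, SchemaDef

DEFAULT_NAMESPACE = "http://example.org/oncograph/"

_NAME_PROPERTY = {
    "Patient": "Patient_ID",
    "Gene": "Gene_Name",
    "Variant": "Var_Name",
    "Disease": "Disease_Name",
    "Drug": "Drug_Name",
}


def slugify(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_\-]", "_", name.strip())


def entity_iri(namespace: str, cls: str, entity: dict) -> IRI:
    """Deterministic IRI: the slugified name, suffixed with the CUI when one
    is present so homonymous concepts stay distinct.  Keeping the name in the
    IRI is what lets the gene-centric retrieval filter on ``str(?Gene)``."""
    name = entity[_NAME_PROPERTY[cls]]
    local = slugify(str(name))
    if cls != "Patient" and entity.get("UMLS_CUI"):
        local = f"{local}_{entity['UMLS_CUI']}"
    return IRI(f"{namespace}{cls}/{local}")


def build_graph(entities: dict, relations, schema: SchemaDef = DEFAULT_SCHEMA,
                namespace: str = DEFAULT_NAMESPACE) -> KnowledgeGraph:
    """Emit one typing triple plus one triple per populated data property per
    entity, and one object-property triple per unique relation."""
    schema.validate()
    g = KnowledgeGraph(namespace=namespace)
    by_name: dict[tuple[str, str], IRI] = {}

    for cls in schema.classes:
        for entity in entities.get(cls, []):
            iri = entity_iri(namespace, cls, entity)
            name = str(entity[_NAME_PROPERTY[cls]])
            by_name[(cls, name)] = iri
            g.add(iri, A, IRI(namespace + cls))
            for prop in schema.data_properties[cls]:
                value = entity.get(prop)
                if value is None or value == "":
                    continue
                if isinstance(value, dt.date):
                    obj = Literal(value.isoformat(), XSD_DATE)
                else:
                    obj = Literal(str(value))
                g.add(iri, IRI(namespace + prop), obj)

    for rel in relations:
        for cls, name, side in ((rel.subject_class, rel.subject, "subject"),
                                (rel.object_class, rel.object, "object")):
            if (cls, name) not in by_name:
                raise ReferentialIntegrityError(
                    f"relation {rel.predicate} {side} ({cls}, {name!r}) "
                    f"missing from entity tables")
        g.add(by_name[(rel.subject_class, rel.subject)],
              IRI(namespace + rel.predicate),
              by_name[(rel.object_class, rel.object)])
    return g


def count_by_class(graph: KnowledgeGraph) -> dict:
    """Triples per class, attributed to the subject's class; includes the
    typing triple itself.  The 'total' key is the full graph size."""
    types: dict[IRI, str] = {}
    ns = graph.namespace
    for s, p, o in graph.match(p=A):
        if isinstance(o, IRI) and o.value.startswith(ns):
            types[s] = o.value[len(ns):]
    counts: dict[str, int] = {}
    for s, _, _ in graph.triples:
        cls = types.get(s)
        if cls is not None:
            counts[cls] = counts.get(cls, 0) + 1
    counts["total"] = len(graph)
    return counts


# ---- entity-table construction ---------------------------------------------

def _gene_entity(name: str, dictionary: ConceptDictionary) -> dict:
    e = dictionary.lookup("gene", name)
    row = {"Gene_Name": name}
    if e:
        row.update({
            "UMLS_CUI": e.cui, "OMIM_ID": e.external_id("omim_id"),
            "CIViC_Gene_ID": e.external_id("civic_id"),
            "OncoKB_Gene_ID": e.external_id("oncokb_id"),
            "PharmGKB_Gene_ID": e.external_id("pharmgkb_id"),
        })
    return row


def _variant_entity(label: str, dictionary: ConceptDictionary) -> dict:
    e = dictionary.lookup("variant", label)
    row = {"Var_Name": label}
    if e:
        row.update({
            "UMLS_CUI": e.cui, "ClinVar_ID": e.external_id("clinvar_id"),
            "dbSNP_ID": e.external_id("dbsnp_id"),
            "CIViC_Var_ID": e.external_id("civic_id"),
            "OncoKB_Var_ID": e.external_id("oncokb_id"),
        })
    return row


def _disease_entity(name: str, dictionary: ConceptDictionary) -> dict:
    e = dictionary.lookup("disease", name)
    row = {"Disease_Name": name}
    if e:
        row.update({
            "UMLS_CUI": e.cui, "OMIM_ID": e.external_id("omim_id"),
            "CIViC_DOID": e.external_id("doid"),
            "OncoKB_Disease_ID": e.external_id("oncokb_id"),
            "PharmGKB_Disease_ID": e.external_id("pharmgkb_id"),
        })
    return row


def _drug_entity(name: str, dictionary: ConceptDictionary,
                 brand_by_chem: dict) -> dict:
    e = dictionary.lookup("drug", name)
    row = {"Drug_Name": name, "Brand_Name": brand_by_chem.get(name)}
    if e:
        row.update({
            "Drug_Category": e.drug_category, "UMLS_CUI": e.cui,
            "NUI": e.external_id("nui"),
            "CIViC_Drug_ID": e.external_id("civic_id"),
            "OncoKB_Drug_ID": e.external_id("oncokb_id"),
            "PharmGKB_Drug_ID": e.external_id("pharmgkb_id"),
        })
    return row


def _brand_index(dictionary: ConceptDictionary) -> dict:
    brands: dict[str, str] = {}
    for (cls_, surface), e in sorted(dictionary.entries.items()):
        if cls_ == "drug" and e.brand_of:
            brands.setdefault(e.brand_of, surface.capitalize())
    return brands


def entities_from_dictionary(dictionary: ConceptDictionary) -> dict:
    """Entity tables covering every concept in a dictionary (no patients)."""
    brands = _brand_index(dictionary)
    tables = {"Patient": [], "Gene": [], "Variant": [], "Disease": [],
              "Drug": []}
    for e in sorted(dictionary.iter_class("gene"),
                    key=lambda x: x.preferred_term):
        tables["Gene"].append(_gene_entity(e.preferred_term, dictionary))
    for e in sorted(dictionary.iter_class("variant"),
                    key=lambda x: x.preferred_term):
        tables["Variant"].append(_variant_entity(e.preferred_term, dictionary))
    for e in sorted(dictionary.iter_class("disease"),
                    key=lambda x: x.preferred_term):
        tables["Disease"].append(_disease_entity(e.preferred_term, dictionary))
    seen = set()
    for e in sorted(dictionary.iter_class("drug"),
                    key=lambda x: x.preferred_term):
        chem = e.brand_of or e.preferred_term
        if chem in seen:
            continue
        seen.add(chem)
        tables["Drug"].append(_drug_entity(chem, dictionary, brands))
    return tables


def entities_from_bundles(bundles, relations,
                          dictionary: ConceptDictionary) -> dict:
    """Entity tables restricted to concepts actually referenced by the
    bundles/relations, plus one Patient row per bundle."""
    brands = _brand_index(dictionary)
    names = {"Gene": set(), "Variant": set(), "Disease": set(),
             "Drug": set()}
    for rel in relations:
        for cls, name in ((rel.subject_class, rel.subject),
                          (rel.object_class, rel.object)):
            if cls in names:
                names[cls].add(name)

    tables = {"Patient": [], "Gene": [], "Variant": [], "Disease": [],
              "Drug": []}
    for b in bundles:
        tables["Patient"].append({
            "Patient_ID": b.patient_id, "Date_of_Birth": b.dob,
            "Race": b.race, "Ethnicity": b.ethnicity, "Sex": b.sex,
            "Death": b.death_date,
        })
    for name in sorted(names["Gene"]):
        tables["Gene"].append(_gene_entity(name, dictionary))
    for name in sorted(names["Variant"]):
        tables["Variant"].append(_variant_entity(name, dictionary))
    for name in sorted(names["Disease"]):
        tables["Disease"].append(_disease_entity(name, dictionary))
    for name in sorted(names["Drug"]):
        tables["Drug"].append(_drug_entity(name, dictionary, brands))
    return tables


def unique_relations(relations):
    """Relations deduplicated to unique (subject, predicate, object)."""
    seen = set()
    out = []
    for r in relations:
        k = (r.subject_class, r.subject, r.predicate, r.object_class,
             r.object)
        if k not in seen:
            seen.add(k)
            out.append(r)
    return out
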