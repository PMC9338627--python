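"""Graph schema: classes, data properties and object properties.

Property names are bit-exact contract strings used in the serialized graph;
do not rename them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..integrate import OBJECT_PROPERTIES

CLASSES = ("Patient", "Gene", "Variant", "Disease", "Drug")

DATA_PROPERTIES = {
    "Patient": ["Patient_ID", "Date_of_Birth", "Race", "Ethnicity", "Sex",
                "Death"],
    "Gene": ["Gene_Name", "UMLS_CUI", "OMIM_ID", "CIViC_Gene_ID",
             "OncoKB_Gene_ID", "PharmGKB_Gene_ID"],
    "Variant": ["Var_Name", "UMLS_CUI", "ClinVar_ID", "dbSNP_ID",
                "CIViC_Var_ID", "OncoKB_Var_ID"],
    "Disease": ["Disease_Name", "UMLS_CUI", "OMIM_ID", "CIViC_DOID",
                "OncoKB_Disease_ID", "PharmGKB_Disease_ID",
                "Stage_At_Diagnosis"],
    "Drug": ["Drug_Name", "Brand_Name", "Drug_Category", "UMLS_CUI", "NUI",
             "CIViC_Drug_ID", "OncoKB_Drug_ID", "PharmGKB_Drug_ID"],
}


@dataclass(frozen=True)
class SchemaDef:
    classes: tuple = CLASSES
    data_properties: dict = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 DATA_PROPERTIES.items()})
    object_properties: dict = field(
        default_factory=lambda: dict(OBJECT_PROPERTIES))

    def validate(self) -> None:
        for name, dr in self.object_properties.items():
            if len(dr) != 2:
                raise ValueError(
                    f"object property {name} needs one (domain, range) pair")
            dom, rng = dr
            if dom not in self.classes or rng not in self.classes:
                raise ValueError(
                    f"object property {name}: unknown class in ({dom}, {rng})")


DEFAULT_SCHEMA = SchemaDef()
DEFAULT_SCHEMA.validate()
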