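"""Concept normalization: dictionary lookup, drug brand resolution, protein
variant fallback, note-mention extraction and coverage statistics.

The normalizer is deliberately deterministic: a term either hits the
dictionary exactly (after case folding and edge-punctuation trimming) with
score 1.0, or it misses with score 0.0.  Variants that miss get one fallback:
single-substitution protein changes such as ``L858R`` are rewritten to the
three-letter protein form ``p.Leu858Arg``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

ENTITY_CLASSES = ("gene", "variant", "disease", "drug")

#: canonical one- to three-letter amino-acid code expansion
AMINO_ACIDS = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_PROTEIN_SUBST = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")

DICTIONARY_COLUMNS = [
    "entity_class", "surface", "preferred", "cui", "omim_id", "civic_id",
    "oncokb_id", "pharmgkb_id", "clinvar_id", "dbsnp_id", "nui", "doid",
    "drug_category", "brand_of", "is_cancer", "targets",
]

_ID_SYSTEMS = [
    "omim_id", "civic_id", "oncokb_id", "pharmgkb_id", "clinvar_id",
    "dbsnp_id", "nui", "doid",
]


def fold(term: str) -> str:
    """Case-fold a surface form and trim surrounding punctuation/whitespace."""
    return term.strip().strip(".,;:()[]\"'").strip().casefold()


@dataclass(frozen=True)
class ConceptEntry:
    entity_class: str
    preferred_term: str
    cui: str = ""
    external_ids: tuple = ()  # ((id_system, value), ...)
    drug_category: str = ""
    brand_of: str = ""
    is_cancer: bool = False
    targets: tuple = ()  # gene symbols this drug is directed at

    def external_id(self, system: str) -> Optional[str]:
        for k, v in self.external_ids:
            if k == system:
                return v
        return None


class ConceptDictionary:
    """Surface-form lookup table keyed by (entity_class, folded surface)."""

    def __init__(self, entries: dict[tuple[str, str], ConceptEntry]):
        self.entries = entries
        self._validate()

    def _validate(self) -> None:
        for (cls, _), e in self.entries.items():
            if e.brand_of:
                target = ("drug", fold(e.brand_of))
                if target not in self.entries:
                    raise ValueError(
                        f"brand entry {e.preferred_term!r} points to missing "
                        f"chemical {e.brand_of!r}"
                    )

    @classmethod
    def from_file(cls, path) -> "ConceptDictionary":
        entries: dict[tuple[str, str], ConceptEntry] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(DICTIONARY_COLUMNS) - set(reader.fieldnames or [])
            if missing:
                raise ValueError(
                    f"dictionary {path} missing columns: {sorted(missing)}"
                )
            for row in reader:
                ec = row["entity_class"].strip()
                if ec not in ENTITY_CLASSES:
                    raise ValueError(f"unknown entity class {ec!r} in {path}")
                key = (ec, fold(row["surface"]))
                if key in entries:
                    raise ValueError(f"duplicate surface {key} in {path}")
                ext = tuple(
                    (sys_, row[sys_].strip())
                    for sys_ in _ID_SYSTEMS
                    if row[sys_].strip()
                )
                entries[key] = ConceptEntry(
                    entity_class=ec,
                    preferred_term=row["preferred"].strip() or row["surface"].strip(),
                    cui=row["cui"].strip(),
                    external_ids=ext,
                    drug_category=row["drug_category"].strip(),
                    brand_of=row["brand_of"].strip(),
                    is_cancer=row["is_cancer"].strip() == "1",
                    targets=tuple(
                        t for t in row["targets"].strip().split(";") if t
                    ),
                )
        return cls(entries)

    @classmethod
    def bundled(cls) -> "ConceptDictionary":
        """The curated fixture shipped with the package."""
        ref = resources.files("oncograph.data") / "concept_dictionary.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def lookup(self, entity_class: str, term: str) -> Optional[ConceptEntry]:
        if entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity class {entity_class!r}")
        return self.entries.get((entity_class, fold(term)))

    def iter_class(self, entity_class: str) -> Iterable[ConceptEntry]:
        for (cls_, _), e in self.entries.items():
            if cls_ == entity_class:
                yield e


@dataclass(frozen=True)
class ConceptMapping:
    raw_term: str
    entity_class: str
    status: str  # mapped | unmapped | hgvs_normalized
    cui: Optional[str] = None
    preferred_term: Optional[str] = None
    score: float = 0.0

    def __post_init__(self):
        if self.status == "mapped" and not self.cui:
            raise ValueError("mapped status requires a CUI")
        if self.status != "mapped" and self.cui:
            raise ValueError("CUI present requires mapped status")
        if self.status == "hgvs_normalized" and self.entity_class != "variant":
            raise ValueError("hgvs_normalized is variant-only")

    @property
    def identifiable(self) -> bool:
        return self.status == "mapped"


def map_term(raw_term: str, entity_class: str,
             dictionary: ConceptDictionary) -> ConceptMapping:
    """Exact (case-folded, punctuation-trimmed) dictionary lookup."""
    if entity_class not in ENTITY_CLASSES:
        raise ValueError(f"unknown entity class {entity_class!r}")
    if not raw_term or not raw_term.strip():
        raise ValueError("raw_term must be non-empty")
    entry = dictionary.lookup(entity_class, raw_term)
    if entry is not None and entry.brand_of:
        # brand names resolve to their chemical concept
        entry = dictionary.lookup("drug", entry.brand_of)
    if entry is None or not entry.cui:
        return ConceptMapping(raw_term, entity_class, "unmapped", score=0.0)
    return ConceptMapping(
        raw_term, entity_class, "mapped", cui=entry.cui,
        preferred_term=entry.preferred_term, score=1.0,
    )


def normalize_drug(raw: str, dictionary: ConceptDictionary) -> ConceptMapping:
    """Resolve a brand or chemical drug name to its chemical entry."""
    entry = dictionary.lookup("drug", raw)
    if entry is None:
        return ConceptMapping(raw, "drug", "unmapped", score=0.0)
    if entry.brand_of:
        entry = dictionary.lookup("drug", entry.brand_of)
        assert entry is not None  # guaranteed by dictionary validation
    if not entry.cui:
        return ConceptMapping(
            raw, "drug", "unmapped",
            preferred_term=entry.preferred_term, score=0.0,
        )
    return ConceptMapping(
        raw, "drug", "mapped", cui=entry.cui,
        preferred_term=entry.preferred_term, score=1.0,
    )


def normalize_variant(raw: str, gene: str,
                      dictionary: ConceptDictionary) -> ConceptMapping:
    """Map a variant string; fall back to three-letter protein notation for
    single-substitution patterns; otherwise keep the raw form verbatim."""
    for candidate in (raw, f"{gene} {raw}".strip()):
        entry = dictionary.lookup("variant", candidate)
        if entry is not None and entry.cui:
            return ConceptMapping(
                raw, "variant", "mapped", cui=entry.cui,
                preferred_term=entry.preferred_term, score=1.0,
            )
    token = raw.strip()
    if gene and token.upper().startswith(gene.upper() + " "):
        token = token[len(gene) + 1:].strip()
    m = _PROTEIN_SUBST.match(token)
    if m and m.group(1) in AMINO_ACIDS and m.group(3) in AMINO_ACIDS:
        ref, pos, alt = m.groups()
        hgvs = f"p.{AMINO_ACIDS[ref]}{pos}{AMINO_ACIDS[alt]}"
        return ConceptMapping(
            raw, "variant", "hgvs_normalized", preferred_term=hgvs, score=0.0,
        )
    return ConceptMapping(raw, "variant", "unmapped", score=0.0)


def extract_drug_mentions(sentences, dictionary: ConceptDictionary):
    """Whole-word, case-insensitive drug-mention matching over note sentences.

    Returns one record per (sentence, chemical) pair; repeated mentions of the
    same drug within a sentence collapse.  Records are plain dicts with keys
    patient_id, drug, date, source so callers can feed them to `integrate`.
    """
    surfaces = {}
    for (cls_, folded), entry in dictionary.entries.items():
        if cls_ != "drug":
            continue
        chem = entry.brand_of or entry.preferred_term
        surfaces[folded] = chem
    if not surfaces:
        raise ValueError("dictionary contains no drug entries")
    pattern = re.compile(
        r"\b(" + "|".join(
            re.escape(s) for s in sorted(surfaces, key=len, reverse=True)
        ) + r")\b",
        re.IGNORECASE,
    )
    records = []
    for patient_id, date, text in sentences:
        seen = set()
        for m in pattern.finditer(text):
            chem = surfaces[m.group(1).casefold()]
            if chem in seen:
                continue
            seen.add(chem)
            records.append({
                "patient_id": patient_id, "drug": chem,
                "date": date, "source": "notes",
            })
    return records


@dataclass
class ClassCoverage:
    total_occurrences: int = 0
    identifiable_occurrences: int = 0
    unique_concepts: int = 0
    unique_identifiable: int = 0

    @property
    def identifiable_pct(self) -> float:
        if self.total_occurrences == 0:
            return 0.0
        return 100.0 * self.identifiable_occurrences / self.total_occurrences


@dataclass
class CoverageTable:
    per_class: dict[str, ClassCoverage] = field(default_factory=dict)

    def __getitem__(self, entity_class: str) -> ClassCoverage:
        return self.per_class[entity_class]


def coverage_stats(mappings: Iterable[ConceptMapping]) -> CoverageTable:
    """Occurrence and unique-concept coverage per entity class.

    A mapping is identifiable only when it carries a CUI; protein-normalized
    variants without a CUI do not count as identifiable.
    """
    table = CoverageTable({c: ClassCoverage() for c in ENTITY_CLASSES})
    uniq: dict[str, set[str]] = {c: set() for c in ENTITY_CLASSES}
    uniq_id: dict[str, set[str]] = {c: set() for c in ENTITY_CLASSES}
    for m in mappings:
        cov = table.per_class[m.entity_class]
        cov.total_occurrences += 1
        key = fold(m.raw_term)
        uniq[m.entity_class].add(key)
        if m.identifiable:
            cov.identifiable_occurrences += 1
            uniq_id[m.entity_class].add(key)
    for c in ENTITY_CLASSES:
        table.per_class[c].unique_concepts = len(uniq[c])
        table.per_class[c].unique_identifiable = len(uniq_id[c])
    return table


def coverage_to_frame(table: CoverageTable):
    """Coverage table as a pandas DataFrame for CSV output."""
    import pandas as pd

    rows = []
    for cls_, cov in table.per_class.items():
        rows.append({
            "entity_class": cls_,
            "total_occurrences": cov.total_occurrences,
            "identifiable_occurrences": cov.identifiable_occurrences,
            "identifiable_pct": round(cov.identifiable_pct, 1),
            "unique_concepts": cov.unique_concepts,
            "unique_identifiable": cov.unique_identifiable,
        })
    return pd.DataFrame(rows)


def default_dictionary_path() -> Path:
    ref = resources.files("oncograph.data") / "concept_dictionary.tsv"
    with resources.as_file(ref) as p:
        return Path(p)
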