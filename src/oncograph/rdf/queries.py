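"""Canned gene-centric SPARQL queries.

``gene_properties`` mirrors the published gene-retrieval query shape: type
the subject, filter its IRI on the gene symbol, then enumerate every
(property, value) pair with a variable in predicate position.
"""

from __future__ import annotations

import re

from .build import DEFAULT_NAMESPACE

CANNED = ("gene-properties", "gene-diseases", "gene-drugs", "gene-patients")


def _prefix(namespace: str) -> str:
    return f"PREFIX og: <{namespace}>\n"


def gene_properties(gene: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    return _prefix(namespace) + (
        "SELECT distinct ?Gene ?property ?hasValue\n"
        "WHERE {?Gene a og:Gene. "
        f'FILTER regex(str(?Gene), "{re.escape(gene)}") '
        "?Gene ?property ?hasValue}"
    )


def gene_diseases(gene: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    return _prefix(namespace) + (
        "SELECT DISTINCT ?name\n"
        "WHERE {\n"
        "  ?Gene a og:Gene .\n"
        f'  FILTER regex(str(?Gene), "{re.escape(gene)}")\n'
        "  ?Disease og:AssociatedWithGene ?Gene .\n"
        "  ?Disease og:Disease_Name ?name .\n"
        "}"
    )


def gene_drugs(gene: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    return _prefix(namespace) + (
        "SELECT DISTINCT ?name\n"
        "WHERE {\n"
        "  ?Gene a og:Gene .\n"
        f'  FILTER regex(str(?Gene), "{re.escape(gene)}")\n'
        "  ?Gene og:MayTargetedBy ?Drug .\n"
        "  ?Drug og:Drug_Name ?name .\n"
        "}"
    )


def gene_patients(gene: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    return _prefix(namespace) + (
        "SELECT DISTINCT ?pid\n"
        "WHERE {\n"
        "  ?Gene a og:Gene .\n"
        f'  FILTER regex(str(?Gene), "{re.escape(gene)}")\n'
        "  ?Patient og:HasMutGene ?Gene .\n"
        "  ?Patient og:Patient_ID ?pid .\n"
        "}"
    )


def canned_query(name: str, gene: str,
                 namespace: str = DEFAULT_NAMESPACE) -> str:
    table = {
        "gene-properties": gene_properties,
        "gene-diseases": gene_diseases,
        "gene-drugs": gene_drugs,
        "gene-patients": gene_patients,
    }
    if name not in table:
        raise KeyError(f"unknown canned query {name!r}; choose from {CANNED}")
    return table[name](gene, namespace)
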