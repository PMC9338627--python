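# oncograph

Turn heterogeneous precision-oncology real-world records — genetic-report
findings, structured diagnosis/medication data, and drug mentions in clinical
notes — into a normalized RDF knowledge graph, then analyze it: gene–drug
association rules (support/confidence over patient transactions) and
mutation-stratified Kaplan–Meier survival.

Because real institutional data of this kind cannot be shared, the package
ships a synthetic-cohort generator that emulates the structure of such a
cohort (cohort size, demographic marginals, partial structured-diagnosis
coverage, variant-nomenclature mappability, planted gene–drug treatment
affinities, and a TP53 survival penalty), so every stage is testable offline.

## Components

| module | what it does |
| --- | --- |
| `oncograph.cohort` | configurable, seeded synthetic cohort generator + TSV persistence |
| `oncograph.normalize` | dictionary-based concept mapping (CUIs), drug brand→chemical normalization, protein-variant fallback (`L858R` → `p.Leu858Arg`), note drug-mention extraction, coverage statistics |
| `oncograph.integrate` | record linkage (clinic number, then name+DOB), report-vs-warehouse disease resolution, temporal-window relation derivation |
| `oncograph.rdf` | schema-typed triple store, Turtle/N-Triples round-trip, SPARQL SELECT subset (BGP, DISTINCT, `FILTER regex`, variables in predicate position), canned gene-centric queries |
| `oncograph.analytics` | transactions, support/confidence, drug ranking per gene, product-limit survival curves stratified by mutation status × stage, co-occurrence summaries |

A curated concept dictionary (~30 genes, ~40 drugs with brands and
categories, ~20 diseases, ~30 variants) is bundled at
`oncograph/data/concept_dictionary.tsv`; larger dictionaries in the same
format can be supplied with `--dict`.

## CLI

```sh
oncograph simulate  --seed 7 --out cohort/            # default 2593-patient config
oncograph normalize --cohort cohort/ --out norm/      # mappings + coverage tables
oncograph integrate --cohort cohort/ --window-days 365 --out integrated/
oncograph build     --relations integrated/ --cohort cohort/ --out graph.ttl
oncograph query     --graph graph.ttl --canned gene-properties --gene EGFR
oncograph query     --graph graph.ttl --sparql myquery.rq
oncograph assoc     --cohort cohort/ --gene EGFR --top 10 --out assoc.csv
oncograph survival  --cohort cohort/ --gene TP53 \
                    --disease "lung adenocarcinoma" --out curves.csv
```

`simulate --config cfg.yaml` accepts a YAML file mirroring
`oncograph.cohort.CohortConfig`; the shipped defaults are at
`oncograph/data/default_config.yaml`.

## Temporal validity rules

Relations are derived per patient with the genetic-test receipt date as the
anchor (window `w` = 365 days by default):

- Disease–Gene: diagnosis within `[test − w, test]` (closed).
- Drug–Gene: prescription within `(test, test + w]` (half-open), targeted
  therapies only.
- Disease–Drug: prescription on/after the diagnosis date, any category,
  counted once per patient.
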