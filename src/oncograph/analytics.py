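"""Cohort analytics: gene-drug association rules and stratified survival.

Association rules use the patient-as-transaction model: each patient's item
set is their mutated genes plus every drug prescribed within the post-test
window (all categories, not just targeted therapy).  support(X) is the
fraction of all patients whose item set contains X; confidence(X, Y) is
support(X union Y) / support(X).

Survival uses the product-limit estimator with the diagnosis date as the
time origin; the group median is the smallest observed time with S <= 0.5.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import UndefinedRuleError


@dataclass
class TransactionSet:
    transactions: dict  # patient_id -> frozenset of items

    @property
    def size(self) -> int:
        return len(self.transactions)


def build_transactions(bundles, window_days: int = 365) -> TransactionSet:
    """Item set per patient: mutated genes plus post-test-window drugs.

    Every patient counts toward the transaction total, including those with
    empty item sets.
    """
    tx = {}
    for b in bundles:
        items = set(b.mutated_genes())
        t = b.index_test_date
        if t is not None:
            for drug_m, date, _ in b.drugs:
                if date is None:
                    continue
                if t < date <= t + dt.timedelta(days=window_days):
                    items.add(drug_m.preferred_term or drug_m.raw_term)
        tx[b.patient_id] = frozenset(items)
    return TransactionSet(tx)


def support(X: Iterable[str], T: TransactionSet) -> float:
    if T.size == 0:
        raise UndefinedRuleError("support undefined on empty transaction set")
    X = frozenset(X)
    n = sum(1 for items in T.transactions.values() if X <= items)
    return n / T.size


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support_x: float
    support_xy: float
    confidence: float


def confidence(X: Iterable[str], Y: Iterable[str],
               T: TransactionSet) -> float:
    X = frozenset(X)
    Y = frozenset(Y)
    sx = support(X, T)
    if sx == 0.0:
        raise UndefinedRuleError(
            f"confidence undefined: support({sorted(X)}) = 0")
    return support(X | Y, T) / sx


def rank_drugs_for_gene(gene: str, T: TransactionSet, k: int = 10,
                        drug_items: Optional[set] = None):
    """Top-k drugs by confidence({gene} -> {drug}); ties break
    lexicographically by drug name for determinism.

    `drug_items` restricts which items count as drugs; by default every item
    that is not an all-caps-style gene symbol co-occurring with `gene` is
    considered, so callers normally pass the explicit drug universe.
    """
    sx = support({gene}, T)
    if sx == 0.0:
        raise UndefinedRuleError(f"gene {gene!r} has zero support")
    if drug_items is None:
        drug_items = set()
        for items in T.transactions.values():
            for item in items:
                if item != item.upper():  # crude: drugs are lower-case items
                    drug_items.add(item)
    scored = []
    for drug in drug_items:
        c = confidence({gene}, {drug}, T)
        scored.append((drug, c))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


# ---- Kaplan-Meier ----------------------------------------------------------

@dataclass
class SurvivalCurve:
    label: str
    event_times: list = field(default_factory=list)  # distinct event times
    at_risk: list = field(default_factory=list)  # n_i at each event time
    events: list = field(default_factory=list)  # d_i at each event time
    survival: list = field(default_factory=list)  # S after each event time
    n: int = 0

    def S(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.event_times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s

    @property
    def median(self) -> Optional[float]:
        """Smallest event time with S <= 0.5; None if never reached."""
        for time, surv in zip(self.event_times, self.survival):
            if surv <= 0.5 + 1e-12:
                return time
        return None


def km_curve(records, label: str = "") -> SurvivalCurve:
    """Product-limit estimator over (time_days, event_flag) records.

    Censored observations leave the risk set after their time (ties between
    deaths and censorings at the same time count the deaths first).
    """
    records = list(records)
    for t, _ in records:
        if t < 0:
            raise ValueError(f"negative survival time {t}")
    curve = SurvivalCurve(label=label, n=len(records))
    if not records:
        return curve
    by_time: dict[float, list[int]] = {}
    for t, e in records:
        by_time.setdefault(float(t), []).append(int(bool(e)))
    n_at_risk = len(records)
    s = 1.0
    for t in sorted(by_time):
        flags = by_time[t]
        d = sum(flags)
        if d > 0:
            s *= 1.0 - d / n_at_risk
            curve.event_times.append(t)
            curve.at_risk.append(n_at_risk)
            curve.events.append(d)
            curve.survival.append(s)
        n_at_risk -= len(flags)
    return curve


def _survival_record(bundle, index_date):
    """(time, event) from diagnosis to death or last contact; None if no
    usable follow-up."""
    if bundle.death_date is not None:
        t = (bundle.death_date - index_date).days
        return (max(t, 0), 1)
    if bundle.last_contact_date is not None:
        t = (bundle.last_contact_date - index_date).days
        return (max(t, 0), 0)
    return None


def stratified_survival(bundles, gene: str, disease: str):
    """Kaplan-Meier curves per (mutation status x stage) for patients whose
    active diseases include `disease`; index date is the diagnosis date.

    Returns a dict ``{(status, stage): SurvivalCurve}`` where status is
    "mutant" or "wildtype"; empty dict when no patient has the disease.
    """
    groups: dict[tuple[str, str], list] = {}
    for b in bundles:
        entry = next((d for d in b.active_diseases()
                      if d.name == disease), None)
        if entry is None or entry.date is None:
            continue
        rec = _survival_record(b, entry.date)
        if rec is None:
            continue
        status = "mutant" if gene in b.mutated_genes() else "wildtype"
        stage = entry.stage or "unknown"
        groups.setdefault((status, stage), []).append(rec)
    return {
        key: km_curve(recs, label=f"{key[0]}/stage {key[1]}")
        for key, recs in sorted(groups.items())
    }


def median_table(curves: dict):
    """(status, stage, n, median_days) rows from stratified curves."""
    rows = []
    for (status, stage), curve in curves.items():
        rows.append({
            "status": status, "stage": stage, "n": curve.n,
            "median_days": curve.median,
        })
    return rows


# ---- co-occurrence summary -------------------------------------------------

_PAIR_KINDS = {
    ("Disease", "Gene"): "gene-disease",
    ("Disease", "Drug"): "disease-drug",
    ("Gene", "Drug"): "gene-drug",
}


@dataclass
class CooccurrenceSummary:
    edges: dict  # (kind, node_a, node_b) -> patient count
    degree: dict  # (class, node) -> number of distinct partners

    def edge_weight(self, kind, a, b) -> int:
        return self.edges.get((kind, a, b), 0)


def cooccurrence_summary(relations) -> CooccurrenceSummary:
    """Weighted tripartite edge list over gene-disease, disease-drug and
    gene-drug pairs; edge weight counts distinct contributing patients."""
    contributors: dict[tuple, set] = {}
    for r in relations:
        key = (r.subject_class, r.object_class)
        if key in _PAIR_KINDS:
            kind = _PAIR_KINDS[key]
            a, b = r.subject, r.object
        elif (key[1], key[0]) in _PAIR_KINDS:
            kind = _PAIR_KINDS[(key[1], key[0])]
            a, b = r.object, r.subject
        else:
            continue
        contributors.setdefault((kind, a, b), set()).add(r.patient_id)
    edges = {k: len(v) for k, v in contributors.items()}
    partners: dict[tuple, set] = {}
    for (kind, a, b) in edges:
        cls_a, cls_b = {
            "gene-disease": ("Disease", "Gene"),
            "disease-drug": ("Disease", "Drug"),
            "gene-drug": ("Gene", "Drug"),
        }[kind]
        partners.setdefault((cls_a, a), set()).add((cls_b, b))
        partners.setdefault((cls_b, b), set()).add((cls_a, a))
    degree = {k: len(v) for k, v in partners.items()}
    return CooccurrenceSummary(edges=edges, degree=degree)
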