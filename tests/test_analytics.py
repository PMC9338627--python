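import itertools
import random

import numpy as np
import pytest

from oncograph import analytics
from oncograph.analytics import (
    TransactionSet, build_transactions, confidence, cooccurrence_summary,
    km_curve, rank_drugs_for_gene, stratified_survival, support,
)
from oncograph.errors import UndefinedRuleError


@pytest.fixture(scope="module")
def pair_tx(two_patient_bundles):
    return build_transactions(two_patient_bundles, 365)


class TestTransactions:
    def test_reference_pair_item_sets(self, pair_tx):
        assert pair_tx.transactions["PT1"] == frozenset(
            {"EGFR", "TP53", "CHEK2", "osimertinib"})
        assert pair_tx.transactions["PT2"] == frozenset(
            {"EGFR", "TP53", "DNMT3A", "CDKN2A/B", "RAF1", "pembrolizumab"})

    def test_patient_without_drugs_still_counts(self, two_patient_bundles):
        b = two_patient_bundles[0]
        stripped = type(b)(patient_id="PX", index_test_date=b.index_test_date,
                           findings=list(b.findings))
        T = build_transactions([stripped], 365)
        assert T.size == 1
        assert T.transactions["PX"] == frozenset({"EGFR", "TP53", "CHEK2"})

    def test_empty_cohort(self):
        T = build_transactions([], 365)
        assert T.size == 0 and T.transactions == {}

    def test_nontargeted_drugs_included(self, pair_tx):
        # transaction items are NOT restricted to targeted therapy
        assert "pembrolizumab" in pair_tx.transactions["PT2"]


class TestSupportConfidence:
    def test_universal_item(self, pair_tx):
        assert support({"EGFR"}, pair_tx) == 1.0

    def test_half_support(self, pair_tx):
        assert support({"osimertinib"}, pair_tx) == 0.5

    def test_empty_set_error(self):
        with pytest.raises(UndefinedRuleError):
            support({"EGFR"}, TransactionSet({}))

    def test_confidence_reference_pair(self, pair_tx):
        assert confidence({"EGFR"}, {"osimertinib"}, pair_tx) == 0.5

    def test_subset_consequent_is_one(self, pair_tx):
        assert confidence({"EGFR", "TP53"}, {"TP53"}, pair_tx) == 1.0

    def test_disjoint_is_zero(self, pair_tx):
        assert confidence({"CHEK2"}, {"pembrolizumab"}, pair_tx) == 0.0

    def test_zero_support_antecedent_raises(self, pair_tx):
        with pytest.raises(UndefinedRuleError):
            confidence({"BRAF"}, {"osimertinib"}, pair_tx)

    def test_identity_confidence_times_support(self, small_bundles):
        T = build_transactions(small_bundles, 365)
        items = sorted(set().union(*T.transactions.values()))
        rng = random.Random(1)
        for _ in range(50):
            X = frozenset(rng.sample(items, rng.randint(1, 2)))
            Y = frozenset(rng.sample(items, rng.randint(1, 2)))
            sx = support(X, T)
            if sx == 0:
                continue
            assert abs(confidence(X, Y, T) * sx - support(X | Y, T)) < 1e-12

    def test_brute_force_oracle_small_cohort(self, small_bundles):
        """Exhaustive set-inclusion recount on a <=20-patient cohort."""
        bundles = small_bundles[:20]
        T = build_transactions(bundles, 365)
        raw = {b.patient_id: T.transactions[b.patient_id] for b in bundles}
        items = sorted(set().union(*raw.values()))
        for X in itertools.combinations(items, 1):
            expected = sum(1 for s in raw.values() if set(X) <= s) / len(raw)
            assert support(set(X), T) == expected
        rng = random.Random(7)
        for _ in range(100):
            X = set(rng.sample(items, rng.randint(1, 3)))
            Y = set(rng.sample(items, rng.randint(1, 3)))
            nx = sum(1 for s in raw.values() if X <= s)
            nxy = sum(1 for s in raw.values() if (X | Y) <= s)
            if nx == 0:
                continue
            assert confidence(X, Y, T) == pytest.approx(nxy / nx, abs=1e-12)


class TestRanking:
    def test_planted_affinity_recovered(self, small_bundles, bundled_dict):
        T = build_transactions(small_bundles, 365)
        drugs = {e.preferred_term for e in bundled_dict.iter_class("drug")
                 if not e.brand_of}
        ranked = rank_drugs_for_gene("TP53", T, 5, drugs)
        assert len(ranked) == 5
        assert all(ranked[i][1] >= ranked[i + 1][1] for i in range(4))

    def test_k_larger_than_universe(self, pair_tx):
        ranked = rank_drugs_for_gene(
            "EGFR", pair_tx, 50, {"osimertinib", "pembrolizumab"})
        assert len(ranked) == 2

    def test_tie_broken_lexicographically(self, pair_tx):
        ranked = rank_drugs_for_gene(
            "EGFR", pair_tx, 2, {"osimertinib", "pembrolizumab"})
        # both have confidence 0.5 -> alphabetical order, stable
        assert [d for d, _ in ranked] == ["osimertinib", "pembrolizumab"]

    def test_unsupported_gene_raises(self, pair_tx):
        with pytest.raises(UndefinedRuleError):
            rank_drugs_for_gene("BRAF", pair_tx, 3, {"osimertinib"})


class TestKaplanMeier:
    def test_all_censored_flat_one(self):
        c = km_curve([(5, 0), (9, 0), (20, 0)])
        assert c.event_times == []
        assert c.S(100) == 1.0
        assert c.median is None

    def test_hand_product_limit(self):
        # events at 1 and 3, censored at 2: S(1)=2/3, S(3)=0
        c = km_curve([(1, 1), (2, 0), (3, 1)])
        assert c.event_times == [1.0, 3.0]
        assert c.survival[0] == pytest.approx(2 / 3)
        assert c.survival[1] == pytest.approx(0.0)
        assert c.at_risk == [3, 1]
        assert c.median == 3.0

    def test_single_event_steps_to_zero(self):
        c = km_curve([(5, 1)])
        assert c.S(4.9) == 1.0
        assert c.S(5) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve([(-1, 1)])

    def test_no_censoring_closed_form(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 50, size=40)
        c = km_curve([(t, 1) for t in times])
        for t in range(0, 55):
            closed = np.mean(times > t)
            assert c.S(t) == pytest.approx(closed, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(42)
        times = rng.exponential(100, size=80)
        events = rng.integers(0, 2, size=80)
        c = km_curve(list(zip(times, events)))
        kmf = KaplanMeierFitter().fit(times, events)
        for t in (10, 50, 100, 200, 400):
            assert c.S(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-9)

    def test_survival_non_increasing_in_unit_interval(self):
        rng = np.random.default_rng(3)
        recs = [(float(t), int(e)) for t, e in
                zip(rng.exponential(30, 60), rng.integers(0, 2, 60))]
        c = km_curve(recs)
        assert all(0.0 <= s <= 1.0 for s in c.survival)
        assert all(a >= b for a, b in zip(c.survival, c.survival[1:]))


class TestStratifiedSurvival:
    def test_no_patients_with_disease_empty(self, two_patient_bundles):
        assert stratified_survival(
            two_patient_bundles, "TP53", "glioma") == {}

    def test_groups_keyed_by_status_and_stage(self, two_patient_bundles):
        curves = stratified_survival(
            two_patient_bundles, "TP53", "lung adenocarcinoma")
        assert set(curves) == {("mutant", "IV")}

    def test_all_censored_day_zero(self, two_patient_bundles):
        b = two_patient_bundles[0]
        entry = b.active_diseases()[0]
        b2 = type(b)(patient_id="PZ", index_test_date=b.index_test_date,
                     findings=list(b.findings),
                     last_contact_date=entry.date)
        b2.diseases = [entry]
        curves = stratified_survival(
            [b2], "TP53", "lung adenocarcinoma")
        ((_, curve),) = curves.items()
        assert curve.S(1e9) == 1.0 and curve.median is None

    def test_null_multiplier_no_systematic_gap(self, bundled_dict):
        from oncograph.cohort import default_config, generate_cohort
        from oncograph.integrate import build_bundles

        cfg = default_config()
        cfg.n_patients = 800
        cfg.survival_model.gene_hazard_multiplier = {"TP53": 1.0}
        diffs = []
        for seed in (11, 12, 13, 14):
            bundles, _ = build_bundles(generate_cohort(cfg, seed),
                                       bundled_dict)
            curves = stratified_survival(
                bundles, "TP53", "lung adenocarcinoma")
            for stage in ("III", "IV"):
                m = curves.get(("mutant", stage))
                w = curves.get(("wildtype", stage))
                if m and w and m.median and w.median:
                    diffs.append(m.median - w.median)
        assert diffs
        # under the null the mutant is not consistently shorter
        assert not all(d < -200 for d in diffs)

    def test_penalized_gene_recovered(self, bundled_dict):
        from oncograph.cohort import default_config, generate_cohort
        from oncograph.integrate import build_bundles

        cfg = default_config()
        cfg.n_patients = 2593
        bundles, _ = build_bundles(generate_cohort(cfg, 99), bundled_dict)
        curves = stratified_survival(bundles, "TP53", "lung adenocarcinoma")
        n_lung = sum(c.n for c in curves.values())
        assert n_lung >= 500
        for stage in ("III", "IV"):
            m = curves[("mutant", stage)].median
            w = curves[("wildtype", stage)].median
            assert m is not None
            assert w is None or m < w


class TestCooccurrence:
    def test_reference_pair_edges(self, two_patient_relations):
        summ = cooccurrence_summary(two_patient_relations)
        assert summ.edge_weight(
            "gene-disease", "lung adenocarcinoma", "EGFR") == 1
        assert summ.edge_weight("gene-drug", "EGFR", "osimertinib") == 1
        assert summ.edge_weight(
            "disease-drug", "melanoma", "pembrolizumab") == 1
        # gene-gene pairs are never emitted
        assert all(kind in ("gene-disease", "disease-drug", "gene-drug")
                   for kind, _, _ in summ.edges)

    def test_empty_relations(self):
        summ = cooccurrence_summary([])
        assert summ.edges == {} and summ.degree == {}

    def test_duplicate_patient_counted_once(self, two_patient_relations):
        doubled = list(two_patient_relations) * 2
        summ = cooccurrence_summary(doubled)
        assert summ.edge_weight(
            "gene-disease", "lung adenocarcinoma", "EGFR") == 1

    def test_degree_counts_distinct_partners(self, two_patient_relations):
        summ = cooccurrence_summary(two_patient_relations)
        # PT1's lung adenocarcinoma associates with 3 genes + 1 drug
        assert summ.degree[("Disease", "lung adenocarcinoma")] == 4

    def test_weights_match_brute_force(self, small_relations):
        summ = cooccurrence_summary(small_relations)
        for (kind, a, b), w in list(summ.edges.items())[:50]:
            pred = {"gene-disease": "AssociatedWithGene",
                    "disease-drug": "MayTreatedBy",
                    "gene-drug": "MayTargetedBy"}[kind]
            if kind == "gene-drug":
                subj, obj = a, b
            else:
                subj, obj = a, b
            pids = {r.patient_id for r in small_relations
                    if r.predicate == pred and r.subject == subj
                    and r.object == obj}
            assert w == len(pids)


def test_median_table(two_patient_bundles):
    curves = stratified_survival(
        two_patient_bundles, "TP53", "lung adenocarcinoma")
    rows = analytics.median_table(curves)
    assert rows and set(rows[0]) == {"status", "stage", "n", "median_days"}
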