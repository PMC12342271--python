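"""FP-growth, association rules, marker tree, propensity, pair statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comutnet.metastasis import (
    STRONG_COOCCURRING,
    STRONG_EXCLUSIVE,
    WEAK,
    AssociationRule,
    TransactionDB,
    association_rules,
    build_marker_tree,
    cohort_pair_stats,
    fp_growth,
    pair_frequency_comparison,
    propensity,
    volcano_classify,
)
from comutnet.pairs import ContingencyTable, fisher_exact_two_sided

from conftest import matrix_from_carriers, metadata_for


def db_of(*itemsets):
    return TransactionDB(
        transactions={f"t{i}": frozenset(s) for i, s in enumerate(itemsets)}
    )


def apriori_oracle(db, min_support):
    """Exhaustive itemset enumeration — ground truth for FP-growth."""
    items = sorted({it for t in db.transactions.values() for it in t})
    n = len(db)
    out = {}
    for r in range(1, len(items) + 1):
        for combo in itertools.combinations(items, r):
            s = frozenset(combo)
            count = sum(1 for t in db.transactions.values() if s <= t)
            if count / n >= min_support - 1e-12:
                out[s] = count / n
    return out


class TestFPGrowth:
    def test_toy_database_supports(self):
        db = db_of({"A", "B"}, {"A", "B"}, {"A"}, {"B", "C"})
        mined = dict(fp_growth(db, 0.5))
        assert mined == {
            frozenset({"A"}): 0.75,
            frozenset({"B"}): 0.75,
            frozenset({"A", "B"}): 0.5,
        }

    def test_full_support_boundary(self):
        db = db_of({"A", "B"}, {"A", "C"}, {"A"})
        mined = dict(fp_growth(db, 1.0))
        assert mined == {frozenset({"A"}): 1.0}

    def test_empty_database(self):
        assert fp_growth(db_of(), 0.5) == []

    def test_invalid_support_rejected(self):
        with pytest.raises(ValueError):
            fp_growth(db_of({"A"}), 0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_oracle(self, data):
        universe = "ABCDEFGH"
        n_t = data.draw(st.integers(2, 12))
        transactions = [
            data.draw(st.sets(st.sampled_from(universe), min_size=1, max_size=6))
            for _ in range(n_t)
        ]
        min_support = data.draw(st.sampled_from([0.1, 0.25, 0.5]))
        db = db_of(*transactions)
        assert dict(fp_growth(db, min_support)) == pytest.approx(
            apriori_oracle(db, min_support)
        )

    def test_support_anti_monotone_over_mined_sets(self):
        db = db_of(*[{"A", "B", "C"}, {"A", "B"}, {"A", "C"}, {"B", "C"}, {"A"}])
        mined = dict(fp_growth(db, 0.2))
        for s, sup in mined.items():
            for t, sup_t in mined.items():
                if s < t:
                    assert sup >= sup_t - 1e-12

    def test_output_order_deterministic(self):
        db = db_of({"B", "A"}, {"A"}, {"B"})
        out = fp_growth(db, 0.1)
        assert out == fp_growth(db, 0.1)
        sups = [s for _, s in out]
        assert sups == sorted(sups, reverse=True)


class TestAssociationRules:
    def test_toy_confidence(self):
        db = db_of({"A", "B"}, {"A", "B"}, {"A"}, {"B", "C"})
        itemsets = fp_growth(db, 0.25)
        rules = association_rules(itemsets, db, min_confidence=0.0)
        a_to_b = [r for r in rules if r.antecedent == {"A"} and r.consequent == {"B"}][0]
        assert a_to_b.confidence == pytest.approx(0.5 / 0.75)
        assert a_to_b.support == pytest.approx(0.5)

    def test_singletons_yield_no_rules(self):
        db = db_of({"A"}, {"B"})
        rules = association_rules(fp_growth(db, 0.1), db, 0.0)
        assert rules == []

    def test_confidence_threshold_filters(self):
        db = db_of({"A", "B"}, {"A"}, {"A"}, {"A"})
        rules = association_rules(fp_growth(db, 0.1), db, min_confidence=0.5)
        # A=>B has confidence 0.25; B=>A has confidence 1
        assert all(not (r.antecedent == {"A"} and r.consequent == {"B"}) for r in rules)
        assert any(r.antecedent == {"B"} for r in rules)

    def test_recomputed_confidence_matches(self):
        db = db_of(*[{"A", "B", "C"}, {"A", "B"}, {"B", "C"}, {"A", "C"}, {"A", "B", "C"}])
        itemsets = fp_growth(db, 0.2)
        n = len(db)
        for r in association_rules(itemsets, db, 0.0):
            union = r.antecedent | r.consequent
            sup_u = sum(1 for t in db.transactions.values() if union <= t) / n
            sup_a = sum(1 for t in db.transactions.values() if r.antecedent <= t) / n
            assert r.confidence == pytest.approx(sup_u / sup_a, abs=1e-12)
            assert 0 <= r.confidence <= 1

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            AssociationRule(frozenset("A"), frozenset("A"), 0.5, 0.5)


class TestMarkerTree:
    def _rules_chain(self):
        # supports: A 0.8, B 0.6, C 0.4 -> chain order A, B, C
        itemsets = [
            (frozenset("A"), 0.8), (frozenset("B"), 0.6), (frozenset("C"), 0.4),
            (frozenset("AB"), 0.55), (frozenset("ABC"), 0.4),
        ]
        rules = [
            AssociationRule(frozenset("A"), frozenset("B"), 0.55, 0.69),
            AssociationRule(frozenset("AB"), frozenset("C"), 0.4, 0.73),
        ]
        return rules, itemsets

    def test_chain_constructed_root_to_leaf(self):
        rules, itemsets = self._rules_chain()
        tree = build_marker_tree(rules, itemsets, prune_root_pairs=False)
        assert ("A", "B", "C") in tree.paths()

    def test_prefix_rule_below_threshold_blocks_extension(self):
        rules, itemsets = self._rules_chain()
        tree = build_marker_tree(rules, itemsets, min_confidence=0.7, prune_root_pairs=False)
        assert all(len(p) < 3 for p in tree.paths())

    def test_root_pair_pruning_empties_single_pair_tree(self):
        itemsets = [(frozenset("A"), 0.5), (frozenset("B"), 0.4), (frozenset("AB"), 0.35)]
        rules = [AssociationRule(frozenset("A"), frozenset("B"), 0.35, 0.7)]
        tree = build_marker_tree(rules, itemsets, prune_root_pairs=True)
        assert tree.nodes == {} and tree.edges == []

    def test_triplet_survives_pruning(self):
        rules, itemsets = self._rules_chain()
        tree = build_marker_tree(rules, itemsets, prune_root_pairs=True)
        assert ("A", "B", "C") in tree.paths()

    def test_tree_is_acyclic_prefix_structure(self):
        rules, itemsets = self._rules_chain()
        tree = build_marker_tree(rules, itemsets, prune_root_pairs=False)
        for e in tree.edges:
            if e["source"] != tree.root:
                assert e["target"].startswith(e["source"] + "|")

    def test_json_and_dot_export(self, tmp_path):
        rules, itemsets = self._rules_chain()
        tree = build_marker_tree(rules, itemsets, prune_root_pairs=False)
        tree.to_json(tmp_path / "tree.json")
        text = tree.to_dot()
        import json

        payload = json.loads((tmp_path / "tree.json").read_text())
        assert {n["item"] for n in payload["nodes"]} == {"A", "B", "C"}
        assert "digraph" in text


class TestPropensity:
    def test_worked_example(self):
        assert propensity(3, 4, 50, 200) == pytest.approx(3.0)

    def test_background_rate_gives_one(self):
        assert propensity(5, 20, 50, 200) == pytest.approx(1.0)

    def test_absent_from_metastatic_gives_zero(self):
        assert propensity(0, 10, 50, 200) == 0.0

    def test_scale_invariance(self):
        base = propensity(3, 12, 40, 160)
        assert propensity(6, 24, 80, 320) == pytest.approx(base)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            propensity(0, 0, 50, 200)
        with pytest.raises(ValueError):
            propensity(1, 2, 0, 200)
        with pytest.raises(ValueError):
            propensity(5, 4, 50, 200)


class TestCohortPairStats:
    def test_or_arithmetic(self):
        m = matrix_from_carriers(
            {
                "A:G1D": ["s0", "s1", "s2", "s3", "s4", "s5"],
                "B:R2H": ["s0", "s1", "s2", "s3", "s6"],
            },
            [f"s{i}" for i in range(10)],
        )
        out = cohort_pair_stats(m)
        row = out.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (4, 2, 1, 3)
        assert row.odds_ratio == pytest.approx(6.0)

    def test_fisher_matches_pair_mining_oracle(self, rng):
        samples = [f"s{i}" for i in range(30)]
        carriers = {
            f"G{j}:A{j+1}V": [s for s in samples if rng.random() < 0.3]
            for j in range(5)
        }
        carriers = {k: v for k, v in carriers.items() if v}
        m = matrix_from_carriers(carriers, samples)
        out = cohort_pair_stats(m)
        for row in out.itertuples(index=False):
            _, p = fisher_exact_two_sided(ContingencyTable(row.a, row.b, row.c, row.d))
            assert row.fisher_p == pytest.approx(p, abs=1e-12)

    def test_degenerate_margins_give_missing_chi2(self):
        m = matrix_from_carriers(
            {"A:G1D": ["s0", "s1", "s2"], "B:R2H": []}, ["s0", "s1", "s2"]
        )
        # empty carrier column dropped by builder; use all-carriers instead
        m = matrix_from_carriers(
            {"A:G1D": ["s0", "s1", "s2"], "B:R2H": ["s0", "s1", "s2"]},
            ["s0", "s1", "s2"],
        )
        out = cohort_pair_stats(m)
        assert math.isnan(out.iloc[0].chi2)


class TestVolcanoClassify:
    @pytest.mark.parametrize(
        "orr,p,expected",
        [
            (10.0, 0.001, STRONG_COOCCURRING),
            (0.1, 0.001, STRONG_EXCLUSIVE),
            (10.0, 0.05, WEAK),   # -log10(0.05) ~ 1.30 < 1.65
            (2.0, 0.001, WEAK),   # log10(2) ~ 0.30 < 0.75
        ],
    )
    def test_threshold_logic(self, orr, p, expected):
        assert volcano_classify(orr, p)[0] == expected

    def test_infinite_or_uses_continuity_correction(self):
        cls, corrected = volcano_classify(
            math.inf, 1e-6, table=ContingencyTable(20, 0, 0, 20)
        )
        assert cls == STRONG_COOCCURRING and corrected


class TestPairFrequencyComparison:
    def test_metastatic_only_pair(self):
        samples = [f"s{i}" for i in range(10)]
        m = matrix_from_carriers(
            {"A:G1D": ["s0", "s1"], "B:R2H": ["s0", "s1"]}, samples
        )
        meta = metadata_for(samples, metastatic=["s0", "s1"])
        out = pair_frequency_comparison(m, meta)
        row = out.iloc[0]
        assert row.primary_fraction == 0.0
        assert row.propensity == pytest.approx(10 / 2)  # N/X

    def test_proportional_pair_has_unit_propensity(self):
        samples = [f"s{i}" for i in range(10)]
        m = matrix_from_carriers(
            {"A:G1D": ["s0", "s5"], "B:R2H": ["s0", "s5"]}, samples
        )
        meta = metadata_for(samples, metastatic=["s0", "s1", "s2", "s3", "s4"])
        out = pair_frequency_comparison(m, meta)
        assert out.iloc[0].propensity == pytest.approx(1.0)
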