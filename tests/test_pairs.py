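"""Pair enumeration, Fisher exact test, BH correction, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import hypergeom

from comutnet.cohort import DataError, DriverCatalog, MutationKey, parse_key
from comutnet.pairs import (
    CO_EXISTING,
    EXCLUDED,
    NEUTRAL,
    ContingencyTable,
    PairResult,
    bh_adjust,
    build_table,
    classify_pair,
    composition,
    enumerate_candidates,
    fisher_exact_batch,
    fisher_exact_two_sided,
    mine_pairs,
    odds_ratio,
    summarize_pairs,
)
from comutnet.simulate import PairSpec, generate_cohort
from comutnet.cohort import filter_cohort

from conftest import matrix_from_carriers


def enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


class TestEnumerateCandidates:
    def test_same_gene_pairs_excluded(self, toy_matrix):
        # 4 mutations in 3 genes, PIK3CA contributes two -> C(4,2)-1 = 5
        pairs = enumerate_candidates(toy_matrix)
        assert len(pairs) == 5
        assert all(a.gene != b.gene for a, b in pairs)
        assert all(a < b for a, b in pairs)

    def test_single_gene_cohort_yields_nothing(self):
        m = matrix_from_carriers(
            {"KRAS:G12D": ["s0"], "KRAS:G12V": ["s1"]}, ["s0", "s1"]
        )
        assert enumerate_candidates(m) == []

    def test_minimal_two_gene_case(self):
        m = matrix_from_carriers(
            {"KRAS:G12D": ["s0"], "TP53:R175H": ["s1"]}, ["s0", "s1"]
        )
        assert len(enumerate_candidates(m)) == 1


class TestBuildTable:
    def test_counts_partition_the_cohort(self, toy_matrix):
        t = build_table(toy_matrix, parse_key("KRAS:G12D"), parse_key("TP53:R175H"))
        assert (t.a, t.b, t.c, t.d) == (3, 1, 1, 3)
        assert t.n_total == toy_matrix.n_samples

    def test_disjoint_carriers_give_zero_joint(self, toy_matrix):
        t = build_table(toy_matrix, parse_key("PIK3CA:E545K"), parse_key("KRAS:G12D"))
        assert t.a == 0

    def test_identical_carrier_sets(self):
        m = matrix_from_carriers(
            {"A:G1D": ["s0", "s1"], "B:R2H": ["s0", "s1"]}, ["s0", "s1", "s2"]
        )
        t = build_table(m, parse_key("A:G1D"), parse_key("B:R2H"))
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 1)

    def test_missing_key_is_error(self, toy_matrix):
        with pytest.raises(DataError):
            build_table(toy_matrix, parse_key("NOPE:X1Y"), parse_key("KRAS:G12D"))


class TestFisherExact:
    def test_perfectly_concordant_table(self):
        orr, p = fisher_exact_two_sided(ContingencyTable(3, 0, 0, 3))
        assert math.isinf(orr)
        assert p == pytest.approx(0.1)  # 2/20 of the hypergeometric mass

    def test_balanced_table_is_null(self):
        orr, p = fisher_exact_two_sided(ContingencyTable(1, 1, 1, 1))
        assert orr == 1.0
        assert p == 1.0

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_zero_cell_odds_ratio_conventions(self):
        assert math.isinf(odds_ratio(ContingencyTable(2, 0, 1, 3)))
        assert odds_ratio(ContingencyTable(0, 2, 1, 0)) == 0.0
        assert math.isnan(odds_ratio(ContingencyTable(0, 0, 1, 1)))

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_matches_enumeration_oracle_and_scipy(self, a, b, c, d):
        _, p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(enumeration_oracle(a, b, c, d), abs=1e-12)
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], abs=1e-10)

    def test_batch_agrees_with_single(self, rng):
        tables = rng.integers(0, 40, size=(50, 4))
        batch = fisher_exact_batch(tables)
        singles = [fisher_exact_two_sided(ContingencyTable(*map(int, t)))[1] for t in tables]
        assert np.allclose(batch, singles, atol=1e-14)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.integers(1, 10), b=st.integers(1, 10),
        c=st.integers(1, 10), d=st.integers(1, 10),
    )
    def test_odds_ratio_reciprocal_identity(self, a, b, c, d):
        orr = odds_ratio(ContingencyTable(a, b, c, d))
        rec = odds_ratio(ContingencyTable(b, a, d, c))
        assert orr * rec == pytest.approx(1.0)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_clipped(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_oracle_on_random_vectors(self, rng):
        # q_i = min over j with p_j >= p_i of p_j * m / rank_j
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)
            ranked = p[order]
            q_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.random(30))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-15)


def _result(q, orr, a=5, n=100):
    b = c = 10
    return PairResult(
        key_a=MutationKey("A", "G1D"), key_b=MutationKey("B", "R2H"),
        table=ContingencyTable(a, b, c, n - a - b - c),
        odds_ratio=orr, p_value=q / 2, q_value=q,
    )


class TestClassifyPair:
    def test_significant_cooccurring(self):
        assert classify_pair(_result(0.29, 5.2, a=4)) == CO_EXISTING

    def test_significant_exclusive_with_zero_joint(self):
        assert classify_pair(_result(0.29, 0.1, a=0)) == EXCLUDED

    def test_above_q_threshold_not_reported(self):
        assert classify_pair(_result(0.31, 9.0)) == NEUTRAL

    def test_cooccurring_needs_min_joint(self):
        assert classify_pair(_result(0.01, 5.0, a=2)) == NEUTRAL

    def test_or_exactly_one_is_neutral(self):
        assert classify_pair(_result(0.01, 1.0)) == NEUTRAL


class TestComposition:
    @pytest.mark.parametrize(
        "catalog_keys,expected",
        [
            (["A:G1D", "B:R2H"], "D+D"),
            (["A:G1D"], "D+P"),
            ([], "P+P"),
        ],
    )
    def test_unordered_composition(self, catalog_keys, expected):
        catalog = DriverCatalog.from_keys(catalog_keys)
        assert composition(parse_key("A:G1D"), parse_key("B:R2H"), catalog) == expected


class TestMinePairs:
    def test_empty_candidate_list(self):
        m = matrix_from_carriers({"KRAS:G12D": ["s0"]}, ["s0", "s1"])
        assert mine_pairs(m) == []

    def test_planted_pair_recovered_and_sorted(self):
        spec = PairSpec(MutationKey("A", "G12D"), MutationKey("B", "R175H"), 0.2, 0.2, 9.0)
        mutations, metadata, _ = generate_cohort(
            2000, 10, pair_specs=[spec], seed=21
        )
        from comutnet.cohort import MutationRecord

        records = [
            MutationRecord(r.sample_id, r.gene, r.protein_change, r.vaf)
            for r in mutations.itertuples(index=False)
        ]
        matrix = filter_cohort(records, list(metadata["sample_id"]))
        results = mine_pairs(matrix)
        top = results[0]
        assert {top.key_a.render(), top.key_b.render()} == {"A:G12D", "B:R175H"}
        assert top.pair_class == CO_EXISTING
        qs = [r.q_value for r in results]
        assert qs == sorted(qs)

    def test_deterministic_for_fixed_input(self, toy_matrix):
        r1 = mine_pairs(toy_matrix, significant_only=False)
        r2 = mine_pairs(toy_matrix, significant_only=False)
        assert r1 == r2

    def test_classification_invariant_to_input_order(self, toy_matrix):
        shuffled = matrix_from_carriers(
            {
                k.render(): [
                    s for s, bit in zip(toy_matrix.samples, toy_matrix.carriers(k)) if bit
                ]
                for k in reversed(toy_matrix.mutations)
            },
            list(reversed(toy_matrix.samples)),
        )
        r1 = mine_pairs(toy_matrix, significant_only=False)
        r2 = mine_pairs(shuffled, significant_only=False)
        assert [(r.key_a, r.key_b, r.pair_class) for r in r1] == [
            (r.key_a, r.key_b, r.pair_class) for r in r2
        ]


class TestSummarizePairs:
    def test_tallies_partition_the_results(self):
        results = (
            [_result(0.1, 5.0)] * 2 + [_result(0.1, 0.5)] * 1
        )
        results = [
            PairResult(
                key_a=r.key_a, key_b=r.key_b, table=r.table,
                odds_ratio=r.odds_ratio, p_value=r.p_value, q_value=r.q_value,
                pair_class=cls, composition=comp,
            )
            for r, cls, comp in zip(
                results, [CO_EXISTING, CO_EXISTING, EXCLUDED], ["D+D", "D+P", "D+D"]
            )
        ]
        s = summarize_pairs(results)
        total = int(s.loc[(s.pair_class == "total") & (s.composition == "total"), "n"].iloc[0])
        class_totals = s[(s.composition == "total") & (s.pair_class != "total")]["n"].sum()
        comp_totals = s[(s.pair_class == "total") & (s.composition != "total")]["n"].sum()
        assert total == 3 == class_totals == comp_totals
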