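import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fuzzydea.fuzzy_counts import (
    TrapezoidalCount,
    centroid_counts,
    compute_abcd,
    compute_all_abcd,
    discrete_possibility,
    merge_biological,
    merge_technical,
)
from fuzzydea.io_mappings import PossibilityTable
from fuzzydea.simulate import random_small_table


def table_of(rows):
    return PossibilityTable(
        pd.DataFrame(rows, columns=["read_id", "reference_id", "possibility"])
    )


trapezoids = st.builds(
    lambda vals: TrapezoidalCount(*sorted(vals)),
    st.tuples(*[st.floats(0, 500) for _ in range(4)]),
)


class TestComputeAbcd:
    def test_worked_example_gene1(self, toy_table):
        """One unique read, two strict best, three best with ties, five total."""
        t = compute_abcd(toy_table, "gene-1")
        assert (t.a, t.b, t.c, t.d) == (1, 2, 3, 5)

    def test_worked_example_gene3_matches_oracle(self, toy_table):
        t = compute_abcd(toy_table, "gene-3")
        oracle = discrete_possibility(toy_table, "gene-3")
        lo, hi = oracle.support_bounds()
        b, c = oracle.plateau_bounds()
        assert (t.a, t.b, t.c, t.d) == (lo, b, c, hi) == (0, 1, 1, 2)

    def test_absent_gene_is_certain_zero(self, toy_table):
        t = compute_abcd(toy_table, "gene-404")
        assert t == TrapezoidalCount.ZERO

    def test_unique_perfect_hits_collapse_to_point(self):
        table = table_of([(f"r{i}", "gA", 1.0) for i in range(4)])
        t = compute_abcd(table, "gA")
        assert (t.a, t.b, t.c, t.d) == (4, 4, 4, 4)
        assert t.is_point


class TestDiscreteOracle:
    def test_worked_example_gene1_distribution(self, toy_table):
        """Counts 2-3 fully possible, intermediate possibility for 1, 4, 5."""
        got = discrete_possibility(toy_table, "gene-1").as_array()
        np.testing.assert_allclose(got, [0.0, 0.792, 1.0, 1.0, 0.864, 0.76], atol=1e-12)

    def test_single_unique_read(self):
        table = table_of([("r0", "gA", 1.0)])
        assert discrete_possibility(table, "gA").possibilities == {0: 0.0, 1: 1.0}

    def test_cap_exceeded_points_to_trapezoid(self):
        table = table_of([(f"r{i}", "gA", 1.0) for i in range(6)])
        with pytest.raises(ValueError, match="compute_abcd"):
            discrete_possibility(table, "gA", cap=5)


class TestCentroids:
    def test_unique_read_contributes_one(self):
        table = table_of([("r0", "gA", 0.6)])
        assert centroid_counts(table)["gA"] == pytest.approx(1.0)

    def test_worked_example_share_split(self, toy_table):
        cents = centroid_counts(toy_table)
        # read-wise proportional shares of gene-1, summed by hand
        expected = 1.0 + 1.0 / (1 + 0.792 + 0.76) + 0.5 \
            + 0.864 / (0.864 + 0.873 + 1.0) + 0.76 / (0.76 + 1.0)
        assert cents["gene-1"] == pytest.approx(expected, abs=1e-12)

    def test_total_is_read_count(self, toy_table):
        assert centroid_counts(toy_table).sum() == pytest.approx(5.0, abs=1e-9)


@pytest.mark.parametrize(
    "t1,t2,expected",
    [
        ((1, 2, 3, 5), (0, 0, 0, 0), (1, 2, 3, 5)),
        ((1, 2, 3, 5), (1, 2, 3, 5), (2, 4, 6, 10)),
        ((0, 1, 1, 3), (2, 2, 2, 2), (2, 3, 3, 5)),
    ],
)
def test_technical_merge_is_componentwise_sum(t1, t2, expected):
    got = merge_technical(TrapezoidalCount(*t1), TrapezoidalCount(*t2))
    assert tuple(got) == expected


@pytest.mark.parametrize(
    "t1,t2,expected",
    [
        ((1, 2, 3, 5), (4, 6, 7, 9), (1, 2, 7, 9)),
        ((0, 0, 0, 0), (3, 3, 3, 3), (0, 0, 3, 3)),
    ],
)
def test_biological_merge_is_envelope(t1, t2, expected):
    got = merge_biological(TrapezoidalCount(*t1), TrapezoidalCount(*t2))
    assert tuple(got) == expected


@given(trapezoids, trapezoids, trapezoids)
def test_merge_algebra(t1, t2, t3):
    """Sum merge commutes/associates; envelope merge also idempotent, widening."""
    assert merge_technical(t1, t2) == merge_technical(t2, t1)
    assert tuple(merge_technical(merge_technical(t1, t2), t3)) == pytest.approx(
        tuple(merge_technical(t1, merge_technical(t2, t3)))
    )
    assert merge_biological(t1, t1) == t1
    assert merge_biological(t1, t2) == merge_biological(t2, t1)
    assert merge_biological(merge_biological(t1, t2), t3) == merge_biological(
        t1, merge_biological(t2, t3)
    )
    env = merge_biological(t1, t2)
    for t in (t1, t2):
        assert env.support[0] <= t.support[0] and env.support[1] >= t.support[1]


def test_membership_shape():
    t = TrapezoidalCount(2, 4, 6, 9)
    assert t.membership(1) == 0.0          # at A' = A-1
    assert t.membership(2) == pytest.approx(1 / 3)
    assert t.membership(4) == 1.0
    assert t.membership(6) == 1.0
    assert t.membership(9) == pytest.approx(0.25)
    assert t.membership(10) == 0.0         # at D' = D+1
    assert t.membership(-1) == 0.0


def test_membership_positive_at_extreme_counts():
    t = TrapezoidalCount(3, 3, 3, 3)
    assert t.membership(3) == 1.0
    assert 0 < t.membership(2.5) < 1


class TestOracleAgreement:
    """Exhaustive enumeration vs the A,B,C,D summary on random tables."""

    def test_random_tables(self):
        rng = np.random.default_rng(1234)
        for _ in range(40):
            table = random_small_table(rng)
            self._check(table)

    @staticmethod
    def _check(table):
        for gene in table.genes:
            t = compute_abcd(table, gene)
            oracle = discrete_possibility(table, gene)
            arr = oracle.as_array()
            lo, hi = oracle.support_bounds()
            b, c = oracle.plateau_bounds()
            assert (lo, b, c, hi) == (t.a, t.b, t.c, t.d), gene
            # monotone up on [A, B], down on [C, D]
            assert np.all(np.diff(arr[int(t.a): int(t.b) + 1]) >= -1e-12)
            assert np.all(np.diff(arr[int(t.c): int(t.d) + 1]) <= 1e-12)

    def test_centroid_conservation_and_containment(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            table = random_small_table(rng)
            cents = centroid_counts(table)
            assert cents.sum() == pytest.approx(table.n_reads, abs=1e-9)
            abcd = compute_all_abcd(table)
            for gene, row in abcd.iterrows():
                assert row.A - 1e-9 <= cents[gene] <= row.D + 1e-9

    def test_point_trapezoid_iff_no_multiread(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            table = random_small_table(rng)
            multi = set(table.multiread_ids())
            touched = set(
                table.df.loc[table.df.read_id.isin(multi), "reference_id"]
            )
            abcd = compute_all_abcd(table)
            for gene, row in abcd.iterrows():
                if gene not in touched:
                    assert row.A == row.B == row.C == row.D
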