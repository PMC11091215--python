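"""Per-edge values, direct summation vs partition evaluation, Randic family."""

import math
import warnings
from fractions import Fraction

import networkx as nx
import pytest

from fuchsheet import (
    EdgePartition,
    compute_from_partition,
    compute_index,
    edge_partition,
    edge_value,
    general_randic,
    get_spec,
    randic,
)
from fuchsheet.indices import ExactPathUnavailable, INDEX_SPECS
from fuchsheet.surd import SQRT2, SQRT3, SQRT6, Surd

TEN_COLUMNS = ("M1", "M2", "HM", "F", "ABC", "GA", "R-1", "R1/2", "R-1/2", "R1")


class TestEdgeValue:
    @pytest.mark.parametrize(
        "name, pair, expected",
        [
            ("GA", (3, 3), Surd(1)),
            ("GA", (1, 3), SQRT3 / 2),
            ("GA", (2, 3), 2 * SQRT6 / 5),
            ("ABC", (3, 3), Surd(Fraction(2, 3))),
            ("ABC", (2, 3), SQRT2 / 2),
            ("ABC", (1, 3), SQRT6 / 3),
            ("HM", (2, 3), Surd(25)),
            ("M1", (1, 3), Surd(4)),
            ("M2", (2, 3), Surd(6)),
            ("F", (2, 3), Surd(13)),
            ("H", (3, 3), Surd(Fraction(1, 3))),
            ("R-1/2", (2, 3), SQRT6 / 6),
            ("R1/2", (1, 3), SQRT3),
        ],
    )
    def test_exact_values_on_sheet_degree_pairs(self, name, pair, expected):
        v = edge_value(get_spec(name), *pair)
        assert v == expected
        assert math.isclose(float(v), get_spec(name).numeric(*pair), rel_tol=1e-12)

    def test_per_edge_functions_are_symmetric(self):
        for spec in INDEX_SPECS.values():
            for x, y in [(1, 3), (2, 3), (2, 5), (4, 4)]:
                assert math.isclose(spec.numeric(x, y), spec.numeric(y, x))
                if spec.exact(x, y) is not None:
                    assert spec.exact(x, y) == spec.exact(y, x)

    def test_nonpositive_degrees_are_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            edge_value(get_spec("M1"), 0, 3)

    def test_abc_is_zero_on_a_1_1_pair(self):
        assert edge_value(get_spec("ABC"), 1, 1) == Surd(0)

    def test_exact_fallback_warns_and_returns_float(self):
        with pytest.warns(ExactPathUnavailable):
            v = edge_value(get_spec("ABC"), 3, 5)  # sqrt(2/5) leaves the ring
        assert isinstance(v, float)
        assert math.isclose(v, math.sqrt(6 / 15))
        with pytest.warns(ExactPathUnavailable):
            assert isinstance(edge_value(randic(0.3), 2, 3), float)


class TestComputeIndex:
    @pytest.mark.parametrize(
        "name, expected",
        [("M1", 216), ("M2", 270), ("HM", 1152), ("F", 612), ("R1", 270)],
    )
    def test_unit_sheet_integer_indices(self, sheet, name, expected):
        assert compute_index(sheet(1, 1), get_spec(name)) == Surd(expected)

    def test_harmonic_index_of_unit_sheet_is_exactly_17(self, sheet):
        assert compute_index(sheet(1, 1), get_spec("H")) == Surd(17)

    def test_abc_of_unit_sheet_by_direct_float_summation(self, sheet):
        assert math.isclose(
            float(compute_index(sheet(1, 1), get_spec("ABC"))), 30.6966, abs_tol=5e-4
        )

    def test_exact_and_float_paths_agree(self, sheet):
        g = sheet(2, 3)
        for name in TEN_COLUMNS:
            spec = get_spec(name)
            exact = float(compute_index(g, spec, exact=True))
            direct = compute_index(g, spec, exact=False)
            assert math.isclose(exact, direct, rel_tol=1e-9)


class TestPartitionEvaluation:
    def test_known_partitions(self):
        p11 = EdgePartition({(3, 3): 24, (1, 3): 18})
        assert compute_from_partition(p11, get_spec("M2")) == Surd(270)
        p22 = EdgePartition({(3, 3): 96, (1, 3): 64, (2, 3): 8})
        assert compute_from_partition(p22, get_spec("HM")) == Surd(4680)
        assert compute_from_partition(EdgePartition({}), get_spec("GA")) == Surd(0)

    def test_direct_equals_partition_on_sheets_exactly(self, sheet):
        for m, n in [(1, 1), (2, 2), (3, 2)]:
            g = sheet(m, n)
            p = edge_partition(g)
            for name in TEN_COLUMNS:
                spec = get_spec(name)
                assert compute_index(g, spec) == compute_from_partition(p, spec)

    def test_direct_equals_partition_on_random_graphs(self, random_graphs):
        """Oracle equivalence: both evaluation routes agree on 50 random graphs."""
        assert len(random_graphs) >= 50
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExactPathUnavailable)
            for g in random_graphs:
                p = edge_partition(g)
                for name in TEN_COLUMNS:
                    spec = get_spec(name)
                    a = float(compute_index(g, spec, exact=False))
                    b = float(compute_from_partition(p, spec, exact=False))
                    assert math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-12)


class TestGeneralRandic:
    def test_lambda_one_equals_second_zagreb(self, sheet, random_graphs):
        for g in [sheet(1, 1), sheet(2, 2)] + random_graphs[:10]:
            assert math.isclose(
                general_randic(g, 1.0), float(compute_index(g, get_spec("M2"))),
                rel_tol=1e-12,
            )

    def test_lambda_zero_counts_edges(self, sheet, random_graphs):
        for g in [sheet(2, 1)] + random_graphs[:5]:
            assert general_randic(g, 0.0) == g.number_of_edges()

    def test_lambda_minus_one_on_three_by_three_sheet(self, sheet):
        assert math.isclose(general_randic(sheet(3, 3), -1.0), 74.0, rel_tol=1e-12)
        assert compute_index(sheet(3, 3), get_spec("R-1")) == Surd(74)

    def test_special_exponents_agree_with_exact_path(self, sheet):
        g = sheet(2, 2)
        for lam in (1.0, -1.0, 0.5, -0.5):
            exact = float(compute_index(g, randic(lam)))
            assert math.isclose(general_randic(g, lam), exact, rel_tol=1e-9)

    def test_rejects_non_finite_exponent(self, sheet):
        with pytest.raises(ValueError):
            general_randic(sheet(1, 1), float("nan"))


class TestIndexProperties:
    def test_all_indices_positive_on_any_graph_with_an_edge(self, random_graphs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExactPathUnavailable)
            for g in random_graphs[:15]:
                for name in TEN_COLUMNS:
                    assert float(compute_index(g, get_spec(name), exact=False)) > 0

    def test_every_index_strictly_increases_in_m_and_n(self, sheet):
        vals = {
            (m, n): {
                c: float(compute_index(sheet(m, n), get_spec(c))) for c in TEN_COLUMNS
            }
            for m in range(1, 7)
            for n in range(1, 7)
        }
        for c in TEN_COLUMNS:
            for m in range(1, 6):
                for n in range(1, 7):
                    assert vals[(m + 1, n)][c] > vals[(m, n)][c], (c, m, n)
                    assert vals[(n, m + 1)][c] > vals[(n, m)][c], (c, m, n)

    def test_geometric_arithmetic_edge_values_bounded_by_one(self, sheet, random_graphs):
        ga = get_spec("GA")
        for x in range(1, 7):
            for y in range(x, 7):
                v = ga.numeric(x, y)
                assert v <= 1.0 + 1e-12
                assert (v == 1.0) == (x == y)
        for g in [sheet(3, 3)] + random_graphs[:10]:
            assert compute_index(g, ga, exact=False) <= g.number_of_edges() + 1e-9
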