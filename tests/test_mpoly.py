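"""M-polynomial construction, operator calculus and the nine indices."""

import math

import pytest

from mpolyqspr.molgraph import EdgePartition, edge_partition
from mpolyqspr.mpoly import (
    INDEX_NAMES,
    MPolynomial,
    add,
    all_indices,
    apply_operator,
    descriptor_table,
    evaluate,
    index_via_operators,
    m_polynomial,
    topological_index,
)
from mpolyqspr.synthetic import random_molecular_graph

from conftest import cycle, path


def brute_force_index(g, kind):
    """Independent oracle: sum the kernel edge by edge over the raw graph."""
    kernels = {
        "M1": lambda a, b: a + b,
        "M2": lambda a, b: a * b,
        "HM": lambda a, b: (a + b) ** 2,
        "R": lambda a, b: 1 / math.sqrt(a * b),
        "H": lambda a, b: 2 / (a + b),
        "SCI": lambda a, b: 1 / math.sqrt(a + b),
        "F": lambda a, b: a * a + b * b,
        "GA": lambda a, b: 2 * math.sqrt(a * b) / (a + b),
        "ABC": lambda a, b: math.sqrt((a + b - 2) / (a * b)) if (a, b) != (1, 1) else 0.0,
    }
    deg = g.graph.degree
    return sum(kernels[kind](deg[u], deg[v]) for u, v in g.graph.edges)


class TestPolynomial:
    def test_p4_polynomial(self, p4):
        mp = m_polynomial(edge_partition(p4))
        assert mp.coefficients == {(1, 2): 2, (2, 2): 1}

    def test_cycle_polynomial_single_term(self, c6):
        assert m_polynomial(edge_partition(c6)).coefficients == {(2, 2): 6}

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m_polynomial(EdgePartition({}))

    @pytest.mark.parametrize("seed", range(5))
    def test_evaluate_at_one_one_counts_edges(self, seed):
        g = random_molecular_graph(14, seed=seed)
        mp = m_polynomial(edge_partition(g))
        assert evaluate(mp, 1, 1) == g.n_edges

    def test_evaluate_point(self, k13):
        mp = m_polynomial(edge_partition(k13))  # 3 x y^3
        assert evaluate(mp, 2, 1) == 6


class TestOperators:
    def test_dx_scales_by_x_exponent(self):
        mp = MPolynomial({(1, 2): 2, (2, 2): 1})
        assert apply_operator(mp, "Dx").coefficients == {(1, 2): 2, (2, 2): 2}

    def test_sx_divides(self):
        mp = MPolynomial({(1, 3): 3})
        assert apply_operator(mp, "Sx").coefficients == {(1, 3): 3.0}

    def test_unknown_operator_rejected(self):
        with pytest.raises(ValueError):
            apply_operator(MPolynomial({(1, 1): 1}), "Dz")

    def test_m1_of_cycle_via_operators(self):
        # (Dx + Dy)M |_(1,1) = 4n for Cn, by the handshake argument
        for n in (3, 7, 20):
            mp = m_polynomial(edge_partition(cycle(n)))
            assert evaluate(add(apply_operator(mp, "Dx"), apply_operator(mp, "Dy")), 1, 1) == 4 * n

    @pytest.mark.parametrize("kind", ["M1", "M2", "F", "HM"])
    @pytest.mark.parametrize("seed", range(8))
    def test_operator_route_equals_kernel_sum_exactly(self, kind, seed):
        g = random_molecular_graph(16, seed=seed)
        p = edge_partition(g)
        assert index_via_operators(m_polynomial(p), kind) == topological_index(p, kind)

    def test_operator_route_undefined_for_fractional_kinds(self, p4):
        mp = m_polynomial(edge_partition(p4))
        with pytest.raises(ValueError):
            index_via_operators(mp, "ABC")


class TestIndices:
    def test_m1_p4(self, p4):
        assert topological_index(edge_partition(p4), "M1") == 10

    def test_h_p4(self, p4):
        assert topological_index(edge_partition(p4), "H") == pytest.approx(11 / 6)

    def test_ga_cycle_equals_edge_count(self, c6):
        assert topological_index(edge_partition(c6), "GA") == pytest.approx(6)

    def test_abc_c6(self, c6):
        assert topological_index(edge_partition(c6), "ABC") == pytest.approx(3 * math.sqrt(2))

    def test_unknown_kind_rejected(self, p4):
        with pytest.raises(ValueError):
            topological_index(edge_partition(p4), "Wiener")

    @pytest.mark.parametrize("n", [3, 10, 37, 50])
    def test_cycle_closed_forms(self, n):
        p = edge_partition(cycle(n))
        expected = {
            "M1": 4 * n, "M2": 4 * n, "HM": 16 * n, "F": 8 * n,
            "R": n / 2, "H": n / 2, "SCI": n / 2, "GA": n,
            "ABC": n * math.sqrt(2) / 2,
        }
        for kind, val in expected.items():
            assert topological_index(p, kind) == pytest.approx(val)

    @pytest.mark.parametrize("n", [3, 4, 12, 50])
    def test_path_partition_closed_form(self, n):
        p = edge_partition(path(n))
        if n == 3:
            assert p.counts == {(1, 2): 2}
        else:
            assert p.counts == {(1, 2): 2, (2, 2): n - 3}

    @pytest.mark.parametrize("seed", range(10))
    def test_kernel_sum_matches_edgewise_oracle(self, seed):
        g = random_molecular_graph(18, seed=seed)
        p = edge_partition(g)
        for kind in INDEX_NAMES:
            assert topological_index(p, kind) == pytest.approx(
                brute_force_index(g, kind), rel=1e-12
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_ga_and_randic_bounded_by_edge_count(self, seed):
        g = random_molecular_graph(15, seed=seed)
        p = edge_partition(g)
        assert topological_index(p, "GA") <= g.n_edges + 1e-12
        assert topological_index(p, "R") <= g.n_edges + 1e-12

    def test_ga_attains_edge_count_iff_regular(self, c5):
        assert topological_index(edge_partition(c5), "GA") == pytest.approx(5)


class TestDescriptorTable:
    def test_two_rows_nine_columns(self, c5, p4):
        df = descriptor_table({"c5": c5, "p4": p4})
        assert df.shape == (2, 9)
        assert df.loc["c5", "M1"] == 20 and df.loc["p4", "M1"] == 10

    def test_empty_map(self):
        assert descriptor_table({}).empty

    def test_batch_has_no_missing_values(self):
        graphs = {f"g{i}": random_molecular_graph(10 + i % 7, seed=i) for i in range(50)}
        df = descriptor_table(graphs)
        assert df.shape == (50, 9)
        assert df.notna().all().all()

    def test_all_indices_keys(self, c6):
        assert tuple(all_indices(c6)) == INDEX_NAMES
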