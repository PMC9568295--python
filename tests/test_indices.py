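"""Index catalog, single-edge terms, and the two evaluation routes."""

import logging
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topodnn import (
    DNNSpec,
    IndexDomainError,
    build_dnn_graph,
    build_graph,
    degree_map,
    edge_partition,
    edge_term,
    evaluate_on_graph,
    evaluate_on_partition,
    get_index,
    index_catalog,
    index_names,
    log_space_product,
)
from topodnn.graph_core import EdgePartition

from conftest import make_random_graph, make_random_spec

TRIANGLE = build_graph(("a", "b", "c"), (("a", "b"), ("b", "c"), ("a", "c")))
K2 = build_graph(("a", "b"), (("a", "b"),))


class TestCatalog:
    def test_twelve_entries(self):
        assert len(index_catalog()) == 12

    def test_expected_names_and_aggregations(self):
        by_name = {d.name: d for d in index_catalog()}
        assert set(by_name) == {
            "randic", "general_randic", "zagreb1", "zagreb2", "mult_zagreb1",
            "mult_zagreb2", "hyper_zagreb", "abc", "sci", "ga", "forgotten",
            "azi",
        }
        assert by_name["mult_zagreb1"].aggregation == "product"
        assert by_name["mult_zagreb2"].aggregation == "product"
        assert sum(d.aggregation == "sum" for d in index_catalog()) == 10

    def test_unknown_name_lists_catalog(self):
        with pytest.raises(KeyError, match="randic"):
            get_index("wiener")


class TestEdgeTerm:
    @pytest.mark.parametrize(
        "name,du,dv,alpha,expected",
        [
            ("ga", 5, 5, None, 1.0),              # equal degrees: 2*sqrt(d^2)/2d
            ("abc", 1, 1, None, 0.0),             # zero numerator under the root
            ("azi", 2, 3, None, 8.0),             # (2*3/(2+3-2))^3
            ("randic", 4, 9, None, 1 / 6),
            ("general_randic", 2, 3, 2.0, 36.0),
            ("sci", 2, 2, None, 0.5),
            ("hyper_zagreb", 1, 2, None, 9.0),
            ("forgotten", 3, 4, None, 25.0),
        ],
    )
    def test_worked_values(self, name, du, dv, alpha, expected):
        assert edge_term(get_index(name), du, dv, alpha) == pytest.approx(
            expected, rel=1e-12
        )

    def test_azi_undefined_on_two_pendant_ends(self):
        with pytest.raises(IndexDomainError):
            edge_term(get_index("azi"), 1, 1)

    def test_degrees_below_one_rejected(self):
        with pytest.raises(IndexDomainError):
            edge_term(get_index("randic"), 0, 3)

    @settings(max_examples=100, derandomize=True)
    @given(
        du=st.integers(min_value=1, max_value=40),
        dv=st.integers(min_value=1, max_value=40),
        alpha=st.floats(min_value=-2, max_value=2, allow_nan=False),
    )
    def test_symmetry_and_nonnegativity(self, du, dv, alpha):
        for d in index_catalog():
            if d.name == "azi" and du + dv == 2:
                continue
            lhs = edge_term(d, du, dv, alpha)
            rhs = edge_term(d, dv, du, alpha)
            assert lhs == rhs
            assert math.isfinite(lhs) and lhs >= 0


class TestEvaluateOnGraph:
    def test_zagreb1_triangle(self):
        iv = evaluate_on_graph(TRIANGLE, get_index("zagreb1"))
        assert iv.exact == 12 and iv.value == 12.0

    def test_zagreb1_equals_sum_of_squared_degrees(self, figure_arch):
        # independent oracle: M1 = sum of d_v^2 over the 29 nodes
        g = build_dnn_graph(figure_arch)
        expected = sum(d * d for d in degree_map(g).values())
        assert expected == 1872
        assert evaluate_on_graph(g, get_index("zagreb1")).exact == 1872

    def test_mult_zagreb2_path3_exact(self, path3):
        # PM2 = product of d_v^{d_v} = 1 * 2^2 * 1
        iv = evaluate_on_graph(build_dnn_graph(path3), get_index("mult_zagreb2"))
        assert iv.exact == 4
        assert iv.log10 == pytest.approx(math.log10(4), rel=1e-12)

    def test_edgeless_graph_conventions(self, caplog):
        lonely = build_graph(("a",), ())
        with caplog.at_level(logging.WARNING, logger="topodnn.indices"):
            assert evaluate_on_graph(lonely, get_index("zagreb1")).value == 0.0
            assert evaluate_on_graph(lonely, get_index("mult_zagreb2")).exact == 1
        assert "edgeless" in caplog.text


class TestEvaluateOnPartition:
    @pytest.mark.parametrize(
        "classes,name,expected",
        [
            ({(2, 2): 3}, "zagreb1", 12),        # triangle
            ({(3, 4): 12}, "zagreb1", 84),       # DNN(2;[3];2): 12*(3+4)
            ({(1, 2): 2}, "hyper_zagreb", 18),   # DNN(1;[1];1): 2*(1+2)^2
        ],
    )
    def test_integer_worked_values(self, classes, name, expected):
        iv = evaluate_on_partition(EdgePartition(classes), get_index(name))
        assert iv.exact == expected

    def test_cross_check_against_handshake_squared(self):
        # 12*(3+4) must equal sum d_v^2 = 2*9 + 3*16 + 2*9 on DNN(2;[3];2)
        assert 12 * 7 == 2 * 9 + 3 * 16 + 2 * 9

    def test_general_randic_exact_only_for_nonneg_integer_alpha(self):
        part = EdgePartition({(2, 3): 4})
        assert evaluate_on_partition(part, get_index("general_randic"), 2.0).exact == 144
        assert evaluate_on_partition(part, get_index("general_randic"), -1.0).exact is None


class TestLogSpaceProduct:
    def test_k2_mult_zagreb2_is_zero(self):
        part = edge_partition(K2)
        assert log_space_product(part, get_index("mult_zagreb2")) == 0.0

    def test_path3_mult_zagreb1(self):
        part = EdgePartition({(1, 2): 2})
        got = log_space_product(part, get_index("mult_zagreb1"))
        assert got == pytest.approx(2 * math.log10(3), rel=1e-12)

    def test_single_class_closed_form(self):
        part = EdgePartition({(3, 4): 12})
        got = log_space_product(part, get_index("mult_zagreb2"))
        assert got == pytest.approx(12 * math.log10(12), rel=1e-12)

    def test_agrees_with_exact_big_integer(self, figure_arch):
        from topodnn import closed_form_partition

        part = closed_form_partition(figure_arch)
        for name in ("mult_zagreb1", "mult_zagreb2"):
            iv = evaluate_on_partition(part, get_index(name))
            lg = log_space_product(part, get_index(name))
            assert lg == pytest.approx(math.log10(iv.exact), rel=1e-9)

    def test_rejects_sum_aggregation(self):
        with pytest.raises(ValueError):
            log_space_product(EdgePartition({(2, 2): 1}), get_index("zagreb1"))


def _compare_routes(graph, definition, alpha=None):
    part = edge_partition(graph)
    if definition.name == "azi" and (1, 1) in part.classes:
        with pytest.raises(IndexDomainError):
            evaluate_on_graph(graph, definition)
        return
    direct = evaluate_on_graph(graph, definition, alpha)
    via_part = evaluate_on_partition(part, definition, alpha)
    if direct.exact is not None:
        assert via_part.exact == direct.exact
    else:
        assert via_part.value == pytest.approx(direct.value, rel=1e-9)
    if direct.log10 is not None:
        assert via_part.log10 == pytest.approx(direct.log10, rel=1e-9, abs=1e-12)


@pytest.mark.parametrize("seed", range(40))
def test_partition_route_matches_direct_route(seed):
    """Edge-partition evaluation equals the edge-by-edge oracle, all indices."""
    graph = make_random_graph(seed) if seed % 2 else build_dnn_graph(make_random_spec(seed))
    for definition in index_catalog():
        alphas = (-0.5, 0.5, 2.0) if definition.needs_alpha else (None,)
        for alpha in alphas:
            _compare_routes(graph, definition, alpha)


@pytest.mark.parametrize("seed", range(25))
def test_algebraic_identities(seed):
    """Classical exact relations among the catalog indices."""
    g = make_random_graph(seed)
    val = {
        name: evaluate_on_graph(g, get_index(name))
        for name in ("zagreb1", "zagreb2", "hyper_zagreb", "forgotten",
                     "randic", "ga", "mult_zagreb2")
    }
    degrees = degree_map(g)
    # HM = F + 2*M2 and M1 = sum d^2, exact in integers
    assert val["hyper_zagreb"].exact == val["forgotten"].exact + 2 * val["zagreb2"].exact
    assert val["zagreb1"].exact == sum(d * d for d in degrees.values())
    # PM2 = prod d^d (degree-0 nodes contribute factor 1)
    assert val["mult_zagreb2"].exact == math.prod(d**d for d in degrees.values() if d)
    # general Randic specializations
    r0 = evaluate_on_graph(g, get_index("general_randic"), 0.0)
    assert r0.value == pytest.approx(g.num_edges, rel=1e-12)
    rm = evaluate_on_graph(g, get_index("general_randic"), -0.5)
    assert rm.value == pytest.approx(val["randic"].value, rel=1e-12)
    r1 = evaluate_on_graph(g, get_index("general_randic"), 1.0)
    assert r1.value == pytest.approx(val["zagreb2"].value, rel=1e-12)
    # GA <= |E|, equality iff every edge joins equal degrees
    part = edge_partition(g)
    if all(a == b for a, b in part.classes):
        assert val["ga"].value == pytest.approx(g.num_edges, rel=1e-12)
    else:
        assert val["ga"].value < g.num_edges
    for name in ("randic", "sci", "abc", "ga"):
        assert evaluate_on_graph(g, get_index(name)).value >= 0
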