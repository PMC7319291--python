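"""Heterogeneity indices: hand-computed values, closed forms and bounds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degvar.generators import (
    complete_graph,
    cycle_graph,
    empty_graph,
    er_gnm,
    path_graph,
    quasi_complete,
    quasi_star,
    star_graph,
)
from degvar.graph import Graph, complement
from degvar.metrics import (
    avg_degree_normalization,
    degree_irregularity,
    degree_variance,
    expected_vbar_er_gnm,
    expected_vbar_er_gnp,
    heterogeneity_index,
    lower_bound_vbar,
    max_lower_bound,
    normalized_degree_variance,
    quasistar_normalization,
    relative_degree,
    report,
    vbar_perfect_quasistar_closed_form,
    vbar_star_closed_form,
)
from degvar.undefined import Undefined, is_defined


class TestDegreeVariance:
    def test_star4_by_hand(self, star4):
        # sample variance of {3,1,1,1}: mean 1.5, SS = 2.25+3*0.25 = 3, /3
        assert degree_variance(star4) == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("g", [cycle_graph(7), complete_graph(5), empty_graph(4)])
    def test_regular_graphs_zero(self, g):
        assert degree_variance(g) == 0.0

    def test_equals_sample_variance_of_degrees(self, catalogue):
        for g in catalogue.values():
            k = g.degree_array()
            assert degree_variance(g) == pytest.approx(
                np.var(k, ddof=1), abs=1e-10
            )

    def test_gnm_ensemble_mean(self):
        # E[v] over G(10, 20) = 2m(n(n-1)-2m)/(n(n^2-1)) = 2.0202; the
        # n-denominator variant 2m(n^2-n-2m)/(n^3+n^2) rescaled by n/(n-1)
        rng = np.random.default_rng(42)
        draws = np.array(
            [degree_variance(er_gnm(10, 20, rng)) for _ in range(2000)]
        )
        expected = 2 * 20 * (10 * 9 - 40) / (10 * 99)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se


class TestNormalizedDegreeVariance:
    def test_star4(self, star4):
        assert normalized_degree_variance(star4) == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("g", [cycle_graph(9), complete_graph(6), empty_graph(5)])
    def test_regular_graphs_zero(self, g):
        assert normalized_degree_variance(g) == 0.0

    def test_complement_invariance(self, catalogue):
        for name, g in catalogue.items():
            if 0 < g.m < g.max_edges:
                assert normalized_degree_variance(g) == pytest.approx(
                    normalized_degree_variance(complement(g)), abs=1e-12
                ), name

    def test_bounded_in_unit_interval(self, catalogue):
        for g in catalogue.values():
            assert 0.0 <= normalized_degree_variance(g) <= 1.0


class TestQuasistarNormalization:
    @pytest.mark.parametrize("n,m", [(6, 5), (6, 10), (16, 40), (32, 200)])
    def test_equals_one_on_quasi_stars(self, n, m):
        assert quasistar_normalization(quasi_star(n, m)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_exceeds_one_on_quasi_complete(self):
        # degrees {4,4,4,4,4,0} vs quasi-star degrees {5,5,3,3,2,2}
        val = quasistar_normalization(quasi_complete(6, 10))
        assert val == pytest.approx(2.6667 / 1.8667, abs=1e-3)
        assert val > 1.0

    def test_zero_on_regular(self):
        assert quasistar_normalization(cycle_graph(8)) == 0.0

    @pytest.mark.parametrize("g", [empty_graph(5), complete_graph(5)])
    def test_undefined_when_reference_regular(self, g):
        val = quasistar_normalization(g)
        assert isinstance(val, Undefined)


class TestAvgDegreeNormalization:
    def test_star4(self, star4):
        assert avg_degree_normalization(star4) == pytest.approx(1 / 1.5, abs=1e-12)

    def test_zero_on_regular(self):
        assert avg_degree_normalization(cycle_graph(6)) == 0.0

    def test_undefined_on_empty(self):
        assert isinstance(avg_degree_normalization(empty_graph(4)), Undefined)


class TestHeterogeneityIndex:
    @pytest.mark.parametrize("n", [3, 4, 8, 16, 64])
    def test_one_on_stars(self, n):
        assert heterogeneity_index(star_graph(n)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_on_regular(self):
        assert heterogeneity_index(cycle_graph(10)) == 0.0

    def test_undefined_with_isolated_node(self):
        val = heterogeneity_index(quasi_complete(6, 10))
        assert isinstance(val, Undefined)
        assert val.reason == "isolated_node"


class TestDegreeIrregularity:
    @pytest.mark.parametrize(
        "g, expected",
        [(star_graph(4), 6.0), (path_graph(4), 2.0), (cycle_graph(5), 0.0)],
    )
    def test_examples(self, g, expected):
        assert degree_irregularity(g) == expected


class TestClosedForms:
    def test_star_n4(self):
        assert vbar_star_closed_form(4) == pytest.approx(0.5, abs=1e-14)

    def test_star_limit(self):
        assert abs(vbar_star_closed_form(10**6) - 1.0) < 1e-5

    @pytest.mark.parametrize("n", [3, 4, 5, 8, 16, 64, 250, 1000, 2000])
    def test_star_closed_form_matches_direct(self, n):
        direct = normalized_degree_variance(star_graph(n))
        assert direct == pytest.approx(vbar_star_closed_form(n), abs=1e-12)

    def test_perfect_quasistar_n4_r1_matches_star(self):
        assert vbar_perfect_quasistar_closed_form(4, 1) == pytest.approx(
            0.5, abs=1e-14
        )

    @pytest.mark.parametrize("n", [5, 17, 64])
    def test_complete_graph_limit(self, n):
        assert vbar_perfect_quasistar_closed_form(n, n - 1) == 0.0

    def test_strictly_decreasing_in_r(self):
        n = 64
        vals = [vbar_perfect_quasistar_closed_form(n, r) for r in range(1, n)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("n", [8, 33, 128, 512])
    def test_factorised_equals_unsimplified(self, n):
        # unsimplified quotient before the (n-r)(n-r-1) cancellation
        for r in range(1, n - 1):
            raw = (
                2 * (n - 1)
                * (r * (n - r) * n + (n - 1) ** 2 * n - r * (2 * n - r - 1) ** 2)
                / (n * (n - r) * (n - r - 1) * (2 * n - r - 1))
            )
            assert vbar_perfect_quasistar_closed_form(n, r) == pytest.approx(
                raw, abs=1e-12
            )


class TestErExpectations:
    def test_gnm_value_and_exact_enumeration(self):
        assert expected_vbar_er_gnm(10) == pytest.approx(18 / 110, abs=1e-14)
        # exact oracle: average v̄ over ALL graphs with n=4 and m edges
        import itertools

        from degvar.graph import Graph
        from degvar.metrics import normalized_degree_variance

        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        for m in (2, 3, 4):
            vals = [
                normalized_degree_variance(
                    Graph.from_edges(4, [pairs[e] for e in sub])
                )
                for sub in itertools.combinations(range(6), m)
            ]
            assert np.mean(vals) == pytest.approx(
                expected_vbar_er_gnm(4), abs=1e-12
            )

    def test_gnm_halves_asymptotically(self):
        n = 10**5
        ratio = expected_vbar_er_gnm(2 * n) / expected_vbar_er_gnm(n)
        assert ratio == pytest.approx(0.5, abs=1e-4)

    def test_gnp_matches_gnm(self):
        for n in (10, 100, 1000):
            assert expected_vbar_er_gnp(n) == expected_vbar_er_gnm(n)

    def test_gnm_monte_carlo(self):
        rng = np.random.default_rng(3)
        n = 16
        draws = np.array(
            [
                normalized_degree_variance(er_gnm(n, 60, rng))
                for _ in range(800)
            ]
        )
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - expected_vbar_er_gnm(n)) < 3 * se


class TestLowerBounds:
    def test_zero_at_average_degree(self):
        # a = 2m/n makes the bound vanish
        n, m = 12, 18  # average degree 3
        assert lower_bound_vbar(n, m, 4, 3) == 0.0

    def test_star4_tight(self):
        assert lower_bound_vbar(4, 3, 3, 1) == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("d,x_frac", [(0.2, 0.01), (0.4, 0.05)])
    def test_degree_one_asymptotic(self, d, x_frac):
        n = 1000
        m = round(d * n * (n - 1) / 2)
        x = round(x_frac * n)
        limit = (x / n) * 2 * d / (1 - d)
        assert lower_bound_vbar(n, m, x, 1) == pytest.approx(limit, rel=0.05)

    def test_max_lower_bound_star4(self, star4):
        res = max_lower_bound(star4)
        assert res.bound == pytest.approx(0.5, abs=1e-14)
        assert res.argmax_degree == 1  # tie with degree 3, smallest wins
        assert res.argmax_relative_degree == 0.0

    def test_max_lower_bound_regular(self):
        res = max_lower_bound(cycle_graph(8))
        assert res.bound == 0.0
        assert res.argmax_degree is None
        assert isinstance(res.argmax_relative_degree, Undefined)

    def test_bound_below_vbar_on_catalogue(self, catalogue):
        for name, g in catalogue.items():
            if 0 < g.m < g.max_edges:
                assert (
                    max_lower_bound(g).bound
                    <= normalized_degree_variance(g) + 1e-12
                ), name

    @given(n=st.integers(5, 60), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_bound_below_vbar_random(self, n, seed):
        m = max(1, (n * (n - 1) // 2) // 4)
        g = er_gnm(n, m, seed)
        assert max_lower_bound(g).bound <= normalized_degree_variance(g) + 1e-12


class TestRelativeDegree:
    def test_example(self):
        assert relative_degree([1, 2, 3]) == [0.0, 0.5, 1.0]

    def test_endpoints(self):
        vals = relative_degree([7, 2, 9, 4])
        assert max(vals) == 1.0 and min(vals) == 0.0

    def test_constant_undefined(self):
        assert isinstance(relative_degree([5, 5, 5]), Undefined)


class TestReport:
    def test_star4_record(self, star4):
        rec = report(star4).to_record()
        assert rec["v_bar"] == pytest.approx(0.5)
        assert rec["rho"] == pytest.approx(1.0)
        assert rec["J_reason"] == ""

    def test_undefined_flags_carry_reasons(self):
        rec = report(quasi_complete(6, 10)).to_record()
        assert rec["rho"] == "NA"
        assert rec["rho_reason"] == "isolated_node"

    def test_all_catalogue_graphs_reportable(self, catalogue):
        for g in catalogue.values():
            rep = report(g)
            assert 0.0 <= rep.v_bar <= 1.0
            assert rep.irr >= 0.0
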