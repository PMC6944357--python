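import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restconn import (
    area_threshold,
    enumerate_triangles,
    heron_area,
    triangle_estimators,
)
from restconn.exceptions import ParameterError, ScopeError

import oracles
from conftest import make_matrix, random_r_matrix


def _uniform_matrix(n, r):
    return make_matrix(r * (np.ones((n, n)) - np.eye(n)))


class TestHeronArea:
    def test_equilateral_side_06(self):
        assert heron_area(0.6, 0.6, 0.6) == pytest.approx(0.155885, abs=1e-6)
        assert round(heron_area(0.6, 0.6, 0.6), 4) == 0.1559

    def test_unit_equilateral(self):
        assert heron_area(1, 1, 1) == pytest.approx(math.sqrt(3) / 4, abs=1e-12)

    def test_triangle_inequality_violation_invalid(self):
        assert heron_area(0.9, 0.1, 0.1) is None

    def test_degenerate_flat_triangle_invalid(self):
        assert heron_area(0.5, 0.3, 0.2) is None

    def test_nonpositive_side_rejected(self):
        with pytest.raises(ParameterError):
            heron_area(0.0, 0.5, 0.5)


class TestAreaThreshold:
    def test_default_side(self):
        assert round(area_threshold(0.6), 4) == 0.1559

    def test_unit_side(self):
        assert area_threshold(1.0) == pytest.approx(0.4330, abs=1e-4)

    def test_zero_side_rejected(self):
        with pytest.raises(ParameterError):
            area_threshold(0.0)


class TestEnumerateTriangles:
    def test_whole_brain_candidate_count(self):
        C = random_r_matrix(np.random.default_rng(1), 90)
        ts = enumerate_triangles(C, list(range(90)))
        assert ts.n_candidates == math.comb(90, 3) == 117480

    def test_boundary_areas_admitted(self):
        # all sides exactly at the admission side -> every triple on the boundary
        ts = enumerate_triangles(_uniform_matrix(12, 0.6), list(range(12)))
        assert len(ts) == math.comb(12, 3) == 220
        assert ts.areas.min() >= ts.admission_threshold - 1e-12

    def test_weak_matrix_admits_none(self):
        ts = enumerate_triangles(_uniform_matrix(12, 0.5), list(range(12)))
        assert len(ts) == 0  # equilateral-0.5 area ~0.1083 < 0.1559

    def test_too_few_indices_rejected(self):
        C = random_r_matrix(np.random.default_rng(1), 5)
        with pytest.raises(ScopeError):
            enumerate_triangles(C, [0, 1])

    def test_zero_sides_and_invalid_geometry_counted(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.9  # (0,1,2): 0.9 > 0.05 + 0.05, inequality violated
        v[0, 2] = v[2, 0] = 0.05
        v[1, 2] = v[2, 1] = 0.05  # all triples with node 3 have a zero side
        C = make_matrix(v)
        ts = enumerate_triangles(C, [0, 1, 2, 3])
        assert len(ts) == 0
        assert ts.n_invalid == 1
        assert ts.n_zero_side == 3

    def test_matches_exhaustive_oracle_on_seeded_matrices(self):
        thr = area_threshold(0.6)
        for seed in range(10):
            C = random_r_matrix(np.random.default_rng(seed), 12)
            ts = enumerate_triangles(C, list(range(12)), thr)
            expected, n_invalid = oracles.oracle_triangles(C.values, range(12), thr)
            assert ts.n_invalid == n_invalid
            got = {tuple(n): a for n, a in zip(ts.nodes.tolist(), ts.areas)}
            assert set(got) == {n for n, _ in expected}
            for nodes, area in expected:
                assert got[nodes] == pytest.approx(area, abs=1e-12)

    def test_min_side_restriction_is_subset(self):
        C = random_r_matrix(np.random.default_rng(4), 15)
        full = enumerate_triangles(C, list(range(15)), thr=0.0)
        restricted = enumerate_triangles(C, list(range(15)), thr=0.0, min_side=0.5)
        full_set = {tuple(n) for n in full.nodes.tolist()}
        restricted_set = {tuple(n) for n in restricted.nodes.tolist()}
        assert restricted_set <= full_set
        assert (restricted.sides > 0.5).all()

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.4), st.floats(0.0, 0.4))
    def test_admitted_count_nonincreasing_in_threshold(self, seed, t1, t2):
        lo, hi = sorted((t1, t2))
        C = random_r_matrix(np.random.default_rng(seed), 10)
        n_lo = len(enumerate_triangles(C, list(range(10)), lo))
        n_hi = len(enumerate_triangles(C, list(range(10)), hi))
        assert n_hi <= n_lo

    def test_raising_a_correlation_never_removes_triangles(self):
        rng = np.random.default_rng(6)
        C = random_r_matrix(rng, 10)
        before = enumerate_triangles(C, list(range(10)))
        v = C.values.copy()
        i, j = 2, 7
        v[i, j] = v[j, i] = min(1.0, v[i, j] + 0.2)
        after = enumerate_triangles(make_matrix(v), list(range(10)))
        before_set = {tuple(n) for n in before.nodes.tolist()}
        after_set = {tuple(n) for n in after.nodes.tolist()}
        assert before_set <= after_set


class TestTriangleEstimators:
    def test_two_equal_areas(self):
        ts = enumerate_triangles(_uniform_matrix(4, 0.6), [0, 1, 2, 3], thr=0.0)
        est = triangle_estimators(ts)
        assert est["skewness"] == 0.0
        assert est["mean"] == pytest.approx(est["median"])

    def test_empty_set_reports_only_n(self):
        ts = enumerate_triangles(_uniform_matrix(5, 0.2), list(range(5)))
        est = triangle_estimators(ts)
        assert est["N"] == 0
        assert est["mean"] is None and est["sd"] is None

    def test_moments_match_direct_formulas(self):
        rng = np.random.default_rng(12)
        C = random_r_matrix(rng, 12)
        ts = enumerate_triangles(C, list(range(12)), thr=0.0)
        assert len(ts) > 20
        areas = ts.areas
        est = triangle_estimators(ts)
        n = len(areas)
        mean = areas.sum() / n
        m2 = ((areas - mean) ** 2).sum() / n
        m3 = ((areas - mean) ** 3).sum() / n
        assert est["mean"] == pytest.approx(mean, abs=1e-12)
        assert est["sd"] == pytest.approx(math.sqrt(((areas - mean) ** 2).sum() / (n - 1)), abs=1e-12)
        assert est["skewness"] == pytest.approx(m3 / m2**1.5, abs=1e-12)
        assert est["min"] == areas.min() and est["max"] == areas.max()

    def test_adjusted_skewness_scales_g1(self):
        rng = np.random.default_rng(13)
        C = random_r_matrix(rng, 10)
        ts = enumerate_triangles(C, list(range(10)), thr=0.0)
        n = len(ts)
        g1 = triangle_estimators(ts)["skewness"]
        adj = triangle_estimators(ts, adjusted_skewness=True)["skewness"]
        assert adj == pytest.approx(g1 * math.sqrt(n * (n - 1)) / (n - 2), abs=1e-12)
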