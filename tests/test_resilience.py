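"""Stress classes, CMBV and recovery-potential arithmetic."""

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st

from reefconnect.deltamaps import Domain, FunctionalNetwork, NetworkLink
from reefconnect.resilience import (
    candidate_score,
    cmbv,
    compute_thresholds,
    cumulative_stress,
    dhw_to_class,
    interpolate_to_grid,
    rps,
    sigma_plus,
)
from reefconnect.synthetic import HotspotSpec, generate_baa_raster
from conftest import toy_network


def grid2d(values, lat=None, lon=None, name="tsbaa"):
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    return xr.DataArray(
        values,
        dims=("lat", "lon"),
        coords={
            "lat": np.arange(ny, dtype=float) if lat is None else np.asarray(lat, float),
            "lon": np.arange(nx, dtype=float) if lon is None else np.asarray(lon, float),
        },
        name=name,
    )


class TestDhwClasses:
    @pytest.mark.parametrize(
        "dhw,expected",
        [(0, 0), (3, 2), (5, 3), (8, 4), (3.999, 2), (4, 3), (7.999, 3), (12, 4), (0.001, 2)],
    )
    def test_class_boundaries(self, dhw, expected):
        assert dhw_to_class(dhw) == expected

    def test_sequence_mapping_and_cumulative(self):
        classes = dhw_to_class([0, 3, 5, 9])
        np.testing.assert_array_equal(classes, [0, 2, 3, 4])
        assert classes.sum() == 9

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            dhw_to_class(-1.0)


class TestCumulativeStress:
    def test_all_zero(self):
        baa = generate_baa_raster((4, 4), 12)
        assert int(cumulative_stress(baa).cumulative.sum()) == 0

    def test_hotspot_arithmetic(self):
        baa = generate_baa_raster((4, 4), 12, [HotspotSpec(1, 2, 1, 2, 0, 6, 4)])
        assert int(cumulative_stress(baa).cumulative[1, 1]) == 24

    def test_phase_month_selection(self):
        baa = generate_baa_raster((2, 2), 12, [HotspotSpec(0, 1, 0, 1, 0, 12, 2)])
        out = cumulative_stress(baa, month_positions=[0, 1, 2])
        assert int(out.cumulative[0, 0]) == 6

    def test_empty_phase_rejected(self):
        baa = generate_baa_raster((2, 2), 12)
        with pytest.raises(ValueError, match="no months"):
            cumulative_stress(baa, month_positions=[])

    def test_bilinear_center_of_four_cells(self):
        """Fine patch [0, 8; 8, 16] interpolated at its center gives 8."""
        fine = grid2d([[0.0, 8.0], [8.0, 16.0]], lat=[0.0, 1.0], lon=[0.0, 1.0])
        out = interpolate_to_grid(fine, [0.5], [0.5])
        assert float(out[0, 0]) == pytest.approx(8.0)

    def test_edge_clamping(self):
        fine = grid2d([[0.0, 8.0], [8.0, 16.0]], lat=[0.0, 1.0], lon=[0.0, 1.0])
        out = interpolate_to_grid(fine, [-0.5, 1.5], [0.0])
        assert float(out[0, 0]) == pytest.approx(0.0)
        assert float(out[1, 0]) == pytest.approx(8.0)


class TestSigmaPlus:
    def test_single_undirected_positive_link(self):
        net = FunctionalNetwork(
            domains=[Domain("A", frozenset({(0, 0)})), Domain("B", frozenset({(1, 1)}))],
            links=[NetworkLink("A", "B", 2.0, 0, 0.9, "undirected", (0,))],
        )
        assert sigma_plus(net, "A") == pytest.approx(2.0)

    def test_outgoing_only_gives_zero(self):
        net = FunctionalNetwork(
            domains=[Domain("A", frozenset({(0, 0)})), Domain("B", frozenset({(1, 1)}))],
            links=[NetworkLink("A", "B", 2.0, 1, 0.9, "a_to_b", (1,))],
        )
        assert sigma_plus(net, "A") == 0.0
        assert sigma_plus(net, "B") == pytest.approx(2.0)

    def test_mixed_toy_network_hand_enumeration(self, mixed_toy_network):
        """D1: undirected +2.0 and incoming +1.5 count; outgoing +0.5 does
        not; undirected -1.0 (D2-D3) is negative and never counts."""
        assert sigma_plus(mixed_toy_network, "D1") == pytest.approx(3.5)
        assert sigma_plus(mixed_toy_network, "D2") == pytest.approx(2.25)
        assert sigma_plus(mixed_toy_network, "D3") == pytest.approx(0.0)
        assert sigma_plus(mixed_toy_network, "D4") == pytest.approx(0.5)


class TestCmbv:
    def _domains(self):
        return [
            Domain("A", frozenset({(0, 0), (0, 1)})),
            Domain("B", frozenset({(0, 1), (1, 1)})),  # overlaps A at (0, 1)
        ]

    def test_zero_stress_zero_cmbv(self):
        out = cmbv(grid2d(np.zeros((2, 2))), self._domains(), {"A": 2.0, "B": 5.0})
        assert float(out[0, 0]) == 0.0
        assert np.isnan(float(out[1, 0]))  # outside every domain

    def test_overlap_takes_maximum(self):
        tsbaa = grid2d([[10.0, 10.0], [10.0, 10.0]])
        out = cmbv(tsbaa, self._domains(), {"A": 2.0, "B": 5.0})
        assert float(out[0, 1]) == pytest.approx(5.0)  # max(10/2, 10/5)

    def test_zero_sigma_is_infinite(self):
        tsbaa = grid2d([[10.0, 10.0], [10.0, 10.0]])
        out = cmbv(tsbaa, self._domains(), {"A": 0.0, "B": 5.0})
        assert np.isinf(float(out[0, 0]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        tsbaa = grid2d(rng.integers(0, 40, size=(3, 3)).astype(float))
        doms = [
            Domain("A", frozenset({(0, 0), (0, 1), (1, 1)})),
            Domain("B", frozenset({(1, 1), (2, 1), (2, 2)})),
        ]
        sigma = {"A": 3.0, "B": 7.0}
        out = cmbv(tsbaa, doms, sigma)
        for r in range(3):
            for c in range(3):
                vals = [
                    float(tsbaa[r, c]) / sigma[d.id] for d in doms if (r, c) in d.cells
                ]
                if vals:
                    assert float(out[r, c]) == pytest.approx(max(vals))
                else:
                    assert np.isnan(float(out[r, c]))


class TestCandidateAndRps:
    def test_zero_stress_everywhere_all_candidates(self):
        tsbaa = grid2d(np.zeros((2, 2)))
        cm = grid2d(np.full((2, 2), 9.0), name="cmbv")
        out = candidate_score(tsbaa, cm, {"tsbaa": 5.0, "cmbv": 1.0})
        assert out.values.sum() == 4

    def test_above_both_thresholds_zero(self):
        out = candidate_score(
            grid2d([[7.0]]), grid2d([[3.0]], name="cmbv"), {"tsbaa": 5.0, "cmbv": 1.0}
        )
        assert int(out[0, 0]) == 0

    def test_handcrafted_map(self):
        """4x4 inputs scored against hand enumeration: candidate = 1 iff
        t.s.baa < 10 or (CMBV defined and < 2)."""
        tsbaa = grid2d(
            [[0, 12, 9, 20], [10, 3, 15, 15], [30, 30, 1, 10], [5, 40, 40, 9]]
        )
        cm = grid2d(
            [
                [np.nan, 1.0, 5.0, np.nan],
                [3.0, 0.5, 1.9, 2.0],
                [1.0, 2.1, np.nan, np.nan],
                [np.nan, np.inf, 1.0, 2.0],
            ],
            name="cmbv",
        )
        expected = np.array(
            [[1, 1, 1, 0], [0, 1, 1, 0], [1, 0, 1, 0], [1, 0, 1, 1]]
        )
        out = candidate_score(tsbaa, cm, {"tsbaa": 10.0, "cmbv": 2.0})
        np.testing.assert_array_equal(out.values, expected)

    def test_rps_sums_phases(self):
        c1 = grid2d([[1, 1], [0, 0]], name="candidate")
        c2 = grid2d([[1, 0], [0, 1]], name="candidate")
        c3 = grid2d([[1, 1], [0, 0]], name="candidate")
        out = rps([c1, c2, c3])
        np.testing.assert_array_equal(out.values, [[3, 2], [0, 1]])

    def test_rps_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            rps([grid2d(np.zeros((2, 2))), grid2d(np.zeros((3, 3))), grid2d(np.zeros((2, 2)))])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 1), min_size=4, max_size=4), min_size=4, max_size=4))
    def test_rps_is_exact_integer_sum(self, m):
        maps = [grid2d(np.array(m)), grid2d(np.roll(np.array(m), 1)), grid2d(np.array(m).T)]
        out = rps(maps)
        expected = sum(np.asarray(x.values, dtype=int) for x in maps)
        np.testing.assert_array_equal(out.values, expected)

    def test_monotonicity_in_stress(self):
        """Raising a cell's t.s.baa can never raise its candidate score."""
        rng = np.random.default_rng(1)
        base = rng.integers(0, 30, size=(4, 4)).astype(float)
        cm = grid2d(rng.uniform(0, 4, size=(4, 4)), name="cmbv")
        th = {"tsbaa": 12.0, "cmbv": 2.0}
        before = candidate_score(grid2d(base), cm, th).values
        bumped = base.copy()
        bumped[2, 2] += 15
        after = candidate_score(grid2d(bumped), cm, th).values
        assert after[2, 2] <= before[2, 2]
        np.testing.assert_array_equal(np.delete(after, 10), np.delete(before, 10))

    def test_thresholds_percentile_population(self):
        tsbaa = grid2d(np.arange(16, dtype=float).reshape(4, 4))
        cm = grid2d(np.arange(16, dtype=float).reshape(4, 4), name="cmbv")
        th = compute_thresholds(tsbaa, cm, 25.0)
        assert th["tsbaa"] == pytest.approx(np.percentile(np.arange(16), 25))
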