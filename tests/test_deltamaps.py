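"""Domain identification and lagged network inference."""

import itertools

import numpy as np
import pytest

from reefconnect.deltamaps import (
    Domain,
    domain_signal,
    homogeneity_map,
    identify_domains,
    infer_delta_threshold,
    infer_network,
    lagged_correlation_test,
    local_homogeneity,
    regrid,
)
from reefconnect.synthetic import PlantedCouplingSpec, generate_ssta, _ar1
from conftest import make_field, two_block_scenario


def brute_force_homogeneity(series):
    """Average pairwise Pearson correlation by explicit pair enumeration."""
    pairs = list(itertools.combinations(range(len(series)), 2))
    return np.mean([np.corrcoef(series[i], series[j])[0, 1] for i, j in pairs])


class TestLocalHomogeneity:
    def test_identical_neighborhood_is_one(self):
        s = np.sin(np.arange(48.0))
        field = make_field(np.tile(s[:, None, None], (1, 5, 5)))
        assert local_homogeneity(field, (2, 2)) == pytest.approx(1.0)

    def test_matches_brute_force_pair_enumeration(self):
        """Half the neighborhood carries +s(t), half -s(t); the map value must
        equal the explicit average over all 36 pairs to 1e-12."""
        rng = np.random.default_rng(0)
        s = rng.normal(size=48)
        vals = np.empty((48, 3, 3))
        series = []
        for k, (r, c) in enumerate(itertools.product(range(3), range(3))):
            sign = 1.0 if k % 2 == 0 else -1.0
            noise = 0.3 * rng.normal(size=48)
            vals[:, r, c] = sign * s + noise
            series.append(vals[:, r, c])
        field = make_field(vals)
        expected = brute_force_homogeneity(np.array(series))
        assert local_homogeneity(field, (1, 1)) == pytest.approx(expected, abs=1e-12)

    def test_white_noise_homogeneity_near_zero(self):
        hits, n = 0, 40
        for seed in range(n):
            vals = np.random.default_rng(seed).normal(size=(288, 3, 3))
            hits += abs(local_homogeneity(make_field(vals), (1, 1))) < 0.1
        assert hits >= 0.95 * n

    def test_masked_neighbors_undefined(self):
        vals = np.random.default_rng(1).normal(size=(48, 3, 3))
        vals[:, 0, 0] = np.nan
        vals[:, 0, 1] = np.nan
        vals[:, 1, 0] = np.nan
        vals[:, 1, 1] = np.nan
        # corner cell (0,0) is masked; (2,2) still has enough neighbors
        h = homogeneity_map(make_field(vals))
        assert np.isnan(h[0, 0])
        assert np.isfinite(h[2, 2])


class TestDeltaThreshold:
    def test_white_noise_delta_is_small(self):
        vals = np.random.default_rng(5).normal(size=(288, 20, 20))
        delta = infer_delta_threshold(make_field(vals), n_draws=2000, seed=0)
        assert 0 < delta < 0.2

    def test_alpha_one_gives_null_minimum(self):
        vals = np.random.default_rng(6).normal(size=(48, 15, 15))
        d_min = infer_delta_threshold(make_field(vals), alpha=1.0, n_draws=500, seed=1)
        d_999 = infer_delta_threshold(make_field(vals), alpha=1e-3, n_draws=500, seed=1)
        assert d_min < d_999

    def test_deterministic_for_fixed_seed(self):
        vals = np.random.default_rng(7).normal(size=(48, 15, 15))
        field = make_field(vals)
        assert infer_delta_threshold(field, n_draws=500, seed=3) == infer_delta_threshold(
            field, n_draws=500, seed=3
        )

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="100"):
            infer_delta_threshold(make_field(np.zeros((48, 5, 5)) + np.random.default_rng(0).normal(size=(48, 5, 5))), seed=0)


class TestIdentifyDomains:
    def test_noise_free_blocks_recovered_exactly(self, noise_free_field):
        field, truth = noise_free_field
        delta = infer_delta_threshold(field, n_draws=2000, seed=0)
        domains = identify_domains(field, delta)
        found = {frozenset(map(tuple, v)) for v in truth.domains.values()}
        assert {d.cells for d in domains} == found

    def test_noisy_blocks_recovered_with_high_jaccard(self):
        field, truth = generate_ssta(two_block_scenario(seed=11, noise_sd=0.5, loading=0.9))
        delta = infer_delta_threshold(field, n_draws=2000, seed=0)
        domains = identify_domains(field, delta)
        js = []
        for cells in truth.domains.values():
            planted = set(map(tuple, cells))
            js.append(
                max(len(planted & d.cells) / len(planted | d.cells) for d in domains)
            )
        assert np.mean(js) >= 0.8

    def test_delta_one_yields_no_domains(self):
        vals = np.random.default_rng(2).normal(size=(48, 12, 12))
        with pytest.warns(UserWarning, match="no cores"):
            assert identify_domains(make_field(vals), delta=1.0) == []

    def test_emitted_domains_satisfy_homogeneity_guarantee(self):
        field, _ = generate_ssta(two_block_scenario(seed=12, noise_sd=0.5, loading=0.9))
        delta = infer_delta_threshold(field, n_draws=1000, seed=0)
        for d in identify_domains(field, delta):
            rows = np.array(sorted(d.cells))
            series = field.values[:, rows[:, 0], rows[:, 1]].T
            assert brute_force_homogeneity(series) >= delta - 1e-12


class TestDomainSignal:
    def test_equator_cell_weight_one(self):
        vals = np.random.default_rng(3).normal(size=(48, 3, 3))
        field = make_field(vals, lat=[0.0, 30.0, 60.0])
        x = domain_signal(Domain("d", frozenset({(0, 1)})), field)
        np.testing.assert_allclose(x, vals[:, 0, 1])

    def test_sixty_degrees_halves_weight(self):
        vals = np.random.default_rng(4).normal(size=(48, 3, 3))
        field = make_field(vals, lat=[0.0, 30.0, 60.0])
        x = domain_signal(Domain("d", frozenset({(2, 0)})), field)
        np.testing.assert_allclose(x, 0.5 * vals[:, 2, 0], atol=1e-12)

    def test_matches_brute_force_weighted_sum(self):
        vals = np.random.default_rng(5).normal(size=(48, 3, 3))
        lat = [-10.0, 20.0, 45.0]
        field = make_field(vals, lat=lat)
        cells = {(0, 0), (1, 2), (2, 1)}
        x = domain_signal(Domain("d", frozenset(cells)), field)
        expected = sum(vals[:, r, c] * np.cos(np.deg2rad(lat[r])) for (r, c) in cells)
        np.testing.assert_allclose(x, expected, atol=1e-12)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            domain_signal(Domain("d", frozenset()), make_field(np.zeros((48, 2, 2))))


class TestLaggedCorrelation:
    def test_exact_lagged_copy(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=288)
        b = np.roll(a, 2)  # b(t) = a(t-2)
        res = lagged_correlation_test(a, b, tau_max=2)
        assert 2 in res.significant_lags
        assert res.r[res.lags == 2][0] > 0.99

    def test_shift_beyond_window_rarely_significant(self):
        hits, n = 0, 50
        for seed in range(n):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=288)
            b = np.concatenate([rng.normal(size=5), a[:-5]])  # lag 5 > tau_max
            res = lagged_correlation_test(a, b, tau_max=2)
            hits += not res.significant.any()
        assert hits >= 0.80 * n  # 5 lags at level 0.03 each

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            lagged_correlation_test(np.ones(48), np.random.default_rng(0).normal(size=48), 1)


class TestInferNetwork:
    def test_identical_signals_undirected_at_zero(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=288)
        d1 = Domain("a", frozenset({(0, 0)}), signal=s.copy())
        d2 = Domain("b", frozenset({(5, 5)}), signal=s.copy())
        net = infer_network([d1, d2], tau_max=2)
        (link,) = net.links
        assert link.direction == "undirected"
        assert link.lag == 0
        assert link.weight == pytest.approx(np.var(s, ddof=1))

    def test_planted_coupling_direction_and_lag(self):
        field, truth = generate_ssta(
            two_block_scenario(
                seed=4, noise_sd=0.5, loading=0.9,
                couplings=[PlantedCouplingSpec("A", "B", 2, 0.6)], ar1=0.05,
            )
        )
        doms = [
            Domain(k, frozenset(map(tuple, v))) for k, v in sorted(truth.domains.items())
        ]
        net = infer_network(doms, field, tau_max=2)
        (link,) = [l for l in net.links if {l.a, l.b} == {"A", "B"}]
        assert link.direction == "a_to_b" and link.lag == 2

    def test_symmetry_under_domain_reordering(self):
        field, truth = generate_ssta(
            two_block_scenario(seed=5, couplings=[PlantedCouplingSpec("A", "B", 1, 0.5)])
        )
        def domains(order):
            return [Domain(k, frozenset(map(tuple, truth.domains[k]))) for k in order]
        net_ab = infer_network(domains(["A", "B"]), field, tau_max=2)
        net_ba = infer_network(domains(["B", "A"]), field, tau_max=2)
        (l1,) = net_ab.links
        (l2,) = net_ba.links
        assert abs(l1.weight) == pytest.approx(abs(l2.weight), rel=1e-12)
        assert l1.lag == -l2.lag
        flips = {"a_to_b": "b_to_a", "b_to_a": "a_to_b", "undirected": "undirected"}
        assert l2.direction == flips[l1.direction]

    def test_strength_is_sum_of_incident_absolute_weights(self):
        rng = np.random.default_rng(9)
        doms = [
            Domain(f"d{k}", frozenset({(k, 0)}), signal=rng.normal(size=96))
            for k in range(5)
        ]
        # plant correlations so several links exist
        doms[1].signal = doms[0].signal + 0.1 * rng.normal(size=96)
        doms[2].signal = -doms[0].signal + 0.1 * rng.normal(size=96)
        net = infer_network(doms, tau_max=1)
        strengths = net.strengths()
        for d in net.domains:
            manual = sum(abs(l.weight) for l in net.links if d.id in (l.a, l.b))
            assert d.strength == manual == strengths[d.id]


class TestRegrid:
    def test_uniform_field_unchanged(self):
        field = make_field(np.full((12, 4, 4), 1.7))
        out = regrid(field, 2)
        np.testing.assert_allclose(out.values, 1.7)

    def test_block_mean_arithmetic(self):
        vals = np.zeros((1, 2, 2))
        vals[0] = [[1, 2], [3, 4]]
        out = regrid(make_field(vals), 2)
        assert out.values[0, 0, 0] == pytest.approx(2.5)

    def test_matches_brute_force_block_mean(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(6, 8, 8))
        vals[:, 0, 0] = np.nan  # one masked cell
        out = regrid(make_field(vals), 2)
        for i in range(4):
            for j in range(4):
                block = vals[:, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].reshape(6, -1)
                expected = np.nanmean(block, axis=1)
                np.testing.assert_allclose(out.values[:, i, j], expected, atol=1e-12)

    def test_non_divisible_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            regrid(make_field(np.zeros((6, 5, 5))), 2)
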