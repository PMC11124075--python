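"""Descriptor time-series statistics: histograms, occupancies, block
averages, and contiguous-mode grouping."""

import numpy as np
import pytest

from cyclobind import (
    ParameterError,
    TrajSimParams,
    block_average,
    bound_fraction,
    group_contiguous_modes,
    histogram,
    mode_occupancy,
    simulate_descriptor_trajectory,
    subsample_indices,
)
from cyclobind.stats import ModeInterval


class TestHistogram:
    def test_constant_series_single_bin(self):
        edges, density = histogram(np.full(50, 3.2), bin_width=0.25)
        assert (density > 0).sum() == 1
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_uniform_samples_flat_within_sampling_error(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.0, 1.0, size=100_000)
        edges, density = histogram(x, bin_width=0.1, range_=(0.0, 1.0))
        mass = density * np.diff(edges)
        # binomial 3-sigma bound on each bin's mass at p = 0.1, n = 1e5
        sigma = np.sqrt(0.1 * 0.9 / 100_000)
        assert np.all(np.abs(mass - 0.1) < 3.5 * sigma)

    def test_normalization_for_random_input(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=1000)
        edges, density = histogram(x, bin_width=0.3)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ParameterError):
            histogram([], bin_width=0.1)


class TestBoundFraction:
    def test_trivial_extremes(self):
        assert bound_fraction(np.zeros(10)) == 1.0
        assert bound_fraction(np.full(10, 10.0)) == 0.0
        assert bound_fraction(np.full(10, -10.0)) == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(-10, 10, size=200)
        assert bound_fraction(d) == bound_fraction(rng.permutation(d))

    def test_markov_unbound_dwell_recovered(self):
        """A chain with ~30% stationary unbound occupancy: the measured bound
        fraction must match the generator's state log exactly (state means sit
        far from the cutoff) and the log must match the stationary value
        within 3 sigma of the correlated-chain sampling error."""
        p_u, stay = 0.30, 0.98
        # two-state switch bound <-> unbound with stationary P(unbound) = 0.3
        p_bu = (1 - stay) * p_u / (1 - p_u)   # bound -> unbound rate
        tm = (
            (1 - p_bu, 0.0, p_bu),
            (0.0, 1 - p_bu, p_bu),
            ((1 - stay) * 0.5, (1 - stay) * 0.5, stay),
        )
        params = TrajSimParams(
            n_frames=10_000, transition_matrix=tm,
            state_means=((-1.0, 20.0), (1.2, 152.0), (12.0, 90.0)),
            state_sds=((0.3, 5.0), (0.3, 5.0), (0.5, 20.0)), seed=123)
        sim = simulate_descriptor_trajectory(params)
        log_bound = float((sim.log["state"] != "UNBOUND").mean())
        measured = bound_fraction(sim.log["d_signed"].to_numpy())
        assert measured == pytest.approx(log_bound, abs=1e-12)
        # correlated-sample error: var ~ p(1-p)/n * (1+rho)/(1-rho)
        rho = stay - p_bu  # spectral gap of the bound/unbound lumped chain
        sigma = np.sqrt(p_u * (1 - p_u) / 10_000 * (1 + rho) / (1 - rho))
        assert abs((1 - log_bound) - p_u) < 3 * sigma


class TestModeOccupancy:
    def test_single_mode(self):
        stats = mode_occupancy(["BS"] * 7)
        assert stats.occupancy == {"BS": 1.0}
        assert stats.n_transitions == 0

    def test_alternating_series_counts_transitions(self):
        stats = mode_occupancy(["BS", "BP"] * 5)
        assert stats.n_transitions == 9
        assert stats.occupancy["BS"] == pytest.approx(0.5)

    def test_occupancy_permutation_invariant_transitions_not(self):
        modes = ["BS"] * 6 + ["BP"] * 4
        grouped = mode_occupancy(modes)
        interleaved = mode_occupancy(["BS", "BS", "BP", "BS", "BP", "BS",
                                      "BP", "BS", "BP", "BS"])
        assert grouped.occupancy == interleaved.occupancy
        assert grouped.n_transitions == 1
        assert interleaved.n_transitions == 8

    def test_symmetric_two_state_chain_half_half(self):
        tm = ((0.95, 0.05, 0.0), (0.05, 0.95, 0.0), (0.0, 0.0, 1.0))
        params = TrajSimParams(n_frames=10_000, transition_matrix=tm, seed=9)
        sim = simulate_descriptor_trajectory(params)
        stats = mode_occupancy(sim.log["state"])
        rho = 0.90  # 1 - p01 - p10
        sigma = np.sqrt(0.25 / 10_000 * (1 + rho) / (1 - rho))
        assert abs(stats.occupancy["BS"] - 0.5) < 3 * sigma


class TestBlockAverage:
    def test_constant_series_zero_spread(self):
        ba = block_average(np.full(100, 2.5), n_blocks=5)
        assert ba.mean == 2.5
        assert ba.sd_of_block_means == 0.0

    def test_block_indicator_closed_form(self):
        """Series = 1 on the 3rd of 4 blocks: block means are (0,0,1,0),
        whose sample SD is 0.5."""
        x = np.zeros(40)
        x[20:30] = 1.0
        ba = block_average(x, n_blocks=4)
        assert ba.mean == pytest.approx(0.25)
        assert ba.sd_of_block_means == pytest.approx(0.5)

    def test_mean_equals_global_mean_when_divisible(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        assert block_average(x, n_blocks=5).mean == pytest.approx(
            x.mean(), abs=1e-12)

    def test_remainder_frames_dropped_from_end(self):
        x = np.arange(13.0)
        ba = block_average(x, n_blocks=4)   # uses first 12 values
        assert ba.mean == pytest.approx(np.arange(12.0).mean())

    def test_sd_shrinks_with_noise(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=1000)
        sds = [block_average(s * base, n_blocks=5).sd_of_block_means
               for s in (1.0, 0.1, 0.0)]
        assert sds[0] > sds[1] > sds[2] == 0.0

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ParameterError):
            block_average(np.arange(10.0), n_blocks=1)


class TestGroupContiguousModes:
    def test_two_runs(self):
        out = group_contiguous_modes([1, 2, 3, 4, 5],
                                     ["BS", "BS", "BS", "BP", "BP"])
        assert out == [ModeInterval(1.0, 3.0, "BS"), ModeInterval(4.0, 5.0, "BP")]

    def test_singleton(self):
        assert group_contiguous_modes([-7.0], ["BS"]) == [
            ModeInterval(-7.0, -7.0, "BS")]

    def test_alternating_all_singletons(self):
        coords = list(range(6))
        modes = ["BS", "BP"] * 3
        out = group_contiguous_modes(coords, modes)
        assert len(out) == 6
        assert all(iv.start == iv.end for iv in out)

    def test_intervals_partition_the_coordinates(self):
        rng = np.random.default_rng(2)
        coords = np.arange(50.0)
        modes = rng.choice(["BS", "BP", "UNBOUND"], size=50)
        out = group_contiguous_modes(coords, modes)
        covered = []
        for iv in out:
            covered.extend(coords[(coords >= iv.start) & (coords <= iv.end)])
        assert np.array_equal(np.sort(covered), coords)
        for a, b in zip(out[:-1], out[1:]):
            assert a.end < b.start
            assert a.mode != b.mode


def test_subsample_preset_cadence():
    times = np.arange(0.0, 20001.0, 2.0)  # 2 ps frames over 20 ns
    idx = subsample_indices(times)  # default: 10 ps step, max 1001 frames
    assert len(idx) == 1001
    assert np.allclose(np.diff(times[idx]), 10.0)
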