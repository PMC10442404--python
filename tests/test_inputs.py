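"""Spike-raster generation and exponential filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prespike import (
    SequenceSpec,
    SpikeRaster,
    filter_raster,
    generate_sequence_epoch,
    make_stdp_schedule,
    make_two_input_pattern,
)
from prespike.inputs import bin_raster
from prespike.io import raster_from_csv, raster_to_csv

H = 0.05


class TestRasterInvariants:
    def test_out_of_window_spikes_rejected(self):
        with pytest.raises(ValueError):
            SpikeRaster(1, [np.array([500.0])], 500.0)
        with pytest.raises(ValueError):
            make_two_input_pattern(-1.0, 2.0, 500.0)

    def test_channel_count_must_match(self):
        with pytest.raises(ValueError):
            SpikeRaster(3, [np.array([1.0])], 500.0)

    def test_superposition_merges_channelwise(self):
        a = SpikeRaster(2, [np.array([1.0]), np.array([])], 10.0)
        b = SpikeRaster(2, [np.array([3.0]), np.array([2.0])], 10.0)
        c = a + b
        assert np.allclose(c.spikes[0], [1.0, 3.0])
        assert np.allclose(c.spikes[1], [2.0])


class TestSequenceEpoch:
    def test_noiseless_sequence_spans_nominal_length(self):
        # 100 channels at 2 ms delays: spikes at 0..198 ms, booked as a
        # 200 ms sequence (span plus one inter-spike interval)
        spec = SequenceSpec(n_seq=100, inter_spike_delay=2.0, jitter_range=0.0,
                            background_rate=0.0, n_distractors=0, onset=0.0,
                            T=400.0)
        r = generate_sequence_epoch(spec, seed=0)
        times = np.array([ts[0] for ts in r.spikes])
        assert times[0] == 0.0
        assert times[-1] == pytest.approx(198.0)
        assert spec.nominal_span == 200.0

    def test_no_generators_gives_empty_raster(self):
        spec = SequenceSpec(n_seq=0, background_rate=0.0, n_distractors=2,
                            onset=0.0, T=100.0)
        r = generate_sequence_epoch(spec, seed=0)
        assert r.n_spikes == 0

    def test_poisson_background_rate(self):
        # 10 Hz over 500 ms -> 5 expected spikes per epoch; Monte Carlo mean
        # within 3 standard errors of the Bernoulli-thinning expectation
        spec = SequenceSpec(n_seq=0, background_rate=10.0, n_distractors=1,
                            onset=0.0, T=500.0)
        n_draws = 3000
        counts = np.array([
            generate_sequence_epoch(spec, seed=s).n_spikes for s in range(n_draws)
        ])
        n_steps = int(round(500.0 / H))
        p = 10.0 * H / 1000.0
        expected = n_steps * p
        se = np.sqrt(n_steps * p * (1 - p) / n_draws)
        assert abs(counts.mean() - expected) < 3 * se

    def test_seed_determinism(self):
        spec = SequenceSpec(n_seq=10, n_distractors=10, T=400.0)
        a = generate_sequence_epoch(spec, seed=7)
        b = generate_sequence_epoch(spec, seed=7)
        for x, y in zip(a.spikes, b.spikes):
            assert np.array_equal(x, y)
        assert a.meta["onset"] == b.meta["onset"]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_jitter_bounded_by_range(self, seed):
        spec = SequenceSpec(n_seq=20, inter_spike_delay=2.0, jitter_range=2.0,
                            background_rate=0.0, n_distractors=0,
                            onset=(0.0, 200.0), T=400.0)
        r = generate_sequence_epoch(spec, seed=seed)
        nominal = r.meta["nominal_sequence_times"]
        actual = np.array([ts[0] for ts in r.spikes])
        assert np.all(np.abs(actual - nominal) <= 2.0 + 1e-12)

    def test_population_rate_flat_where_onset_fully_smears(self):
        # With onset uniform over a range much longer than the sequence span,
        # the across-seeds mean rate in 10 ms bins is flat in the interior
        # (between the onset ramp-in and ramp-out); no interior bin deviates
        # from the interior mean beyond sampling error.
        spec = SequenceSpec(n_seq=5, inter_spike_delay=2.0, jitter_range=0.0,
                            background_rate=0.0, n_distractors=0,
                            onset=(0.0, 180.0), T=200.0)
        n_seeds = 400
        edges = np.arange(0, 200.0 + 1e-9, 10.0)
        hist = np.zeros(len(edges) - 1)
        for s in range(n_seeds):
            r = generate_sequence_epoch(spec, seed=s)
            ts = np.concatenate(r.spikes)
            hist += np.histogram(ts, edges)[0]
        interior = hist[1:18]  # bins fully covered by the smeared sequence
        mean = interior.mean()
        se = np.sqrt(mean)  # Poisson-scale counting error per bin
        assert np.all(np.abs(interior - mean) < 4 * se)

    def test_boundary_configuration_allowed_and_clipped(self):
        spec = SequenceSpec()  # onset up to 200, span 198, jitter 2 -> == T
        r = generate_sequence_epoch(spec, seed=3)
        assert all(ts.size == 0 or ts[-1] < spec.T for ts in r.spikes)


class TestStdpSchedules:
    def test_pairing_sign_convention(self):
        r = make_stdp_schedule("pairing", dt=-4.0, t_ref=50.0)
        assert r.spikes[0][0] == pytest.approx(46.0)  # probe 4 ms before ch-2
        assert r.spikes[1][0] == pytest.approx(50.0)

    def test_burst_spacing_is_inverse_frequency(self):
        r = make_stdp_schedule("burst", freq_hz=100.0, t_ref=20.0,
                               branch="pre_post", probe_gap=10.0)
        # three driver spikes at 1/f spacing; probe 10 ms before the first
        assert np.allclose(r.spikes[1] - 20.0, [0.0, 10.0, 20.0])
        assert r.spikes[0][0] == pytest.approx(10.0)

    def test_one_n_degenerates_to_single_pairing(self):
        r1 = make_stdp_schedule("one_n", n=1, t_ref=50.0)
        rp = make_stdp_schedule("pairing", dt=10.0, t_ref=50.0)
        assert np.allclose(r1.spikes[0], rp.spikes[0])
        assert np.allclose(r1.spikes[1], rp.spikes[1])

    def test_freq_pairing_extends_window_when_needed(self):
        r = make_stdp_schedule("freq_pairing", pairing_freq_hz=1.0, T=500.0)
        assert r.duration > 4000.0  # 5 pairs at 1 Hz cannot fit in 500 ms

    @pytest.mark.parametrize("kwargs", [
        dict(protocol="burst", freq_hz=0.0),
        dict(protocol="one_n", n=0),
        dict(protocol="freq_pairing", pairing_freq_hz=-5.0),
    ])
    def test_invalid_protocol_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_stdp_schedule(**kwargs)


class TestFiltering:
    def test_empty_raster_filters_to_zero(self):
        r = SpikeRaster(3, [np.array([])] * 3, 10.0)
        tr = filter_raster(r, H, 2.0)
        assert not tr.values.any()

    def test_single_spike_exponential_decay(self):
        r = SpikeRaster(1, [np.array([1.0])], 20.0)
        tr = filter_raster(r, H, 2.0)
        i0 = int(round(1.0 / H))
        assert tr.values[i0, 0] == pytest.approx(1.0)
        # 2 ms (= tau_x) later the trace has decayed to 1/e, within 1%
        i1 = i0 + int(round(2.0 / H))
        assert tr.values[i1, 0] == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_linearity_and_superposition(self, rng):
        a = SpikeRaster(2, [np.sort(rng.uniform(0, 50, 5)), np.array([3.0])], 50.0)
        b = SpikeRaster(2, [np.array([10.0]), np.sort(rng.uniform(0, 50, 4))], 50.0)
        fa = filter_raster(a, H, 2.0).values
        fb = filter_raster(b, H, 2.0).values
        fab = filter_raster(a + b, H, 2.0).values
        assert np.allclose(fab, fa + fb, atol=1e-12)

    def test_coincident_spikes_sum(self):
        r = SpikeRaster(1, [np.array([5.0, 5.0])], 10.0)
        counts = bin_raster(r, H)
        assert counts[int(round(5.0 / H)), 0] == 2.0


def test_raster_csv_round_trip(tmp_path, rng):
    spec = SequenceSpec(n_seq=5, n_distractors=3, T=300.0)
    r = generate_sequence_epoch(spec, seed=11)
    path = tmp_path / "raster.csv"
    raster_to_csv(r, path, sidecar={"seed": 11})
    back = raster_from_csv(path)
    assert back.n_channels == r.n_channels
    assert back.duration == r.duration
    for x, y in zip(r.spikes, back.spikes):
        assert np.allclose(x, y)
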