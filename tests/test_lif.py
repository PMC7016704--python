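"""LIF field integration, WTA first spike, noise scheme."""

import numpy as np
import pytest

from salif.lif import (
    LIFParams,
    NeuronFieldState,
    NoiseParams,
    WTAParams,
    batch_simulate,
    count_distinct_latencies,
    euler_step,
    first_spike,
    init_input_current,
    saccades_to_frame,
)
from salif.synthetic import generate_synthetic_saliency_map, random_map_set


def _state(V, I):
    V = np.asarray(V, dtype=float)
    return NeuronFieldState(V=V, I=np.asarray(I, dtype=float),
                            fired=np.zeros(V.shape, bool))


class TestEulerStep:
    def test_resting_fixed_point(self):
        p = LIFParams()
        st = _state(np.full((3, 3), p.Eleak), np.zeros((3, 3)))
        out = euler_step(st, p)
        np.testing.assert_array_equal(out.V, st.V)

    def test_pure_integrator(self):
        """With all conductances zero, dV = dt * I / C exactly."""
        p = LIFParams(Gleak=0.0, Gexc=0.0, Ginh=0.0)
        st = _state(np.zeros((2, 2)), np.full((2, 2), 3e-9))
        out = euler_step(st, p)
        np.testing.assert_allclose(out.V, p.dt * 3e-9 / p.C)

    def test_single_step_hand_computation(self):
        """V=0, I=2e-9 A, Gleak=1e-8 S, C=1e-9 F, dt=1e-4 s -> 2e-4 V."""
        p = LIFParams(Gleak=1e-8, C=1e-9, dt=1e-4, Gexc=0.0)
        out = euler_step(_state([[0.0]], [[2e-9]]), p)
        assert out.V[0, 0] == pytest.approx(2e-4, rel=1e-12)

    def test_fire_and_reset_strict_threshold(self):
        p = LIFParams(Gleak=0.0, Gexc=0.0, Vthresh=1e-3)
        # resting exactly at threshold with zero drive: strict rule, no spike
        at = euler_step(_state([[p.Vthresh]], [[0.0]]), p)
        assert not at.fired.any()
        below = euler_step(_state([[0.0]], [[0.99e-3 * 1e-9 / 1e-4]]), p)
        assert not below.fired.any()
        over = euler_step(_state([[0.0]], [[1.01e-3 * 1e-9 / 1e-4]]), p)
        assert over.fired.all()
        assert over.V[0, 0] == p.Eleak

    def test_dt_times_c_variant_differs(self):
        p = LIFParams(Gleak=0.0, Gexc=0.0)
        st = _state([[0.0]], [[2e-9]])
        a = euler_step(st, p, form="dt_over_C").V[0, 0]
        b = euler_step(st, p, form="dt_times_C").V[0, 0]
        assert a != b and b == pytest.approx(p.dt * p.C * 2e-9)

    def test_nonfinite_raises_with_parameter_hint(self):
        p = LIFParams(Gleak=0.0, Gexc=0.0)
        with pytest.raises(FloatingPointError, match="dt"):
            euler_step(_state([[0.0]], [[np.inf]]), p)

    def test_time_advances_in_ms(self):
        p = LIFParams()
        out = euler_step(_state([[0.0]], [[0.0]]), p)
        assert out.t == pytest.approx(p.dt * 1000.0)


class TestInitInputCurrent:
    def test_zero_noise_is_scaled_map(self, bundle, single_peak_map):
        lif, _, _ = bundle
        noise = NoiseParams(0.0, 0.0, single_peak_map.value_range)
        st = init_input_current(single_peak_map, lif, noise, seed=0)
        np.testing.assert_allclose(st.I, lif.Ginput * single_peak_map.values)
        np.testing.assert_array_equal(st.V, lif.Eleak)

    def test_constant_noise_on_zero_map(self, bundle):
        lif, _, _ = bundle
        m = generate_synthetic_saliency_map(6, 6, [], seed=0)
        st = init_input_current(m, lif, NoiseParams(0.0, 3e-10, 1e-9), seed=0)
        np.testing.assert_allclose(st.I, lif.Ginput * 3e-10)

    def test_noise_bounds(self, bundle, single_peak_map):
        lif, _, _ = bundle
        noise = NoiseParams(2e-10, 1e-10, single_peak_map.value_range)
        st = init_input_current(single_peak_map, lif, noise, seed=11)
        lo = lif.Ginput * single_peak_map.values
        hi = lif.Ginput * (single_peak_map.values + 1e-10 + 2e-10)
        assert np.all(st.I >= lo) and np.all(st.I <= hi)


class TestFirstSpike:
    def test_zero_map_censored_at_timeout(self, bundle, zero_noise):
        lif, wta, _ = bundle
        m = generate_synthetic_saliency_map(6, 6, [], seed=0)
        s = first_spike(m, lif, wta, zero_noise, seed=0)
        assert s.censored and np.isnan(s.latency_ms)

    def test_zero_noise_deterministic_across_seeds(self, bundle, zero_noise,
                                                   single_peak_map):
        lif, wta, _ = bundle
        a = first_spike(single_peak_map, lif, wta, zero_noise, seed=1)
        b = first_spike(single_peak_map, lif, wta, zero_noise, seed=99)
        assert a.latency_ms == b.latency_ms and a.winner == b.winner

    def test_zero_noise_winner_is_argmax(self, bundle, zero_noise):
        lif, wta, _ = bundle
        rng = np.random.default_rng(8)
        for _ in range(20):
            vals = rng.uniform(0.3, 1.0, size=(8, 8))
            r, c = rng.integers(0, 8, 2)
            vals[r, c] = 1.5  # unique maximum
            m = generate_synthetic_saliency_map(
                8, 8, [((int(r), int(c)), 1.0)], seed=0,
                background_ampl=0.0)
            m = type(m)(vals * 1e-9, m.map_scale, 1e-9)
            s = first_spike(m, lif, wta, zero_noise, seed=0, engine="reduced")
            assert s.winner == (r, c)

    def test_latency_on_dt_grid(self, bundle, zero_noise, single_peak_map):
        lif, wta, _ = bundle
        s = first_spike(single_peak_map, lif, wta, zero_noise, seed=0)
        steps = s.latency_ms / (lif.dt * 1000.0)
        assert steps == pytest.approx(round(steps))

    def test_spike_time_monotone_in_peak_height(self, bundle, zero_noise):
        lif, wta, _ = bundle
        lats = []
        for h in (0.4, 0.6, 0.8, 1.0):
            m = generate_synthetic_saliency_map(12, 12, [((6, 6), h)],
                                                seed=1, background_ampl=0.0)
            lats.append(first_spike(m, lif, wta, zero_noise, seed=0).latency_ms)
        assert all(a >= b for a, b in zip(lats, lats[1:]))

    def test_engines_bit_identical(self, bundle, map_set):
        lif, wta, noise = bundle
        noisy = NoiseParams(1e-11, 1e-11, 1e-9)
        for eng_noise in (noise, noisy):
            full = batch_simulate(map_set, lif, wta, eng_noise,
                                  runs_per_image=2, seed=5, engine="full")
            red = batch_simulate(map_set, lif, wta, eng_noise,
                                 runs_per_image=2, seed=5, engine="reduced")
            for a, b in zip(full, red):
                assert a.latency_ms == b.latency_ms or (
                    a.censored and b.censored)
                assert a.winner == b.winner

    def test_matches_numpy_reference_integration(self, bundle, zero_noise):
        """Step-by-step euler_step reference reproduces the kernel's
        first WTA spike exactly on a small map."""
        lif, wta, _ = bundle
        m = generate_synthetic_saliency_map(5, 5, [((2, 3), 0.9)], seed=4)
        kernel = first_spike(m, lif, wta, zero_noise, seed=0)

        sal = init_input_current(m, lif, zero_noise, seed=0)
        wta_state = NeuronFieldState(V=np.full(m.values.shape, lif.Eleak),
                                     I=np.zeros(m.values.shape),
                                     fired=np.zeros(m.values.shape, bool))
        wta_lif = LIFParams(dt=lif.dt, Eleak=lif.Eleak, Eexc=lif.Eexc,
                            Einh=lif.Einh, Gleak=wta.Gleak, Gexc=0.0,
                            Ginh=wta.Ginh, Ginput=0.0,
                            Vthresh=lif.Vthresh, C=wta.C)
        for step in range(1, 20001):
            sal = euler_step(sal, lif)
            gexc = np.where(sal.fired, lif.Gexc, 0.0)
            wta_state = euler_step(wta_state, wta_lif, Gexc_field=gexc)
            if wta_state.fired.any():
                break
        assert step * lif.dt * 1000.0 == kernel.latency_ms
        ref_winner = np.unravel_index(np.argmax(wta_state.fired),
                                      m.values.shape)
        assert tuple(int(i) for i in ref_winner) == kernel.winner

    def test_bad_timeout_raises(self, bundle, zero_noise, single_peak_map):
        lif, wta, _ = bundle
        with pytest.raises(ValueError):
            first_spike(single_peak_map, lif, wta, zero_noise, timeout_ms=0)


class TestBatchSimulate:
    def test_run_counts(self, bundle, zero_noise):
        lif, wta, _ = bundle
        maps = random_map_set(5, shape=(12, 12), seed=2)
        assert len(batch_simulate(maps, lif, wta, zero_noise)) == 5
        assert len(batch_simulate(maps, lif, wta, zero_noise,
                                  runs_per_image=10)) == 50

    def test_master_seed_reproducible(self, bundle):
        lif, wta, _ = bundle
        noise = NoiseParams(1e-10, 0.0, 1e-9)
        maps = random_map_set(4, shape=(12, 12), seed=2)
        a = batch_simulate(maps, lif, wta, noise, runs_per_image=3, seed=17)
        b = batch_simulate(maps, lif, wta, noise, runs_per_image=3, seed=17)
        assert [s.latency_ms for s in a] == [s.latency_ms for s in b]

    def test_frame_columns(self, bundle, zero_noise):
        lif, wta, _ = bundle
        maps = random_map_set(3, shape=(12, 12), seed=2)
        frame = saccades_to_frame(batch_simulate(maps, lif, wta, zero_noise))
        assert list(frame.columns) == ["image_id", "run_id", "latency_ms",
                                       "censored", "winner_row", "winner_col",
                                       "seed"]


class TestCountDistinctLatencies:
    def test_literal_counts(self, bundle, zero_noise, single_peak_map):
        lif, wta, _ = bundle
        sacs = [first_spike(single_peak_map, lif, wta, zero_noise, seed=s)
                for s in range(5)]
        assert count_distinct_latencies(sacs) == 1

    def test_two_values(self):
        from salif.lif import SimulatedSaccade

        sacs = [SimulatedSaccade(0, i, lat, False, (0, 0), (0.0, 0.0))
                for i, lat in enumerate([150.0, 150.0, 151.0])]
        assert count_distinct_latencies(sacs) == 2

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            count_distinct_latencies([])

    def test_mixed_images_raise(self):
        from salif.lif import SimulatedSaccade

        sacs = [SimulatedSaccade(i, 0, 100.0, False, (0, 0), (0.0, 0.0))
                for i in range(2)]
        with pytest.raises(ValueError):
            count_distinct_latencies(sacs)


def test_param_validation():
    with pytest.raises(ValueError):
        LIFParams(dt=0)
    with pytest.raises(ValueError):
        LIFParams(Vthresh=-1.0, Eleak=0.0)
    with pytest.raises(ValueError):
        WTAParams(C=0)
    with pytest.raises(ValueError):
        NoiseParams(noise_ampl=-1e-9)
    with pytest.raises(ValueError):
        NoiseParams(map_range=0)
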