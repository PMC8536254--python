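"""Generator: state paths, rendering, ensembles, movies."""

import numpy as np
import pytest

from smkin.simulate import (
    ABSENT,
    BLEACHED,
    ENHANCED,
    KineticScheme,
    SimulationConfig,
    render_fret_trace,
    render_movie,
    render_uife_trace,
    sample_state_path,
    simulate_ensemble,
)
from smkin.traces import IntensityTrace


class TestSampleStatePath:
    def test_single_absorbing_state_spans_duration(self, rng):
        scheme = KineticScheme(
            sub_step_lifetimes_s=(float("inf"),), bleach_lifetime_s=float("inf")
        )
        path = sample_state_path(scheme, 10.0, rng)
        assert path == [("bound1", 0.0)]

    def test_mean_time_to_enhanced_is_sum_of_substeps(self):
        # Monte-Carlo oracle: E[sum of Exp(3.0) + Exp(4.5)] = 7.5 s
        scheme = KineticScheme(
            sub_step_lifetimes_s=(3.0, 4.5), bleach_lifetime_s=float("inf")
        )
        rng = np.random.default_rng(7)
        waits = []
        for _ in range(10_000):
            path = sample_state_path(scheme, 1e6, rng)
            t_enh = next(t for s, t in path if s == ENHANCED)
            waits.append(t_enh)
        se = 7.5 / np.sqrt(len(waits))  # rough MC error scale
        assert np.mean(waits) == pytest.approx(7.5, abs=4 * se)

    def test_zero_lifetime_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(sub_step_lifetimes_s=(0.0, 4.5))

    def test_substeps_visited_in_order(self, rng):
        scheme = KineticScheme(sub_step_lifetimes_s=(1.0, 1.0, 1.0), bleach_lifetime_s=float("inf"))
        for _ in range(50):
            path = sample_state_path(scheme, 1e5, rng)
            states = [s for s, _ in path]
            bound = [s for s in states if s.startswith("bound")]
            assert bound == ["bound1", "bound2", "bound3"]

    def test_holding_times_exponential_mean(self, rng):
        scheme = KineticScheme(sub_step_lifetimes_s=(2.0,), bleach_lifetime_s=float("inf"))
        holds = []
        for _ in range(5_000):
            path = sample_state_path(scheme, 1e6, rng)
            t_next = path[1][1] if len(path) > 1 else None
            holds.append(t_next)
        assert np.mean(holds) == pytest.approx(2.0, rel=0.1)

    def test_nonpositive_duration_rejected(self, rng, uife_scheme):
        with pytest.raises(ValueError):
            sample_state_path(uife_scheme, 0.0, rng)


class TestRenderUife:
    def test_full_frame_in_enhanced_state(self, uife_scheme, quiet_config):
        path = [(ENHANCED, 0.0)]
        trace = render_uife_trace(path, quiet_config, uife_scheme, noiseless=True)
        assert trace.counts[0] == pytest.approx(450.0)
        assert len(trace) == quiet_config.n_frames

    def test_split_frame_linear_average(self, uife_scheme):
        config = SimulationConfig(
            frame_s=0.05, duration_s=0.1, shot_noise=False, read_noise_sd=0.0,
        )
        # frame 0 split 50/50 between the 200- and 450-count levels
        path = [("bound1", 0.0), (ENHANCED, 0.025)]
        trace = render_uife_trace(path, config, uife_scheme, noiseless=True)
        assert trace.counts[0] == pytest.approx(325.0)
        assert trace.counts[1] == pytest.approx(450.0)

    def test_read_noise_mean_converges_to_level(self, uife_scheme, rng):
        config = SimulationConfig(
            frame_s=0.05, duration_s=60.0, shot_noise=False, read_noise_sd=25.0
        )
        trace = render_uife_trace([(ENHANCED, 0.0)], config, uife_scheme, rng)
        assert len(trace) >= 1000
        assert trace.counts.mean() == pytest.approx(450.0, abs=2.0)

    def test_background_added(self, uife_scheme):
        config = SimulationConfig(frame_s=0.05, duration_s=1.0, background=100.0,
                                  shot_noise=False, read_noise_sd=0.0)
        trace = render_uife_trace([(ENHANCED, 0.0)], config, uife_scheme, noiseless=True)
        assert trace.counts[0] == pytest.approx(550.0)


class TestRenderFret:
    def test_noiseless_streams_follow_estar_formula(self, uife_scheme, quiet_config):
        trace = render_fret_trace([("bound1", 0.0)], quiet_config, uife_scheme, noiseless=True)
        assert trace.i_dd[0] == pytest.approx(300.0)  # 500 * (1 - 0.40)
        assert trace.i_da[0] == pytest.approx(200.0)  # 500 * 0.40
        locked = render_fret_trace([(ENHANCED, 0.0)], quiet_config, uife_scheme, noiseless=True)
        assert locked.i_dd[0] == pytest.approx(260.0)
        assert locked.i_da[0] == pytest.approx(240.0)
        assert locked.i_aa[0] == pytest.approx(600.0)

    def test_noiseless_estar_exact(self, uife_scheme, quiet_config):
        from smkin.hmm import compute_estar

        trace = render_fret_trace([(ENHANCED, 0.0)], quiet_config, uife_scheme, noiseless=True)
        estar = compute_estar(trace.i_dd, trace.i_da)
        np.testing.assert_allclose(estar, 0.48, rtol=1e-12)

    def test_bleached_segment_at_background(self, uife_scheme, quiet_config):
        path = [("bound1", 0.0), (BLEACHED, 30.0)]
        trace = render_fret_trace(path, quiet_config, uife_scheme, noiseless=True)
        tail = trace.i_aa[int(30.0 / quiet_config.frame_s) + 1 :]
        np.testing.assert_allclose(tail, quiet_config.background)

    def test_invalid_estar_rejected(self):
        with pytest.raises(ValueError):
            KineticScheme(estar={"bound": 1.2, "enhanced": 0.48, "rewound": 0.4, "open": 0.2})


class TestEnsemble:
    def test_class_counts_match_binomial(self):
        config = SimulationConfig(
            frame_s=0.1, duration_s=30.0, n_traces=1000, seed=42, estar_noise_sd=0.0,
            proportions={"I": 0.45, "II": 0.44, "III": 0.09, "IV": 0.02},
        )
        scheme = KineticScheme(sub_step_lifetimes_s=(1.0, 1.5), enhanced_lifetime_s=8.0,
                               bleach_lifetime_s=40.0)
        sims = simulate_ensemble(config, scheme, kind="fret")
        counts = {c: sum(s.true_class == c for s in sims) for c in "I II III IV".split()}
        for cls, p in config.proportions.items():
            sd = np.sqrt(1000 * p * (1 - p))
            assert abs(counts[cls] - 1000 * p) <= 3 * sd

    def test_empty_ensemble(self, uife_scheme):
        config = SimulationConfig(n_traces=0, seed=0)
        assert simulate_ensemble(config, uife_scheme, kind="uife") == []

    def test_empty_mixture_rejected(self, uife_scheme):
        config = SimulationConfig(n_traces=5, proportions={}, seed=0)
        with pytest.raises(ValueError):
            simulate_ensemble(config, uife_scheme, kind="uife")

    def test_class_ii_only_has_transition_before_bleach(self, uife_scheme):
        config = SimulationConfig(n_traces=50, duration_s=60.0, seed=3,
                                  proportions={"II": 1.0})
        sims = simulate_ensemble(config, uife_scheme, kind="uife")
        for s in sims:
            assert s.transition_time_s is not None
            if s.bleach_time_s is not None:
                assert s.transition_time_s < s.bleach_time_s

    def test_seed_determinism_bit_identical(self, uife_scheme):
        config = SimulationConfig(n_traces=10, duration_s=20.0, seed=99)
        a = simulate_ensemble(config, uife_scheme, kind="uife")
        b = simulate_ensemble(config, uife_scheme, kind="uife")
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.trace.counts, tb.trace.counts)
            assert ta.true_class == tb.true_class and ta.path == tb.path

    def test_class_labels_match_noiseless_shape(self, uife_scheme):
        """On noiseless rendering, each labelled trace has its class's shape."""
        config = SimulationConfig(
            n_traces=60, duration_s=60.0, seed=11, shot_noise=False, read_noise_sd=0.0,
            proportions={"I": 0.4, "II": 0.4, "III": 0.2},
        )
        sims = simulate_ensemble(config, uife_scheme, kind="uife")
        for s in sims:
            states = [st for st, _ in s.path]
            if s.true_class == "II":
                assert ENHANCED in states and states[0] in (ABSENT, "bound1")
            elif s.true_class == "I":
                assert ENHANCED not in states
            elif s.true_class == "III":
                emitting = [st for st in states if st not in (ABSENT, BLEACHED)]
                assert emitting[0] == ENHANCED and "rewound" in emitting


class TestRenderMovie:
    def test_flux_conserved(self, quiet_config):
        trace = IntensityTrace(0.05, np.full(5, 450.0))
        stack = render_movie([trace], [(20.0, 20.0)], 1.3, quiet_config, shape=(40, 40))
        assert stack[0].sum() == pytest.approx(450.0, rel=0.005)

    def test_two_emitters_two_maxima(self, quiet_config):
        from skimage.feature import peak_local_max

        traces = [IntensityTrace(0.05, np.full(2, 400.0))] * 2
        stack = render_movie(traces, [(15.0, 20.0), (23.0, 20.0)], 1.3, quiet_config, shape=(40, 40))
        peaks = peak_local_max(stack[0], min_distance=3, threshold_abs=1.0)
        assert len(peaks) == 2

    def test_close_emitters_warn(self, quiet_config):
        traces = [IntensityTrace(0.05, np.full(2, 400.0))] * 2
        with pytest.warns(UserWarning):
            render_movie(traces, [(20.0, 20.0), (20.5, 20.0)], 1.3, quiet_config, shape=(40, 40))
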