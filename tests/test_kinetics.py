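"""Trace kinetics: kymographs, compaction, exponential fits, step finding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bips.kinetics import (
    IntensityTrace,
    build_kymograph,
    cluster_size_kbp,
    compaction_time,
    count_complexes,
    find_steps,
    fit_exponential,
)
from bips.synthetic import (
    gen_bleach_staircase,
    gen_compaction_kymograph,
    gen_exponential_trace,
    kymograph_traces,
)


def _ramp_trace(duration=100.0, t_start=20.0, plateau=20.0, t_end=300.0, n=3001):
    t = np.linspace(0.0, t_end, n)
    y = np.clip((t - t_start) / duration, 0.0, 1.0) * plateau
    return IntensityTrace(t, y)


class TestClusterSize:
    def test_roi_equals_total_gives_genome(self):
        t = np.arange(10.0)
        tr = cluster_size_kbp(
            IntensityTrace(t, np.full(10, 7.0)), IntensityTrace(t, np.full(10, 7.0))
        )
        np.testing.assert_allclose(tr.intensity, 48.5)

    def test_zero_roi_gives_zero(self):
        t = np.arange(10.0)
        tr = cluster_size_kbp(
            IntensityTrace(t, np.zeros(10)), IntensityTrace(t, np.ones(10))
        )
        np.testing.assert_allclose(tr.intensity, 0.0)

    def test_nonpositive_total_masked_with_warning(self):
        t = np.arange(5.0)
        total = np.array([1.0, 1.0, 0.0, 1.0, -2.0])
        with pytest.warns(UserWarning):
            tr = cluster_size_kbp(
                IntensityTrace(t, np.ones(5)), IntensityTrace(t, total)
            )
        assert np.isnan(tr.intensity[[2, 4]]).all()

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(0.01, 1e6))
    def test_scale_invariance(self, scale):
        t = np.arange(20.0)
        rng = np.random.default_rng(3)
        roi = rng.random(20) + 0.1
        tot = roi + rng.random(20)
        a = cluster_size_kbp(IntensityTrace(t, roi), IntensityTrace(t, tot))
        b = cluster_size_kbp(
            IntensityTrace(t, roi * scale), IntensityTrace(t, tot * scale)
        )
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-9)


class TestCompactionTime:
    def test_linear_ramp_is_ninety_percent_of_duration(self):
        # 5-95% of a linear ramp spans exactly 0.9 of its duration
        tr = _ramp_trace(duration=100.0)
        assert compaction_time(tr) == pytest.approx(90.0, abs=0.5)

    def test_step_function_within_one_frame(self):
        t = np.linspace(0, 100, 1001)
        y = (t >= 50).astype(float) * 10
        assert compaction_time(IntensityTrace(t, y), savgol_window=5) <= 0.5

    def test_affine_intensity_and_time_shift_invariance(self):
        tr = _ramp_trace()
        base = compaction_time(tr)
        shifted = IntensityTrace(tr.time_s + 55.0, tr.intensity * 3.7 + 11.0)
        assert compaction_time(shifted) == pytest.approx(base, abs=1e-9)

    def test_drifting_trace_raises(self):
        t = np.linspace(0, 100, 2001)
        with pytest.raises(ValueError):
            compaction_time(IntensityTrace(t, t**2))

    def test_synthetic_kymograph_pipeline_recovers_duration(self):
        # 30 s ramp with 5% noise: 5-95% time ~ 27 s, the lambda-DNA scale
        times = []
        for seed in range(15):
            kym, truth = gen_compaction_kymograph(
                duration=30.0, plateau_kbp=20.0, noise_sd=0.05, seed=seed
            )
            roi, tot = kymograph_traces(kym, truth["spot_position"])
            kbp = cluster_size_kbp(roi, tot)
            times.append(compaction_time(kbp, savgol_window=250))
        assert np.mean(times) == pytest.approx(27.0, abs=3.0)


class TestExponentialFits:
    def test_noiseless_decay_exact(self):
        tr, _ = gen_exponential_trace("decay", tau=10.0, frame_interval=1.0)
        fit = fit_exponential(tr, "decay")
        assert fit.tau_s == pytest.approx(10.0, rel=1e-6)

    @pytest.mark.parametrize("tau", [0.79, 7.5, 41.9, 126.0, 476.0])
    def test_paper_scale_constants_recovered_under_noise(self, tau):
        # the dissociation/FRAP time-constant fixtures, 5% amplitude noise
        kind = "recovery" if tau == 126.0 else "decay"
        taus = []
        for seed in range(25):
            tr, _ = gen_exponential_trace(
                kind,
                tau=tau,
                amplitude=1.0,
                noise_sd=0.05,
                frame_interval=tau / 12.0,
                n_frames=120,
                seed=seed,
            )
            taus.append(fit_exponential(tr, kind).tau_s)
        assert np.mean(taus) == pytest.approx(tau, rel=0.05)

    @pytest.mark.parametrize("tau", [1.0, 10.0, 100.0])
    def test_bias_below_two_percent_at_five_percent_noise(self, tau):
        taus = []
        for seed in range(40):
            tr, _ = gen_exponential_trace(
                "decay", tau=tau, noise_sd=0.05,
                frame_interval=tau / 15.0, n_frames=150, seed=seed,
            )
            taus.append(fit_exponential(tr, "decay").tau_s)
        assert abs(np.mean(taus) - tau) < 0.02 * tau

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_exponential(
                IntensityTrace(np.arange(5.0), np.exp(-np.arange(5.0))), "decay"
            )


def _oracle_best_breaks(y, k):
    """Exhaustive enumeration: optimal k-step segmentation by SSE."""
    n = len(y)
    best, best_breaks = np.inf, None
    for breaks in itertools.combinations(range(1, n), k):
        edges = (0,) + breaks + (n,)
        sse = sum(
            ((y[a:b] - y[a:b].mean()) ** 2).sum()
            for a, b in zip(edges[:-1], edges[1:])
        )
        if sse < best - 1e-12:
            best, best_breaks = sse, breaks
    return best, best_breaks


class TestFindSteps:
    def test_noiseless_three_steps_exact(self):
        tr, truth = gen_bleach_staircase(3, noise_sd=0.0, seed=11)
        st = find_steps(tr)
        assert st.n_steps == 3
        np.testing.assert_allclose(st.step_sizes, -truth["step_size"], rtol=1e-9)
        # detected within one frame of the true transition times
        assert np.all(
            np.abs(st.step_times - truth["step_times"])
            <= 1.5 * truth["frame_interval"]
        )

    def test_flat_noise_rarely_reports_steps(self):
        rng_hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tr = IntensityTrace(np.arange(150.0), rng.normal(0, 1, 150))
            if find_steps(tr).n_steps == 0:
                rng_hits += 1
        assert rng_hits >= 95

    def test_noisy_staircase_recovery(self):
        # 5 steps at 30%-of-step noise: >= 95% correct counts, sizes ~ truth
        counts, sizes = [], []
        for seed in range(100):
            tr, truth = gen_bleach_staircase(
                5, step_size=3.0, noise_sd=0.9, seed=seed
            )
            st = find_steps(tr)
            counts.append(st.n_steps)
            if st.n_steps == 5:
                sizes.append(-st.step_sizes.mean())
        assert sum(c == 5 for c in counts) >= 95
        assert np.mean(sizes) == pytest.approx(3.0, rel=0.10)

    def test_matches_exhaustive_changepoint_oracle(self):
        # exact DP equals brute-force enumeration on short traces
        rng = np.random.default_rng(8)
        y = np.concatenate([np.full(11, 6.0), np.full(9, 3.2), np.full(10, 0.0)])
        y = y + rng.normal(0, 0.3, y.size)
        tr = IntensityTrace(np.arange(float(y.size)), y)
        st = find_steps(tr)
        assert st.n_steps == 2
        _, oracle_breaks = _oracle_best_breaks(y, 2)
        detected = [int(np.searchsorted(tr.time_s, t, "left")) for t in st.step_times]
        assert tuple(detected) == oracle_breaks


class TestCountComplexes:
    def test_worked_ratios(self):
        assert count_complexes(9.0, 3.0) == pytest.approx(3.0)
        assert count_complexes(2220.0, 3.0) == pytest.approx(740.0)
        assert count_complexes(0.0, 3.0) == 0.0

    def test_propagated_sd(self):
        val, sd = count_complexes(2220.0, 3.0, cluster_sd=222.0, unit_sd=1.2)
        assert val == pytest.approx(740.0)
        expected = 740.0 * np.hypot(222.0 / 2220.0, 1.2 / 3.0)
        assert sd == pytest.approx(expected)

    def test_rejects_bad_unit(self):
        with pytest.raises(ValueError):
            count_complexes(10.0, 0.0)


class TestBuildKymograph:
    def _stack_with_line(self, n_frames=5, shape=(41, 61), spot_col=None):
        stack = np.zeros((n_frames,) + shape)
        stack[:, 20, 10:51] = 10.0  # horizontal DNA line
        if spot_col is not None:
            stack[:, 20, spot_col] += 30.0
        return stack

    def test_uniform_line_flat_profile(self):
        stack = self._stack_with_line()
        kym = build_kymograph(stack, ((20, 10), (20, 50)), background_kernel=5)
        inner = kym.data[5:-5]
        assert np.ptp(inner) < 0.2  # flat after normalisation

    def test_spot_position_recovered(self):
        stack = self._stack_with_line(spot_col=30)
        kym = build_kymograph(stack, ((20, 10), (20, 50)), background_kernel=5)
        assert abs(int(np.argmax(kym.data[:, 0])) - 20) <= 1  # 30-10=20 along line

    def test_all_zero_frame_guarded(self):
        stack = np.zeros((3, 21, 21))
        kym = build_kymograph(stack, ((10, 2), (10, 18)), background_kernel=3)
        assert np.all(kym.data == 0.0)

    def test_line_outside_image_raises(self):
        with pytest.raises(ValueError):
            build_kymograph(np.zeros((2, 10, 10)), ((5, 2), (5, 30)))
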