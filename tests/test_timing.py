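"""Peak-delay computation, classification, binning and cohort statistics."""

import math

import numpy as np
import pytest

from dualtrace.profiles import (
    FitConfig,
    GaussianComponent,
    GaussianMixtureModel,
    IntensityProfile,
)
from dualtrace.timing import (
    EventTiming,
    bin_delta_t,
    classify_delta_t_norm,
    compute_timing,
    curve_average,
    duration_comparison,
    summarize,
)


def timing(delta_t_s, d_dynamin_s=40.0, event_id=0, **kw):
    base = dict(
        t_dynamin=20.0, t_dynab=20.0 + delta_t_s, d_dynamin=d_dynamin_s,
        d_dynab=0.75 * d_dynamin_s, p_dynamin=100.0, p_dynab=80.0,
        double_dynab=False, double_dynamin=False, frame_interval_s=2.0,
    )
    base.update(kw)
    return EventTiming(event_id=event_id, **base)


def mixture_results(p, t, d, second=None):
    """A results object carrying known principal components."""
    prof = IntensityProfile(np.arange(30) * 2.0, np.zeros(30), 2.0)
    model = GaussianMixtureModel(prof)
    comps = [GaussianComponent(p, t, d / 4.0)]
    if second is not None:
        comps.append(GaussianComponent(*second))
    while len(comps) < 4:
        comps.append(GaussianComponent(0.001 * p, -100.0, 1.0))
    from dualtrace.profiles import GaussianMixtureResults

    return GaussianMixtureResults(model, tuple(comps), gof=0.99, converged=True)


class TestComputeTiming:
    def test_zero_delay_is_simultaneous(self):
        t = timing(0.0)
        assert t.delta_t == 0.0
        assert t.timing_class == "simultaneous"

    def test_plus_ten_percent_is_inclusive(self):
        t = timing(4.0, d_dynamin_s=40.0)  # 24 vs 20 s, d = 40 s
        assert t.delta_t_norm == pytest.approx(10.0)
        assert t.timing_class == "simultaneous"

    def test_minus_fifteen_percent_is_before(self):
        t = timing(-6.0, d_dynamin_s=40.0)  # 14 vs 20 s
        assert t.delta_t_norm == pytest.approx(-15.0)
        assert t.timing_class == "before"

    def test_sign_convention_negative_means_dynab_first(self):
        t = timing(-6.0)
        assert t.t_dynab < t.t_dynamin
        assert t.delta_t < 0

    def test_quantized_delay_has_quarter_frame_granularity(self):
        t = timing(1.3)  # 0.65 frames at 2 s/frame
        assert t.delta_t_frames_quantized == 0.75
        assert t.delta_t_frames_quantized * 4 == round(t.delta_t_frames_quantized * 4)

    def test_built_from_fits(self):
        f1 = mixture_results(100.0, 20.0, 40.0)
        f2 = mixture_results(80.0, 26.0, 30.0)
        t = compute_timing(3, f1, f2, frame_interval_s=2.0)
        assert t.delta_t == pytest.approx(6.0)
        assert t.d_dynamin == pytest.approx(40.0)
        assert not t.double_dynab

    def test_missing_principal_excluded(self):
        from dualtrace.profiles import GaussianMixtureResults

        prof = IntensityProfile(np.arange(30) * 2.0, np.zeros(30), 2.0)
        empty = GaussianMixtureResults(
            GaussianMixtureModel(prof), (), gof=-math.inf, converged=False
        )
        with pytest.raises(ValueError):
            compute_timing(0, empty, mixture_results(80.0, 26.0, 30.0), 2.0)

    def test_classification_invariant_under_time_translation(self):
        for dt in (-9.0, -3.0, 0.0, 5.0, 12.0):
            a = timing(dt)
            b = timing(dt, t_dynamin=520.0, t_dynab=520.0 + dt)
            assert a.timing_class == b.timing_class


class TestBinDeltaT:
    def test_small_values_fall_in_central_clusters(self):
        h = bin_delta_t([3.0, -4.0])
        lows = dict(zip(h["bin_low"], h["count"]))
        assert lows[0.0] == 1  # [0, 5)
        assert lows[-5.0] == 1  # [-5, 0)

    def test_boundary_value_goes_right(self):
        h = bin_delta_t([5.0])
        lows = dict(zip(h["bin_low"], h["count"]))
        assert lows[5.0] == 1

    def test_empty_input_gives_zero_histogram(self):
        h = bin_delta_t([])
        assert h["count"].sum() == 0
        assert len(h) >= 2

    def test_bin_width_is_five_and_symmetric(self):
        h = bin_delta_t([12.0, -33.0])
        widths = (h["bin_high"] - h["bin_low"]).unique()
        assert list(widths) == [5.0]
        assert set(h["bin_low"]) == set(-h["bin_high"])

    def test_overflow_values_retained(self):
        h = bin_delta_t([250.0, -130.0, 2.0])
        assert h["count"].sum() == 3


class TestSummarize:
    def test_identical_simultaneous_events(self):
        ts = [timing(0.0, event_id=i) for i in range(5)]
        s = summarize(ts)
        assert (s.fraction_before, s.fraction_simultaneous, s.fraction_after) == (0.0, 100.0, 0.0)
        assert s.histogram["count"].sum() == 5

    def test_proportional_peak_intensities_give_unit_correlation(self):
        ts = [
            timing(0.0, event_id=i, p_dynamin=50.0 + 10 * i, p_dynab=2.5 * (50.0 + 10 * i))
            for i in range(6)
        ]
        assert summarize(ts).intensity_correlation == pytest.approx(1.0)

    def test_class_fractions_recovered_from_sampled_cohort(self):
        """Cohort with (before, simultaneous, after) probabilities
        (0.25, 0.5, 0.25) recovers fractions within 3 points at n=1000."""
        rng = np.random.default_rng(0)
        ts = []
        counts = {"before": 0, "simultaneous": 0, "after": 0}
        for i in range(1000):
            u = rng.random()
            if u < 0.25:
                dtn = rng.uniform(-35, -12)
                counts["before"] += 1
            elif u < 0.75:
                dtn = rng.uniform(-8, 8)
                counts["simultaneous"] += 1
            else:
                dtn = rng.uniform(12, 35)
                counts["after"] += 1
            ts.append(timing(dtn / 100.0 * 40.0, event_id=i))
        s = summarize(ts)
        # classification reproduces the drawn classes exactly
        assert s.fraction_before == pytest.approx(counts["before"] / 10.0)
        assert s.fraction_simultaneous == pytest.approx(counts["simultaneous"] / 10.0)
        assert s.fraction_before == pytest.approx(25.0, abs=3.0)
        assert s.fraction_simultaneous == pytest.approx(50.0, abs=3.0)
        assert s.fraction_after == pytest.approx(25.0, abs=3.0)
        assert (
            s.fraction_before + s.fraction_simultaneous + s.fraction_after
        ) == pytest.approx(100.0)

    def test_double_peak_rate(self):
        ts = [timing(0.0, event_id=i, double_dynab=(i < 2)) for i in range(10)]
        assert summarize(ts).double_peak_rate == pytest.approx(20.0)

    def test_histogram_total_equals_n_events(self):
        rng = np.random.default_rng(21)
        ts = [timing(float(d), event_id=i) for i, d in enumerate(rng.normal(0, 30, 137))]
        s = summarize(ts)
        assert s.histogram["count"].sum() == 137

    def test_empty_cohort_signalled(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_channel_swap_antisymmetry(self):
        """Swapping channel roles negates every delay and maps before/after."""
        rng = np.random.default_rng(22)
        for _ in range(50):
            dt = float(rng.normal(0, 8))
            d1, d2 = float(rng.uniform(20, 60)), float(rng.uniform(20, 60))
            fwd = timing(dt, d_dynamin_s=d1, d_dynab=d2)
            swp = EventTiming(
                event_id=0, t_dynamin=fwd.t_dynab, t_dynab=fwd.t_dynamin,
                d_dynamin=d2, d_dynab=d1, p_dynamin=fwd.p_dynab,
                p_dynab=fwd.p_dynamin, double_dynab=False, double_dynamin=False,
                frame_interval_s=2.0,
            )
            assert swp.delta_t == -fwd.delta_t
            # normalization uses the (new) reference duration
            assert swp.delta_t_norm == pytest.approx(-100.0 * fwd.delta_t / d2)
            mapped = {"before": "after", "after": "before", "simultaneous": "simultaneous"}
            assert classify_delta_t_norm(-fwd.delta_t_norm) == mapped[fwd.timing_class]


class TestCurveAverage:
    def test_single_event_average_is_itself_normalized(self):
        f1 = mixture_results(100.0, 20.0, 40.0)
        f2 = mixture_results(80.0, 26.0, 30.0)
        curves = curve_average([(f1, f2)])
        i0 = int(np.argmin(np.abs(curves["rel_time_s"].to_numpy())))
        assert curves["mean_ch1"].iloc[i0] == pytest.approx(1.0, abs=1e-6)
        assert curves["mean_ch1"].max() == pytest.approx(1.0, abs=1e-6)

    def test_identical_events_have_zero_sem(self):
        f1 = mixture_results(100.0, 20.0, 40.0)
        f2 = mixture_results(80.0, 26.0, 30.0)
        curves = curve_average([(f1, f2)] * 4)
        assert float(curves["sem_ch1"].max()) == pytest.approx(0.0, abs=1e-12)
        assert float(curves["sem_ch2"].max()) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_offsets_average_peaks_at_zero(self):
        f1 = mixture_results(100.0, 20.0, 40.0)
        plus = mixture_results(80.0, 26.0, 30.0)
        minus = mixture_results(80.0, 14.0, 30.0)
        curves = curve_average([(f1, plus), (f1, minus)])
        peak_t = curves["rel_time_s"].iloc[int(np.argmax(curves["mean_ch2"]))]
        assert abs(peak_t) <= 0.5

    def test_zero_peak_event_excluded(self):
        with pytest.raises(ValueError):
            curve_average([(mixture_results(0.0, 20.0, 40.0), mixture_results(80.0, 26.0, 30.0))])


class TestDurationComparison:
    def test_equal_groups_ratio_100(self):
        d = duration_comparison([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert d.ratio_pct == pytest.approx(100.0)

    def test_known_ratio_recovered(self):
        rng = np.random.default_rng(23)
        a = rng.normal(30.0, 6.0, 500)  # true ratio 0.75
        b = rng.normal(40.0, 8.0, 500)
        d = duration_comparison(a, b)
        assert d.ratio_pct == pytest.approx(75.0, abs=5.0)

    def test_single_element_group_flagged(self):
        d = duration_comparison([10.0], [10.0, 12.0])
        assert math.isnan(d.sem_a)
        assert math.isnan(d.t_statistic)

    def test_empty_group_signalled(self):
        with pytest.raises(ValueError):
            duration_comparison([], [1.0])
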