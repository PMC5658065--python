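"""Peak-delay statistics between the two channels.

For each validated event, channel 1 (dynamin) and channel 2 (the GTPase
activity reporter, "dynab") each contribute a principal-Gaussian peak
(p, t, d).  The delay

    delta_t = t_ch2 - t_ch1        (negative: reporter peaks first)

is normalized by the channel-1 duration, delta_t_norm = 100 * delta_t / d_ch1
(percent), binned in 5% clusters, and classified as

    before        delta_t_norm < -cutoff
    simultaneous  -cutoff <= delta_t_norm <= +cutoff   (cutoff 10 by default)
    after         delta_t_norm > +cutoff.

Double-peaked channel-2 fits contribute their higher-amplitude peak to the
delay and are counted in the double-peak rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import GaussianMixtureResults

__all__ = [
    "EventTiming",
    "TimingSummary",
    "compute_timing",
    "classify_delta_t_norm",
    "bin_delta_t",
    "summarize",
    "curve_average",
    "duration_comparison",
    "DurationComparison",
]

CLASSES = ("before", "simultaneous", "after")


def classify_delta_t_norm(delta_t_norm: float, cutoff: float = 10.0) -> str:
    """Class boundaries are inclusive on the simultaneous side."""
    if delta_t_norm < -cutoff:
        return "before"
    if delta_t_norm > cutoff:
        return "after"
    return "simultaneous"


@dataclass(frozen=True)
class EventTiming:
    event_id: int
    t_dynamin: float  # s
    t_dynab: float  # s
    d_dynamin: float  # s
    d_dynab: float  # s
    p_dynamin: float
    p_dynab: float
    double_dynab: bool
    double_dynamin: bool
    frame_interval_s: float
    cutoff_pct: float = 10.0

    @property
    def delta_t(self) -> float:
        return self.t_dynab - self.t_dynamin

    @property
    def delta_t_frames(self) -> float:
        return self.delta_t / self.frame_interval_s

    @property
    def delta_t_frames_quantized(self) -> float:
        """Delay reported at the 0.25-frame granularity of the analysis."""
        return round(self.delta_t_frames * 4.0) / 4.0

    @property
    def delta_t_norm(self) -> float:
        return 100.0 * self.delta_t / self.d_dynamin

    @property
    def timing_class(self) -> str:
        return classify_delta_t_norm(self.delta_t_norm, self.cutoff_pct)


def compute_timing(
    event_id: int,
    fit_dynamin: GaussianMixtureResults,
    fit_dynab: GaussianMixtureResults,
    frame_interval_s: float,
    cutoff_pct: float = 10.0,
) -> EventTiming:
    """Build the per-event timing record from the two channels' fits.

    Raises ValueError when either channel lacks a principal component or the
    dynamin duration is non-positive; such events are excluded upstream with
    a logged reason.
    """
    pk1, pk2 = fit_dynamin.peak, fit_dynab.peak
    if pk1 is None or pk2 is None:
        raise ValueError("both channels need a principal peak for timing")
    if pk1.d <= 0:
        raise ValueError("dynamin duration must be > 0")
    return EventTiming(
        event_id=event_id,
        t_dynamin=pk1.t,
        t_dynab=pk2.t,
        d_dynamin=pk1.d,
        d_dynab=pk2.d,
        p_dynamin=pk1.p,
        p_dynab=pk2.p,
        double_dynab=fit_dynab.is_double_peak,
        double_dynamin=fit_dynamin.is_double_peak,
        frame_interval_s=frame_interval_s,
        cutoff_pct=cutoff_pct,
    )


def bin_delta_t(values: Sequence[float], bin_width: float = 5.0) -> pd.DataFrame:
    """Histogram of normalized delays in clusters of ``bin_width`` percent.

    Bins are [k*w, (k+1)*w), left-inclusive, anchored at zero and extended
    symmetrically about it; values beyond +-100% fall in their own overflow
    bins and stay counted.  Returns columns (bin_low, bin_high, count).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size and not np.all(np.isfinite(vals)):
        raise ValueError("delta_t values must be finite")
    if vals.size:
        ks = np.floor(vals / bin_width).astype(int)
        k_ext = max(abs(int(ks.min())), abs(int(ks.max()) + 1), 1)
    else:
        ks = np.array([], dtype=int)
        k_ext = 1
    k_range = np.arange(-k_ext, k_ext)
    counts = {k: 0 for k in k_range}
    for k in ks:
        counts[int(k)] += 1
    return pd.DataFrame(
        {
            "bin_low": k_range * bin_width,
            "bin_high": (k_range + 1) * bin_width,
            "count": [counts[k] for k in k_range],
        }
    )


@dataclass(frozen=True)
class TimingSummary:
    n_events: int
    fraction_before: float  # percent
    fraction_simultaneous: float
    fraction_after: float
    fraction_negative_delta_t: float
    double_peak_rate: float  # percent of events with a double dynab peak
    double_dynamin_rate: float
    histogram: pd.DataFrame
    mean_duration_dynamin: float
    sem_duration_dynamin: float
    mean_duration_dynab: float
    sem_duration_dynab: float
    duration_ratio_pct: float  # 100 * mean(d_dynab) / mean(d_dynamin)
    intensity_correlation: float  # Pearson r of (p_dynab, p_dynamin)

    def summary(self) -> str:
        return "\n".join(
            [
                f"Events analyzed:            {self.n_events}",
                f"Before / simultaneous / after (%):  "
                f"{self.fraction_before:.1f} / {self.fraction_simultaneous:.1f} / {self.fraction_after:.1f}",
                f"Negative delta_t (%):       {self.fraction_negative_delta_t:.1f}",
                f"Double dynab peaks (%):     {self.double_peak_rate:.1f}",
                f"Double dynamin peaks (%):   {self.double_dynamin_rate:.1f}",
                f"Duration dynamin (s):       {self.mean_duration_dynamin:.2f} +/- {self.sem_duration_dynamin:.2f} (SEM)",
                f"Duration dynab (s):         {self.mean_duration_dynab:.2f} +/- {self.sem_duration_dynab:.2f} (SEM)",
                f"Duration ratio dynab/dynamin (%): {self.duration_ratio_pct:.1f}",
                f"Peak-intensity correlation: {self.intensity_correlation:.3f}",
            ]
        )


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")


def summarize(timings: Sequence[EventTiming], bin_width: float = 5.0) -> TimingSummary:
    """Cohort statistics over per-event timing records; n must be >= 1."""
    if not timings:
        raise ValueError("cannot summarize an empty timing list")
    n = len(timings)
    classes = [t.timing_class for t in timings]
    d1 = np.array([t.d_dynamin for t in timings])
    d2 = np.array([t.d_dynab for t in timings])
    p1 = np.array([t.p_dynamin for t in timings])
    p2 = np.array([t.p_dynab for t in timings])
    if n >= 2 and np.std(p1) > 0 and np.std(p2) > 0:
        r = float(stats.pearsonr(p2, p1).statistic)
    else:
        r = float("nan")
    return TimingSummary(
        n_events=n,
        fraction_before=100.0 * classes.count("before") / n,
        fraction_simultaneous=100.0 * classes.count("simultaneous") / n,
        fraction_after=100.0 * classes.count("after") / n,
        fraction_negative_delta_t=100.0 * sum(t.delta_t < 0 for t in timings) / n,
        double_peak_rate=100.0 * sum(t.double_dynab for t in timings) / n,
        double_dynamin_rate=100.0 * sum(t.double_dynamin for t in timings) / n,
        histogram=bin_delta_t([t.delta_t_norm for t in timings], bin_width),
        mean_duration_dynamin=float(np.mean(d1)),
        sem_duration_dynamin=_sem(d1),
        mean_duration_dynab=float(np.mean(d2)),
        sem_duration_dynab=_sem(d2),
        duration_ratio_pct=100.0 * float(np.mean(d2) / np.mean(d1)),
        intensity_correlation=r,
    )


def curve_average(
    fits: Sequence[tuple[GaussianMixtureResults, GaussianMixtureResults]],
    rel_time_range_s: tuple[float, float] | None = None,
    grid_step_s: float | None = None,
) -> pd.DataFrame:
    """Average the fitted principal curves across events.

    Each event's principal mixture functions (both channels) are evaluated on
    a common grid of time relative to the dynamin peak and normalized by the
    event's dynamin peak value, then averaged pointwise.  Events without a
    principal peak in either channel, or with a zero dynamin peak value, are
    excluded.  Returns columns (rel_time_s, mean_ch1, sem_ch1, mean_ch2,
    sem_ch2); the mean dynamin curve peaks at relative time 0 with value 1.
    """
    usable = [
        (f1, f2)
        for f1, f2 in fits
        if f1.peak is not None and f2.peak is not None and f1.peak.p > 0
    ]
    if not usable:
        raise ValueError("no events with principal fits in both channels")
    if rel_time_range_s is None:
        dmax = max(max(f1.peak.d, f2.peak.d) for f1, f2 in usable)
        rel_time_range_s = (-1.5 * dmax, 1.5 * dmax)
    if grid_step_s is None:
        grid_step_s = usable[0][0].model.profile.frame_interval_s / 4.0
    grid = np.arange(rel_time_range_s[0], rel_time_range_s[1] + grid_step_s / 2, grid_step_s)
    c1 = np.empty((len(usable), grid.size))
    c2 = np.empty((len(usable), grid.size))
    for i, (f1, f2) in enumerate(usable):
        t0, p0 = f1.peak.t, f1.peak.p
        c1[i] = f1.predict(grid + t0, principal_only=True) / p0
        c2[i] = f2.predict(grid + t0, principal_only=True) / p0
    n = len(usable)
    sem1 = np.std(c1, axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.full(grid.size, np.nan)
    sem2 = np.std(c2, axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.full(grid.size, np.nan)
    return pd.DataFrame(
        {
            "rel_time_s": grid,
            "mean_ch1": c1.mean(axis=0),
            "sem_ch1": sem1,
            "mean_ch2": c2.mean(axis=0),
            "sem_ch2": sem2,
        }
    )


@dataclass(frozen=True)
class DurationComparison:
    ratio_pct: float  # 100 * mean_a / mean_b
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float  # Welch two-sample t (descriptive)
    p_value: float


def duration_comparison(
    durations_a: Sequence[float], durations_b: Sequence[float]
) -> DurationComparison:
    """Ratio of mean durations (percent) with a descriptive Welch t-test."""
    a = np.asarray(list(durations_a), dtype=float)
    b = np.asarray(list(durations_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both duration groups must be non-empty")
    if a.size > 1 and b.size > 1:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
    else:
        t_stat, p_val = float("nan"), float("nan")
    return DurationComparison(
        ratio_pct=100.0 * float(np.mean(a) / np.mean(b)),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sem_a=_sem(a),
        sem_b=_sem(b),
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )
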