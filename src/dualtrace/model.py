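"""Top-level model object tying the analysis stages together.

``TwoChannelEventModel`` is built from two time-lapse image stacks (channel 1:
dynamin; channel 2: the activity reporter).  ``fit()`` runs detection in both
channels, links spots into candidate events, extracts paired intensity
profiles at the frozen event anchors, fits each profile with a four-Gaussian
mixture, labels the five validation criteria, and computes the peak-delay
statistics.  The returned ``TwoChannelEventResults`` carries the full event
list, tidy tables, a ``TimingSummary`` and a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import events as ev
from . import timing as tm
from .detection import ApertureOutOfBoundsError, DetectionConfig, Spot, detect_stack
from .profiles import (
    FitConfig,
    GaussianMixtureModel,
    FitError,
    baseline_shift,
    spline_upsample,
)
from .simulate import SyntheticMovie

__all__ = ["TwoChannelEventModel", "TwoChannelEventResults", "spots_to_table"]


def spots_to_table(spots_per_frame: list[list[Spot]]) -> pd.DataFrame:
    rows = [
        dict(frame=s.frame_index, x_px=s.x_px, y_px=s.y_px,
             intensity=s.integrated_intensity, background=s.local_background,
             sigma_px=s.fit_sigma_px, amplitude=s.amplitude, significant=s.significant)
        for frame in spots_per_frame
        for s in frame
    ]
    cols = ["frame", "x_px", "y_px", "intensity", "background", "sigma_px",
            "amplitude", "significant"]
    return pd.DataFrame(rows, columns=cols)


class TwoChannelEventModel:
    """Two-channel puncta event-timing model.

    Parameters
    ----------
    channel1, channel2 : (n_frames, H, W) arrays
        Dynamin and reporter stacks (identical shapes).
    frame_interval_s : acquisition interval in seconds (default 2).
    detection, linking, fit : stage configurations.
    cutoff_pct : simultaneity cutoff on the normalized delay (default 10%).
    """

    def __init__(
        self,
        channel1: np.ndarray,
        channel2: np.ndarray,
        frame_interval_s: float = 2.0,
        detection: DetectionConfig | None = None,
        linking: ev.LinkingConfig | None = None,
        fit: FitConfig | None = None,
        cutoff_pct: float = 10.0,
    ) -> None:
        channel1 = np.asarray(channel1, dtype=float)
        channel2 = np.asarray(channel2, dtype=float)
        if channel1.shape != channel2.shape or channel1.ndim != 3:
            raise ValueError("channels must be equal-shaped (n_frames, H, W) stacks")
        if frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        self.channel1 = channel1
        self.channel2 = channel2
        self.frame_interval_s = float(frame_interval_s)
        self.detection = detection or DetectionConfig()
        self.linking = linking or ev.LinkingConfig()
        self.fit_config = fit or FitConfig()
        self.cutoff_pct = float(cutoff_pct)

    @classmethod
    def from_movie(cls, movie: SyntheticMovie, **kwargs) -> "TwoChannelEventModel":
        kwargs.setdefault("frame_interval_s", movie.frame_interval_s)
        if movie.config is not None:
            kwargs.setdefault("detection", DetectionConfig(psf_sigma_px=movie.config.psf_sigma_px))
        return cls(movie.channel1, movie.channel2, **kwargs)

    @classmethod
    def from_tiff(
        cls, path_ch1, path_ch2, frame_interval_s: float = 2.0, **kwargs
    ) -> "TwoChannelEventModel":
        from .pipeline import read_movie

        return cls(
            read_movie(path_ch1), read_movie(path_ch2),
            frame_interval_s=frame_interval_s, **kwargs,
        )

    # ------------------------------------------------------------------

    def fit(self) -> "TwoChannelEventResults":
        """Run the full analysis; deterministic for given inputs."""
        spots1 = detect_stack(self.channel1, self.detection)
        spots2 = detect_stack(self.channel2, self.detection)

        candidates = ev.assemble_candidates(spots1, self.linking)
        events_ch2 = ev.assemble_candidates(spots2, self.linking)
        n_frames = self.channel1.shape[0]
        ev.mark_truncated(candidates, n_frames)
        ev.mark_truncated(events_ch2, n_frames)

        for cand in candidates:
            try:
                p1, p2 = ev.extract_profiles(
                    cand, self.channel1, self.channel2,
                    self.detection, self.linking, self.frame_interval_s,
                )
            except ApertureOutOfBoundsError as exc:
                cand.unmeasurable = True
                cand.exclusion_reason = f"unmeasurable: {exc}"
                continue
            cand.profile_ch1, cand.profile_ch2 = p1, p2
            # candidates below the duration threshold can never validate;
            # skip the mixture fit (criterion 5 then reads false, as does 2)
            if cand.frame_span < self.linking.min_duration_frames:
                cand.exclusion_reason = "not fitted: below minimum duration"
                continue
            for chan, prof in (("ch1", p1), ("ch2", p2)):
                try:
                    model = GaussianMixtureModel(
                        spline_upsample(baseline_shift(prof), self.fit_config.upsample_factor),
                        self.fit_config,
                    )
                    setattr(cand, f"fit_{chan}", model.fit())
                except FitError as exc:
                    cand.exclusion_reason = f"fit failed ({chan}): {exc}"

        measurable = [c for c in candidates if not c.unmeasurable]
        for cand in measurable:
            ev.label_criteria(cand, measurable, self.linking)

        timings: list[tm.EventTiming] = []
        for cand in measurable:
            if not cand.valid or cand.truncated:
                continue
            try:
                timings.append(
                    tm.compute_timing(
                        cand.event_id, cand.fit_ch1, cand.fit_ch2,
                        self.frame_interval_s, self.cutoff_pct,
                    )
                )
            except ValueError as exc:
                cand.exclusion_reason = f"timing excluded: {exc}"

        return TwoChannelEventResults(
            model=self,
            spots_ch1=spots1,
            spots_ch2=spots2,
            events=candidates,
            events_ch2=events_ch2,
            timings=tuple(timings),
        )


@dataclass(frozen=True)
class TwoChannelEventResults:
    model: TwoChannelEventModel
    spots_ch1: list[list[Spot]]
    spots_ch2: list[list[Spot]]
    events: list[ev.CandidateEvent]
    events_ch2: list[ev.CandidateEvent]
    timings: tuple[tm.EventTiming, ...]

    # -- tables ---------------------------------------------------------

    @property
    def event_table(self) -> pd.DataFrame:
        rows = []
        for c in self.events:
            flags = c.criteria.as_tuple() if c.criteria else (None,) * 5
            rows.append(
                dict(
                    event_id=c.event_id, x_px=c.x_px, y_px=c.y_px,
                    first_frame=c.first_frame, last_frame=c.last_frame,
                    n_spots=len(c.spots_by_frame),
                    flag_spatial=flags[0], flag_duration=flags[1],
                    flag_intensity=flags[2], flag_correlation=flags[3],
                    flag_gof=flags[4], valid=c.valid, truncated=c.truncated,
                    unmeasurable=c.unmeasurable, override_valid=c.override_valid,
                    gof_ch1=c.fit_ch1.gof if c.fit_ch1 else np.nan,
                    gof_ch2=c.fit_ch2.gof if c.fit_ch2 else np.nan,
                )
            )
        cols = ["event_id", "x_px", "y_px", "first_frame", "last_frame", "n_spots",
                "flag_spatial", "flag_duration", "flag_intensity", "flag_correlation",
                "flag_gof", "valid", "truncated", "unmeasurable", "override_valid",
                "gof_ch1", "gof_ch2"]
        return pd.DataFrame(rows, columns=cols)

    @property
    def timing_table(self) -> pd.DataFrame:
        rows = [
            dict(
                event_id=t.event_id,
                t_dynamin_s=t.t_dynamin, t_dynab_s=t.t_dynab,
                delta_t_s=t.delta_t, delta_t_frames=t.delta_t_frames,
                delta_t_frames_q=t.delta_t_frames_quantized,
                d_dynamin_s=t.d_dynamin, d_dynab_s=t.d_dynab,
                delta_t_norm_pct=t.delta_t_norm, timing_class=t.timing_class,
                p_dynamin=t.p_dynamin, p_dynab=t.p_dynab,
                double_dynab=t.double_dynab, double_dynamin=t.double_dynamin,
            )
            for t in self.timings
        ]
        cols = ["event_id", "t_dynamin_s", "t_dynab_s", "delta_t_s", "delta_t_frames",
                "delta_t_frames_q", "d_dynamin_s", "d_dynab_s", "delta_t_norm_pct",
                "timing_class", "p_dynamin", "p_dynab", "double_dynab", "double_dynamin"]
        return pd.DataFrame(rows, columns=cols)

    # -- statistics -----------------------------------------------------

    @property
    def n_validated(self) -> int:
        return sum(c.valid for c in self.events)

    @property
    def timing_summary(self) -> tm.TimingSummary | None:
        return tm.summarize(list(self.timings)) if self.timings else None

    def curve_average(self, **kwargs) -> pd.DataFrame:
        fits = [
            (c.fit_ch1, c.fit_ch2)
            for c in self.events
            if c.valid and not c.truncated and c.fit_ch1 and c.fit_ch2
        ]
        return tm.curve_average(fits, **kwargs)

    def colocalization(self, radius_px: float = 3.0, min_overlap_frames: int = 3) -> float:
        """Fraction of channel-1 events colocalized with a channel-2 event."""
        a = [c for c in self.events if c.valid]
        return ev.colocalization_fraction(a, self.events_ch2, radius_px, min_overlap_frames)

    def summary(self) -> str:
        lines = [
            "Two-channel event-timing analysis",
            "=" * 48,
            f"Frames: {self.model.channel1.shape[0]}   "
            f"frame interval: {self.model.frame_interval_s} s   "
            f"image: {self.model.channel1.shape[1]}x{self.model.channel1.shape[2]} px",
            f"Candidate events (ch1-anchored): {len(self.events)}",
            f"Validated events:                {self.n_validated}",
            f"Events entering timing:          {len(self.timings)}",
        ]
        ts = self.timing_summary
        if ts is not None:
            lines += ["-" * 48, ts.summary()]
        return "\n".join(lines)

    # -- plots ----------------------------------------------------------

    def plot_delta_t_histogram(self, ax=None):
        """Bar plot of the normalized-delay histogram (5% clusters)."""
        import matplotlib.pyplot as plt

        ts = self.timing_summary
        if ts is None:
            raise ValueError("no timing data to plot")
        if ax is None:
            _, ax = plt.subplots()
        h = ts.histogram
        ax.bar(h["bin_low"], h["count"], width=h["bin_high"] - h["bin_low"],
               align="edge", edgecolor="black")
        ax.set_xlabel(r"$\Delta t$ (% of dynamin duration)")
        ax.set_ylabel("events")
        return ax

    def plot_curve_average(self, ax=None, **kwargs):
        """Mean fitted curves (both channels) relative to the dynamin peak."""
        import matplotlib.pyplot as plt

        curves = self.curve_average(**kwargs)
        if ax is None:
            _, ax = plt.subplots()
        for ch, color in (("ch1", "tab:red"), ("ch2", "tab:green")):
            m, s = curves[f"mean_{ch}"], curves[f"sem_{ch}"]
            ax.plot(curves["rel_time_s"], m, color=color, label=ch)
            if np.isfinite(s).all():
                ax.fill_between(curves["rel_time_s"], m - s, m + s, color=color, alpha=0.3)
        ax.set_xlabel("time relative to dynamin peak (s)")
        ax.set_ylabel("normalized intensity")
        ax.legend()
        return ax
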