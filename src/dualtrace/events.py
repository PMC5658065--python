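"""Temporal linking of spots into candidate events and event validation.

A candidate event is a sequence of spots at a quasi-stationary position over
consecutive frames, tolerating up to two consecutive missing frames.  Each
candidate is labelled with five validation criteria:

1. spatial   — consecutive spot displacements stay within the link radius;
2. duration  — the event spans at least ``min_duration_frames`` frames
               (default 10);
3. intensity — the event's raw peak intensity reaches at least 40% of the
               highest event peak in the whole sequence (same channel);
4. correlation — Pearson correlation between the two channels' raw intensity
               profiles exceeds 0.45 (strict);
5. gof       — both channels' Gaussian-mixture fits reach a goodness of fit
               above 0.6.

No candidate is discarded on criterion failure: every candidate is retained
with its flags so the final decision stays with the user; ``valid`` is simply
the conjunction of the five flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr

from .detection import ApertureOutOfBoundsError, DetectionConfig, Spot, measure_intensity
from .profiles import GaussianMixtureResults, IntensityProfile

__all__ = [
    "LinkingConfig",
    "CriteriaFlags",
    "CandidateEvent",
    "assemble_candidates",
    "extract_profiles",
    "label_criteria",
    "apply_review_overrides",
    "colocalization_fraction",
    "UndefinedFractionError",
]


class UndefinedFractionError(ValueError):
    """Raised when a colocalization fraction is 0/0."""


@dataclass(frozen=True)
class LinkingConfig:
    link_radius_px: float = 2.0
    max_gap_frames: int = 2
    min_duration_frames: int = 10
    intensity_fraction_threshold: float = 0.40
    correlation_threshold: float = 0.45
    gof_threshold: float = 0.6
    profile_margin_frames: int = 10

    def __post_init__(self) -> None:
        if self.link_radius_px <= 0:
            raise ValueError("link_radius_px must be > 0")
        if self.max_gap_frames < 0 or self.min_duration_frames < 1:
            raise ValueError("invalid gap / duration settings")
        for v in (self.intensity_fraction_threshold, self.correlation_threshold):
            if not 0 <= v <= 1:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.profile_margin_frames < 0:
            raise ValueError("profile_margin_frames must be >= 0")


@dataclass(frozen=True)
class CriteriaFlags:
    spatial: bool
    duration: bool
    intensity: bool
    correlation: bool
    gof: bool

    @property
    def all_pass(self) -> bool:
        return self.spatial and self.duration and self.intensity and self.correlation and self.gof

    def as_tuple(self) -> tuple[bool, bool, bool, bool, bool]:
        return (self.spatial, self.duration, self.intensity, self.correlation, self.gof)


@dataclass
class CandidateEvent:
    event_id: int
    spots_by_frame: dict[int, Spot]
    x_px: float = field(init=False)
    y_px: float = field(init=False)
    profile_ch1: IntensityProfile | None = None
    profile_ch2: IntensityProfile | None = None
    fit_ch1: GaussianMixtureResults | None = None
    fit_ch2: GaussianMixtureResults | None = None
    criteria: CriteriaFlags | None = None
    truncated: bool = False
    unmeasurable: bool = False
    exclusion_reason: str | None = None
    override_valid: bool | None = None  # reviewer decision, wins over flags

    def __post_init__(self) -> None:
        if not self.spots_by_frame:
            raise ValueError("a candidate needs at least one spot")
        frames = sorted(self.spots_by_frame)
        gaps = np.diff(frames)
        if gaps.size and int(gaps.max()) > 3:
            raise ValueError("internal gap of more than 2 consecutive missing frames")
        # anchor: intensity-weighted mean spot position (weights floored at 0)
        wsum = x = y = 0.0
        for s in self.spots_by_frame.values():
            wgt = max(s.integrated_intensity, 0.0)
            wsum += wgt
            x += wgt * s.x_px
            y += wgt * s.y_px
        if wsum <= 0:
            xs = [s.x_px for s in self.spots_by_frame.values()]
            ys = [s.y_px for s in self.spots_by_frame.values()]
            self.x_px, self.y_px = float(np.mean(xs)), float(np.mean(ys))
        else:
            self.x_px, self.y_px = x / wsum, y / wsum

    @property
    def first_frame(self) -> int:
        return min(self.spots_by_frame)

    @property
    def last_frame(self) -> int:
        return max(self.spots_by_frame)

    @property
    def frame_span(self) -> int:
        return self.last_frame - self.first_frame + 1

    @property
    def missing_frames(self) -> tuple[int, ...]:
        return tuple(
            f for f in range(self.first_frame, self.last_frame + 1) if f not in self.spots_by_frame
        )

    @property
    def valid(self) -> bool:
        if self.override_valid is not None:
            return self.override_valid
        return self.criteria is not None and self.criteria.all_pass


def apply_review_overrides(
    events: Sequence["CandidateEvent"], overrides: dict[int, bool]
) -> None:
    """Apply reviewer decisions (event_id -> keep) on top of the automatic
    flags; events absent from ``overrides`` keep their automatic validity."""
    for ev in events:
        if ev.event_id in overrides:
            ev.override_valid = bool(overrides[ev.event_id])


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------


@dataclass
class _OpenTrack:
    spots: dict[int, Spot]
    wsum: float
    wx: float
    wy: float

    @property
    def anchor(self) -> tuple[float, float]:
        if self.wsum <= 0:
            xs = [s.x_px for s in self.spots.values()]
            ys = [s.y_px for s in self.spots.values()]
            return float(np.mean(xs)), float(np.mean(ys))
        return self.wx / self.wsum, self.wy / self.wsum

    @property
    def last_frame(self) -> int:
        return max(self.spots)

    def add(self, frame: int, spot: Spot) -> None:
        self.spots[frame] = spot
        wgt = max(spot.integrated_intensity, 0.0)
        self.wsum += wgt
        self.wx += wgt * spot.x_px
        self.wy += wgt * spot.y_px


def assemble_candidates(
    spots_per_frame: Sequence[Sequence[Spot]], cfg: LinkingConfig
) -> list[CandidateEvent]:
    """Greedy nearest-anchor temporal linking with gap closing.

    A spot extends an open candidate iff its distance to the candidate's
    running intensity-weighted anchor is at most ``link_radius_px`` and the
    candidate's trailing gap does not exceed ``max_gap_frames`` missing
    frames; otherwise it seeds a new candidate.  A candidate is closed once
    three or more consecutive frames pass without a matched spot.  Spots are
    processed in descending intensity within each frame; each spot joins at
    most one candidate and each candidate gains at most one spot per frame.
    """
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    for frame, spots in enumerate(spots_per_frame):
        still_open: list[_OpenTrack] = []
        for tr in open_tracks:
            # a gap of max_gap missing frames means the next spot may appear
            # at last_frame + max_gap + 1
            if frame - tr.last_frame > cfg.max_gap_frames + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        matched: set[int] = set()
        for spot in sorted(spots, key=lambda s: -s.integrated_intensity):
            best_i, best_d = -1, math.inf
            for i, tr in enumerate(open_tracks):
                if i in matched or frame <= tr.last_frame:
                    continue
                ax, ay = tr.anchor
                d = math.hypot(spot.x_px - ax, spot.y_px - ay)
                if d <= cfg.link_radius_px and d < best_d:
                    best_i, best_d = i, d
            if best_i >= 0:
                open_tracks[best_i].add(frame, spot)
                matched.add(best_i)
            else:
                tr = _OpenTrack({}, 0.0, 0.0, 0.0)
                tr.add(frame, spot)
                open_tracks.append(tr)
                matched.add(len(open_tracks) - 1)
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (min(tr.spots), tr.anchor[1], tr.anchor[0]))
    return [CandidateEvent(event_id=i, spots_by_frame=dict(sorted(tr.spots.items())))
            for i, tr in enumerate(closed)]


def mark_truncated(events: list[CandidateEvent], n_frames: int) -> None:
    """Flag events touching the first or last movie frame (excluded from
    timing statistics by default)."""
    for ev in events:
        ev.truncated = ev.first_frame == 0 or ev.last_frame == n_frames - 1


# ---------------------------------------------------------------------------
# Profile extraction
# ---------------------------------------------------------------------------


def extract_profiles(
    event: CandidateEvent,
    movie_ch1: np.ndarray,
    movie_ch2: np.ndarray,
    det_cfg: DetectionConfig,
    cfg: LinkingConfig,
    frame_interval_s: float,
) -> tuple[IntensityProfile, IntensityProfile]:
    """Measure both channels at the frozen event anchor over the event span
    plus a margin.  Missing frames inside the span are measured identically
    (the anchor persists).  Raises ApertureOutOfBoundsError when the anchor
    sits too close to the border; callers flag the event unmeasurable."""
    n_frames = movie_ch1.shape[0]
    f0 = max(0, event.first_frame - cfg.profile_margin_frames)
    f1 = min(n_frames - 1, event.last_frame + cfg.profile_margin_frames)
    frames = np.arange(f0, f1 + 1)
    vals1 = np.empty(frames.size)
    vals2 = np.empty(frames.size)
    for i, f in enumerate(frames):
        vals1[i], _ = measure_intensity(movie_ch1[f], event.x_px, event.y_px, det_cfg)
        vals2[i], _ = measure_intensity(movie_ch2[f], event.x_px, event.y_px, det_cfg)
    times = frames * frame_interval_s
    missing = tuple(int(f) for f in frames if f not in event.spots_by_frame)
    p1 = IntensityProfile(times, vals1, frame_interval_s, missing)
    p2 = IntensityProfile(times, vals2, frame_interval_s, missing)
    return p1, p2


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------


def _raw_peak(profile: IntensityProfile | None) -> float:
    if profile is None or profile.values.size == 0:
        return -math.inf
    return float(np.max(profile.values))


def sequence_peak_maxima(events: Sequence[CandidateEvent]) -> tuple[float, float]:
    """Per-channel maximum raw profile peak over all candidate events."""
    m1 = max((_raw_peak(ev.profile_ch1) for ev in events), default=-math.inf)
    m2 = max((_raw_peak(ev.profile_ch2) for ev in events), default=-math.inf)
    return m1, m2


def label_criteria(
    event: CandidateEvent,
    all_events: Sequence[CandidateEvent],
    cfg: LinkingConfig,
) -> CandidateEvent:
    """Set the five criteria flags on ``event`` (returned for chaining).

    The intensity criterion (3) compares the raw profile peak against the
    per-sequence maximum in the same channel, inclusively at the threshold;
    both channels must pass.  The correlation criterion (4) is strict
    (r must exceed the threshold) and fails on zero-variance profiles.  The
    goodness-of-fit criterion (5) requires converged fits with a principal
    component in both channels.
    """
    frames = sorted(event.spots_by_frame)
    spatial = True
    for fa, fb in zip(frames, frames[1:]):
        sa, sb = event.spots_by_frame[fa], event.spots_by_frame[fb]
        if math.hypot(sb.x_px - sa.x_px, sb.y_px - sa.y_px) > cfg.link_radius_px:
            spatial = False
            break

    duration = event.frame_span >= cfg.min_duration_frames

    max1, max2 = sequence_peak_maxima(all_events)
    intensity = (
        _raw_peak(event.profile_ch1) >= cfg.intensity_fraction_threshold * max1
        and _raw_peak(event.profile_ch2) >= cfg.intensity_fraction_threshold * max2
    )

    correlation = False
    if event.profile_ch1 is not None and event.profile_ch2 is not None:
        v1, v2 = event.profile_ch1.values, event.profile_ch2.values
        # exact-constant check: round-off can leave np.std of a constant
        # array slightly positive while the correlation is still undefined
        if v1.size >= 2 and not np.all(v1 == v1[0]) and not np.all(v2 == v2[0]):
            r = float(pearsonr(v1, v2).statistic)
            correlation = r > cfg.correlation_threshold

    gof = (
        event.fit_ch1 is not None
        and event.fit_ch2 is not None
        and event.fit_ch1.converged
        and event.fit_ch2.converged
        and len(event.fit_ch1.principal) >= 1
        and len(event.fit_ch2.principal) >= 1
        and event.fit_ch1.gof > cfg.gof_threshold
        and event.fit_ch2.gof > cfg.gof_threshold
    )

    event.criteria = CriteriaFlags(spatial, duration, intensity, correlation, bool(gof))
    return event


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------


def _temporal_overlap(a: CandidateEvent, b: CandidateEvent) -> int:
    return min(a.last_frame, b.last_frame) - max(a.first_frame, b.first_frame) + 1


def colocalization_fraction(
    events_a: Sequence[CandidateEvent],
    events_b: Sequence[CandidateEvent],
    radius_px: float = 3.0,
    min_overlap_frames: int = 3,
) -> float:
    """Fraction of A events having a B event within ``radius_px`` whose frame
    span overlaps by at least ``min_overlap_frames`` frames."""
    if not events_a:
        raise UndefinedFractionError("colocalization of an empty event list is undefined")
    hits = 0
    for a in events_a:
        for b in events_b:
            if (
                math.hypot(a.x_px - b.x_px, a.y_px - b.y_px) <= radius_px
                and _temporal_overlap(a, b) >= min_overlap_frames
            ):
                hits += 1
                break
    return hits / len(events_a)
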