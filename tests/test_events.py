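"""Temporal linking, criteria labelling and colocalization."""

import math

import numpy as np
import pytest
from scipy.stats import pearsonr

from dualtrace.detection import DetectionConfig, Spot
from dualtrace.events import (
    CandidateEvent,
    CriteriaFlags,
    LinkingConfig,
    UndefinedFractionError,
    assemble_candidates,
    colocalization_fraction,
    extract_profiles,
    label_criteria,
)
from dualtrace.profiles import IntensityProfile

CFG = LinkingConfig()


def spot(frame, x, y, intensity=100.0):
    return Spot(frame, x, y, intensity, 10.0, 1.5, intensity / 10, True)


def frames_with_spot_at(frames, x=10.0, y=10.0, n_frames=30):
    per_frame = [[] for _ in range(n_frames)]
    for f in frames:
        per_frame[f].append(spot(f, x, y))
    return per_frame


class TestAssembleCandidates:
    def test_contiguous_spots_form_one_candidate(self):
        cands = assemble_candidates(frames_with_spot_at(range(12)), CFG)
        assert len(cands) == 1
        assert cands[0].frame_span == 12

    def test_three_missing_frames_split_into_two_candidates(self):
        frames = list(range(8)) + list(range(11, 21))
        cands = assemble_candidates(frames_with_spot_at(frames), CFG)
        assert len(cands) == 2
        assert (cands[0].first_frame, cands[0].last_frame) == (0, 7)
        assert (cands[1].first_frame, cands[1].last_frame) == (11, 20)

    def test_two_missing_frames_tolerated(self):
        frames = list(range(10)) + list(range(12, 21))
        cands = assemble_candidates(frames_with_spot_at(frames), CFG)
        assert len(cands) == 1
        assert (cands[0].first_frame, cands[0].last_frame) == (0, 20)
        assert cands[0].missing_frames == (10, 11)

    def test_distant_spots_seed_separate_candidates(self):
        per_frame = [[] for _ in range(15)]
        for f in range(12):
            per_frame[f].extend([spot(f, 10.0, 10.0), spot(f, 30.0, 30.0)])
        cands = assemble_candidates(per_frame, CFG)
        assert len(cands) == 2

    def test_no_two_candidates_share_a_spot(self):
        rng = np.random.default_rng(0)
        per_frame = []
        for f in range(40):
            per_frame.append(
                [spot(f, rng.uniform(5, 45), rng.uniform(5, 45), rng.uniform(10, 200))
                 for _ in range(rng.integers(0, 4))]
            )
        cands = assemble_candidates(per_frame, CFG)
        seen = set()
        for c in cands:
            for f, s in c.spots_by_frame.items():
                key = (f, s.x_px, s.y_px)
                assert key not in seen
                seen.add(key)
        n_spots = sum(len(fr) for fr in per_frame)
        assert len(seen) == n_spots  # union of assignments covers the input

    def test_gap_invariant_holds_for_every_candidate(self):
        rng = np.random.default_rng(1)
        per_frame = [
            [spot(f, 10 + rng.normal(0, 0.3), 10 + rng.normal(0, 0.3))]
            if rng.random() > 0.3 else []
            for f in range(60)
        ]
        for c in assemble_candidates(per_frame, CFG):
            frames = sorted(c.spots_by_frame)
            assert max(np.diff(frames), default=1) <= CFG.max_gap_frames + 1

    def test_empty_input_gives_empty_list(self):
        assert assemble_candidates([], CFG) == []
        assert assemble_candidates([[], [], []], CFG) == []


def make_event(values1, values2, event_id=0, frames=None, dt=2.0):
    n = len(values1)
    frames = frames if frames is not None else range(n)
    spots = {f: spot(f, 10.0, 10.0, float(v)) for f, v in zip(frames, values1)}
    ev = CandidateEvent(event_id=event_id, spots_by_frame=spots)
    t = np.array(sorted(spots)) * dt
    ev.profile_ch1 = IntensityProfile(t, np.asarray(values1, float), dt)
    ev.profile_ch2 = IntensityProfile(t, np.asarray(values2, float), dt)
    return ev


class TestLabelCriteria:
    def test_correlation_exactly_at_threshold_fails(self):
        """The correlation criterion is strict: r equal to the threshold
        does not pass, r above it does."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        b = b - (a @ b / 12) * a  # orthogonalize
        b = b / b.std()
        v2 = 0.45 * a + math.sqrt(1 - 0.45**2) * b
        ev = make_event(a + 5, v2 + 5)
        r = pearsonr(ev.profile_ch1.values, ev.profile_ch2.values).statistic
        assert r == pytest.approx(0.45, abs=1e-9)
        # threshold set to the measured r exactly: strict '>' must fail
        label_criteria(ev, [ev], LinkingConfig(correlation_threshold=r))
        assert not ev.criteria.correlation
        label_criteria(ev, [ev], LinkingConfig(correlation_threshold=r - 1e-12))
        assert ev.criteria.correlation

    def test_intensity_exactly_at_forty_percent_passes(self):
        big = make_event([0, 1000.0, 0] * 4, [0, 1000.0, 0] * 4, event_id=0)
        small = make_event([0, 400.0, 0] * 4, [0, 400.0, 0] * 4, event_id=1)
        label_criteria(small, [big, small], CFG)
        assert small.criteria.intensity

    def test_intensity_below_forty_percent_fails(self):
        big = make_event([0, 1000.0, 0] * 4, [0, 1000.0, 0] * 4, event_id=0)
        small = make_event([0, 399.9, 0] * 4, [0, 399.9, 0] * 4, event_id=1)
        label_criteria(small, [big, small], CFG)
        assert not small.criteria.intensity

    def test_zero_variance_profile_fails_correlation(self):
        ev = make_event([5.0] * 12, [1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1, 0])
        label_criteria(ev, [ev], CFG)
        assert not ev.criteria.correlation

    def test_duration_criterion_uses_frame_span(self):
        short = make_event(list(range(9)), list(range(9)))
        label_criteria(short, [short], CFG)
        assert not short.criteria.duration
        exact = make_event(list(range(10)), list(range(10)))
        label_criteria(exact, [exact], CFG)
        assert exact.criteria.duration

    def test_valid_is_conjunction_of_flags(self):
        ev = make_event(list(range(12)), list(range(12)))
        ev.criteria = CriteriaFlags(True, True, True, True, True)
        assert ev.valid
        ev.criteria = CriteriaFlags(True, True, True, True, False)
        assert not ev.valid

    def test_order_independence_of_labels(self):
        """Criterion 3 depends only on the per-sequence maximum, so any
        permutation of the context list yields identical flags."""
        rng = np.random.default_rng(3)
        evs = [
            make_event(rng.uniform(0, 900, 12), rng.uniform(0, 900, 12), event_id=i)
            for i in range(6)
        ]
        flags_fwd = [label_criteria(e, evs, CFG).criteria for e in evs]
        flags_rev = [label_criteria(e, evs[::-1], CFG).criteria for e in evs]
        assert flags_fwd == flags_rev


class TestExtractProfiles:
    def test_margin_zero_profile_length_equals_span(self):
        movie = np.full((30, 40, 40), 10.0)
        cfg = LinkingConfig(profile_margin_frames=0)
        spots = {f: spot(f, 20.0, 20.0) for f in range(5, 17)}
        ev = CandidateEvent(event_id=0, spots_by_frame=spots)
        p1, p2 = extract_profiles(ev, movie, movie, DetectionConfig(), cfg, 2.0)
        assert p1.times.size == ev.frame_span
        assert p1.times[0] == 5 * 2.0

    def test_profile_matches_planted_temporal_gaussian(self):
        n, A, sig_t = 40, 100.0, 3.0
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        spatial = np.exp(-(((xx - 20) ** 2 + (yy - 20) ** 2) / (2 * 1.5**2)))
        t = np.arange(n)
        movie = 10.0 + A * np.exp(-((t - 20.0) ** 2) / (2 * sig_t**2))[:, None, None] * spatial
        spots = {f: spot(f, 20.0, 20.0) for f in range(14, 27)}
        ev = CandidateEvent(event_id=0, spots_by_frame=spots)
        p1, _ = extract_profiles(ev, movie, movie, DetectionConfig(), LinkingConfig(), 2.0)
        peak = p1.values.max()
        assert peak == pytest.approx(2 * math.pi * A * 1.5**2, rel=0.05)

    def test_border_anchor_signalled(self):
        movie = np.full((30, 40, 40), 10.0)
        spots = {f: spot(f, 2.0, 20.0) for f in range(12)}
        ev = CandidateEvent(event_id=0, spots_by_frame=spots)
        from dualtrace.detection import ApertureOutOfBoundsError

        with pytest.raises(ApertureOutOfBoundsError):
            extract_profiles(ev, movie, movie, DetectionConfig(), LinkingConfig(), 2.0)


class TestColocalization:
    def _events(self, positions, first=0, last=12):
        out = []
        for i, (x, y) in enumerate(positions):
            spots = {f: spot(f, x, y) for f in range(first, last)}
            out.append(CandidateEvent(event_id=i, spots_by_frame=spots))
        return out

    def test_self_colocalization_is_one(self):
        a = self._events([(10, 10), (30, 30)])
        assert colocalization_fraction(a, a) == 1.0

    def test_empty_b_gives_zero(self):
        a = self._events([(10, 10)])
        assert colocalization_fraction(a, []) == 0.0

    def test_empty_a_is_undefined(self):
        with pytest.raises(UndefinedFractionError):
            colocalization_fraction([], self._events([(10, 10)]))

    def test_known_fraction_recovered(self):
        # 10x10 grid, 8 px pitch: all pairs separated by > 2x the radius
        pos = [(10.0 + 8 * i, 10.0 + 8 * j) for i in range(10) for j in range(10)]
        a = self._events(pos)
        b = self._events(pos[:80])  # 80 of 100 paired
        assert colocalization_fraction(a, b) == pytest.approx(0.80, abs=1e-12)

    def test_temporal_overlap_required(self):
        a = self._events([(10, 10)], first=0, last=10)
        b = self._events([(10, 10)], first=20, last=30)
        assert colocalization_fraction(a, b, min_overlap_frames=3) == 0.0


class TestReviewOverrides:
    def test_override_wins_over_flags(self):
        from dualtrace.events import apply_review_overrides

        good = make_event(list(range(12)), list(range(12)), event_id=0)
        good.criteria = CriteriaFlags(True, True, True, True, True)
        bad = make_event(list(range(12)), list(range(12)), event_id=1)
        bad.criteria = CriteriaFlags(True, True, True, True, False)
        apply_review_overrides([good, bad], {0: False, 1: True})
        assert not good.valid
        assert bad.valid
        good.override_valid = None  # clearing restores automatic validity
        assert good.valid
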