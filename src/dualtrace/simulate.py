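"""Synthetic two-channel TIRF-like movies with planted ground truth.

The generator renders diffraction-limited, quasi-stationary punctae whose
per-event intensity follows a temporal Gaussian, paired with a second channel
whose peak is shifted by a configurable offset distribution.  It emulates the
data regime of dual-colour endocytosis imaging (dynamin + activity reporter at
clathrin-coated pits, 2 s/frame TIRF sequences) so that every downstream stage
of the analysis can be validated against known truth at desk scale.

Signal model for one event, channel c::

    I_c(x, y, t) = sum_k  a_ck * exp(-(t - t_ck)^2 / (2 s_ck^2))
                        * exp(-((x - x0)^2 + (y - y0)^2) / (2 psf_sigma^2))

Noise model: Poisson(signal + background) followed by additive zero-mean
Gaussian camera noise, clipped at zero.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "PointOffset",
    "GaussianMixtureOffset",
    "CategoricalOffset",
    "SimulationConfig",
    "GroundTruthEvent",
    "SyntheticMovie",
    "OvercrowdedError",
    "generate_movie",
    "render_noiseless_event",
    "ground_truth_table",
    "save_movie",
    "load_simulation_config",
]


class OvercrowdedError(RuntimeError):
    """Raised when events cannot be placed at the requested minimum separation."""


# ---------------------------------------------------------------------------
# Channel-2 peak-offset distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointOffset:
    """Every channel-2 peak is shifted by exactly ``offset_frames``."""

    offset_frames: float = 0.0

    def sample(self, rng: np.random.Generator, duration_frames: float) -> float:
        return float(self.offset_frames)


@dataclass(frozen=True)
class GaussianMixtureOffset:
    """Offset in frames drawn from a Gaussian mixture."""

    means_frames: tuple[float, ...] = (0.0,)
    sds_frames: tuple[float, ...] = (1.0,)
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not (len(self.means_frames) == len(self.sds_frames) == len(self.weights)):
            raise ValueError("means, sds and weights must have equal length")
        if any(s < 0 for s in self.sds_frames):
            raise ValueError("sds must be >= 0")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and sum > 0")

    def sample(self, rng: np.random.Generator, duration_frames: float) -> float:
        w = np.asarray(self.weights, dtype=float)
        k = rng.choice(len(w), p=w / w.sum())
        return float(rng.normal(self.means_frames[k], self.sds_frames[k]))


@dataclass(frozen=True)
class CategoricalOffset:
    """Offset drawn by class (before / simultaneous / after).

    The per-class ranges are expressed as a percentage of the channel-1 event
    duration d = 4*sigma, matching how peak delays are normalized downstream.
    Negative offsets mean the channel-2 peak precedes channel 1.
    """

    p_before: float = 0.29
    p_simultaneous: float = 0.47
    p_after: float = 0.24
    before_range_pct: tuple[float, float] = (-35.0, -12.0)
    simultaneous_range_pct: tuple[float, float] = (-8.0, 8.0)
    after_range_pct: tuple[float, float] = (12.0, 35.0)

    def __post_init__(self) -> None:
        p = (self.p_before, self.p_simultaneous, self.p_after)
        if any(x < 0 for x in p):
            raise ValueError("class probabilities must be >= 0")
        if not math.isclose(sum(p), 1.0, abs_tol=1e-9):
            raise ValueError("class probabilities must sum to 1")
        for lo, hi in (self.before_range_pct, self.simultaneous_range_pct, self.after_range_pct):
            if hi < lo:
                raise ValueError("range max must be >= min")

    def sample_class(self, rng: np.random.Generator) -> str:
        u = rng.random()
        if u < self.p_before:
            return "before"
        if u < self.p_before + self.p_simultaneous:
            return "simultaneous"
        return "after"

    def sample(self, rng: np.random.Generator, duration_frames: float) -> float:
        cls = self.sample_class(rng)
        rng_pct = {
            "before": self.before_range_pct,
            "simultaneous": self.simultaneous_range_pct,
            "after": self.after_range_pct,
        }[cls]
        pct = rng.uniform(*rng_pct) if rng_pct[0] < rng_pct[1] else rng_pct[0]
        return float(pct / 100.0 * duration_frames)


def _offset_spec_from_dict(d: dict) -> PointOffset | GaussianMixtureOffset | CategoricalOffset:
    kind = d.get("kind")
    params = {k: v for k, v in d.items() if k != "kind"}
    # YAML gives lists; the dataclasses expect tuples
    params = {k: tuple(v) if isinstance(v, list) else v for k, v in params.items()}
    if kind == "point":
        return PointOffset(**params)
    if kind == "gaussian_mixture":
        return GaussianMixtureOffset(**params)
    if kind == "categorical":
        return CategoricalOffset(**params)
    raise ValueError(f"unknown delta_t_spec kind: {kind!r}")


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemporalPeak:
    """One temporal Gaussian component of an event in one channel."""

    amplitude: float
    peak_time_frames: float
    sigma_frames: float


@dataclass(frozen=True)
class GroundTruthEvent:
    """A planted event: true position, amplitudes, peak times and widths."""

    event_id: int
    x_px: float
    y_px: float
    ch1: TemporalPeak
    ch2_peaks: tuple[TemporalPeak, ...]

    def __post_init__(self) -> None:
        if self.ch1.sigma_frames <= 0:
            raise ValueError("temporal sigma must be > 0")
        if not 1 <= len(self.ch2_peaks) <= 2:
            raise ValueError("channel 2 must carry one or two peaks")

    @property
    def n_channel2_peaks(self) -> int:
        return len(self.ch2_peaks)

    @property
    def primary_ch2(self) -> TemporalPeak:
        """Highest-amplitude channel-2 peak (the one entering peak-delay truth)."""
        return max(self.ch2_peaks, key=lambda p: p.amplitude)

    @property
    def delta_t_frames(self) -> float:
        return self.primary_ch2.peak_time_frames - self.ch1.peak_time_frames

    @property
    def duration_ch1_frames(self) -> float:
        return 4.0 * self.ch1.sigma_frames


@dataclass(frozen=True)
class SimulationConfig:
    image_height_px: int = 64
    image_width_px: int = 64
    n_frames: int = 150
    frame_interval_s: float = 2.0
    psf_sigma_px: float = 1.5
    n_events: int = 30
    amplitude_range: tuple[float, float] = (300.0, 600.0)
    channel2_amplitude_scale: float = 0.8
    channel2_sigma_scale: float = 0.75
    temporal_sigma_range_frames: tuple[float, float] = (2.0, 5.0)
    delta_t_spec: PointOffset | GaussianMixtureOffset | CategoricalOffset = field(
        default_factory=CategoricalOffset
    )
    double_peak_fraction: float = 0.0
    double_peak_amplitude_ratio: float = 0.8
    background_level: float = 20.0
    camera_noise_sd: float = 2.0
    min_event_separation_px: float = 9.0
    position_jitter_sd_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0 or self.n_frames <= 0:
            raise ValueError("image dimensions and frame count must be positive")
        if self.frame_interval_s <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("frame_interval_s and psf_sigma_px must be > 0")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        lo, hi = self.amplitude_range
        if not (0 < lo <= hi):
            raise ValueError("amplitude_range must satisfy 0 < min <= max")
        slo, shi = self.temporal_sigma_range_frames
        if not (0 < slo <= shi):
            raise ValueError("temporal_sigma_range_frames must satisfy 0 < min <= max")
        if self.channel2_amplitude_scale <= 0 or self.channel2_sigma_scale <= 0:
            raise ValueError("channel-2 scales must be > 0")
        if not 0.0 <= self.double_peak_fraction <= 1.0:
            raise ValueError("double_peak_fraction must lie in [0, 1]")
        if self.background_level < 0 or self.camera_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.min_event_separation_px < 0 or self.position_jitter_sd_px < 0:
            raise ValueError("distances must be >= 0")

    @property
    def edge_margin_px(self) -> float:
        """Events are kept this far from the image border so the measurement
        aperture of the default detection configuration always fits."""
        return math.ceil(4.0 * self.psf_sigma_px) + 1


@dataclass(frozen=True)
class SyntheticMovie:
    channel1: np.ndarray
    channel2: np.ndarray
    frame_interval_s: float
    ground_truth: tuple[GroundTruthEvent, ...]
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.channel1.shape != self.channel2.shape:
            raise ValueError("channel stacks must have identical shapes")
        if np.any(self.channel1 < 0) or np.any(self.channel2 < 0):
            raise ValueError("pixel values must be >= 0")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _render_peaks(
    peaks: Sequence[TemporalPeak],
    x: float,
    y: float,
    config: SimulationConfig,
    jitter: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless additive contribution of one event's peaks in one channel."""
    h, w, n = config.image_height_px, config.image_width_px, config.n_frames
    stack = np.zeros((n, h, w), dtype=float)
    t = np.arange(n, dtype=float)
    s2 = 2.0 * config.psf_sigma_px**2
    # restrict to a local window; the Gaussian is negligible beyond 6 sigma
    r = int(math.ceil(6.0 * config.psf_sigma_px))
    for peak in peaks:
        temporal = peak.amplitude * np.exp(
            -((t - peak.peak_time_frames) ** 2) / (2.0 * peak.sigma_frames**2)
        )
        for fi in np.nonzero(temporal > 1e-12 * peak.amplitude)[0]:
            xf, yf = x, y
            if jitter is not None:
                xf, yf = x + jitter[fi, 0], y + jitter[fi, 1]
            x0, x1 = max(0, int(xf) - r), min(w, int(xf) + r + 1)
            y0, y1 = max(0, int(yf) - r), min(h, int(yf) + r + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1, dtype=float)
            ys = np.arange(y0, y1, dtype=float)
            gx = np.exp(-((xs - xf) ** 2) / s2)
            gy = np.exp(-((ys - yf) ** 2) / s2)
            stack[fi, y0:y1, x0:x1] += temporal[fi] * np.outer(gy, gx)
    return stack


def render_noiseless_event(
    event: GroundTruthEvent, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Render one event's additive noiseless contribution to both channels.

    The value at (x, y, t) is amplitude * temporal Gaussian * spatial Gaussian
    (separable); contributions of multiple events add pixel-wise.
    """
    if not (0 <= event.x_px < config.image_width_px and 0 <= event.y_px < config.image_height_px):
        raise ValueError("event position outside frame bounds")
    ch1 = _render_peaks([event.ch1], event.x_px, event.y_px, config)
    ch2 = _render_peaks(event.ch2_peaks, event.x_px, event.y_px, config)
    return ch1, ch2


# ---------------------------------------------------------------------------
# Event placement and generation
# ---------------------------------------------------------------------------


def _place_positions(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Random positions at guaranteed pairwise separation.

    Cells of a square lattice with pitch = min_separation + 2*jitter are
    sampled without replacement and each point jittered within its cell, so
    the separation constraint holds by construction (dense plantings would
    make plain rejection sampling stall well below the packing limit).
    """
    if config.n_events == 0:
        return []
    margin = config.edge_margin_px
    w = config.image_width_px - 2 * margin
    h = config.image_height_px - 2 * margin
    if w <= 0 or h <= 0:
        raise OvercrowdedError("image too small for the detection aperture margin")
    if config.min_event_separation_px == 0:
        return [
            (rng.uniform(margin, margin + w), rng.uniform(margin, margin + h))
            for _ in range(config.n_events)
        ]
    jit = 0.5
    pitch = config.min_event_separation_px + 2 * jit
    nx = int(w // pitch) + 1
    ny = int(h // pitch) + 1
    if nx * ny < config.n_events:
        raise OvercrowdedError(
            f"cannot place {config.n_events} events at separation "
            f">= {config.min_event_separation_px} px in "
            f"{config.image_width_px}x{config.image_height_px} px "
            f"(capacity {nx * ny})"
        )
    cells = rng.choice(nx * ny, size=config.n_events, replace=False)
    positions = []
    for c in cells:
        i, j = divmod(int(c), nx)
        x = margin + j * pitch + rng.uniform(-jit, jit)
        y = margin + i * pitch + rng.uniform(-jit, jit)
        positions.append(
            (float(np.clip(x, margin, margin + w)), float(np.clip(y, margin, margin + h)))
        )
    return positions


def _sample_event(
    event_id: int, x: float, y: float, config: SimulationConfig, rng: np.random.Generator
) -> GroundTruthEvent:
    n = config.n_frames
    sigma1 = rng.uniform(*config.temporal_sigma_range_frames)
    amp1 = rng.uniform(*config.amplitude_range)
    duration1 = 4.0 * sigma1
    # keep the whole visible extent of the event inside the movie, so events
    # never touch the first/last frame (truncated events are excluded downstream)
    t_lo = 3.0 * sigma1 + 2.0
    t_hi = (n - 1) - 3.0 * sigma1 - 2.0
    if t_hi <= t_lo:
        raise ValueError("movie too short for the requested temporal sigmas")
    t1 = rng.uniform(t_lo, t_hi)

    amp2 = amp1 * config.channel2_amplitude_scale
    sigma2 = sigma1 * config.channel2_sigma_scale
    double = rng.random() < config.double_peak_fraction
    if double:
        # two hydrolysis bursts: one before and one after the channel-1 peak
        d1 = rng.uniform(12.0, 35.0) / 100.0 * duration1
        d2 = rng.uniform(12.0, 35.0) / 100.0 * duration1
        peaks = (
            TemporalPeak(amp2, t1 - d1, sigma2),
            TemporalPeak(amp2 * config.double_peak_amplitude_ratio, t1 + d2, sigma2),
        )
    else:
        for _ in range(100):
            delta = config.delta_t_spec.sample(rng, duration1)
            if 1.0 <= t1 + delta <= n - 2:
                break
        else:
            delta = 0.0
        peaks = (TemporalPeak(amp2, t1 + delta, sigma2),)
    for p in peaks + (TemporalPeak(amp1, t1, sigma1),):
        if not 0.0 <= p.peak_time_frames <= n - 1:
            raise ValueError("peak time outside movie")
    return GroundTruthEvent(event_id, x, y, TemporalPeak(amp1, t1, sigma1), peaks)


def generate_movie(config: SimulationConfig) -> SyntheticMovie:
    """Generate a two-channel movie plus its ground-truth table.

    Deterministic: equal configs (including seed) yield bit-identical stacks.
    """
    rng = np.random.default_rng(config.seed)
    positions = _place_positions(config, rng)
    events = [
        _sample_event(i, x, y, config, rng) for i, (x, y) in enumerate(positions)
    ]

    h, w, n = config.image_height_px, config.image_width_px, config.n_frames
    clean1 = np.full((n, h, w), float(config.background_level))
    clean2 = np.full((n, h, w), float(config.background_level))
    for ev in events:
        jitter = None
        if config.position_jitter_sd_px > 0:
            jitter = rng.normal(0.0, config.position_jitter_sd_px, size=(n, 2))
        clean1 += _render_peaks([ev.ch1], ev.x_px, ev.y_px, config, jitter)
        clean2 += _render_peaks(ev.ch2_peaks, ev.x_px, ev.y_px, config, jitter)

    noisy = []
    for clean in (clean1, clean2):
        img = rng.poisson(clean).astype(float)
        if config.camera_noise_sd > 0:
            img += rng.normal(0.0, config.camera_noise_sd, size=img.shape)
        noisy.append(np.clip(img, 0.0, None))

    return SyntheticMovie(
        channel1=noisy[0],
        channel2=noisy[1],
        frame_interval_s=config.frame_interval_s,
        ground_truth=tuple(events),
        config=config,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def ground_truth_table(movie: SyntheticMovie) -> pd.DataFrame:
    """One row per (event, channel, peak)."""
    rows = []
    for ev in movie.ground_truth:
        rows.append(
            dict(event_id=ev.event_id, x_px=ev.x_px, y_px=ev.y_px, ch=1,
                 amplitude=ev.ch1.amplitude, peak_time_frames=ev.ch1.peak_time_frames,
                 sigma_frames=ev.ch1.sigma_frames, peak_index=0)
        )
        for j, p in enumerate(ev.ch2_peaks):
            rows.append(
                dict(event_id=ev.event_id, x_px=ev.x_px, y_px=ev.y_px, ch=2,
                     amplitude=p.amplitude, peak_time_frames=p.peak_time_frames,
                     sigma_frames=p.sigma_frames, peak_index=j)
            )
    cols = ["event_id", "x_px", "y_px", "ch", "amplitude",
            "peak_time_frames", "sigma_frames", "peak_index"]
    return pd.DataFrame(rows, columns=cols)


def save_movie(movie: SyntheticMovie, out_dir: str | Path, prefix: str = "movie") -> dict[str, Path]:
    """Write one multi-page TIFF per channel, the ground-truth CSV and a
    metadata YAML recording the seed and configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "channel1": out / f"{prefix}_ch1.tif",
        "channel2": out / f"{prefix}_ch2.tif",
        "ground_truth": out / f"{prefix}_ground_truth.csv",
        "metadata": out / f"{prefix}_metadata.yaml",
    }
    tifffile.imwrite(paths["channel1"], movie.channel1.astype(np.float32))
    tifffile.imwrite(paths["channel2"], movie.channel2.astype(np.float32))
    ground_truth_table(movie).to_csv(paths["ground_truth"], index=False)
    meta: dict = {"frame_interval_s": movie.frame_interval_s}
    if movie.config is not None:
        cfg = dataclasses.asdict(movie.config)
        cfg["delta_t_spec"] = {
            "kind": {
                PointOffset: "point",
                GaussianMixtureOffset: "gaussian_mixture",
                CategoricalOffset: "categorical",
            }[type(movie.config.delta_t_spec)],
            **dataclasses.asdict(movie.config.delta_t_spec),
        }
        meta["config"] = cfg
        meta["seed"] = movie.config.seed
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return paths


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML/JSON file (YAML is a JSON superset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "config" in raw:  # allow reading back a saved metadata file
        raw = raw["config"]
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "delta_t_spec" in raw and isinstance(raw["delta_t_spec"], dict):
        raw["delta_t_spec"] = _offset_spec_from_dict(raw["delta_t_spec"])
    for key in ("amplitude_range", "temporal_sigma_range_frames"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
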