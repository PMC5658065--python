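"""File formats, configuration, orchestration and run manifests.

The pipeline stage order is fixed: detect -> assemble -> extract -> fit ->
label -> timing -> summarize (all inside ``TwoChannelEventModel.fit``), with
an optional leading simulate stage.  Every intermediate table is persisted as
CSV (fixed column order, seconds with six decimals) and a JSON manifest with
config snapshot, seed, version and SHA-256 digests of all inputs and outputs
is written atomically at the end of the run.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .detection import DetectionConfig
from .events import LinkingConfig
from .model import TwoChannelEventModel, TwoChannelEventResults, spots_to_table
from .profiles import FitConfig
from .simulate import (
    SimulationConfig,
    SyntheticMovie,
    _offset_spec_from_dict,
    generate_movie,
    ground_truth_table,
    save_movie,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "MovieFormatError",
    "read_movie",
    "write_movie",
    "run_pipeline",
    "evaluate_against_truth",
]

log = logging.getLogger("dualtrace")


class MovieFormatError(ValueError):
    pass


def read_movie(path: str | Path, channel_layout: str = "single", channel: int = 0) -> np.ndarray:
    """Read a grayscale multi-page TIFF as an (n_frames, H, W) float stack.

    channel_layout 'single': one file per channel.  'interleaved': pages
    alternate channels (T*C order); ``channel`` selects which to return.
    Mixed page shapes/dtypes or unreadable files raise MovieFormatError.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            dtypes = {p.dtype for p in tif.pages}
            if len(shapes) != 1 or len(dtypes) != 1:
                raise MovieFormatError(f"{path}: pages have mixed shapes or dtypes")
            stack = tif.asarray()
    except MovieFormatError:
        raise
    except Exception as exc:
        raise MovieFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise MovieFormatError(f"{path}: expected grayscale pages, got shape {stack.shape}")
    if channel_layout == "single":
        return stack.astype(float)
    if channel_layout == "interleaved":
        if channel not in (0, 1):
            raise ValueError("channel must be 0 or 1 for interleaved layout")
        if stack.shape[0] % 2:
            raise MovieFormatError(f"{path}: odd page count for interleaved 2-channel layout")
        return stack[channel::2].astype(float)
    raise ValueError(f"unknown channel_layout {channel_layout!r}")


def write_movie(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IOPaths:
    channel1: str | None = None
    channel2: str | None = None
    channel_layout: str = "single"
    out_dir: str = "dualtrace_out"


@dataclass(frozen=True)
class PipelineConfig:
    simulate: SimulationConfig | None = None
    detect: DetectionConfig = field(default_factory=DetectionConfig)
    link: LinkingConfig = field(default_factory=LinkingConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    io: IOPaths = field(default_factory=IOPaths)
    frame_interval_s: float = 2.0
    cutoff_pct: float = 10.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")

        def build(klass, section):
            if section is None:
                return None
            if not isinstance(section, dict):
                raise ValueError(f"section for {klass.__name__} must be a mapping")
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(section) - names
            if bad:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(bad)}")
            for k, v in list(section.items()):
                if isinstance(v, list):
                    section[k] = tuple(v)
            if klass is SimulationConfig and isinstance(section.get("delta_t_spec"), dict):
                section["delta_t_spec"] = _offset_spec_from_dict(section["delta_t_spec"])
            return klass(**section)

        kwargs = {}
        if "simulate" in raw and raw["simulate"] is not None:
            kwargs["simulate"] = build(SimulationConfig, dict(raw.pop("simulate")))
        for key, klass in (("detect", DetectionConfig), ("link", LinkingConfig),
                           ("fit", FitConfig), ("io", IOPaths)):
            if key in raw and raw[key] is not None:
                kwargs[key] = build(klass, dict(raw.pop(key)))
            raw.pop(key, None)
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class RunManifest:
    config: dict
    seed: int
    version: str
    started: str
    finished: str
    inputs: dict[str, str]  # path -> sha256
    outputs: dict[str, str]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_json(obj: dict, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def persist_results(results: TwoChannelEventResults, out_dir: Path) -> dict[str, Path]:
    """Write all analysis tables under ``out_dir``; returns name -> path."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["spots_ch1"] = out_dir / "spots_ch1.csv"
    paths["spots_ch2"] = out_dir / "spots_ch2.csv"
    _write_csv(spots_to_table(results.spots_ch1), paths["spots_ch1"])
    _write_csv(spots_to_table(results.spots_ch2), paths["spots_ch2"])

    paths["events"] = out_dir / "events.csv"
    _write_csv(results.event_table, paths["events"])

    profile_dir = out_dir / "profiles"
    profile_dir.mkdir(exist_ok=True)
    fit_rows = []
    for c in results.events:
        if c.profile_ch1 is None or c.profile_ch2 is None:
            continue
        pdf = pd.DataFrame(
            {
                "time_s": c.profile_ch1.times,
                "ch1": c.profile_ch1.values,
                "ch2": c.profile_ch2.values,
            }
        )
        path = profile_dir / f"event_{c.event_id:04d}.csv"
        _write_csv(pdf, path)
        paths[f"profile_{c.event_id}"] = path
        for ch, fit in (("ch1", c.fit_ch1), ("ch2", c.fit_ch2)):
            if fit is None:
                continue
            for i, comp in enumerate(fit.components):
                fit_rows.append(
                    dict(event_id=c.event_id, channel=ch, component=i,
                         amplitude=comp.amplitude, center_s=comp.center,
                         sigma_s=comp.sigma,
                         label="principal" if comp in fit.principal else "background",
                         gof=fit.gof)
                )
    paths["fits"] = out_dir / "fits.csv"
    _write_csv(
        pd.DataFrame(fit_rows, columns=["event_id", "channel", "component", "amplitude",
                                        "center_s", "sigma_s", "label", "gof"]),
        paths["fits"],
    )

    paths["timing"] = out_dir / "timing.csv"
    _write_csv(results.timing_table, paths["timing"])

    ts = results.timing_summary
    summary: dict = {"n_candidates": len(results.events),
                     "n_validated": results.n_validated,
                     "n_timed": len(results.timings)}
    if ts is not None:
        paths["histogram"] = out_dir / "delta_t_histogram.csv"
        _write_csv(ts.histogram, paths["histogram"])
        summary.update(
            fraction_before_pct=ts.fraction_before,
            fraction_simultaneous_pct=ts.fraction_simultaneous,
            fraction_after_pct=ts.fraction_after,
            fraction_negative_delta_t_pct=ts.fraction_negative_delta_t,
            double_peak_rate_pct=ts.double_peak_rate,
            double_dynamin_rate_pct=ts.double_dynamin_rate,
            mean_duration_dynamin_s=ts.mean_duration_dynamin,
            mean_duration_dynab_s=ts.mean_duration_dynab,
            duration_ratio_pct=ts.duration_ratio_pct,
            intensity_correlation=ts.intensity_correlation,
        )
        try:
            paths["curves"] = out_dir / "curve_average.csv"
            _write_csv(results.curve_average(), paths["curves"])
        except ValueError:
            paths.pop("curves", None)
    paths["summary"] = out_dir / "summary.json"
    _atomic_write_json(summary, paths["summary"])
    return paths


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline per ``config`` and write a run manifest."""
    logging.basicConfig(level=config.log_level)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    out_dir = Path(config.io.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        log.info("simulating movie (seed=%d)", config.seed)
        movie = generate_movie(sim_cfg)
        sim_paths = save_movie(movie, out_dir, prefix="sim")
        inputs.update({str(p): _sha256(p) for p in sim_paths.values()})
        frame_interval = sim_cfg.frame_interval_s
        detection = dataclasses.replace(config.detect, psf_sigma_px=sim_cfg.psf_sigma_px)
        ch1, ch2 = movie.channel1, movie.channel2
    else:
        if config.io.channel1 is None or config.io.channel2 is None:
            raise ValueError("io.channel1 and io.channel2 are required without a simulate section")
        layout = config.io.channel_layout
        if layout == "interleaved":
            ch1 = read_movie(config.io.channel1, "interleaved", 0)
            ch2 = read_movie(config.io.channel1, "interleaved", 1)
            inputs[str(config.io.channel1)] = _sha256(Path(config.io.channel1))
        else:
            ch1 = read_movie(config.io.channel1)
            ch2 = read_movie(config.io.channel2)
            for p in (config.io.channel1, config.io.channel2):
                inputs[str(p)] = _sha256(Path(p))
        frame_interval = config.frame_interval_s
        detection = config.detect

    model = TwoChannelEventModel(
        ch1, ch2, frame_interval_s=frame_interval,
        detection=detection, linking=config.link, fit=config.fit,
        cutoff_pct=config.cutoff_pct,
    )
    log.info("running analysis")
    results = model.fit()
    paths = persist_results(results, out_dir)

    finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    cfg_snapshot = json.loads(json.dumps(dataclasses.asdict(config), default=str))
    manifest = RunManifest(
        config=cfg_snapshot,
        seed=config.seed,
        version=__version__,
        started=started,
        finished=finished,
        inputs=inputs,
        outputs={str(p): _sha256(p) for p in paths.values()},
    )
    _atomic_write_json(dataclasses.asdict(manifest), out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Ground-truth evaluation
# ---------------------------------------------------------------------------


def evaluate_against_truth(
    results: TwoChannelEventResults,
    movie: SyntheticMovie,
    match_radius_px: float = 2.0,
) -> dict:
    """Recall / spurious-rate / timing-error metrics on a planted movie.

    A planted event is recovered when a validated, non-truncated analysis
    event sits within ``match_radius_px`` of its true position and its fitted
    dynamin peak time falls within the true event's visible extent.  Each
    analysis event may match one planted event and vice versa.
    """
    truth = list(movie.ground_truth)
    validated = [c for c in results.events if c.valid and not c.truncated]
    dt = movie.frame_interval_s

    matches: list[tuple[int, int]] = []
    used_truth: set[int] = set()
    timing_errors = []
    for c in validated:
        best, best_d = None, np.inf
        for gt in truth:
            if gt.event_id in used_truth:
                continue
            d = np.hypot(c.x_px - gt.x_px, c.y_px - gt.y_px)
            if d <= match_radius_px and d < best_d:
                t_fit = c.fit_ch1.peak.t / dt if (c.fit_ch1 and c.fit_ch1.peak) else np.nan
                if np.isfinite(t_fit) and abs(t_fit - gt.ch1.peak_time_frames) <= 4 * gt.ch1.sigma_frames:
                    best, best_d = gt, d
        if best is not None:
            used_truth.add(best.event_id)
            matches.append((c.event_id, best.event_id))
            timing = next((t for t in results.timings if t.event_id == c.event_id), None)
            if timing is not None:
                timing_errors.append(timing.delta_t_frames - best.delta_t_frames)

    n_truth = len(truth)
    recall = len(matches) / n_truth if n_truth else float("nan")
    spurious = (len(validated) - len(matches)) / len(validated) if validated else 0.0
    errs = np.array(timing_errors) if timing_errors else np.array([np.nan])
    return {
        "n_planted": n_truth,
        "n_validated": len(validated),
        "n_matched": len(matches),
        "recall": recall,
        "spurious_fraction": spurious,
        "median_abs_delta_t_error_frames": float(np.nanmedian(np.abs(errs))),
        "matches": matches,
    }
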