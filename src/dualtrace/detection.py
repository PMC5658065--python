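"""Per-frame sub-pixel puncta detection and aperture photometry.

Detector: Laplacian-of-Gaussian band-pass at the PSF scale, 8-neighbourhood
local maxima above a robust noise threshold, least-squares 2-D Gaussian
refinement of position, and an amplitude-vs-local-noise significance test.

Photometry follows the integrated-circle definition: the intensity of a spot
is the integral of the gray level in a circle centred on the spot maximum,
after subtracting the local background (median of a surrounding annulus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.stats import norm

__all__ = [
    "DetectionConfig",
    "Spot",
    "ApertureOutOfBoundsError",
    "detect_spots",
    "measure_intensity",
]


class ApertureOutOfBoundsError(ValueError):
    """The measurement circle does not fit inside the frame."""


@dataclass(frozen=True)
class DetectionConfig:
    """Detector and photometry parameters.

    aperture_radius_px defaults to 3*psf_sigma_px (captures >98% of a
    Gaussian spot's flux); the background annulus defaults to
    (aperture + 1.5, aperture + 4.5) px.
    """

    psf_sigma_px: float = 1.5
    significance_alpha: float = 0.05
    aperture_radius_px: float | None = None
    local_background_annulus: tuple[float, float] | None = None
    detect_threshold_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if not 0 < self.significance_alpha < 1:
            raise ValueError("significance_alpha must lie in (0, 1)")
        r = self.aperture_radius
        r_in, r_out = self.annulus
        if not r < r_in < r_out:
            raise ValueError("need aperture_radius < annulus inner < annulus outer")

    @property
    def aperture_radius(self) -> float:
        return (
            3.0 * self.psf_sigma_px
            if self.aperture_radius_px is None
            else self.aperture_radius_px
        )

    @property
    def annulus(self) -> tuple[float, float]:
        if self.local_background_annulus is None:
            r = self.aperture_radius
            return (r + 1.5, r + 4.5)
        return self.local_background_annulus


@dataclass(frozen=True)
class Spot:
    frame_index: int
    x_px: float
    y_px: float
    integrated_intensity: float
    local_background: float
    fit_sigma_px: float
    amplitude: float
    significant: bool


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    mask = dy**2 + dx**2 <= radius**2  # pixel centres within radius, inclusive
    return dy[mask], dx[mask]


def _annulus_offsets(r_in: float, r_out: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.floor(r_out))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dy**2 + dx**2
    mask = (d2 >= r_in**2) & (d2 <= r_out**2)
    return dy[mask], dx[mask]


def measure_intensity(
    frame: np.ndarray, x_px: float, y_px: float, cfg: DetectionConfig
) -> tuple[float, float]:
    """Background-subtracted integrated intensity in a circle at (x, y).

    Returns (integrated_intensity, local_background).  The background is the
    median over an annulus around the aperture; annulus pixels falling outside
    the frame are ignored, but the aperture itself must fit entirely inside.
    The integrated intensity may be negative over empty regions.
    """
    h, w = frame.shape
    r = cfg.aperture_radius
    cy, cx = int(round(y_px)), int(round(x_px))
    rr = int(math.floor(r))
    if cy - rr < 0 or cx - rr < 0 or cy + rr >= h or cx + rr >= w:
        raise ApertureOutOfBoundsError(
            f"aperture of radius {r} at ({x_px:.1f}, {y_px:.1f}) exceeds frame {frame.shape}"
        )
    dy, dx = _disk_offsets(r)
    circle = frame[cy + dy, cx + dx]

    ady, adx = _annulus_offsets(*cfg.annulus)
    ay, ax = cy + ady, cx + adx
    inside = (ay >= 0) & (ay < h) & (ax >= 0) & (ax < w)
    ann = frame[ay[inside], ax[inside]]
    if ann.size < 8:
        raise ApertureOutOfBoundsError("background annulus has too few in-frame pixels")
    background = float(np.median(ann))
    return float(np.sum(circle - background)), background


def _annulus_noise_sd(frame: np.ndarray, cy: int, cx: int, cfg: DetectionConfig) -> float:
    h, w = frame.shape
    ady, adx = _annulus_offsets(*cfg.annulus)
    ay, ax = cy + ady, cx + adx
    inside = (ay >= 0) & (ay < h) & (ax >= 0) & (ax < w)
    ann = frame[ay[inside], ax[inside]]
    med = np.median(ann)
    return float(1.4826 * np.median(np.abs(ann - med)))


def _fit_gaussian_2d(
    frame: np.ndarray, cy: int, cx: int, cfg: DetectionConfig
) -> tuple[float, float, float, float, float, float] | None:
    """Least-squares symmetric 2-D Gaussian + constant in a local window.

    Returns (x0, y0, amplitude, sigma, offset, amp_se_unit) where
    amp_se_unit is the amplitude standard error per unit pixel-noise sd
    (from the Jacobian at the solution), or None on failure.
    """
    h, w = frame.shape
    half = max(2, int(round(2.0 * cfg.psf_sigma_px)))  # window side 4*sigma + 1
    y0, y1 = max(0, cy - half), min(h, cy + half + 1)
    x0, x1 = max(0, cx - half), min(w, cx + half + 1)
    win = frame[y0:y1, x0:x1].astype(float)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    offset0 = float(np.median(win))
    amp0 = max(float(frame[cy, cx] - offset0), 1e-6)
    p0 = np.array([cx, cy, amp0, cfg.psf_sigma_px, offset0])
    lb = np.array([x0 - 0.5, y0 - 0.5, 0.0, 0.3 * cfg.psf_sigma_px, -np.inf])
    ub = np.array([x1 - 0.5, y1 - 0.5, np.inf, 3.0 * cfg.psf_sigma_px, np.inf])

    def resid(p: np.ndarray) -> np.ndarray:
        x, y, a, s, b = p
        model = a * np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * s**2))) + b
        return (model - win).ravel()

    try:
        sol = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf", xtol=1e-10)
    except Exception:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    x, y, a, s, b = sol.x
    try:
        jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
        amp_se_unit = float(math.sqrt(max(jtj_inv[2, 2], 0.0)))
    except np.linalg.LinAlgError:
        amp_se_unit = 1.0
    return float(x), float(y), float(a), float(s), float(b), amp_se_unit


def detect_spots(frame: np.ndarray, cfg: DetectionConfig) -> list[Spot]:
    """Detect diffraction-limited spots in one frame.

    Candidates are 8-neighbourhood local maxima of the (sign-flipped)
    Laplacian-of-Gaussian response exceeding ``detect_threshold_sigma`` robust
    standard deviations of the response; each candidate is refined by a 2-D
    Gaussian fit and carries an amplitude-significance flag at
    ``significance_alpha`` against the local annulus noise.  The list is
    sorted by descending integrated intensity.  A constant frame yields an
    empty list; non-finite pixels are rejected.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    h, w = frame.shape
    min_dim = 7.0 * cfg.psf_sigma_px
    if h < min_dim or w < min_dim:
        raise ValueError("frame smaller than 7 * psf_sigma_px")

    response = -ndimage.gaussian_laplace(frame, cfg.psf_sigma_px)
    med = np.median(response)
    mad_sd = 1.4826 * np.median(np.abs(response - med))
    if mad_sd > 0.0:
        threshold = med + cfg.detect_threshold_sigma * mad_sd
    else:
        # noiseless frame: flat background gives zero MAD; keep any clearly
        # positive band-pass response (constant frames still yield nothing)
        peak = float(response.max() - med)
        if peak <= 1e-9 * max(abs(med), 1.0) + 1e-12:
            return []
        threshold = med + 1e-6 * peak

    local_max = response == ndimage.maximum_filter(response, size=3, mode="nearest")
    cand = np.argwhere(local_max & (response > threshold))
    # plateau tie-break: among equal-valued touching maxima keep smallest (row, col)
    cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
    kept: list[tuple[int, int]] = []
    for cy, cx in cand:
        if any(
            abs(cy - ky) <= 1 and abs(cx - kx) <= 1 and response[cy, cx] == response[ky, kx]
            for ky, kx in kept
        ):
            continue
        kept.append((int(cy), int(cx)))

    rr = int(math.floor(cfg.aperture_radius))
    z = norm.isf(cfg.significance_alpha)
    spots: list[Spot] = []
    for cy, cx in kept:
        if cy - rr < 0 or cx - rr < 0 or cy + rr >= h or cx + rr >= w:
            continue  # aperture would be clipped; spot unmeasurable
        fit = _fit_gaussian_2d(frame, cy, cx, cfg)
        if fit is None:
            continue
        x, y, amp, sigma, _off, amp_se_unit = fit
        if not (0 <= x < w and 0 <= y < h):
            continue
        try:
            intensity, background = measure_intensity(frame, x, y, cfg)
        except ApertureOutOfBoundsError:
            continue
        noise_sd = _annulus_noise_sd(frame, int(round(y)), int(round(x)), cfg)
        # one-sided test: the amplitude's lower (1 - alpha) confidence bound
        # must exceed the alpha-quantile of the local pixel noise
        if noise_sd > 0:
            significant = bool(amp - z * amp_se_unit * noise_sd > z * noise_sd)
        else:
            significant = bool(amp > 0)
        spots.append(
            Spot(
                frame_index=0,
                x_px=x,
                y_px=y,
                integrated_intensity=intensity,
                local_background=background,
                fit_sigma_px=sigma,
                amplitude=amp,
                significant=significant,
            )
        )
    spots.sort(key=lambda s: -s.integrated_intensity)
    return spots


def detect_stack(stack: np.ndarray, cfg: DetectionConfig) -> list[list[Spot]]:
    """Run detect_spots on every frame, stamping frame indices."""
    out: list[list[Spot]] = []
    for fi, frame in enumerate(stack):
        spots = [
            Spot(fi, s.x_px, s.y_px, s.integrated_intensity, s.local_background,
                 s.fit_sigma_px, s.amplitude, s.significant)
            for s in detect_spots(frame, cfg)
        ]
        out.append(spots)
    return out
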