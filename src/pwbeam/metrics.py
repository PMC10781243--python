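"""Envelope display and image-quality metrics.

All metrics operate on the *linear* envelope magnitude (not the
log-compressed display map):

* lateral FWHM of a point target: width between the two half-maximum
  (-6.02 dB) crossings of the lateral profile through the peak,
* contrast ratio          CR   = 20 log10(mu_bck / mu_cyst)   [dB],
* contrast-to-noise ratio CNR  = 20 log10(|mu_cyst - mu_bck| /
                                  sqrt((sd_cyst^2 + sd_bck^2) / 2)),
* generalized CNR         gCNR = 1 - overlap of the two envelope
                                  histograms (1 = complete separation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .beamformers import BeamformedImage
from .geometry import PixelGrid

__all__ = [
    "RoiCircle",
    "MetricsReport",
    "envelope_log",
    "fwhm_lateral",
    "cr",
    "cnr",
    "gcnr",
    "roi_values",
    "evaluate_image",
]


@dataclass(frozen=True)
class RoiCircle:
    """Circular region of interest in meters; ``role`` is 'cyst' or 'background'."""

    center: tuple[float, float]  # (x, z)
    radius: float
    role: str = "cyst"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.role not in ("cyst", "background"):
            raise ValueError("role must be 'cyst' or 'background'")

    def mask(self, grid: PixelGrid) -> np.ndarray:
        X, Z = grid.meshgrid()
        cx, cz = self.center
        inside = (X - cx) ** 2 + (Z - cz) ** 2 <= self.radius**2
        if not inside.any():
            raise ValueError("ROI contains no grid pixels")
        return inside


def roi_values(image: BeamformedImage, roi: RoiCircle) -> np.ndarray:
    """Linear envelope magnitudes of the pixels inside the ROI."""
    return image.envelope[roi.mask(image.grid)]


def envelope_log(image: BeamformedImage, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Log-compressed display map ``20 log10(|y| / max|y|)`` clipped at
    ``-dynamic_range_db``."""
    env = image.envelope
    peak = env.max()
    if peak <= 0:
        raise ValueError("all-zero image cannot be log-compressed")
    db = 20.0 * np.log10(np.maximum(env, peak * 10 ** (-dynamic_range_db / 20 - 2)) / peak)
    return np.clip(db, -dynamic_range_db, 0.0)


def _crossing(xs: np.ndarray, profile: np.ndarray, ipk: int, half: float, step: int) -> float:
    """Lateral position where the profile falls through ``half``, walking
    from the peak in direction ``step``; linear interpolation between
    samples.  NaN if the profile never crosses."""
    i = ipk
    while 0 <= i + step < profile.size:
        j = i + step
        if profile[j] < half:
            f = (profile[i] - half) / (profile[i] - profile[j])
            return float(xs[i] + f * (xs[j] - xs[i]))
        i = j
    return float("nan")


def fwhm_lateral(
    image: BeamformedImage,
    target_depth: float,
    target_x: float = 0.0,
    search_halfwidth: float = 1.5e-3,
    depth_halfwidth: float = 0.5e-3,
) -> float:
    """Lateral full width at half maximum of a point target, in mm.

    The peak is searched within ``search_halfwidth`` of ``target_x`` and
    ``depth_halfwidth`` of ``target_depth``; the profile is the envelope row
    through the peak.  A side on which the profile never falls below half
    maximum yields NaN."""
    grid = image.grid
    env = image.envelope
    zsel = np.abs(grid.axial_z - target_depth) <= depth_halfwidth + grid.dz
    xsel = np.abs(grid.lateral_x - target_x) <= search_halfwidth
    if not zsel.any() or not xsel.any():
        raise ValueError("target window outside the image grid")
    win = env[np.ix_(zsel, xsel)]
    iz_w, ix_w = np.unravel_index(np.argmax(win), win.shape)
    iz = np.flatnonzero(zsel)[iz_w]
    ipk = np.flatnonzero(xsel)[ix_w]
    profile = env[iz]
    half = profile[ipk] / 2.0
    if half <= 0:
        return float("nan")
    xl = _crossing(grid.lateral_x, profile, ipk, half, -1)
    xr = _crossing(grid.lateral_x, profile, ipk, half, +1)
    return (xr - xl) * 1e3


def cr(cyst_pixels: np.ndarray, bck_pixels: np.ndarray) -> float:
    """Contrast ratio in dB on linear envelope magnitudes."""
    c = np.asarray(cyst_pixels, dtype=float)
    b = np.asarray(bck_pixels, dtype=float)
    if c.size == 0 or b.size == 0:
        raise ValueError("empty ROI")
    mc = c.mean()
    if mc == 0:
        return float("inf")
    return float(20.0 * np.log10(b.mean() / mc))


def cnr(cyst_pixels: np.ndarray, bck_pixels: np.ndarray) -> float:
    """Log-scaled contrast-to-noise ratio on linear envelope magnitudes."""
    c = np.asarray(cyst_pixels, dtype=float)
    b = np.asarray(bck_pixels, dtype=float)
    if c.size == 0 or b.size == 0:
        raise ValueError("empty ROI")
    denom = np.sqrt((c.var() + b.var()) / 2.0)
    if denom == 0:
        raise ValueError("zero variance in both ROIs")
    diff = abs(c.mean() - b.mean())
    if diff == 0:
        return float("-inf")
    return float(20.0 * np.log10(diff / denom))


def gcnr(cyst_pixels: np.ndarray, bck_pixels: np.ndarray, n_bins: int = 100) -> float:
    """Generalized CNR: one minus the overlap of the two envelope
    histograms on a shared bin grid spanning both ROIs."""
    c = np.asarray(cyst_pixels, dtype=float)
    b = np.asarray(bck_pixels, dtype=float)
    if c.size == 0 or b.size == 0:
        raise ValueError("empty ROI")
    lo = min(c.min(), b.min())
    hi = max(c.max(), b.max())
    if hi <= lo:
        return 0.0  # identical constants: full overlap
    edges = np.linspace(lo, hi, n_bins + 1)
    pc, _ = np.histogram(c, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    overlap = np.minimum(pc / c.size, pb / b.size).sum()
    return float(1.0 - overlap)


@dataclass
class MetricsReport:
    """Image-quality summary for one beamformed image."""

    method: str = ""
    params: dict = field(default_factory=dict)
    fwhm_mm: list[float] = field(default_factory=list)
    cr_db: float | None = None
    cnr_value: float | None = None
    gcnr_value: float | None = None

    @property
    def fwhm_mean_mm(self) -> float | None:
        vals = [v for v in self.fwhm_mm if np.isfinite(v)]
        return float(np.mean(vals)) if vals else None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": self.params,
            "fwhm_mm": self.fwhm_mm,
            "fwhm_mean_mm": self.fwhm_mean_mm,
            "cr_db": self.cr_db,
            "cnr": self.cnr_value,
            "gcnr": self.gcnr_value,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        def fmt(v, nd=2):
            return "-" if v is None or not np.isfinite(v) else f"{v:.{nd}f}"

        return (
            f"{'method':<12}{'FWHM (mm)':>12}{'CR (dB)':>10}{'CNR':>8}{'gCNR':>8}\n"
            f"{self.method:<12}{fmt(self.fwhm_mean_mm):>12}"
            f"{fmt(self.cr_db, 1):>10}{fmt(self.cnr_value, 1):>8}"
            f"{fmt(self.gcnr_value):>8}"
        )


def evaluate_image(
    image: BeamformedImage,
    fwhm_targets: list[tuple[float, float]] | None = None,
    cyst_rois: list[RoiCircle] | None = None,
    background_rois: list[RoiCircle] | None = None,
) -> MetricsReport:
    """Compute every applicable metric for one image.

    ``fwhm_targets`` are (x, z) point-target positions; cyst/background ROI
    lists are paired index-wise and the reported CR/CNR/gCNR are plain means
    over the pairs."""
    rep = MetricsReport(method=image.method, params=dict(image.params))
    for (tx, tz) in fwhm_targets or []:
        rep.fwhm_mm.append(fwhm_lateral(image, tz, tx))
    if cyst_rois and background_rois:
        crs, cnrs, gcnrs = [], [], []
        for roi_c, roi_b in zip(cyst_rois, background_rois):
            c = roi_values(image, roi_c)
            b = roi_values(image, roi_b)
            crs.append(cr(c, b))
            cnrs.append(cnr(c, b))
            gcnrs.append(gcnr(c, b))
        rep.cr_db = float(np.mean(crs))
        rep.cnr_value = float(np.mean(cnrs))
        rep.gcnr_value = float(np.mean(gcnrs))
    return rep
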