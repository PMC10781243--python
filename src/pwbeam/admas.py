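"""Adaptive coherence order: GCF / angular-variance maps and TxMV-ADMAS.

A fixed DMAS coherence order p sharpens targets but damages the speckle
background.  The adaptive scheme assigns each pixel its own p from two
per-pixel statistics of the transmit-angle array Z(n):

* GCF -- generalized coherence factor: the fraction of the angular DFT
  energy within +-M0 bins of DC (1 for perfectly coherent pixels);
* Var -- variance of the attenuation-compensated magnitudes |z_i| across
  angles, normalized image-wide to [0, 1] (near zero in fully developed
  speckle, large in off-axis clutter next to bright reflectors).

Thresholds on the two maps flag three low-focusing-quality region types
(off-axis clutter, uncorrelated noise, low-coherence cyst clutter) whose
GCF is reset to zero.  The reset GCF is smoothed into
``alpha = GCF ** Var**(1/m)`` (close to 1 in speckle where Var -> 0),
mapped through the inverse S-curve ``gamma = 1 - 1/(1 + exp(-(18 alpha - 9)))``,
median-filtered against pinholes, and finally scaled affinely into
``p = gamma * (p_max - 1) + p_min``.  Speckle thus gets p near p_min while
clutter and noise get p near p_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.special import expit

from .beamformers import BeamformedImage, _txmv_images, axial_halfwidth, tx_angle_stack
from .geometry import AnalyticDataCube, PixelGrid

__all__ = [
    "AdmasThresholds",
    "CoherenceMaps",
    "gcf_pixel",
    "gcf_map",
    "var_pixel",
    "tgc_gain",
    "var_map",
    "categorize_regions",
    "alpha_pixel",
    "alpha_map",
    "gamma_pixel",
    "median_filter_map",
    "adaptive_p_map",
    "compute_coherence_maps",
    "beamform_txmv_admas",
    "REGION_BACKGROUND",
    "REGION_I",
    "REGION_II",
    "REGION_III",
]

REGION_BACKGROUND = 0
REGION_I = 1  # off-axis clutter near strong reflectors (high variance)
REGION_II = 2  # uncorrelated noise (very low GCF)
REGION_III = 3  # low-coherence clutter inside anechoic regions


@dataclass(frozen=True)
class AdmasThresholds:
    """Region thresholds and map parameters for adaptive-p selection.

    Defaults are the values used with 75-angle acquisitions; they are tied
    to the transmit-angle set and should be re-tuned when it changes.
    """

    thg1: float = 0.1  # GCF lower bound -> uncorrelated noise (region II)
    thg2: float = 0.2  # GCF bound combined with thv1 (region III)
    thv1: float = 0.001  # variance bound combined with thg2 (region III)
    thv2: float = 0.15  # variance upper bound -> off-axis clutter (region I)
    M0: int = 1  # GCF cutoff: spectral bins kept around DC
    m: int = 4  # contrast root applied to the variance exponent
    p_min: float = 1.0
    p_max: float = 2.0
    median_kernel: int = 5  # pixels, odd

    def __post_init__(self) -> None:
        if not (0 <= self.thg1 < self.thg2 <= 1):
            raise ValueError("need 0 <= thg1 < thg2 <= 1")
        if not (0 <= self.thv1 < self.thv2):
            raise ValueError("need 0 <= thv1 < thv2")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (1 <= self.p_min <= self.p_max):
            raise ValueError("need 1 <= p_min <= p_max")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median kernel must be odd and positive")


@dataclass
class CoherenceMaps:
    """Per-pixel diagnostic maps of the adaptive-p pipeline."""

    gcf: np.ndarray
    var: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    p_adaptive: np.ndarray
    region_label: np.ndarray  # int codes REGION_*

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "gcf": self.gcf,
            "var": self.var,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "p_adaptive": self.p_adaptive,
            "region_label": self.region_label,
        }


def gcf_map(Zs: np.ndarray, M0: int = 1) -> np.ndarray:
    """Generalized coherence factor of each length-M vector along the last
    axis: spectral energy in the DC +- M0 bins of the unpadded DFT over the
    total spectral energy.  Identically zero vectors map to 0."""
    M = Zs.shape[-1]
    if not 0 <= M0 < M / 2:
        raise ValueError("need 0 <= M0 < M/2")
    F = np.fft.fft(Zs, axis=-1)
    E = np.abs(F) ** 2
    band = E[..., 0].copy()
    for k in range(1, M0 + 1):
        band += E[..., k] + E[..., M - k]
    total = E.sum(axis=-1)
    out = np.zeros_like(total)
    nz = total > 0
    out[nz] = band[nz] / total[nz]
    return np.clip(out, 0.0, 1.0)


def gcf_pixel(Z, M0: int = 1) -> float:
    """GCF of a single transmit-angle array."""
    from .arrays import TxAngleArray

    z = Z.z_values if isinstance(Z, TxAngleArray) else np.asarray(Z, dtype=complex)
    return float(gcf_map(z[None, :], M0)[0])


def var_pixel(Z, depth_gain: float = 1.0) -> float:
    """Variance across angles of the gain-compensated magnitudes |z_i|."""
    from .arrays import TxAngleArray

    if depth_gain <= 0:
        raise ValueError("depth_gain must be positive")
    z = Z.z_values if isinstance(Z, TxAngleArray) else np.asarray(Z, dtype=complex)
    return float(np.var(np.abs(z) * depth_gain))


def tgc_gain(reference_envelope: np.ndarray, smooth_fraction: float = 0.0625) -> np.ndarray:
    """Depth gain from the mean-vs-depth profile of a reference envelope
    (time-gain compensation): the laterally averaged envelope is smoothed
    along depth and inverted, so compensated magnitudes are depth-flat."""
    env = np.asarray(reference_envelope, dtype=float)
    profile = env.mean(axis=1)
    size = max(3, int(round(env.shape[0] * smooth_fraction)))
    profile = uniform_filter1d(profile, size=size, mode="nearest")
    top = profile.max()
    if top <= 0:
        return np.ones_like(profile)
    return 1.0 / np.maximum(profile, 1e-3 * top)


def var_map(Zs: np.ndarray, depth_gain: np.ndarray | float = 1.0, normalize: bool = True) -> np.ndarray:
    """Angular-variance map of an (nz, nx, M) stack.  ``depth_gain`` is a
    scalar or per-row gain; with ``normalize`` the map is divided by its
    image maximum so thresholds live on a [0, 1] scale."""
    gain = np.asarray(depth_gain, dtype=float)
    if gain.ndim == 1:
        gain = gain[:, None, None]
    v = np.var(np.abs(Zs) * gain, axis=-1)
    if normalize:
        top = v.max()
        if top > 0:
            v = v / top
    return v


def categorize_regions(gcf: np.ndarray, var: np.ndarray, th: AdmasThresholds):
    """Label low-focusing-quality pixels and reset their GCF to zero.

    Region I: var > thv2 (off-axis clutter);
    region II: gcf < thg1 (uncorrelated noise);
    region III: gcf < thg2 and var < thv1 (low-coherence cyst clutter).
    Overlaps resolve with precedence I > II > III; all three reset GCF, so
    the label is diagnostic only.  Returns ``(labels, gcf_reset)``."""
    gcf = np.asarray(gcf, dtype=float)
    var = np.asarray(var, dtype=float)
    if gcf.shape != var.shape:
        raise ValueError("maps must share a shape")
    labels = np.full(gcf.shape, REGION_BACKGROUND, dtype=np.int8)
    r3 = (gcf < th.thg2) & (var < th.thv1)
    r2 = gcf < th.thg1
    r1 = var > th.thv2
    labels[r3] = REGION_III
    labels[r2] = REGION_II
    labels[r1] = REGION_I
    reset = labels != REGION_BACKGROUND
    gcf_reset = np.where(reset, 0.0, gcf)
    return labels, gcf_reset


def alpha_pixel(gcf_reset: float, var: float, m: int = 4) -> float:
    """``alpha = gcf ** var**(1/m)``; a reset GCF of 0 gives 0 (the 0**0
    corner included), and var = 0 with positive GCF gives exactly 1."""
    if not 0 <= gcf_reset <= 1:
        raise ValueError("gcf must lie in [0, 1]")
    if var < 0:
        raise ValueError("var must be >= 0")
    if gcf_reset == 0.0:
        return 0.0
    return float(gcf_reset ** (var ** (1.0 / m)))


def alpha_map(gcf_reset: np.ndarray, var: np.ndarray, m: int = 4) -> np.ndarray:
    g = np.asarray(gcf_reset, dtype=float)
    v = np.asarray(var, dtype=float)
    out = np.zeros_like(g)
    pos = g > 0
    out[pos] = g[pos] ** (v[pos] ** (1.0 / m))
    return out


def gamma_pixel(alpha) -> np.ndarray:
    """Inverse S-curve ``1 - 1/(1 + exp(-(18 alpha - 9)))``: strictly
    decreasing, with gamma(0.5) = 0.5 exactly."""
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie in [0, 1]")
    return expit(9.0 - 18.0 * a)


def median_filter_map(gamma_map: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Square sliding-median filter with edge replication (pinhole removal)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and positive")
    return median_filter(np.asarray(gamma_map, dtype=float), size=kernel, mode="nearest")


def adaptive_p_map(gamma_map: np.ndarray, p_min: float = 1.0, p_max: float = 2.0) -> np.ndarray:
    """Affine map ``p = gamma * (p_max - 1) + p_min``; with p_min = 1 the
    range is [1, p_max]."""
    if not 1 <= p_min <= p_max:
        raise ValueError("need 1 <= p_min <= p_max")
    return np.asarray(gamma_map, dtype=float) * (p_max - 1.0) + p_min


def compute_coherence_maps(
    Zs: np.ndarray,
    reference_envelope: np.ndarray,
    th: AdmasThresholds,
) -> CoherenceMaps:
    """Run the full map chain on an angle-array stack.

    ``reference_envelope`` (normally the CPWC envelope of the same cube)
    supplies the depth profile for attenuation compensation of the variance
    map."""
    gcf = gcf_map(Zs, th.M0)
    gain = tgc_gain(reference_envelope)
    var = var_map(Zs, gain, normalize=True)
    labels, gcf_reset = categorize_regions(gcf, var, th)
    alpha = alpha_map(gcf_reset, var, th.m)
    gamma = gamma_pixel(alpha)
    gamma = median_filter_map(gamma, th.median_kernel)
    p = adaptive_p_map(gamma, th.p_min, th.p_max)
    return CoherenceMaps(gcf, var, alpha, gamma, p, labels)


def beamform_txmv_admas(
    cube: AnalyticDataCube,
    grid: PixelGrid,
    f_number: float = 1.75,
    thresholds: AdmasThresholds | None = None,
    L: int = 25,
    T: int | None = None,
    delta: float = 0.1,
) -> tuple[BeamformedImage, CoherenceMaps]:
    """TxMV-DMAS with the pixel-wise adaptive coherence order.

    The adaptive p map is derived from the same angle-array stack that the
    beamformer consumes, and the pixel's own p is used both for the root
    scaling of Z(n) and for restoring the signal dimensionality."""
    th = thresholds or AdmasThresholds()
    if T is None:
        T = axial_halfwidth(cube, grid)
    Zs = tx_angle_stack(cube, grid, f_number)
    cpwc_env = np.abs(Zs.mean(axis=2))
    maps = compute_coherence_maps(Zs, cpwc_env, th)
    y = _txmv_images(Zs, L, T, delta, p=maps.p_adaptive)
    img = BeamformedImage(
        y,
        grid,
        "txmv-admas",
        {
            "f_number": f_number,
            "L": L,
            "T": T,
            "delta": delta,
            "p_min": th.p_min,
            "p_max": th.p_max,
        },
    )
    return img, maps
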