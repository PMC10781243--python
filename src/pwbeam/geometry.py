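"""Probe geometry, plane-wave acquisition metadata and per-pixel delay handling.

Coordinates follow the usual linear-array convention: ``x`` is lateral along
the array (origin at the array center), ``z`` is axial depth (positive into
the medium), both in meters.  Images are indexed ``[z, x]``.

The plane-wave transmit delay is referenced so that the wavefront crosses the
array center (x = 0) at t = 0; per-angle start times ``t0`` from acquisition
metadata are honored on top of that.  This matches the convention of the
public PICMUS plane-wave datasets, so files from that challenge and cubes
from the bundled simulator share one delay model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "TransducerGeometry",
    "PlaneWaveSequence",
    "AnalyticDataCube",
    "PixelGrid",
    "EchoMatrix",
    "analytic_signal",
    "to_analytic",
    "tx_delay",
    "rx_delay",
    "rx_aperture_mask",
    "build_echo_matrix",
    "sample_linear",
]


@dataclass(frozen=True)
class TransducerGeometry:
    """Uniform linear array described by its element centers.

    Parameters
    ----------
    element_x
        Lateral element-center positions in meters, strictly increasing and
        uniformly spaced.
    center_frequency
        Transmit center frequency in Hz.
    sampling_frequency
        Fast-time sampling rate of the recorded channel data in Hz.
    sound_speed
        Assumed propagation speed in m/s.
    """

    element_x: np.ndarray
    center_frequency: float
    sampling_frequency: float
    sound_speed: float = 1540.0

    def __post_init__(self) -> None:
        ex = np.asarray(self.element_x, dtype=float)
        object.__setattr__(self, "element_x", ex)
        if ex.ndim != 1 or ex.size < 2:
            raise ValueError("need at least 2 elements on one lateral axis")
        d = np.diff(ex)
        if np.any(d <= 0):
            raise ValueError("element_x must be strictly increasing")
        if np.ptp(d) > 1e-9:
            raise ValueError("element_x must be uniformly spaced (within 1e-9 m)")
        if self.center_frequency <= 0 or self.sampling_frequency <= 0:
            raise ValueError("frequencies must be positive")
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")

    @property
    def n_elements(self) -> int:
        return int(self.element_x.size)

    @property
    def pitch(self) -> float:
        return float(self.element_x[1] - self.element_x[0])

    @property
    def wavelength(self) -> float:
        return self.sound_speed / self.center_frequency

    @classmethod
    def linear(
        cls,
        n_elements: int = 128,
        pitch: float = 0.3e-3,
        center_frequency: float = 5.2e6,
        sampling_frequency: float = 20.8e6,
        sound_speed: float = 1540.0,
    ) -> "TransducerGeometry":
        """Centered uniform linear array (defaults: the PICMUS L11-type probe)."""
        ex = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
        return cls(ex, center_frequency, sampling_frequency, sound_speed)


@dataclass(frozen=True)
class PlaneWaveSequence:
    """Ordered set of plane-wave transmit angles with per-angle start times."""

    angles: np.ndarray  # radians, ascending
    t0: np.ndarray | None = None  # seconds, time of first recorded sample

    def __post_init__(self) -> None:
        ang = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if ang.size < 1:
            raise ValueError("need at least one transmit angle")
        if np.any(np.diff(ang) < 0):
            raise ValueError("angles must be sorted ascending")
        if np.any(np.abs(ang) >= np.pi / 2):
            raise ValueError("angles must lie inside (-pi/2, pi/2)")
        t0 = self.t0
        if t0 is None:
            t0 = np.zeros(ang.size)
        else:
            t0 = np.broadcast_to(np.asarray(t0, dtype=float), (ang.size,)).copy()
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "t0", t0)

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @classmethod
    def symmetric(cls, n_angles: int, max_angle_deg: float) -> "PlaneWaveSequence":
        """``n_angles`` equally spaced angles spanning +-``max_angle_deg``."""
        if n_angles == 1:
            ang = np.zeros(1)
        else:
            ang = np.linspace(-max_angle_deg, max_angle_deg, n_angles)
        return cls(np.deg2rad(ang))


@dataclass
class AnalyticDataCube:
    """Complex channel data indexed (transmit angle, element, fast-time sample).

    ``demodulation_frequency`` is zero for analytic RF-band data; for
    baseband IQ data it holds the removed carrier so delay compensation can
    restore the carrier phase.
    """

    data: np.ndarray  # complex (M, N, n_samples)
    geometry: TransducerGeometry
    sequence: PlaneWaveSequence
    demodulation_frequency: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if not np.iscomplexobj(d):
            d = d.astype(complex)
        if d.ndim != 3:
            raise ValueError("data must be (n_angles, n_elements, n_samples)")
        if d.shape[0] != self.sequence.n_angles:
            raise ValueError("angle axis inconsistent with sequence")
        if d.shape[1] != self.geometry.n_elements:
            raise ValueError("element axis inconsistent with geometry")
        if not np.all(np.isfinite(d)):
            raise ValueError("channel data contains non-finite samples")
        self.data = d

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class PixelGrid:
    """Regular rectangular image grid; images on it are indexed ``[z, x]``."""

    lateral_x: np.ndarray
    axial_z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lateral_x", "axial_z"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, v)
            if v.size > 1:
                d = np.diff(v)
                if np.any(d <= 0) or np.ptp(d) > 1e-12 + 1e-9 * abs(d[0]):
                    raise ValueError(f"{name} must be regular and increasing")
        if np.any(self.axial_z <= 0):
            raise ValueError("axial_z must be positive (depth below the array)")

    @property
    def nx(self) -> int:
        return self.lateral_x.size

    @property
    def nz(self) -> int:
        return self.axial_z.size

    @property
    def dx(self) -> float:
        return float(self.lateral_x[1] - self.lateral_x[0]) if self.nx > 1 else 0.0

    @property
    def dz(self) -> float:
        return float(self.axial_z[1] - self.axial_z[0]) if self.nz > 1 else 0.0

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Z)`` arrays of shape ``(nz, nx)``."""
        return np.meshgrid(self.lateral_x, self.axial_z)

    @classmethod
    def regular(
        cls,
        x_range: tuple[float, float],
        z_range: tuple[float, float],
        dx: float,
        dz: float,
    ) -> "PixelGrid":
        return cls(
            np.arange(x_range[0], x_range[1] + dx / 2, dx),
            np.arange(z_range[0], z_range[1] + dz / 2, dz),
        )

    @classmethod
    def for_cube(
        cls,
        cube: AnalyticDataCube,
        x_range: tuple[float, float],
        z_range: tuple[float, float],
        lateral_fraction: float = 0.5,
        axial_samples: int = 1,
    ) -> "PixelGrid":
        """Default imaging grid: ``lateral_fraction`` wavelengths laterally and
        ``axial_samples`` two-way RF sample intervals axially."""
        geom = cube.geometry
        dx = lateral_fraction * geom.wavelength
        dz = axial_samples * geom.sound_speed / (2.0 * geom.sampling_frequency)
        return cls.regular(x_range, z_range, dx, dz)


def analytic_signal(rf: np.ndarray, axis: int = -1) -> np.ndarray:
    """Analytic signal along ``axis``: real part is the input, imaginary part
    its quadrature (Hilbert transform)."""
    rf = np.asarray(rf, dtype=float)
    if rf.shape[axis] < 8:
        raise ValueError("fast-time axis too short for analytic conversion (< 8)")
    if not np.all(np.isfinite(rf)):
        raise ValueError("non-finite samples in RF data")
    return hilbert(rf, axis=axis)


def to_analytic(
    rf_cube: np.ndarray,
    geometry: TransducerGeometry,
    sequence: PlaneWaveSequence,
) -> AnalyticDataCube:
    """Convert a real RF cube (angle, element, sample) to an analytic cube."""
    return AnalyticDataCube(analytic_signal(rf_cube, axis=-1), geometry, sequence)


def tx_delay(angle: float, x, z, c: float):
    """One-way plane-wave arrival time at pixel ``(x, z)`` for transmit
    ``angle``, with the wavefront crossing the array center at t = 0:
    ``(z cos(angle) + x sin(angle)) / c``."""
    return (np.asarray(z) * np.cos(angle) + np.asarray(x) * np.sin(angle)) / c


def rx_delay(element_x, x, z, c: float):
    """One-way return time from pixel ``(x, z)`` to an element at
    ``element_x``: ``sqrt(z^2 + (x - element_x)^2) / c``."""
    x = np.asarray(x)
    z = np.asarray(z)
    return np.sqrt(z * z + (x - element_x) ** 2) / c


def rx_aperture_mask(x, z, geometry: TransducerGeometry, f_number: float) -> np.ndarray:
    """Dynamic receive-aperture mask: element ``j`` is active iff
    ``|element_x[j] - x| <= z / (2 f_number)``, with the two elements nearest
    the pixel always kept active so every pixel has a usable aperture.

    ``x`` and ``z`` may be arrays (broadcast together); the mask gains a
    trailing element axis of length N.
    """
    if f_number <= 0:
        raise ValueError("f_number must be positive")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    x, z = np.broadcast_arrays(x, z)
    ex = geometry.element_x
    dist = np.abs(ex - x[..., None])
    mask = dist <= z[..., None] / (2.0 * f_number) + 1e-12
    nearest2 = np.argsort(dist, axis=-1)[..., :2]
    np.put_along_axis(mask, nearest2, True, axis=-1)
    return mask


def sample_linear(signal: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of a 1-D (complex) signal at fractional sample
    positions ``pos``; positions outside ``[0, n-1]`` contribute exact zeros."""
    signal = np.asarray(signal)
    pos = np.asarray(pos, dtype=float)
    n = signal.shape[0]
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    in0 = (i0 >= 0) & (i0 <= n - 1)
    in1 = (i0 + 1 >= 0) & (i0 + 1 <= n - 1)
    v0 = np.where(in0, signal[np.clip(i0, 0, n - 1)], 0)
    v1 = np.where(in1, signal[np.clip(i0 + 1, 0, n - 1)], 0)
    return v0 * (1.0 - frac) + v1 * frac


@dataclass
class EchoMatrix:
    """Per-pixel M x N matrix of time-compensated complex data
    (transmit angles x receive elements), with the receive-aperture mask.

    Masked-out entries are exactly zero.  ``out_of_window`` flags a pixel
    whose delays all fell outside the recorded time window.
    """

    values: np.ndarray  # complex (M, N)
    rx_mask: np.ndarray  # bool (N,)
    out_of_window: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        m = np.asarray(self.rx_mask, dtype=bool)
        if v.ndim != 2 or m.shape != (v.shape[1],):
            raise ValueError("values must be (M, N) with rx_mask of length N")
        if m.sum() < 2:
            raise ValueError("at least 2 active elements required")
        if np.any(v[:, ~m] != 0):
            raise ValueError("masked-out entries must be exactly zero")
        self.values = v
        self.rx_mask = m

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_elements(self) -> int:
        return self.values.shape[1]


def build_echo_matrix(
    cube: AnalyticDataCube,
    pixel: tuple[float, float],
    f_number: float = 1.75,
) -> EchoMatrix:
    """Time-compensate the cube at one pixel into an M x N echo matrix.

    Entry ``(i, j)`` is the complex channel sample of angle ``i`` / element
    ``j`` linearly interpolated at the two-way delay of the pixel, zero where
    the delay falls outside the recorded window, and zero outside the dynamic
    receive aperture.
    """
    x, z = pixel
    if z <= 0:
        raise ValueError("pixel depth must be positive")
    geom, seq = cube.geometry, cube.sequence
    c = geom.sound_speed
    fs = geom.sampling_frequency
    mask = rx_aperture_mask(x, z, geom, f_number)
    values = np.zeros((seq.n_angles, geom.n_elements), dtype=complex)
    trx = rx_delay(geom.element_x, x, z, c)  # (N,)
    any_in = False
    for i in range(seq.n_angles):
        tau = tx_delay(seq.angles[i], x, z, c) + trx
        pos = (tau - seq.t0[i]) * fs
        row = np.empty(geom.n_elements, dtype=complex)
        for j in range(geom.n_elements):
            row[j] = sample_linear(cube.data[i, j], pos[j])
        if cube.demodulation_frequency:
            row = row * np.exp(2j * np.pi * cube.demodulation_frequency * tau)
        any_in = any_in or bool(np.any((pos >= 0) & (pos <= cube.n_samples - 1)))
        values[i] = row
    values[:, ~mask] = 0.0
    out = not any_in
    if out:
        warnings.warn("pixel delays entirely outside the recorded window; zero matrix")
    return EchoMatrix(values, mask, out_of_window=out)
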