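"""Synthetic plane-wave channel-data simulator.

Single-scattering superposition model: each scatterer contributes a
windowed 2.5-cycle tone to every (angle, element) channel at the exact
two-way geometric delay, using the same delay convention as the
beamformers (plane wavefront through the array center at t = 0).  No
attenuation, dispersion, element directivity or multiple scattering; an
optional additive white Gaussian noise floor emulates thermal noise.

Phantom builders cover the three structures the reconstruction chain
assumes: isolated point targets on a grid, diffuse speckle backgrounds
(uniformly placed scatterers with unit-variance Gaussian amplitudes), and
circular inclusions that are anechoic (scatterers removed) or hyperechoic
(amplitudes scaled up).

The reduced default scale for fast in-memory studies is a 64-element array
with 15 angles spanning +-7.5 degrees; the full 128-element / 75-angle
PICMUS scale runs through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AnalyticDataCube,
    PlaneWaveSequence,
    TransducerGeometry,
    rx_delay,
    to_analytic,
    tx_delay,
)

__all__ = [
    "Phantom",
    "PulseModel",
    "CystSpec",
    "make_point_phantom",
    "make_cyst_phantom",
    "scatterers_for_density",
    "simulate_cube",
    "reduced_geometry",
    "reduced_sequence",
]


@dataclass
class Phantom:
    """Point-scatterer collection: positions in meters, real amplitudes."""

    x: np.ndarray
    z: np.ndarray
    amplitude: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        self.amplitude = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        if not (self.x.shape == self.z.shape == self.amplitude.shape):
            raise ValueError("x, z, amplitude must have equal shapes")
        if self.z.size and np.any(self.z <= 0):
            raise ValueError("scatterer depths must be positive")

    @property
    def n_scatterers(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class PulseModel:
    """Windowed sinusoidal transmit pulse."""

    center_frequency: float = 5.2e6
    n_cycles: float = 2.5
    envelope: str = "hann"

    def __post_init__(self) -> None:
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if self.envelope not in ("hann", "rect"):
            raise ValueError("envelope must be 'hann' or 'rect'")

    @property
    def duration(self) -> float:
        return self.n_cycles / self.center_frequency

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Pulse amplitude at times ``t`` relative to the arrival time; the
        envelope is centered on t = 0 so the envelope peak of a scatterer
        coincides with its geometric delay."""
        t = np.asarray(t, dtype=float)
        half = self.duration / 2.0
        inside = np.abs(t) <= half
        carrier = np.sin(2 * np.pi * self.center_frequency * t)
        if self.envelope == "hann":
            win = np.cos(np.pi * t / self.duration) ** 2
        else:
            win = 1.0
        return np.where(inside, carrier * win, 0.0)


@dataclass(frozen=True)
class CystSpec:
    """Circular inclusion: ``level`` 0 is anechoic, > 1 hyperechoic."""

    x: float
    z: float
    radius: float
    level: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.level < 0:
            raise ValueError("level must be >= 0")


def reduced_geometry(n_elements: int = 64) -> TransducerGeometry:
    """The reduced-scale study array: PICMUS-type probe with fewer elements."""
    return TransducerGeometry.linear(n_elements=n_elements)


def reduced_sequence(n_angles: int = 15, max_angle_deg: float = 7.5) -> PlaneWaveSequence:
    """The reduced-scale angle set: 15 plane waves spanning +-7.5 degrees."""
    return PlaneWaveSequence.symmetric(n_angles, max_angle_deg)


def make_point_phantom(
    z_range: tuple[float, float] = (10e-3, 45e-3),
    x_range: tuple[float, float] = (-15e-3, 15e-3),
    spacing: float = 5e-3,
    cross_depths: tuple[float, ...] = (20e-3, 40e-3),
    positions: list[tuple[float, float]] | None = None,
) -> Phantom:
    """Unit-amplitude point targets.

    The default layout is a central axial column from 10 to 45 mm plus two
    lateral rows at the ``cross_depths``, every point 5 mm from its
    neighbors, 20 points in total spanning -15..15 mm laterally.  Pass
    ``positions`` for an explicit list of (x, z) targets instead."""
    if positions is not None:
        xs = np.array([p[0] for p in positions])
        zs = np.array([p[1] for p in positions])
    else:
        col_z = np.arange(z_range[0], z_range[1] + spacing / 2, spacing)
        xs_list = [np.zeros_like(col_z)]
        zs_list = [col_z]
        row_x = np.arange(x_range[0], x_range[1] + spacing / 2, spacing)
        row_x = row_x[np.abs(row_x) > spacing / 2]  # column already covers x=0
        for zd in cross_depths:
            xs_list.append(row_x)
            zs_list.append(np.full_like(row_x, zd))
        xs = np.concatenate(xs_list)
        zs = np.concatenate(zs_list)
    return Phantom(xs, zs, np.ones_like(xs), label="points")


def scatterers_for_density(
    geometry: TransducerGeometry,
    x_range: tuple[float, float],
    z_range: tuple[float, float],
    per_cell: float = 5.0,
    n_cycles: float = 2.5,
) -> int:
    """Scatterer count giving ``per_cell`` scatterers per resolution cell.

    The cell is estimated as (lateral beamwidth at mid depth) x (axial pulse
    length / 2) for the full aperture."""
    lam = geometry.wavelength
    aperture = geometry.element_x[-1] - geometry.element_x[0]
    z_mid = 0.5 * (z_range[0] + z_range[1])
    lateral = lam * z_mid / aperture
    axial = n_cycles * lam / 2.0
    area = (x_range[1] - x_range[0]) * (z_range[1] - z_range[0])
    return int(np.ceil(per_cell * area / (lateral * axial)))


def make_cyst_phantom(
    x_range: tuple[float, float] = (-6e-3, 6e-3),
    z_range: tuple[float, float] = (20e-3, 30e-3),
    cysts: tuple[CystSpec, ...] = (CystSpec(0.0, 25e-3, 2.5e-3),),
    n_scatterers: int | None = None,
    seed: int = 0,
    per_cell: float = 10.0,
    geometry: TransducerGeometry | None = None,
) -> Phantom:
    """Diffuse speckle background with circular inclusions.

    Scatterers are uniform in the rectangle with unit-variance Gaussian
    amplitudes; scatterers inside an anechoic cyst (level 0) are removed,
    inside a hyperechoic one their amplitude is multiplied by the level.
    When ``n_scatterers`` is not given it is chosen for ``per_cell``
    scatterers per resolution cell of ``geometry`` (default: the reduced
    study array).  Deterministic given the seed."""
    if n_scatterers is None:
        n_scatterers = scatterers_for_density(
            geometry or reduced_geometry(), x_range, z_range, per_cell
        )
    rng = np.random.default_rng(seed)
    xs = rng.uniform(x_range[0], x_range[1], n_scatterers)
    zs = rng.uniform(z_range[0], z_range[1], n_scatterers)
    amp = rng.standard_normal(n_scatterers)
    keep = np.ones(n_scatterers, dtype=bool)
    for cyst in cysts:
        inside = (xs - cyst.x) ** 2 + (zs - cyst.z) ** 2 <= cyst.radius**2
        if cyst.level == 0.0:
            keep &= ~inside
        else:
            amp[inside] *= cyst.level
    return Phantom(xs[keep], zs[keep], amp[keep], label="cysts")


def simulate_cube(
    phantom: Phantom,
    geometry: TransducerGeometry,
    sequence: PlaneWaveSequence,
    pulse: PulseModel | None = None,
    noise_db: float | None = None,
    seed: int = 0,
    max_depth: float | None = None,
) -> AnalyticDataCube:
    """Simulate an analytic channel-data cube for a phantom.

    Each scatterer adds ``amplitude * pulse(t - tau_tx - tau_rx)`` to every
    (angle, element) channel; ``noise_db`` adds white Gaussian noise that
    many dB below the peak RF amplitude.  Deterministic given the seed."""
    pulse = pulse or PulseModel(center_frequency=geometry.center_frequency)
    fs = geometry.sampling_frequency
    c = geometry.sound_speed
    if fs <= 2 * pulse.center_frequency:
        raise ValueError("sampling below Nyquist for the pulse center frequency")
    if phantom.n_scatterers == 0 and noise_db is None:
        raise ValueError("empty phantom with no noise produces no data")

    M, N = sequence.n_angles, geometry.n_elements
    if max_depth is None:
        max_depth = float(phantom.z.max()) if phantom.n_scatterers else 40e-3
    t_max = 2.0 * max_depth * 1.05 / c + pulse.duration / 2.0
    n_samples = int(np.ceil(t_max * fs)) + 4
    if n_samples < 8:
        n_samples = 8
    rf = np.zeros((M, N, n_samples))

    if phantom.n_scatterers:
        K = int(np.ceil(pulse.duration * fs)) + 2
        k = np.arange(K)
        trx = rx_delay(
            geometry.element_x[None, :], phantom.x[:, None], phantom.z[:, None], c
        )  # (S, N)
        elem_base = np.arange(N) * n_samples
        for i in range(M):
            ttx = tx_delay(sequence.angles[i], phantom.x, phantom.z, c)  # (S,)
            tau = ttx[:, None] + trx - sequence.t0[i]  # (S, N)
            # first sample inside the centered pulse support
            s0 = np.ceil((tau - pulse.duration / 2.0) * fs).astype(np.int64)
            t_rel = (s0[..., None] + k) / fs - tau[..., None]  # (S, N, K)
            vals = phantom.amplitude[:, None, None] * pulse.waveform(t_rel)
            idx = s0[..., None] + k + elem_base[None, :, None]
            if s0.min() >= 0 and s0.max() + K <= n_samples:
                flat_idx, flat_vals = idx.ravel(), vals.ravel()
            else:
                ok = (s0[..., None] + k >= 0) & (s0[..., None] + k < n_samples)
                flat_idx, flat_vals = idx[ok].ravel(), vals[ok].ravel()
            rf[i] += np.bincount(
                flat_idx, weights=flat_vals, minlength=N * n_samples
            ).reshape(N, n_samples)

    if noise_db is not None:
        rng = np.random.default_rng(seed)
        peak = np.abs(rf).max() if np.abs(rf).max() > 0 else 1.0
        sigma = peak * 10 ** (-noise_db / 20.0)
        rf += rng.normal(0.0, sigma, rf.shape)

    return to_analytic(rf, geometry, sequence)
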