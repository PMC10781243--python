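"""Whole-image plane-wave beamformers.

Every beamformer maps an analytic channel-data cube and a pixel grid to a
complex image.  The implementations are batched over the grid: per-angle
delayed channel stacks are built once and the per-pixel minimum-variance
solves run as batched Hermitian solves, but pixel values are identical to
evaluating the per-pixel definitions one at a time.

Methods
-------
``cpwc``       coherent plane-wave compounding (delay-and-sum reference)
``rxmv``       MV over the receive-channel array V(n) within the dynamic
               aperture, subarray length one third of the active aperture
``txmv``       MV over the transmit-angle array Z(n) with spatial, temporal
               and forward-backward covariance averaging
``dcr-mvdr``   full-size MV whose covariance snapshots are leave-one-channel-
               out compoundings of the 2D echo matrix (comparison method)
``txmv-dmas``  TxMV on p-th-root magnitude-scaled data with p-th-power
               restoration of signal dimensionality (coherence imaging)
``tx-dmas``    the MV-free variant: uniform compounding of the scaled data
``txmv-admas`` TxMV-DMAS with a pixel-wise adaptive coherence order p
               (implemented in :mod:`pwbeam.admas`, registered here)

The temporal-averaging window is expressed in axial *pixels*; with the
default grid (one RF sample per axial pixel) this coincides with fast-time
samples, and :func:`axial_halfwidth` converts the 5.4-wavelength rule to the
grid actually in use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import (
    AnalyticDataCube,
    PixelGrid,
    rx_aperture_mask,
    rx_delay,
    sample_linear,
    tx_delay,
)
from .mv_core import temporal_halfwidth

__all__ = [
    "BeamformedImage",
    "DmasParams",
    "BEAMFORMERS",
    "get_beamformer",
    "axial_halfwidth",
    "aperture_masks",
    "delayed_channel_stack",
    "tx_angle_stack",
    "rx_channel_stack",
    "echo_matrix_stack",
    "dcr_snapshots",
    "dmas_root_scale",
    "beamform_cpwc",
    "beamform_rxmv",
    "beamform_txmv",
    "beamform_dcr_mvdr",
    "beamform_txmv_dmas",
    "beamform_tx_dmas",
]


@dataclass
class BeamformedImage:
    """Complex pixel grid with envelope/log views and a parameter record."""

    data: np.ndarray  # complex (nz, nx)
    grid: PixelGrid
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=complex)
        if d.shape != (self.grid.nz, self.grid.nx):
            raise ValueError("image shape inconsistent with grid")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite pixel values")
        self.data = d

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class DmasParams:
    """Coherence order for DMAS: a scalar or a per-pixel map, everywhere >= 1."""

    p: float | np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.p) < 1):
            raise ValueError("coherence order p must be >= 1 everywhere")


def axial_halfwidth(cube: AnalyticDataCube, grid: PixelGrid, n_wavelengths: float = 5.4) -> int:
    """Temporal half-window in axial pixels equivalent to the
    ``n_wavelengths`` fast-time rule on this grid."""
    g = cube.geometry
    T_samp = temporal_halfwidth(g.sampling_frequency, g.center_frequency, n_wavelengths)
    dz_samp = g.sound_speed / (2.0 * g.sampling_frequency)
    if grid.nz < 2 or grid.dz <= 0:
        return 0
    return max(0, int(round(T_samp * dz_samp / grid.dz)))


# ---------------------------------------------------------------------------
# delayed data stacks
# ---------------------------------------------------------------------------

def aperture_masks(grid: PixelGrid, geometry, f_number: float):
    """Dynamic-aperture mask (nz, nx, N) and active-element counts (nz, nx)."""
    X, Z = grid.meshgrid()
    mask = rx_aperture_mask(X, Z, geometry, f_number)
    return mask, mask.sum(axis=-1)


def delayed_channel_stack(cube: AnalyticDataCube, grid: PixelGrid, angle_index: int) -> np.ndarray:
    """Per-pixel time-compensated channel data (nz, nx, N) for one transmit
    angle, zero where the delay falls outside the recorded window."""
    geom, seq = cube.geometry, cube.sequence
    c, fs = geom.sound_speed, geom.sampling_frequency
    X, Z = grid.meshgrid()
    t_tx = tx_delay(seq.angles[angle_index], X, Z, c)
    out = np.empty((grid.nz, grid.nx, geom.n_elements), dtype=complex)
    fd = cube.demodulation_frequency
    for j in range(geom.n_elements):
        tau = t_tx + rx_delay(geom.element_x[j], X, Z, c)
        pos = (tau - seq.t0[angle_index]) * fs
        vals = sample_linear(cube.data[angle_index, j], pos)
        if fd:
            vals = vals * np.exp(2j * np.pi * fd * tau)
        out[:, :, j] = vals
    return out


def tx_angle_stack(cube: AnalyticDataCube, grid: PixelGrid, f_number: float = 1.75) -> np.ndarray:
    """Transmit-angle array Z(n) for every pixel: (nz, nx, M), where entry i
    is the mean over active receive channels at angle i."""
    mask, counts = aperture_masks(grid, cube.geometry, f_number)
    Zs = np.empty((grid.nz, grid.nx, cube.n_angles), dtype=complex)
    for i in range(cube.n_angles):
        D = delayed_channel_stack(cube, grid, i)
        Zs[:, :, i] = np.where(mask, D, 0.0).sum(axis=-1) / counts
    return Zs


def rx_channel_stack(cube: AnalyticDataCube, grid: PixelGrid, f_number: float = 1.75):
    """Receive-channel array V(n) for every pixel: (nz, nx, N) plus the
    aperture mask; entry j is the mean over all M angles, zero outside the
    aperture."""
    mask, _ = aperture_masks(grid, cube.geometry, f_number)
    Vs = np.zeros((grid.nz, grid.nx, cube.geometry.n_elements), dtype=complex)
    for i in range(cube.n_angles):
        Vs += delayed_channel_stack(cube, grid, i)
    Vs /= cube.n_angles
    Vs[~mask] = 0.0
    return Vs, mask


def echo_matrix_stack(cube: AnalyticDataCube, grid: PixelGrid, f_number: float = 1.75):
    """Full echo matrices for every pixel: (nz, nx, M, N) plus the mask.
    Memory scales with nz*nx*M*N; intended for the full-matrix (DCR) method
    on moderate grids."""
    mask, _ = aperture_masks(grid, cube.geometry, f_number)
    Xs = np.empty((grid.nz, grid.nx, cube.n_angles, cube.geometry.n_elements), dtype=complex)
    for i in range(cube.n_angles):
        Xs[:, :, i, :] = delayed_channel_stack(cube, grid, i)
    Xs[~mask[:, :, None, :].repeat(cube.n_angles, axis=2)] = 0.0
    return Xs, mask


# ---------------------------------------------------------------------------
# batched MV machinery
# ---------------------------------------------------------------------------

def _axial_box_mean(C: np.ndarray, T: int) -> np.ndarray:
    """Mean of C over a +-T window along axis 0, truncated at the edges with
    normalization by the actual count (unbiased covariance scale)."""
    if T <= 0:
        return C
    nz = C.shape[0]
    cs = np.concatenate([np.zeros((1,) + C.shape[1:], C.dtype), np.cumsum(C, axis=0)])
    idx = np.arange(nz)
    lo = np.maximum(idx - T, 0)
    hi = np.minimum(idx + T, nz - 1)
    sums = cs[hi + 1] - cs[lo]
    counts = (hi - lo + 1).reshape((nz,) + (1,) * (C.ndim - 1))
    return sums / counts


def _fb_batched(C: np.ndarray) -> np.ndarray:
    """Forward-backward averaging on a (..., L, L) batch."""
    return 0.5 * (C + np.swapaxes(C[..., ::-1, ::-1], -1, -2))


def _batched_weights(C: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal-load and solve the MV program on a (..., L, L) batch.

    Returns ``(w, dead)`` where ``dead`` marks pixels whose covariance had
    zero trace (identically zero data); their weights are uniform and the
    caller zeroes the output.
    """
    L = C.shape[-1]
    tr = np.einsum("...ll->...", C).real
    dead = tr <= 0.0
    load = delta * tr / L
    C = C + (load[..., None, None] + dead[..., None, None]) * np.eye(L)
    try:
        y = np.linalg.solve(C, np.ones(C.shape[:-1] + (1,)))[..., 0]
    except np.linalg.LinAlgError:
        # isolated singular pixels: fall back per pixel
        flat = C.reshape(-1, L, L)
        y = np.empty((flat.shape[0], L), dtype=complex)
        for k in range(flat.shape[0]):
            try:
                y[k] = np.linalg.solve(flat[k], np.ones(L))
            except np.linalg.LinAlgError:
                y[k] = np.ones(L)
        y = y.reshape(C.shape[:-1])
    s = y.sum(axis=-1)
    bad = ~np.isfinite(s) | (np.abs(s) < 1e-300)
    if np.any(bad):
        y = np.where(bad[..., None], 1.0, y)
        s = np.where(bad, L, s)
    return y / s[..., None], dead


def _restore_power(y: np.ndarray, p) -> np.ndarray:
    """|y|^p with the phase of y preserved (p-th-power restoration)."""
    return np.abs(y) ** p * np.exp(1j * np.angle(y))


def _root_scale_array(z: np.ndarray, p) -> np.ndarray:
    """|z|^(1/p) with the phase of z preserved; zero maps to zero."""
    return np.abs(z) ** (1.0 / np.asarray(p)) * np.exp(1j * np.angle(z))


def dmas_root_scale(Z, p: float):
    """p-th-root magnitude scaling of a transmit-angle array, phase kept."""
    from .arrays import TxAngleArray

    if np.any(np.asarray(p) < 1):
        raise ValueError("p must be >= 1")
    if isinstance(Z, TxAngleArray):
        return TxAngleArray(_root_scale_array(Z.z_values, p))
    return _root_scale_array(np.asarray(Z, dtype=complex), p)


def _txmv_images(
    Zs: np.ndarray,
    L: int,
    T: int,
    delta: float,
    p=None,
    forward_backward: bool = True,
) -> np.ndarray:
    """Shared TxMV / TxMV-DMAS pipeline on a (nz, nx, M) angle-array stack.

    ``p`` is None for plain MV, or a scalar / (nz, nx) map for DMAS: the
    stack is p-th-root scaled before covariance estimation and each subarray
    output is p-th-power restored before the subarray mean.
    """
    nz, nx, M = Zs.shape
    if L > M:
        raise ValueError(f"subarray length {L} exceeds the number of angles {M}")
    if p is not None:
        pmap = np.asarray(p, dtype=float)
        if pmap.ndim == 2:
            pmap = pmap[..., None]
        Zs = _root_scale_array(Zs, pmap)
    sub = sliding_window_view(Zs, L, axis=2)  # (nz, nx, K, L)
    C = np.einsum("zxkl,zxkm->zxlm", sub, sub.conj()) / sub.shape[2]
    C = _axial_box_mean(C, T)
    if forward_backward:
        C = _fb_batched(C)
    w, dead = _batched_weights(C, delta)
    yk = np.einsum("zxl,zxkl->zxk", w.conj(), sub)
    if p is not None:
        pk = pmap if np.ndim(p) else float(p)
        yk = _restore_power(yk, pk)
    y = yk.mean(axis=2)
    y[dead] = 0.0
    return y


# ---------------------------------------------------------------------------
# public beamformers
# ---------------------------------------------------------------------------

def beamform_cpwc(cube: AnalyticDataCube, grid: PixelGrid, f_number: float = 1.75) -> BeamformedImage:
    """Coherent plane-wave compounding: uniform mean of the angle array."""
    Zs = tx_angle_stack(cube, grid, f_number)
    return BeamformedImage(Zs.mean(axis=2), grid, "cpwc", {"f_number": f_number})


def beamform_txmv(
    cube: AnalyticDataCube,
    grid: PixelGrid,
    f_number: float = 1.75,
    L: int = 25,
    T: int | None = None,
    delta: float = 0.1,
) -> BeamformedImage:
    """MV beamforming in the transmit-angle dimension with spatial,
    temporal and forward-backward covariance averaging."""
    if T is None:
        T = axial_halfwidth(cube, grid)
    Zs = tx_angle_stack(cube, grid, f_number)
    y = _txmv_images(Zs, L, T, delta)
    return BeamformedImage(
        y, grid, "txmv", {"f_number": f_number, "L": L, "T": T, "delta": delta}
    )


def beamform_txmv_dmas(
    cube: AnalyticDataCube,
    grid: PixelGrid,
    f_number: float = 1.75,
    p: float | np.ndarray = 2.0,
    L: int = 25,
    T: int | None = None,
    delta: float = 0.1,
) -> BeamformedImage:
    """TxMV on p-th-root magnitude-scaled angle data; each subarray dot
    product is restored by the p-th power (magnitude-wise, phase preserved)
    before the subarray mean.  ``p`` may be a per-pixel map."""
    DmasParams(p)
    if T is None:
        T = axial_halfwidth(cube, grid)
    Zs = tx_angle_stack(cube, grid, f_number)
    y = _txmv_images(Zs, L, T, delta, p=p)
    rec = {"f_number": f_number, "L": L, "T": T, "delta": delta,
           "p": "map" if np.ndim(p) else float(p)}
    return BeamformedImage(y, grid, "txmv-dmas", rec)


def beamform_tx_dmas(
    cube: AnalyticDataCube,
    grid: PixelGrid,
    f_number: float = 1.75,
    p: float | np.ndarray = 2.0,
) -> BeamformedImage:
    """MV-free coherence imaging: p-th-root scaling, uniform compounding of
    the angle array, p-th-power restoration.  p = 1 is exactly CPWC."""
    DmasParams(p)
    Zs = tx_angle_stack(cube, grid, f_number)
    pmap = np.asarray(p, dtype=float)
    scale_p = pmap[..., None] if pmap.ndim == 2 else pmap
    m = _root_scale_array(Zs, scale_p).mean(axis=2)
    y = _restore_power(m, pmap)
    rec = {"f_number": f_number, "p": "map" if np.ndim(p) else float(p)}
    return BeamformedImage(y, grid, "tx-dmas", rec)


def beamform_rxmv(
    cube: AnalyticDataCube,
    grid: PixelGrid,
    f_number: float = 1.75,
    delta: float = 0.1,
    L: int | None = None,
) -> BeamformedImage:
    """MV beamforming in the receive-channel dimension.

    Channel data outside the dynamic aperture are excluded; the subarray
    length is one third of the active aperture (minimum 2) unless ``L`` is
    forced.  No temporal averaging (the aperture changes with depth)."""
    Vs, mask = rx_channel_stack(cube, grid, f_number)
    y = _rxmv_rows(Vs, mask, delta, L)
    return BeamformedImage(
        y, grid, "rxmv", {"f_number": f_number, "delta": delta, "L": L or "N/3"}
    )


def _rxmv_rows(Vs: np.ndarray, mask: np.ndarray, delta: float, L: int | None) -> np.ndarray:
    """Per-pixel RxMV evaluation: forward covariance over channel subarrays,
    FB averaging, loading, then the subarray mean with MV weights.  The
    subarray length follows the aperture pixel by pixel, so this path stays
    a scalar loop; grids for RxMV should be kept moderate."""
    nz, nx, _ = Vs.shape
    y = np.zeros((nz, nx), dtype=complex)
    for iz in range(nz):
        for ix in range(nx):
            v = Vs[iz, ix, mask[iz, ix]]
            na = v.size
            Lp = max(2, na // 3) if L is None else max(1, min(L, na))
            sub = sliding_window_view(v, Lp)
            C = (sub.T @ sub.conj()) / sub.shape[0]
            tr = np.trace(C).real
            if tr <= 0.0:
                continue
            C = 0.5 * (C + C[::-1, ::-1].T)
            C = C + (delta * tr / Lp) * np.eye(Lp)
            try:
                w0 = np.linalg.solve(C, np.ones(Lp))
            except np.linalg.LinAlgError:
                w0 = np.ones(Lp)
            s = w0.sum()
            if not np.isfinite(s) or abs(s) < 1e-300:
                w0, s = np.ones(Lp), Lp
            y[iz, ix] = (sub @ (w0 / s).conj()).mean()
    return y


def dcr_snapshots(X: np.ndarray, rx_mask: np.ndarray) -> np.ndarray:
    """Leave-one-channel-out transmit vectors from one echo matrix.

    For each active channel j, the snapshot is the mean over the remaining
    active channels of the M x N matrix, a length-M vector; the stack of all
    active-channel snapshots feeds the full-size covariance estimate."""
    X = np.asarray(X, dtype=complex)
    m = np.asarray(rx_mask, dtype=bool)
    na = int(m.sum())
    if na < 2:
        raise ValueError("need at least 2 active channels")
    Xa = X[:, m]  # (M, na)
    S = Xa.sum(axis=1, keepdims=True)
    return ((S - Xa) / (na - 1)).T  # (na, M)


def beamform_dcr_mvdr(
    cube: AnalyticDataCube,
    grid: PixelGrid,
    f_number: float = 1.75,
    delta: float = 1.0,
) -> BeamformedImage:
    """Full-size MV without subarray averaging (comparison method).

    Covariance snapshots are leave-one-channel-out compoundings of the 2D
    echo matrix; weights from the loaded M x M covariance are applied to the
    fully compounded transmit vector.  Memory scales with nz*nx*M*N."""
    Xs, mask = echo_matrix_stack(cube, grid, f_number)
    cnt = mask.sum(axis=-1)  # (nz, nx) -- >= 2 by the aperture contract
    S = Xs.sum(axis=-1)  # (nz, nx, M)
    Tj = (S[..., None] - Xs) / (cnt[..., None, None] - 1)
    Tj = np.where(mask[:, :, None, :], Tj, 0.0)
    R = np.einsum("zxmj,zxnj->zxmn", Tj, Tj.conj()) / cnt[..., None, None]
    w, dead = _batched_weights(R, delta)
    Zfull = S / cnt[..., None]
    y = np.einsum("zxm,zxm->zx", w.conj(), Zfull)
    y[dead] = 0.0
    return BeamformedImage(y, grid, "dcr-mvdr", {"f_number": f_number, "delta": delta})


def _admas_entry(cube, grid, f_number: float = 1.75, **kw) -> BeamformedImage:
    from .admas import beamform_txmv_admas

    img, _ = beamform_txmv_admas(cube, grid, f_number=f_number, **kw)
    return img


BEAMFORMERS: dict[str, Callable[..., BeamformedImage]] = {
    "cpwc": beamform_cpwc,
    "rxmv": beamform_rxmv,
    "txmv": beamform_txmv,
    "dcr-mvdr": beamform_dcr_mvdr,
    "txmv-dmas": beamform_txmv_dmas,
    "tx-dmas": beamform_tx_dmas,
    "txmv-admas": _admas_entry,
}


def get_beamformer(name: str) -> Callable[..., BeamformedImage]:
    try:
        return BEAMFORMERS[name]
    except KeyError:
        raise KeyError(
            f"unknown beamformer {name!r}; available: {sorted(BEAMFORMERS)}"
        ) from None
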