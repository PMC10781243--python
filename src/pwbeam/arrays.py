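"""Reductions of the per-pixel echo matrix.

The M x N echo matrix is compounded along one of its dimensions before
adaptive processing: summing over receive channels gives the transmit-angle
array Z(n) (one complex value per plane-wave angle, i.e. dynamic receive
focusing), while summing over transmit angles gives the receive-channel
array V(n) (synthetic transmit focusing).  Coherent plane-wave compounding
(CPWC) is the uniform-weight reduction of either array; both routes give the
same pixel value.

With a dynamic receive aperture the channel sum is taken as the mean over
*active* channels rather than a fixed 1/N, so border pixels with clipped
apertures are not dimmed by a depth-dependent factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import EchoMatrix

__all__ = ["TxAngleArray", "RxChannelArray", "channel_sum", "angle_sum", "cpwc_pixel"]


@dataclass
class TxAngleArray:
    """Length-M complex array: the echo matrix compounded over receive channels."""

    z_values: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=complex)
        if z.ndim != 1:
            raise ValueError("z_values must be 1-D")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite values")
        self.z_values = z

    @property
    def n_angles(self) -> int:
        return self.z_values.size


@dataclass
class RxChannelArray:
    """Length-N complex array: the echo matrix compounded over transmit angles."""

    v_values: np.ndarray
    rx_mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v_values, dtype=complex)
        m = np.asarray(self.rx_mask, dtype=bool)
        if v.shape != m.shape or v.ndim != 1:
            raise ValueError("v_values and rx_mask must be 1-D of equal length")
        if np.any(v[~m] != 0):
            raise ValueError("masked entries must be zero")
        self.v_values = v
        self.rx_mask = m


def channel_sum(X: EchoMatrix) -> TxAngleArray:
    """z_i = mean over active receive channels of row i of the echo matrix."""
    n_active = int(X.rx_mask.sum())
    if n_active == 0:
        raise ValueError("empty receive aperture")
    z = X.values[:, X.rx_mask].mean(axis=1)
    return TxAngleArray(z)


def angle_sum(X: EchoMatrix) -> RxChannelArray:
    """v_j = mean over all M transmit angles of column j of the echo matrix."""
    v = X.values.mean(axis=0)
    v = np.where(X.rx_mask, v, 0.0)
    return RxChannelArray(v, X.rx_mask.copy())


def cpwc_pixel(X: EchoMatrix) -> complex:
    """CPWC pixel value: uniform-weight mean of the transmit-angle array.

    Computed through both reduction routes (angle array and channel array);
    the two agree to floating precision by construction, which is asserted.
    """
    z = channel_sum(X).z_values
    via_z = z.mean()
    v = angle_sum(X)
    via_v = v.v_values[v.rx_mask].mean()
    scale = max(abs(via_z), 1e-300)
    if abs(via_z - via_v) > 1e-9 * scale:
        raise AssertionError("compounding routes disagree beyond tolerance")
    return complex(via_z)
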