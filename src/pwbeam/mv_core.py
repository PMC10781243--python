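"""Minimum-variance (Capon) estimation on compounded plane-wave data.

The MV weight vector minimizes output power subject to unity gain toward the
main lobe; because the data are already time-compensated per pixel, the
steering vector reduces to all ones.  Robust covariance estimation uses

* spatial (subarray) averaging over sliding length-L sub-vectors,
* optional temporal averaging over a window of 2T+1 depth samples,
* forward-backward averaging with the exchange matrix, and
* diagonal loading proportional to the trace.

Weights are obtained from a Hermitian linear solve of ``R w0 = a`` (never an
explicit inverse); a numerically singular covariance after loading falls
back to uniform weights with a warning so one dark pixel cannot abort an
image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubarrayConfig",
    "CovarianceMatrix",
    "MVWeights",
    "temporal_halfwidth",
    "covariance_forward",
    "fb_average",
    "diagonal_load",
    "mv_weights",
    "mv_output",
]


def temporal_halfwidth(
    sampling_frequency: float,
    center_frequency: float,
    n_wavelengths: float = 5.4,
) -> int:
    """Half-width T of the temporal averaging window, chosen so the full
    window 2T+1 spans about ``n_wavelengths`` periods of the carrier
    (21 samples, T = 10, at the 20.8 MHz / 5.2 MHz PICMUS rates)."""
    window = int(round(n_wavelengths * sampling_frequency / center_frequency))
    return max(0, (window - 1) // 2)


@dataclass(frozen=True)
class SubarrayConfig:
    """Covariance-estimation settings for one MV beamformer."""

    L: int  # subarray length
    T: int = 0  # temporal half-window in depth samples
    delta: float = 0.1  # diagonal-loading factor
    forward_backward: bool = True

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("subarray length L must be >= 1")
        if self.T < 0:
            raise ValueError("temporal half-window T must be >= 0")
        if self.delta < 0:
            raise ValueError("loading factor must be >= 0")


@dataclass
class CovarianceMatrix:
    """L x L Hermitian covariance estimate with bookkeeping."""

    R: np.ndarray
    n_subarrays: int
    loading_applied: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=complex)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")
        herm = np.abs(R - R.conj().T).max() if R.size else 0.0
        if herm > 1e-10 * max(1.0, np.abs(R).max()):
            raise ValueError("R must be Hermitian within 1e-10")
        self.R = R

    @property
    def L(self) -> int:
        return self.R.shape[0]


@dataclass
class MVWeights:
    """MV weight vector satisfying the unity-gain constraint w^H a = 1."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=complex)
        if w.ndim != 1:
            raise ValueError("w must be 1-D")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("distortionless constraint w^H a = 1 violated")
        self.w = w


def _as_family(vectors: np.ndarray) -> np.ndarray:
    v = np.asarray(vectors, dtype=complex)
    if v.ndim == 1:
        v = v[None, :]
    if v.ndim != 2:
        raise ValueError("expected a vector or a (samples, length) family")
    return v


def covariance_forward(
    vectors: np.ndarray,
    L: int,
    T: int = 0,
    center: int = 0,
) -> CovarianceMatrix:
    """Forward covariance: outer products averaged over all length-L sliding
    subarrays and over depth samples ``center - T .. center + T``.

    ``vectors`` is either one complex vector or a family ``(n_samples,
    length)`` indexed by depth sample; the temporal window is truncated at
    the edges of the family and the normalization uses the actual count.
    """
    fam = _as_family(vectors)
    S, n = fam.shape
    if L > n:
        raise ValueError(f"subarray length {L} exceeds vector length {n}")
    if not 0 <= center < S:
        raise ValueError("center sample outside the family")
    lo = max(0, center - T)
    hi = min(S - 1, center + T)
    K = n - L + 1
    R = np.zeros((L, L), dtype=complex)
    count = 0
    for t in range(lo, hi + 1):
        sub = np.lib.stride_tricks.sliding_window_view(fam[t], L)  # (K, L)
        R += sub.T @ sub.conj()
        count += K
    R /= count
    # enforce exact Hermitian symmetry against accumulation round-off
    R = 0.5 * (R + R.conj().T)
    return CovarianceMatrix(R, n_subarrays=count)


def fb_average(cov: CovarianceMatrix) -> CovarianceMatrix:
    """Forward-backward averaging ``(R + J R^T J) / 2`` with the exchange
    (anti-identity) matrix J; the result is Hermitian and persymmetric."""
    R = cov.R
    JRtJ = R[::-1, ::-1].T
    return CovarianceMatrix(
        0.5 * (R + JRtJ), cov.n_subarrays, cov.loading_applied
    )


def diagonal_load(cov: CovarianceMatrix, delta: float, L: int | None = None) -> CovarianceMatrix:
    """Add ``delta * trace(R) / L`` to the diagonal."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    L = cov.L if L is None else L
    load = float(delta * np.trace(cov.R).real / L)
    return CovarianceMatrix(
        cov.R + load * np.eye(cov.L), cov.n_subarrays, cov.loading_applied + load
    )


def mv_weights(cov: CovarianceMatrix) -> MVWeights:
    """Solve the distortionless minimum-power program for the weights,
    ``w = R^{-1} a / (a^H R^{-1} a)`` with ``a = ones(L)``."""
    L = cov.L
    a = np.ones(L)
    try:
        y = np.linalg.solve(cov.R, a)
    except np.linalg.LinAlgError:
        y = None
    if y is None or not np.all(np.isfinite(y)) or abs(y.sum()) < 1e-300:
        warnings.warn("singular covariance after loading; uniform weights used")
        return MVWeights(a / L)
    return MVWeights(y / y.sum())


def mv_output(arr: np.ndarray, w: MVWeights | np.ndarray, L: int | None = None) -> complex:
    """Beamformer output: mean over forward subarrays of ``w^H`` applied to
    each length-L subarray of ``arr``."""
    arr = np.asarray(arr, dtype=complex)
    wv = w.w if isinstance(w, MVWeights) else np.asarray(w, dtype=complex)
    L = wv.size if L is None else L
    if wv.size != L:
        raise ValueError("weight length inconsistent with L")
    if L > arr.size:
        raise ValueError("subarray longer than data vector")
    sub = np.lib.stride_tricks.sliding_window_view(arr, L)  # (K, L)
    return complex((sub @ wv.conj()).mean())
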