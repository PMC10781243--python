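# Methods

## Signal model and delay convention

Channel data are handled as analytic (complex) signals indexed
(transmit angle *i*, receive element *j*, fast-time sample).  Real RF is
converted with the Hilbert transform; baseband IQ is accepted with its
demodulation frequency kept, and the carrier phase `exp(j2πf_d τ)` is
restored during delay compensation.

Delays use the standard linear-array geometry: lateral *x* along the
array (origin at its center), axial depth *z*, images indexed `[z, x]`.
The plane-wave transmit delay to a pixel is
`τ_tx = (z·cosθ + x·sinθ)/c`, referenced so the wavefront crosses the
array center at t = 0 — the convention of the public PICMUS datasets, so
files from that challenge and simulator output share one delay model.
The receive delay is the exact geometric return path
`τ_rx = √(z² + (x−x_j)²)/c`.  Per-angle start times `t0` from file
metadata are honored on top.

Numerical choices:

* **Interpolation**: linear interpolation of the complex analytic
  samples.  At the 4x carrier oversampling of the supported probes this
  is phase-safe; it is also what the per-pixel/batched consistency tests
  pin down.
* **Out-of-window delays** contribute exact zeros rather than
  edge-clamped samples, so image borders cannot acquire spurious
  coherence.
* **Dynamic receive aperture**: element *j* is active at a pixel iff
  `|x_j − x| ≤ z/(2·F#)` with F# = 1.75 by default; the two nearest
  elements are always kept active so every pixel has a usable aperture
  (this floor matches the minimum RxMV subarray of 2).
* **Channel compounding normalization**: the channel sum is the mean over
  *active* channels.  A fixed 1/N would dim shallow and border pixels by
  a depth-dependent factor that is an artifact of the aperture, not of
  the object.
* **Pixel grid default**: half a wavelength laterally, one two-way RF
  sample axially (λ/2 ≈ 0.148 mm and 37 µm at 5.2 MHz / 20.8 MHz).

## Minimum-variance estimation

The covariance of the compounded arrays is estimated with sliding
subarrays of length L, optional temporal averaging over 2T+1 depth
samples (truncated at the image edges, normalized by the actual count so
the scale stays unbiased), then forward–backward averaging, then diagonal
loading `Δ·tr(R)/L`.  The temporal window is applied before FB averaging
and loading last, the order in which the operations are introduced in the
underlying formulation.  Weights come from a Hermitian linear solve of
`R w₀ = a` (never an explicit inverse; the solve is both faster and
better conditioned at Δ = 0.1); a numerically singular covariance after
loading falls back to uniform weights with a warning, because one dark
pixel should not abort an image.  Pixels whose data vector is identically
zero output zero without a solve.

Defaults, with units and origin:

| parameter | default | meaning |
|---|---|---|
| F# | 1.75 | receive aperture = z / F# |
| L (TxMV) | 25 at 75 angles; one third of M in general | transmit-angle subarray |
| L (RxMV) | max(2, N_active/3) | follows the dynamic aperture |
| T | 2T+1 ≈ 5.4 carrier periods (T = 10 at 20.8/5.2 MHz) | temporal half-window |
| Δ | 0.1 (MV), 1 or 5 (DCR-MVDR point/speckle) | loading factor |

The temporal window is expressed in axial *pixels*; on the default grid
one axial pixel is one RF sample, so the two coincide, and
`axial_halfwidth` rescales the rule for coarser grids.

DCR-MVDR (the comparison method) builds its covariance from
leave-one-channel-out compoundings of the full echo matrix — N_active
snapshots of length M, no subarray averaging — and applies the weights to
the fully compounded transmit vector.  Whether the reference formulation
applies the weights to the full vector or averages over snapshots is not
fully specified; the full-vector reading is implemented (the difference
is a real positive scale for rank-deficient covariances and does not
affect envelope-normalized images).

## DMAS and the complex p-th power

The p-th root and p-th power act on magnitudes only, with the phase
preserved: `ẑ = |z|^{1/p} e^{j∠z}` before the MV stage and
`ŷ → |ŷ|^p e^{j∠ŷ}` per subarray output before the subarray mean.  A bare
complex power would be multi-valued and would scramble envelope
detection; the magnitude-power convention keeps the "restore the signal
dimensionality" intent exact, and makes p = 1 collapse to the linear
beamformers bit-for-bit (a tested identity chain:
TxMV-DMAS(p=1) = TxMV, TxMV(L=1) = CPWC, Tx-DMAS(p=1) = CPWC).

## Adaptive coherence order

Per pixel, from the transmit-angle array Z(n):

* **GCF**: energy in the DC ± M0 bins of the unpadded length-M DFT over
  total energy (M0 = 1, i.e. 3 of M bins).  All-zero vectors map to 0.
* **Var**: variance across angles of |z_i| after attenuation
  compensation.  The compensation gain is the inverse of the laterally
  averaged, depth-smoothed CPWC envelope profile (a time-gain-compensation
  profile derived from the image itself), and the variance map is then
  normalized by its image maximum.  The defining publication states
  neither the compensation law nor the normalization; thresholds of 0.001
  and 0.15 only make sense on a [0, 1] scale, which this convention
  provides.  The normalization is meaningful for images that contain
  speckle; on a scene containing only an isolated point the TGC profile
  saturates in the empty rows and the normalized map is dominated by
  them.
* **Regions**: var > thv2 flags off-axis clutter (I); gcf < thg1 flags
  uncorrelated noise (II); gcf < thg2 together with var < thv1 flags
  low-coherence clutter inside anechoic regions (III).  Overlaps resolve
  with precedence I > II > III — the three rules are introduced as an
  ordered sequence and all reset GCF to zero, so the label is purely
  diagnostic.
* **Maps**: `α = GCF^{Var^{1/m}}` with m = 4 (`0^0` corner defined as 0:
  the region reset dominates), `γ = 1 − 1/(1+e^{−(18α−9)})`, a 5x5
  edge-replicated median filter on γ (3x3 does not remove two-pixel
  pinholes at λ/2 pitch; the kernel is configurable), then
  `p = γ(p_max−1) + p_min`.
* The pixel's own p is used both for the root scaling and for the power
  restoration.

The thresholds `[thg1 thg2] = [0.1 0.2]`, `[thv1 thv2] = [0.001 0.15]`
are tied to the transmit-angle set they were tuned for (75 angles over
±16°).  With fewer angles the speckle-baseline GCF shifts; the values are
exposed as configuration, and re-tuning them is deliberately out of
scope.  At the reduced 15-angle study scale this shows up as ADMAS
recovering only part of the fixed-p contrast gain — while still restoring
CNR, which is the claim the test suite asserts.

## Synthetic data

The simulator is a single-scattering superposition model: every scatterer
adds `amplitude · pulse(t − τ_tx − τ_rx)` to each (angle, element)
channel, with a 2.5-cycle Hann-windowed sinusoid at the probe center
frequency whose envelope is centered on the arrival time (so envelope
peaks coincide with scatterer positions).  No attenuation, dispersion,
element directivity or multiple scattering; optional white Gaussian noise
at a stated level below the RF peak.  This reproduces the features the
reconstruction chain assumes — geometric delays, angular coherence,
speckle statistics — and nothing else, so passing tests demonstrate
correctness of the beamforming mathematics on idealized data, not
robustness to absorption, aberration or reverberation in tissue.

Phantoms: a 20-point resolution layout (a 10–45 mm axial column plus two
lateral rows at 20 and 40 mm, 5 mm spacing, spanning ±15 mm), and
rectangles of uniformly placed scatterers with unit-variance Gaussian
amplitudes in which circular inclusions are carved out (anechoic) or
amplified (hyperechoic).  Gaussian amplitudes make the *effective*
scatterer density a third of the count (amplitude kurtosis), so fully
developed speckle — Rayleigh envelope, SNR ≈ 1.91 — needs about 60
scatterers per estimated resolution cell; the density helper and the
speckle fixtures use that figure, while contrast phantoms default to 10
per cell, enough for stable ROI statistics at a fraction of the cost.

## Study scale

All shipped studies (tests and `scripts/acceptance.py`) run at a reduced
scale chosen to keep the full MV/ADMAS chain fast on one CPU: 64
elements, 15 angles over ±7.5°, TxMV subarray length 5 (one third of the
angle count, mirroring the 25-of-75 ratio), imaging grids of 10–25 k
pixels, phantoms of 3–17 k scatterers.  The full 128-element / 75-angle
PICMUS scale runs through exactly the same code path via the PICMUS
reader and the `bench` CLI verb when a dataset file is available.
Absolute metric values at the reduced scale differ from full-scale ones
(smaller aperture, narrower angle span, smaller ROIs); the directional
claims — FWHM ordering CPWC > TxMV > TxMV-DMAS, cyst level monotone in p,
CNR restored by the adaptive order, median speckle p at p_min — are scale
independent and are what the acceptance tests assert.

## Known limitations

* RxMV evaluates per pixel in a scalar loop (the subarray length follows
  the aperture pixel by pixel); keep its grids moderate.
* DCR-MVDR materializes the full per-pixel echo matrix
  (nz·nx·M·N complex values); intended for moderate grids.
* The gCNR histogram uses 100 shared bins over the pooled range
  (configurable); its binning error is visible only for near-complete
  overlap.
* ROI geometry for cyst metrics (concentric at 70% cyst radius,
  equal-radius background at the same depth) is a documented convention;
  published tables based on other ROI choices shift by fractions of a dB.
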