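"""Lateral resolution of a point target across the beamformer family.

Simulates a single scatterer at (0 mm, 25 mm) on the reduced 64-element /
15-angle scale, reconstructs it with CPWC, TxMV and TxMV-DMAS, and prints
the -6 dB lateral width of the point-spread function.  Smaller is better:
MV weighting in the transmit-angle dimension narrows the mainlobe, and the
coherence order p narrows it further.
"""

import pwbeam as pw
from pwbeam.metrics import fwhm_lateral

geom = pw.reduced_geometry()
seq = pw.reduced_sequence()
phantom = pw.make_point_phantom(positions=[(0.0, 25e-3)])
cube = pw.simulate_cube(phantom, geom, seq)
grid = pw.PixelGrid.for_cube(cube, (-4e-3, 4e-3), (23e-3, 27e-3), lateral_fraction=0.25)

L = 5  # transmit-angle subarray length (one third of the 15 angles)
images = {
    "CPWC": pw.beamform_cpwc(cube, grid),
    "TxMV": pw.beamform_txmv(cube, grid, L=L),
    "TxMV-DMAS p=1.5": pw.beamform_txmv_dmas(cube, grid, p=1.5, L=L),
    "TxMV-DMAS p=2.0": pw.beamform_txmv_dmas(cube, grid, p=2.0, L=L),
}
print("lateral FWHM of the point-spread function (-6 dB width):")
for name, img in images.items():
    print(f"  {name:<16} {fwhm_lateral(img, 25e-3):.3f} mm")
print("The width shrinks from CPWC to TxMV to TxMV-DMAS: adaptive weighting"
      " and coherence imaging sharpen the mainlobe.")
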