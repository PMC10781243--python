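"""Shared fixtures: the reduced-scale study conditions.

All simulated fixtures use a 64-element PICMUS-type array with 15 plane
waves spanning +-7.5 degrees.  They are session-scoped because the speckle
simulations dominate the suite's runtime.  The TxMV subarray length at this
scale is 5 (one third of the angle count, mirroring the 25-of-75 ratio used
at full scale).
"""

import numpy as np
import pytest

import pwbeam as pw

L_ANGLES = 5  # TxMV subarray length for the 15-angle reduced scale


@pytest.fixture(scope="session")
def geometry():
    return pw.reduced_geometry()


@pytest.fixture(scope="session")
def sequence():
    return pw.reduced_sequence()


@pytest.fixture(scope="session")
def point_cube(geometry, sequence):
    """Single unit scatterer at (0 mm, 25 mm)."""
    phantom = pw.make_point_phantom(positions=[(0.0, 25e-3)])
    return pw.simulate_cube(phantom, geometry, sequence)


@pytest.fixture(scope="session")
def point_grid(point_cube):
    """Fine lateral sampling (lambda/4) around the point target."""
    return pw.PixelGrid.for_cube(
        point_cube, (-4e-3, 4e-3), (23e-3, 27e-3), lateral_fraction=0.25
    )


@pytest.fixture(scope="session")
def cyst_cube(geometry, sequence):
    """One 2.5 mm anechoic cyst at (0, 25 mm) in a speckle background."""
    phantom = pw.make_cyst_phantom(seed=1)
    return pw.simulate_cube(phantom, geometry, sequence, seed=1)


@pytest.fixture(scope="session")
def cyst_grid(cyst_cube):
    return pw.PixelGrid.for_cube(cyst_cube, (-5e-3, 5e-3), (21e-3, 29e-3))


@pytest.fixture(scope="session")
def cyst_rois():
    """Concentric cyst ROI at 70% cyst radius and an equal-radius
    background ROI at the same depth."""
    cyst = pw.RoiCircle((0.0, 25e-3), 1.75e-3, "cyst")
    bck = pw.RoiCircle((3.8e-3, 25e-3), 1.75e-3, "background")
    return cyst, bck


@pytest.fixture(scope="session")
def speckle_cube(geometry, sequence):
    """Fully developed speckle: 60 scatterers per resolution cell (Gaussian
    amplitudes make the effective density one third of the count)."""
    phantom = pw.make_cyst_phantom(
        cysts=(), x_range=(-4e-3, 4e-3), z_range=(22.5e-3, 27.5e-3),
        per_cell=60, seed=0,
    )
    return pw.simulate_cube(phantom, geometry, sequence, seed=0)


@pytest.fixture(scope="session")
def speckle_grid(speckle_cube):
    return pw.PixelGrid.for_cube(speckle_cube, (-2.5e-3, 2.5e-3), (23.5e-3, 26.5e-3))


@pytest.fixture(scope="session")
def random_cube(geometry):
    """Small random analytic cube for exact identities; no physics needed."""
    rng = np.random.default_rng(7)
    seq = pw.PlaneWaveSequence.symmetric(9, 6.0)
    # 900 samples cover two-way delays past 25 mm depth at 20.8 MHz
    data = rng.standard_normal((9, geometry.n_elements, 900)) \
        + 1j * rng.standard_normal((9, geometry.n_elements, 900))
    return pw.AnalyticDataCube(data, geometry, seq)
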