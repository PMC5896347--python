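"""Shared fixtures: small rendered speckle frames and a coarse phantom."""

from __future__ import annotations

import numpy as np
import pytest

from nsdielast import phantom_fem, usim_rf


@pytest.fixture(scope="session")
def acq_small() -> usim_rf.AcquisitionParams:
    return usim_rf.AcquisitionParams(depth_mm=10.0, width_mm=10.0)


@pytest.fixture(scope="session")
def scatterers_small(acq_small) -> usim_rf.ScattererField:
    return usim_rf.make_scatterers(
        acq_small.depth_mm, acq_small.width_mm, density_per_mm2=30.0, seed=11
    )


@pytest.fixture(scope="session")
def frame_small(scatterers_small, acq_small) -> np.ndarray:
    return usim_rf.render_frame(scatterers_small, acq_small)


@pytest.fixture(scope="session")
def case1_coarse():
    """Bonded 10 mm inclusion phantom on a coarse mesh (fast)."""
    spec = phantom_fem.PhantomSpec(
        modulus_ratio=4.0, applied_compression=0.01, mesh_resolution_mm=0.5
    )
    mesh = phantom_fem.build_mesh(spec)
    sol = phantom_fem.solve(spec, mesh)
    return spec, mesh, sol
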