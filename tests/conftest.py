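"""Shared fixtures: geometry models at desk scale, stopping table, nuclides."""

from __future__ import annotations

import numpy as np
import pytest

from marrowdose.geometry import GeometrySpec, build_lattice
from marrowdose.nuclides import load_packaged_nuclide, packaged_nuclide_names
from marrowdose.synthetic import gen_reduced_geometry
from marrowdose.transport import load_packaged_stopping_table


@pytest.fixture(scope="session")
def stopping_table():
    return load_packaged_stopping_table()


@pytest.fixture(scope="session")
def default_spec():
    return GeometrySpec()


@pytest.fixture(scope="session")
def full_model(default_spec):
    """Full 3x3-cell, 225-vessel configuration."""
    return build_lattice(default_spec)


@pytest.fixture(scope="session")
def reduced_model():
    """One cell, 2x2 vessels: every region present, traces cheap."""
    return build_lattice(gen_reduced_geometry(1.0 / 3.0))


@pytest.fixture(scope="session")
def single_vessel_model():
    """One cell, one central vessel: bone-to-shell separation 270 um."""
    return build_lattice(
        GeometrySpec(
            vessels_per_cell=1, modeled_grids=1, n_cells_total=1600, total_vessels=1600
        )
    )


@pytest.fixture(scope="session")
def alpha_nuclides():
    return [
        load_packaged_nuclide(n)
        for n in packaged_nuclide_names()
        if load_packaged_nuclide(n).mode == "alpha"
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
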