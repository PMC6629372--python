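"""Shared fixtures: synthetic tubule maps at three desk-scale sizes.

Session-scoped because rendering and symmetry-averaging 3D volumes dominates
suite runtime; all fixtures are deterministic (fixed seeds in the specs).
"""

import numpy as np
import pytest

import mtseam as ms


@pytest.fixture(scope="session")
def small_spec():
    """A 96-box tubule (one dimer repeat) for fast I/O and FSC tests."""
    return ms.SyntheticSpec(box=96, voxel_size=2.0, radius=60.0, n_repeats=1)


@pytest.fixture(scope="session")
def small_map(small_spec):
    dmap, gt = ms.simulate_map(small_spec)
    return dmap, gt


@pytest.fixture(scope="session")
def small_mask(small_spec):
    return ms.make_pf_mask(small_spec, threshold=0.2, extend=2.0, soft_edge=3.0)


@pytest.fixture(scope="session")
def mid_spec():
    """A 128-box tubule with clean protofilament separation, the workhorse
    for symmetry-averaging and refinement tests."""
    return ms.SyntheticSpec(box=128, voxel_size=2.0, radius=85.0, n_repeats=2)


@pytest.fixture(scope="session")
def mid_map(mid_spec):
    dmap, gt = ms.simulate_map(mid_spec)
    return dmap, gt


@pytest.fixture(scope="session")
def mid_mask(mid_spec):
    return ms.make_pf_mask(mid_spec, threshold=0.1, extend=3.0, soft_edge=8.0)


@pytest.fixture(scope="session")
def mid_symmetrised(mid_map, mid_mask):
    dmap, gt = mid_map
    return ms.apply_local_symmetry(dmap, mid_mask, gt.operators)


@pytest.fixture(scope="session")
def default_spec():
    """Full-size (160-box, 115 A radius) undistorted tubule."""
    return ms.SyntheticSpec()


@pytest.fixture(scope="session")
def default_map(default_spec):
    dmap, gt = ms.simulate_map(default_spec)
    return dmap, gt


@pytest.fixture(scope="session")
def pf_template(default_spec):
    """Single-protofilament docking template in the 160-box frame."""
    return ms.render_pf_template(default_spec)
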