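import numpy as np
import pytest

import ppcv


@pytest.fixture(scope="session")
def default_geometry():
    return ppcv.ScanGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """A desk-scale scan for expensive voxel/pipeline tests."""
    return ppcv.ScanGeometry(lateral_extent_mm=0.3, n_ascans=64,
                             axial_extent_mm=0.2, n_slices=11)


@pytest.fixture(scope="session")
def default_phantom(default_geometry):
    """One default phantom: network, ground truth, clean + noisy stacks."""
    net = ppcv.generate_network(ppcv.NetworkParams(), default_geometry, seed=1)
    gt = ppcv.analytic_capillary_volume(net, default_geometry)
    clean = ppcv.render_stack(net, default_geometry,
                              ppcv.RenderParams(speckle_shape=None), seed=2)
    noisy = ppcv.render_stack(net, default_geometry, ppcv.RenderParams(), seed=2)
    return {"network": net, "ground_truth": gt, "clean": clean, "noisy": noisy}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
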