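import numpy as np
import pytest

import bnctsim as b


@pytest.fixture(scope="session")
def tiny_phantom():
    """0.9 cm lateral, 100 um cells: fast enough for per-test geometry work."""
    return b.build_phantom(b.PhantomConfig(
        phantom_size=(0.9, 0.9, 0.6), scoring_depth=0.3, fine_voxel=0.01,
        coarse_voxel=0.3, gtv_radius=0.05, me_extent=0.3, ptv_margin=0.05))


@pytest.fixture(scope="session")
def reduced_phantom():
    """Full 9 cm phantom at the reduced (100 um) scoring resolution."""
    return b.build_phantom(b.PhantomConfig(fine_voxel=0.01))


@pytest.fixture(scope="session")
def reduced_run():
    """One end-to-end reduced-preset run: 1e6 histories, calibrated MEP,
    2.0 cm CTV margin, canonical seed 0.  Shared by the acceptance checks."""
    cfg = b.RunConfig(preset="reduced", ctv_margin=2.0,
                      n_histories=1_000_000, n_replicates=1, seed=0)
    return b.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
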