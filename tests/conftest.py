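import numpy as np
import pytest

import kbpadvisor as k


def make_grid(shape, spacing=1.0, origin=None):
    spacing = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
    if origin is None:
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return k.VoxelGrid(origin=origin, spacing=spacing, shape=tuple(shape))


def coarse_grid():
    """3 mm lattice big enough for the full phantom anatomy; keeps tests fast."""
    return make_grid((74, 82, 54), spacing=3.0)


@pytest.fixture(scope="session")
def published_pair():
    """The OARD/MARD coefficient pair of the historical cohort."""
    return k.ModelPair(
        oard=k.SparingModel(A=0.33, B=0.5, C=-2.3),
        mard=k.SparingModel(A=0.38, B=0.5, C=-2.3),
    )


@pytest.fixture(scope="session")
def phantom_plan(published_pair):
    """One mid-overlap synthetic plan, shared by tests that only read it."""
    return k.generate_plan(
        k.AnatomySpec(seed=11, target_overlap_frac=0.25, grid=coarse_grid()),
        k.DoseSpec(seed=12, delta_true=0.1),
        published_pair.oard,
        patient_id="SYN011",
    )
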