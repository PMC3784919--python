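import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from histostack.core import Section2D, SectionSeries, Volume3D
from histostack.phantom import (
    CorruptionSpec,
    PhantomSpec,
    corrupt_sections,
    histology_contrast,
    make_phantom,
    virtual_section,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A small structured phantom shared by many tests."""
    spec = PhantomSpec(
        grid_dims=(40, 96, 96),
        voxel_size=(200.0, 120.0, 120.0),
        n_blobs=10,
        seed=7,
    )
    vol, lab, axis = make_phantom(spec)
    return spec, vol, lab, axis


@pytest.fixture(scope="session")
def tissue_sections(small_phantom):
    """Tissue-contrast sections of the small phantom (content-bearing only)."""
    _, vol, lab, _ = small_phantom
    hvol = histology_contrast(vol, lab)
    series, _ = virtual_section(hvol, thickness=200.0, keep_every=1)
    keep = [
        i for i in range(len(series)) if np.isin(lab.data[i], [2, 3]).mean() > 0.1
    ]
    return SectionSeries([series[i] for i in keep], spacing=200.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
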