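import numpy as np
import pytest

from vmi.phantom import PhantomSpec, make_phantom
from vmi.segmentation import SegmentationParams, segment_vasculature

# Rolling-ball radius used for all default-phantom segmentations: comfortably
# above the largest phantom vessel radius (30 µm).
PHANTOM_RB_RADIUS = 50.0

_phantom_cache: dict = {}
_segmentation_cache: dict = {}


def phantom_bundle(seed: int, **overrides):
    """Cached (volume, mask, tree) for a default-spec phantom at this seed."""
    key = (seed, tuple(sorted(overrides.items())))
    if key not in _phantom_cache:
        _phantom_cache[key] = make_phantom(PhantomSpec(seed=seed, **overrides))
    return _phantom_cache[key]


def segmented_phantom(seed: int):
    """Cached default-pipeline segmentation of the default phantom at this seed."""
    if seed not in _segmentation_cache:
        volume, _, _ = phantom_bundle(seed)
        params = SegmentationParams(rolling_ball_radius=PHANTOM_RB_RADIUS)
        _segmentation_cache[seed] = segment_vasculature(volume, params)
    return _segmentation_cache[seed]


@pytest.fixture
def small_spec():
    """A quick 64³ phantom spec for unit tests."""
    return PhantomSpec(
        shape=(64, 64, 64),
        spacing=(10.0, 10.0, 10.0),
        levels=3,
        root_diameter=60.0,
        branch_length_ratio=5.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
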