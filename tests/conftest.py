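"""Shared fixtures: scaled-down movie specifications.

Three fixture scales are used throughout the suite.  ``default`` is the
nominal acquisition (256 px field at 0.4 um/px).  ``recovery`` halves the
field (128 px) for simulation loops while keeping the pixel size, vessel
geometry and 20-um profile extent; the stalk count is scaled with field
area so the stalk hotspots keep occupying the top-intensity tail that the
masking step targets.  ``tiny`` (48 px at 1.0 um/px) is used only where
thousands of movies are needed.
"""

import numpy as np
import pytest

from perivasc.synthetic import MovieSpec


def recovery_spec(seed: int = 0, **overrides) -> MovieSpec:
    """128-px field, otherwise nominal parameters."""
    kwargs = dict(
        image_height_px=128,
        image_width_px=128,
        pixel_size_um=0.4,
        n_frames=45,
        puff_onset_frame=12,
        n_stalks=10,
        seed=seed,
    )
    kwargs.update(overrides)
    return MovieSpec(**kwargs)


def tiny_spec(seed: int = 0, **overrides) -> MovieSpec:
    """48-px field at 1 um/px for high-repetition simulations."""
    kwargs = dict(
        image_height_px=48,
        image_width_px=48,
        pixel_size_um=1.0,
        n_frames=26,
        puff_onset_frame=11,
        n_stalks=8,
        seed=seed,
    )
    kwargs.update(overrides)
    return MovieSpec(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240916)
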