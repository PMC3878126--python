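"""Shared fixtures: small grids, masks and reduced phantom specs."""

import numpy as np
import pytest

from lascar import BinaryMask, Volume3D
from lascar.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ball_mask(shape=(24, 24, 24), radius=8.0, spacing=(1.0, 1.0, 1.0),
              center=None, role="endocardium"):
    shape = tuple(shape)
    spacing = tuple(spacing)
    if center is None:
        center = [(s - 1) * sp / 2.0 for s, sp in zip(shape, spacing)]
    grids = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                        indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return BinaryMask(r2 <= radius ** 2, spacing, (0.0, 0.0, 0.0), role)


@pytest.fixture
def small_endo():
    return ball_mask()


def small_phantom_spec(**overrides):
    """A reduced-grid phantom for fast end-to-end tests."""
    defaults = dict(shape=(64, 64, 32), la_semi_axes_mm=(22.0, 18.0, 14.0),
                    pv_tube_radius_mm=4.0, pv_tube_reach_mm=34.0,
                    pv_tube_offset_mm=(4.0, 3.0), n_patches=6,
                    patch_radius_mm=(9.0, 11.0))
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return Volume3D(np.asarray(data, dtype=float), spacing)
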