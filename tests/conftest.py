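"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pytest

from cncorr.simulate import CellMovie


def mask_movie(cell_shift_px, nuc_shift_px, pixel_size=0.25,
               shape=(140, 140), cell_r=40, nuc_r=12):
    """Two-frame movie from disk masks translated by whole pixels."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]

    def disk(cx, cy, r):
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2

    cmask = np.stack([
        disk(60, 60, cell_r),
        disk(60 + cell_shift_px[0], 60 + cell_shift_px[1], cell_r),
    ])
    nmask = np.stack([
        disk(60, 60, nuc_r),
        disk(60 + nuc_shift_px[0], 60 + nuc_shift_px[1], nuc_r),
    ])
    return CellMovie.from_masks(cmask, nmask, pixel_size=pixel_size)


@pytest.fixture
def ellipse_mask():
    """A 256x256 elliptical cell mask (major axis along x)."""
    h = w = 256
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    a, b = 0.45 * w, 0.32 * h
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
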