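"""Shared fixtures: small synthetic datasets and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from surfmsi import simgen
from surfmsi.msi_io import MSIDataset, Pixel


def make_random_peak_dataset(
    rng: np.random.Generator,
    grid_shape: tuple[int, int] = (4, 5),
    max_peaks: int = 8,
    drop_pixel_prob: float = 0.1,
) -> MSIDataset:
    """A small dataset with random sparse peak lists (some pixels missing)."""
    rows, cols = grid_shape
    pixels = []
    for y in range(rows):
        for x in range(cols):
            if rng.uniform() < drop_pixel_prob and (x, y) != (0, 0):
                continue
            n = int(rng.integers(1, max_peaks + 1))
            mz = np.sort(rng.uniform(1200, 4500, n))
            # enforce strict ascent
            mz = np.unique(mz)
            inten = rng.uniform(0, 100, mz.size)
            pixels.append(Pixel(x=x, y=y, mz=mz, intensity=inten))
    return MSIDataset(pixels=pixels, grid_shape=grid_shape, sample_id="rand")


def brute_force_ion_image(ds: MSIDataset, target: float, tol: float) -> np.ndarray:
    """Naive double loop over pixels and peaks (extraction oracle)."""
    rows, cols = ds.grid_shape
    out = np.full((rows, cols), np.nan)
    for p in ds.pixels:
        s = 0.0
        for m, i in zip(p.mz, p.intensity):
            if abs(m - target) <= tol:
                s += i
        out[p.y, p.x] = s
    return out


def brute_force_border_distance(tissue: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-off-tissue search; grid edge counts as border
    (a virtual off-tissue ring surrounds the grid)."""
    rows, cols = tissue.shape
    bg = [(y, x) for y in range(-1, rows + 1) for x in range(-1, cols + 1)
          if not (0 <= y < rows and 0 <= x < cols) or not tissue[y, x]]
    bg = np.array(bg, dtype=float)
    out = np.full(tissue.shape, np.nan)
    for y in range(rows):
        for x in range(cols):
            if tissue[y, x]:
                out[y, x] = np.sqrt(((bg - [y, x]) ** 2).sum(axis=1).min())
    return out


@pytest.fixture
def small_section_params() -> simgen.SectionSimParams:
    """A quick-to-generate treated section with a recoverable gradient."""
    return simgen.SectionSimParams(
        grid_shape=(40, 40),
        tissue_phantom=simgen.TissuePhantom(radii=(15.0, 17.0)),
        seed=7,
    )


@pytest.fixture
def calib_params() -> simgen.CalibSimParams:
    return simgen.default_calibration_params()
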