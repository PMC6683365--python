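"""imzML-backed I/O for mass spectrometry imaging datasets.

An MSI dataset is a collection of per-pixel centroided spectra on a
rectangular raster. This module reads and writes the open imzML + ibd
format (both *continuous* and *processed* binary modes) through pyimzML,
and extracts 2D ion images — per-pixel summed intensity of all peaks
inside an m/z tolerance window around a target ion.

Coordinates are 0-based ``(x=column, y=row)`` in memory; the 1-based
imzML pixel indices are converted on read and write. Intensities are
stored as 32-bit floats and m/z values as 64-bit floats in the binary
file, so a round trip preserves intensities only to float32 precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np

__all__ = [
    "Pixel",
    "MSIDataset",
    "IonImage",
    "MSIParseError",
    "read_imzml",
    "write_imzml",
    "extract_ion_image",
    "total_ion_current",
]

#: instrument acquisition window (Da), positive reflectron full scan
ACQ_MZ_MIN = 1200.0
ACQ_MZ_MAX = 4500.0


class MSIParseError(ValueError):
    """Raised when an imzML/ibd pair is missing, inconsistent or malformed."""


@dataclass
class Pixel:
    """One raster position with its centroided spectrum."""

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray

    def validate(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise MSIParseError(
                f"pixel ({self.x},{self.y}): m/z and intensity arrays must be "
                f"1D and equal length, got {mz.shape} vs {inten.shape}"
            )
        if mz.size and np.any(np.diff(mz) <= 0):
            raise MSIParseError(
                f"pixel ({self.x},{self.y}): m/z array not strictly ascending"
            )
        if np.any(inten < 0):
            raise MSIParseError(
                f"pixel ({self.x},{self.y}): negative intensity"
            )


@dataclass
class MSIDataset:
    """Pixel-indexed spectra plus grid metadata; the unit of I/O.

    Parameters
    ----------
    pixels : list of Pixel
        Spectra at their 0-based (x=col, y=row) raster positions. Raster
        positions may be missing (e.g. pixels skipped by the instrument);
        they stay missing through a write/read cycle.
    grid_shape : (rows, cols)
    pixel_pitch : float
        Raster step in micrometres (350 for the lung sections).
    sample_id : str
    group : str
        ``"treated"``, ``"control"`` or ``"calibration"`` (free-form on read).
    """

    pixels: list[Pixel]
    grid_shape: tuple[int, int]
    pixel_pitch: float = 350.0
    sample_id: str = ""
    group: str = ""

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise MSIParseError(f"invalid grid shape {self.grid_shape}")
        seen: set[tuple[int, int]] = set()
        for p in self.pixels:
            if not (0 <= p.x < cols and 0 <= p.y < rows):
                raise MSIParseError(
                    f"pixel ({p.x},{p.y}) outside grid {self.grid_shape}"
                )
            if (p.x, p.y) in seen:
                raise MSIParseError(f"duplicate pixel coordinate ({p.x},{p.y})")
            seen.add((p.x, p.y))
            p.validate()

    @property
    def coordinates(self) -> set[tuple[int, int]]:
        return {(p.x, p.y) for p in self.pixels}

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class IonImage:
    """2D intensity map of one target ion.

    ``values[row, col]`` holds the summed intensity; raster positions with
    no recorded spectrum are NaN, distinct from a recorded zero. The
    boolean ``present`` grid flags recorded pixels.
    """

    values: np.ndarray
    target_mz: float
    tolerance: float

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def extract_ion_image(
    dataset: MSIDataset, target_mz: float, tolerance: float = 1.0
) -> IonImage:
    """Extract a 2D ion image at ``target_mz`` ± ``tolerance``.

    Each pixel's value is the sum of the intensities of every peak with
    ``|mz - target_mz| <= tolerance`` (window closed on both sides);
    a 1 Da tolerance therefore integrates a 2 Da window. Pixels absent
    from the dataset are NaN in the output.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not (ACQ_MZ_MIN <= target_mz <= ACQ_MZ_MAX):
        warnings.warn(
            f"target m/z {target_mz} outside the acquisition range "
            f"[{ACQ_MZ_MIN}, {ACQ_MZ_MAX}]",
            stacklevel=2,
        )
    rows, cols = dataset.grid_shape
    values = np.full((rows, cols), np.nan)
    lo, hi = target_mz - tolerance, target_mz + tolerance
    for p in dataset.pixels:
        mz = np.asarray(p.mz)
        # closed window on both sides
        i0, i1 = np.searchsorted(mz, lo, "left"), np.searchsorted(mz, hi, "right")
        values[p.y, p.x] = float(np.sum(np.asarray(p.intensity)[i0:i1]))
    return IonImage(values=values, target_mz=target_mz, tolerance=tolerance)


def total_ion_current(dataset: MSIDataset) -> IonImage:
    """Per-pixel total ion current (sum of all peak intensities)."""
    rows, cols = dataset.grid_shape
    values = np.full((rows, cols), np.nan)
    for p in dataset.pixels:
        values[p.y, p.x] = float(np.sum(p.intensity))
    return IonImage(values=values, target_mz=np.nan, tolerance=np.inf)


def write_imzml(dataset: MSIDataset, path: str | Path, mode: str = "processed") -> Path:
    """Write an imzML + ibd pair.

    ``mode`` is ``"processed"`` (per-pixel m/z axes, the native form of
    centroided MALDI-TOF data) or ``"continuous"`` (shared m/z axis; every
    pixel must carry identical m/z arrays).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if mode not in ("processed", "continuous"):
        raise ValueError(f"unknown imzML mode {mode!r}")
    if not dataset.pixels:
        raise ValueError("refusing to write a dataset with no pixels")
    dataset.validate()
    for p in dataset.pixels:
        if np.asarray(p.mz).size == 0:
            raise ValueError(
                f"pixel ({p.x},{p.y}) has an empty spectrum; imzML cannot "
                "store zero-length arrays"
            )
    if mode == "continuous":
        ref = np.asarray(dataset.pixels[0].mz, dtype=float)
        for p in dataset.pixels:
            if not np.array_equal(np.asarray(p.mz, dtype=float), ref):
                raise ValueError(
                    "continuous mode requires an identical m/z axis in every pixel"
                )
    path = Path(path)
    if path.suffix != ".imzML":
        path = path.with_suffix(".imzML")
    with ImzMLWriter(str(path), mode=mode, polarity="positive") as writer:
        for p in dataset.pixels:
            # imzML uses 1-based pixel indices
            writer.addSpectrum(
                np.asarray(p.mz, dtype=np.float64),
                np.asarray(p.intensity, dtype=np.float32),
                (p.x + 1, p.y + 1, 1),
            )
    return path


def read_imzml(path: str | Path) -> MSIDataset:
    """Read an imzML + ibd pair into an :class:`MSIDataset`.

    Handles continuous and processed modes transparently. The sample id
    is taken from the file stem; grid shape from the declared max pixel
    counts (falling back to the observed coordinate extent).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise MSIParseError(f"imzML file not found: {path}")
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise MSIParseError(f"binary ibd file missing for {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML / uuid mismatch / truncation
        raise MSIParseError(f"cannot parse {path}: {exc}") from exc

    pixels: list[Pixel] = []
    max_x = max_y = 0
    for i, (cx, cy, _cz) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        x, y = int(cx) - 1, int(cy) - 1
        max_x, max_y = max(max_x, x), max(max_y, y)
        px = Pixel(x=x, y=y, mz=np.asarray(mzs, dtype=np.float64),
                   intensity=np.asarray(ints, dtype=np.float64))
        try:
            px.validate()
        except MSIParseError as exc:
            raise MSIParseError(f"{path}: {exc}") from exc
        pixels.append(px)
    meta = getattr(parser, "imzmldict", {}) or {}
    cols = int(meta.get("max count of pixels x", max_x + 1))
    rows = int(meta.get("max count of pixels y", max_y + 1))
    cols, rows = max(cols, max_x + 1), max(rows, max_y + 1)
    pitch = float(meta.get("pixel size x", 350.0))
    ds = MSIDataset(
        pixels=pixels,
        grid_shape=(rows, cols),
        pixel_pitch=pitch,
        sample_id=path.stem,
        group="",
    )
    ds.validate()
    return ds


def datasets_allclose(a: MSIDataset, b: MSIDataset, rtol: float = 1e-6) -> bool:
    """Spectral equality of two datasets up to float32 storage precision."""
    if a.grid_shape != b.grid_shape or a.coordinates != b.coordinates:
        return False
    bmap = {(p.x, p.y): p for p in b.pixels}
    for p in a.pixels:
        q = bmap[(p.x, p.y)]
        if not np.allclose(p.mz, q.mz, rtol=0, atol=1e-9):
            return False
        if not np.allclose(p.intensity, q.intensity, rtol=rtol, atol=0):
            return False
    return True
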