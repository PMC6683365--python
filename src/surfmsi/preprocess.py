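"""Normalization chain for MSI ion images.

The pipeline mirrors standard practice for MALDI-TOF imaging of a single
target ion across many sections: log10-transform the per-pixel intensity,
segment the tissue from total ion current, split pixels into a background
and a signal population by 1D model-based clustering, remove sample-to-sample
batch effects by subtracting the mode of the log-intensity density (which
sets the background mean to zero), and derive a hard noise threshold from
the pooled corrected intensities of untreated control sections (the 99.5%
quantile, by default). Each target ion (SP-C analog at m/z 3618, SP-B
analog at m/z 3886) gets its own independent background model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .msi_io import IonImage, MSIDataset, total_ion_current

__all__ = [
    "LogIonImage",
    "BackgroundModel",
    "PixelMasks",
    "log_transform",
    "segment_tissue",
    "classify_background",
    "estimate_mode",
    "estimate_background_model",
    "batch_correct",
    "estimate_noise_threshold",
    "above_noise_mask",
]

KDE_GRID_POINTS = 512
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_QUANTILE = 0.995


@dataclass
class LogIonImage:
    """log10-transformed ion image; NaN marks missing raster positions."""

    values: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BackgroundModel:
    """Per-sample, per-ion background description on the log10 scale.

    ``background_mode`` is the density mode subtracted during batch
    correction; ``background_mean`` the mean of the low-intensity cluster
    (used for calibration-slide background subtraction); ``grid_step``
    the KDE evaluation-grid spacing, the natural resolution of the mode.
    """

    background_mode: float
    background_mean: float
    noise_threshold: float = np.nan
    quantile: float = DEFAULT_QUANTILE
    grid_step: float = np.nan


@dataclass
class PixelMasks:
    """Boolean grids: tissue, above-noise signal, and background pixels."""

    tissue: np.ndarray
    above_noise: np.ndarray
    background: np.ndarray

    def validate(self) -> None:
        if np.any(self.above_noise & ~self.tissue):
            raise ValueError("above_noise mask must be a subset of tissue")
        if np.any(self.above_noise & self.background):
            raise ValueError("background and above_noise masks overlap")


def log_transform(image: IonImage, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> LogIonImage:
    """log10(value + pseudocount); missing pixels stay missing (NaN)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return LogIonImage(values=np.log10(image.values + pseudocount),
                       pseudocount=pseudocount)


def segment_tissue(
    dataset: MSIDataset,
    closing_radius: int = 1,
    min_contrast: float = 0.15,
    min_tissue_fraction: float = 0.1,
) -> np.ndarray:
    """Segment the tissue region from the total ion current image.

    Thresholds log10 TIC at its between-class (Otsu) optimum, applies a
    morphological closing and keeps the largest connected component.
    Two situations mean there is no off-tissue population to separate
    and the slide is returned whole (every recorded pixel): a TIC
    distribution with no real bimodality (``min_contrast``, log10 units
    of between-class mean separation — a uniform blank), and a high-TIC
    class covering less than ``min_tissue_fraction`` of the slide (a
    homogenate-covered calibration slide, where the only high-TIC
    pixels are the stamped standard spots).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label
    from skimage.morphology import closing, disk

    if not dataset.pixels:
        raise ValueError("empty dataset")
    tic = total_ion_current(dataset)
    present = tic.present
    logtic = np.log10(tic.values + 1.0)
    vals = logtic[present]
    if vals.size == 0:
        warnings.warn("no recorded pixels; empty tissue mask", stacklevel=2)
        return np.zeros(dataset.grid_shape, dtype=bool)
    if np.ptp(vals) < 1e-12:
        # perfectly uniform slide: single component covering everything
        return present.copy()
    thr = threshold_otsu(vals)
    lo, hi = vals[vals <= thr], vals[vals > thr]
    if lo.size == 0 or hi.size == 0 or (hi.mean() - lo.mean()) < min_contrast:
        return present.copy()
    if hi.size < min_tissue_fraction * vals.size:
        return present.copy()
    mask = present & (logtic > thr)
    if not mask.any():
        warnings.warn("all-background slide; empty tissue mask", stacklevel=2)
        return mask
    mask = closing(mask, disk(closing_radius)).astype(bool)
    mask &= present
    lab = label(mask, connectivity=2)
    if lab.max() > 0:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    return mask


def _two_component_1d(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Deterministic 1D two-component Gaussian mixture (model-based
    clustering); components initialized at the 10th/90th percentiles.

    Pixels are assigned by posterior probability, so a tight, dominant
    background component keeps its boundary near its own upper tail even
    when the signal component is broad (intensities spanning several
    decades) — the regime where plain two-means midpoint boundaries
    absorb low-intensity signal into the background.

    Returns (labels, low_mean, high_mean); labels are 1 for the
    high-intensity cluster. Degenerate (constant) input collapses to a
    single cluster, everything labelled 0.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float)
    c0, c1 = np.percentile(v, [10.0, 90.0])
    if not (c1 > c0):
        # heavily unbalanced mixture: percentiles collapse onto the
        # dominant component; spread the initial centers to the extremes
        c0, c1 = float(v.min()), float(v.max())
    if not (c1 > c0):
        return np.zeros(v.shape, dtype=int), float(v.mean()), float(v.mean())
    var0 = max(np.var(v) / 4.0, 1e-6)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=[[c0], [c1]],
        weights_init=[0.5, 0.5],
        precisions_init=[[[1.0 / var0]], [[1.0 / var0]]],
        max_iter=500,
        tol=1e-8,
        reg_covar=1e-10,
    )
    try:
        with warnings.catch_warnings():
            # near-degenerate slides stop short of the tolerance; the
            # result is still usable and checked below
            warnings.simplefilter("ignore")
            comp = gm.fit_predict(v[:, None])
    except ValueError:
        return np.zeros(v.shape, dtype=int), float(v.mean()), float(v.mean())
    means = gm.means_.ravel()
    low = int(np.argmin(means))
    lab = (comp != low).astype(int)
    if lab.all() or not lab.any():
        return np.zeros(v.shape, dtype=int), float(v.mean()), float(v.mean())
    return lab, float(v[lab == 0].mean()), float(v[lab == 1].mean())


def classify_background(
    log_image: LogIonImage, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Two-population split of log intensities; low cluster = background.

    Returns ``(background_mask, signal_mask, (low_mean, high_mean))`` as
    boolean grids restricted to ``mask`` (default: all recorded pixels).
    Constant input falls back to a single all-background cluster with a
    warning. The partition is invariant under adding a constant.
    """
    if mask is None:
        mask = log_image.present
    mask = mask & log_image.present
    vals = log_image.values[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 pixels to classify background")
    lab, low_mean, high_mean = _two_component_1d(vals)
    if low_mean == high_mean and np.ptp(vals) < 1e-12:
        warnings.warn("constant intensities; all pixels labelled background",
                      stacklevel=2)
    background = np.zeros(log_image.shape, dtype=bool)
    signal = np.zeros(log_image.shape, dtype=bool)
    idx = np.argwhere(mask)
    background[idx[:, 0], idx[:, 1]] = lab == 0
    signal[idx[:, 0], idx[:, 1]] = lab == 1
    return background, signal, (low_mean, high_mean)


def estimate_mode(values: np.ndarray) -> tuple[float, float]:
    """Mode of a Gaussian KDE (Silverman bandwidth, 512-point grid).

    Returns ``(mode, grid_step)``; the grid step is the resolution at
    which the mode is defined. Requires at least 10 values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError(f"need >= 10 values to estimate a density mode, got {v.size}")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return lo, 0.0
    grid = np.linspace(lo, hi, KDE_GRID_POINTS)
    dens = gaussian_kde(v, bw_method="silverman")(grid)
    step = grid[1] - grid[0]
    return float(grid[int(np.argmax(dens))]), float(step)


def estimate_background_model(
    log_image: LogIonImage,
    mask: np.ndarray | None = None,
    mode_on: str = "all",
    quantile: float = DEFAULT_QUANTILE,
) -> BackgroundModel:
    """Fit a :class:`BackgroundModel` for one sample and one ion.

    ``mode_on`` selects the pixel pool for the density mode: ``"all"``
    (every recorded/masked pixel; background dominance assumed, the
    default) or ``"background"`` (low-intensity cluster only).
    """
    if mode_on not in ("all", "background"):
        raise ValueError(f"mode_on must be 'all' or 'background', got {mode_on!r}")
    if mask is None:
        mask = log_image.present
    mask = mask & log_image.present
    background, _signal, (low_mean, _high) = classify_background(log_image, mask)
    pool = log_image.values[background if mode_on == "background" else mask]
    mode, step = estimate_mode(pool)
    return BackgroundModel(background_mode=mode, background_mean=low_mean,
                           quantile=quantile, grid_step=step)


def batch_correct(log_image: LogIonImage, model: BackgroundModel) -> LogIonImage:
    """Subtract the background density mode (sets background mean ≈ 0).

    A per-sample constant shift on the log10 scale: pixel ranking within
    the sample is untouched.
    """
    return LogIonImage(values=log_image.values - model.background_mode,
                       pseudocount=log_image.pseudocount)


def estimate_noise_threshold(
    control_corrected_values: np.ndarray, quantile: float = DEFAULT_QUANTILE
) -> float:
    """Empirical quantile of pooled corrected control-sample intensities.

    The pool must come from untreated (control) sections only, after
    batch correction; the default 0.995 level leaves ~0.5% of control
    pixels above the returned hard threshold.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    v = np.asarray(control_corrected_values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty control pool")
    return float(np.quantile(v, quantile))


def above_noise_mask(
    corrected: LogIonImage, threshold: float, tissue: np.ndarray
) -> np.ndarray:
    """Pixels on tissue with corrected intensity strictly above threshold."""
    if np.isnan(threshold) or threshold == np.inf:
        raise ValueError("threshold must not be +inf or NaN")
    with np.errstate(invalid="ignore"):
        return tissue & corrected.present & (corrected.values > threshold)
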