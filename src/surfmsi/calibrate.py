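"""Calibration of absolute peptide amounts from spotted standards.

A calibration slide is a control tissue homogenate spotted with 0.5 μl
drops of a standard mix (six amounts, 1–50 ng of each peptide) plus a
melittin marker that localizes the deposition area. Preprocessing per
slide: (1) two-population clustering of log10 intensities separates
background pixels, whose cluster mean is subtracted to absorb
slide-to-slide analytical variability; (2) the melittin channel
identifies the actually-spotted pixels; (3) the per-pixel spotted amount
``c_pixel`` is the nominal spot amount divided by the spot's pixel
count; (4) a linear mixed-effects model relates the mean adjusted log10
signal of each spot to ``c_pixel`` — fixed slope and intercept, random
intercept per independent experiment, REML estimation. Inverting the
fitted line (and its 95% confidence envelope) converts corrected
section images into absolute ng-per-pixel maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .msi_io import IonImage
from .preprocess import LogIonImage, classify_background, log_transform

__all__ = [
    "CalibrationSpot",
    "CalibrationFit",
    "QuantMap",
    "detect_spots",
    "spot_background_subtract",
    "build_calibration_table",
    "process_calibration_slide",
    "fit_calibration",
    "quantify",
]


@dataclass
class CalibrationSpot:
    """One spotted standard on one slide."""

    experiment_id: str
    replicate_id: str
    nominal_amount: float  # ng per spot
    pixel_set: frozenset  # {(x, y), ...}
    mean_signal: float  # background-subtracted mean log10 intensity

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set)

    @property
    def c_pixel(self) -> float:
        return self.nominal_amount / self.n_pixels


@dataclass
class CalibrationFit:
    """Mixed-effects calibration line with 95% fixed-effect intervals."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    exp_var: float  # between-experiment random-intercept variance
    residual_var: float
    method: str = "mixedlm"  # "mixedlm" | "ols-fallback"
    n_obs: int = 0
    n_experiments: int = 0


@dataclass
class QuantMap:
    """Estimated ng per pixel with a 95% confidence envelope.

    ``clamped`` flags pixels whose signal fell below the fitted
    intercept; their amount is reported as 0.
    """

    amount: np.ndarray
    amount_lo: np.ndarray
    amount_hi: np.ndarray
    clamped: np.ndarray


def detect_spots(melittin_image: IonImage, expected_n: int) -> list[frozenset]:
    """Locate spotted pixel sets from the melittin marker channel.

    The melittin log-intensity is split by two-means clustering; the
    upper cluster, labelled as spotted, is decomposed into 8-connected
    components ranked by size. Exactly ``expected_n`` disjoint pixel
    sets are returned, ordered left-to-right by centroid column (the
    stamp layout order). Finding fewer components than expected — e.g.
    two touching drops merging into one blob — is an error.
    """
    from skimage.measure import label, regionprops

    if expected_n < 1:
        raise ValueError("expected_n must be >= 1")
    log_img = log_transform(melittin_image)
    vals = log_img.values[log_img.present]
    if vals.size < 2 or np.ptp(vals) < 1e-12:
        raise ValueError("melittin channel carries no signal; found 0 spots")
    _bg, spotted, (low_mean, high_mean) = classify_background(log_img)
    if not spotted.any() or high_mean - low_mean < 1e-9:
        raise ValueError("melittin channel carries no signal; found 0 spots")
    lab = label(spotted, connectivity=2)
    props = sorted(regionprops(lab), key=lambda r: r.area, reverse=True)
    if len(props) < expected_n:
        raise ValueError(
            f"expected {expected_n} calibration spots, found {len(props)} "
            "connected melittin components (touching or missing drops?)"
        )
    kept = sorted(props[:expected_n], key=lambda r: r.centroid[1])
    return [
        frozenset((int(c), int(r)) for r, c in region.coords) for region in kept
    ]


def spot_background_subtract(
    log_image: LogIonImage, background_mean: float
) -> LogIonImage:
    """Subtract the slide's low-intensity cluster mean (uniform shift)."""
    return LogIonImage(values=log_image.values - background_mean,
                       pseudocount=log_image.pseudocount)


def process_calibration_slide(
    analyte_image: IonImage,
    melittin_image: IonImage,
    amounts: list[float],
    experiment_id: str,
    replicate_id: str,
) -> list[CalibrationSpot]:
    """Run steps 1–3 on one slide: background subtraction, melittin spot
    detection, per-spot ``c_pixel`` and mean adjusted signal.

    Spot-to-amount assignment follows the stamp layout (spots ordered by
    position, amounts in the configured deposition order), never by
    intensity.
    """
    if not amounts:
        raise ValueError("no amounts configured for this slide")
    log_img = log_transform(analyte_image)
    _bg, _sig, (low_mean, _high) = classify_background(log_img)
    adjusted = spot_background_subtract(log_img, low_mean)
    spots = detect_spots(melittin_image, expected_n=len(amounts))
    out = []
    for amount, pixel_set in zip(amounts, spots):
        xs = np.array([x for x, _y in pixel_set])
        ys = np.array([y for _x, y in pixel_set])
        mean_signal = float(np.mean(adjusted.values[ys, xs]))
        out.append(CalibrationSpot(experiment_id=experiment_id,
                                   replicate_id=replicate_id,
                                   nominal_amount=float(amount),
                                   pixel_set=pixel_set,
                                   mean_signal=mean_signal))
    return out


def build_calibration_table(spots: list[CalibrationSpot]) -> pd.DataFrame:
    """Tabulate spots: one row per spot per slide."""
    if not spots:
        raise ValueError("no calibration spots")
    return pd.DataFrame(
        [
            (s.experiment_id, s.replicate_id, s.nominal_amount, s.n_pixels,
             s.c_pixel, s.mean_signal)
            for s in spots
        ],
        columns=["experiment_id", "replicate_id", "amount_ng", "n_pixels",
                 "c_pixel", "mean_signal"],
    )


def fit_calibration(table: pd.DataFrame) -> CalibrationFit:
    """Mixed-effects calibration fit: signal ~ c_pixel, random intercept
    per experiment, REML.

    Confidence intervals on the fixed effects use containment-style t
    quantiles — between-experiment degrees of freedom (m − 1) for the
    intercept, within degrees of freedom (N − m − 1) for the slope —
    which hold their nominal level with as few as three experiments,
    where large-sample normal intervals undercover. A singular fit
    (between-experiment variance estimated at zero boundary failure)
    falls back to pooled ordinary least squares with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    n_exp = table["experiment_id"].nunique()
    if n_exp < 2:
        raise ValueError(f"need >= 2 experiments, got {n_exp}")
    if table["c_pixel"].round(12).nunique() < 3:
        raise ValueError("need >= 3 distinct spotted amounts")
    n = len(table)
    df_slope = max(n - n_exp - 1, 1)
    df_int = max(n_exp - 1, 1)

    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("mean_signal ~ c_pixel", table,
                                groups=table["experiment_id"])
            res = model.fit(reml=True)
        if not res.converged:
            res = None
    except (np.linalg.LinAlgError, ValueError):
        res = None

    exp_var = (
        float(res.cov_re.iloc[0, 0]) if res is not None and res.cov_re.size else 0.0
    )
    if res is not None and exp_var > 1e-10:
        slope = float(res.params["c_pixel"])
        intercept = float(res.params["Intercept"])
        se_slope = float(res.bse["c_pixel"])
        se_int = float(res.bse["Intercept"])
        resid_var = float(res.scale)
        method = "mixedlm"
    else:
        # at the zero-variance boundary the mixed fit coincides with OLS
        warnings.warn(
            "singular mixed-effects fit (between-experiment variance ~ 0); "
            "falling back to pooled OLS",
            stacklevel=2,
        )
        X = sm.add_constant(table["c_pixel"].to_numpy())
        ols = sm.OLS(table["mean_signal"].to_numpy(), X).fit()
        slope, intercept = float(ols.params[1]), float(ols.params[0])
        se_slope, se_int = float(ols.bse[1]), float(ols.bse[0])
        exp_var, resid_var = 0.0, float(ols.mse_resid)
        method = "ols-fallback"

    t_s = stats.t.ppf(0.975, df_slope)
    t_i = stats.t.ppf(0.975, df_int)
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        slope_ci=(slope - t_s * se_slope, slope + t_s * se_slope),
        intercept_ci=(intercept - t_i * se_int, intercept + t_i * se_int),
        exp_var=exp_var,
        residual_var=resid_var,
        method=method,
        n_obs=n,
        n_experiments=n_exp,
    )


def quantify(
    corrected: LogIonImage, fit: CalibrationFit, above_noise: np.ndarray
) -> QuantMap:
    """Invert the calibration line per above-noise pixel.

    ``amount = (signal − intercept) / slope``; the 95% envelope takes
    the extreme amounts over the four corners of the fixed-effect
    confidence rectangle. Signals below the intercept clamp to 0 ng and
    are flagged. Below-noise pixels are NaN.
    """
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    shape = corrected.shape
    amount = np.full(shape, np.nan)
    lo = np.full(shape, np.nan)
    hi = np.full(shape, np.nan)
    clamped = np.zeros(shape, dtype=bool)
    sel = above_noise & corrected.present
    s = corrected.values[sel]
    est = (s - fit.intercept) / fit.slope
    clamp = est < 0
    est[clamp] = 0.0
    cands = []
    for b in fit.slope_ci:
        if b <= 0:
            continue
        for i in fit.intercept_ci:
            cands.append((s - i) / b)
    if not cands:  # slope CI straddles zero: envelope unbounded above
        cands = [(s - fit.intercept_ci[1]) / fit.slope_ci[1],
                 np.full_like(s, np.inf)]
    cl = np.clip(np.min(cands, axis=0), 0.0, None)
    ch = np.clip(np.max(cands, axis=0), 0.0, None)
    amount[sel] = est
    lo[sel] = np.minimum(cl, est)
    hi[sel] = np.maximum(ch, est)
    clamped[sel] = clamp
    return QuantMap(amount=amount, amount_lo=lo, amount_hi=hi, clamped=clamped)
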