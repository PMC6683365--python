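"""Synthetic MSI sections, calibration slides and animal cohorts.

The generator produces data with the statistical structure the analysis
pipeline assumes, so every downstream stage is testable without the
original instrument files:

* **Sections** — a raster of sparse centroided spectra over 1200–4500
  m/z. Every pixel carries a lognormal background peak inside each
  monitored channel (SP-C analog adduct at m/z 3618, SP-B analog at
  m/z 3886) plus a handful of decoy matrix peaks; tissue pixels add
  endogenous peaks that raise total ion current (tissue ablates more
  material than bare glass, which is what makes TIC segmentation work).
  Treated sections superimpose peptide peaks whose log10 intensity
  follows the calibration law ``background + intercept + slope ·
  amount``, where the per-pixel amount (ng) decays with distance from
  the section center and is boosted inside a few hotspot foci. A
  per-sample batch offset shifts everything on the log10 scale.

* **Calibration slides** — homogenate-covered slides stamped with a row
  of circular spots (six increasing amounts plus a melittin marker).
  Spot pixels carry log10 signal ``slope·c_pixel + intercept`` plus a
  shared per-experiment random intercept and per-pixel residual noise,
  all riding on the slide's own background level. Inside a spot, the
  stamped analyte peak replaces the channel's background (analyte
  suppresses the matrix signal where it is deposited).

* **Cohorts** — per-animal physiological time courses and matched
  section parameters driven by one latent peripheral-deposition factor:
  the same factor scales peptide abundance in the section and the
  improvement of oxygenation/compliance (and drop of inspiratory
  pressure) over the 120-minute follow-up. Controls get zero abundance
  and no improvement.

All outputs are deterministic functions of the parameter seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .msi_io import ACQ_MZ_MAX, ACQ_MZ_MIN, MSIDataset, Pixel
from .physio import PhysioSeries

__all__ = [
    "MZ_SPC", "MZ_SPB", "MZ_MELITTIN",
    "TissuePhantom", "IonDef", "SectionSimParams", "SectionTruth",
    "CalibSimParams", "CalibTruth", "CohortSimParams", "CohortTruth",
    "generate_section", "generate_calibration_slide",
    "generate_calibration_slides", "generate_cohort",
    "params_from_yaml", "params_to_yaml", "default_calibration_params",
    "write_truth_json",
]

MZ_SPC = 3618.0      # [SP-C analog + Na]+ adduct
MZ_SPB = 3886.0      # [SP-B analog + H]+
MZ_MELITTIN = 2846.5  # [melittin + H]+

#: matrix-cluster decoy peaks present on every pixel (glass and tissue)
DECOY_MZS = (1296.7, 1523.4, 1988.1, 2467.3, 3105.9, 4231.6)
#: endogenous peaks present on tissue pixels only (lipid/peptide-like)
TISSUE_MZS = (1464.8, 1744.6, 2213.5, 2754.2, 3350.1)
#: offset of the in-window background peak from the monitored target m/z
BACKGROUND_CHANNEL_OFFSET = 0.33

_SPC_LABEL = "SP-C analog"
_SPB_LABEL = "SP-B analog"


@dataclass
class TissuePhantom:
    """Elliptical tissue footprint with optional circular holes.

    Radii and hole geometry are in pixels; the center defaults to the
    grid center. Holes emulate large airways/vessels absent of tissue.
    """

    radii: tuple[float, float] = (24.0, 26.0)  # (row, col) semi-axes
    center: tuple[float, float] | None = None  # (row, col); None = grid center
    holes: tuple[tuple[float, float, float], ...] = ()  # (row, col, radius)

    def mask(self, grid_shape: tuple[int, int]) -> np.ndarray:
        rows, cols = grid_shape
        cy, cx = self.center if self.center is not None else ((rows - 1) / 2,
                                                              (cols - 1) / 2)
        ry, rx = self.radii
        if 2 * ry > rows or 2 * rx > cols:
            raise ValueError(
                f"phantom (semi-axes {self.radii}) larger than grid {grid_shape}"
            )
        yy, xx = np.mgrid[0:rows, 0:cols]
        m = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        for hy, hx, hr in self.holes:
            m &= (yy - hy) ** 2 + (xx - hx) ** 2 > hr**2
        return m


@dataclass
class IonDef:
    """One monitored ion: target m/z, intercept of the signal law on the
    log10 scale (above background), and abundance scale in ng/pixel."""

    mz: float
    base_log10: float = 0.2
    abundance: float = 0.8


@dataclass
class SectionSimParams:
    """Parameters of one synthetic lung section."""

    grid_shape: tuple[int, int] = (60, 60)
    pixel_pitch: float = 350.0
    tissue_phantom: TissuePhantom = field(default_factory=TissuePhantom)
    ion_defs: tuple[IonDef, ...] | None = None  # None: built from abundance/sp_ratio
    abundance: float = 0.8       # SP-C analog ng/pixel at full deposition
    sp_ratio: float = 7.5        # SP-C : SP-B abundance ratio (1.5% : 0.2% mass)
    signal_slope: float = 3.1    # log10-intensity per ng (calibration law)
    signal_sigma: float = 0.12   # per-pixel residual SD of peptide log10 signal
    radial_decay: float = 0.03   # per-pixel attenuation from section center
    n_hotspots: int = 3
    hotspot_boost: float = 1.8   # multiplicative amount boost at a focus
    hotspot_sigma: float = 2.5   # focus width, pixels
    background_mu: float = 1.0   # lognormal background, log10 mean
    background_sigma: float = 0.15
    batch_offset: float = 0.0    # additive per-sample shift, log10 scale
    tissue_tic_log10: float = 2.2  # endogenous peak level on tissue pixels
    include_background: bool = True
    sample_id: str = "section"
    group: str = "treated"       # "treated" | "control"
    seed: int = 0

    def resolved_ion_defs(self) -> tuple[IonDef, ...]:
        if self.ion_defs is not None:
            return tuple(self.ion_defs)
        a = self.abundance if self.group == "treated" else 0.0
        return (IonDef(MZ_SPC, 0.2, a), IonDef(MZ_SPB, 0.2, a / self.sp_ratio))

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be > 0")
        if self.sp_ratio <= 0:
            raise ValueError("sp_ratio must be > 0")
        self.tissue_phantom.mask(self.grid_shape)  # raises if phantom too large


@dataclass
class SectionTruth:
    """Ground truth sidecar for one generated section."""

    tissue_mask: np.ndarray
    amount: dict[float, np.ndarray]  # target m/z -> true ng/pixel grid
    hotspot_centers: list[tuple[float, float]]
    batch_offset: float
    background_mu: float


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in key]))


def _spatial_profile(params: SectionSimParams, tissue: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, list]:
    """Deposition profile in [0, boost]: radial decay from the section
    center times hotspot boosts."""
    rows, cols = params.grid_shape
    cy, cx = (params.tissue_phantom.center
              or ((rows - 1) / 2, (cols - 1) / 2))
    yy, xx = np.mgrid[0:rows, 0:cols]
    d_center = np.hypot(yy - cy, xx - cx)
    profile = np.exp(-params.radial_decay * d_center)
    centers = []
    if params.n_hotspots > 0:
        ty, tx = np.nonzero(tissue)
        # foci biased toward the central half of the tissue
        order = np.argsort(d_center[ty, tx])
        pool = order[: max(1, len(order) // 2)]
        pick = rng.choice(pool, size=min(params.n_hotspots, len(pool)),
                          replace=False)
        for i in np.atleast_1d(pick):
            hy, hx = float(ty[i]), float(tx[i])
            centers.append((hy, hx))
            bump = (params.hotspot_boost - 1.0) * np.exp(
                -((yy - hy) ** 2 + (xx - hx) ** 2) / (2 * params.hotspot_sigma**2)
            )
            profile = profile * (1.0 + bump)
    return profile, centers


def _assemble_pixels(channel_grids: list[tuple[float, np.ndarray, np.ndarray]],
                     grid_shape: tuple[int, int]) -> list[Pixel]:
    """Assemble sparse per-pixel spectra from per-channel intensity grids.

    ``channel_grids`` holds (m/z, raw-intensity grid, presence mask)
    triples; channels outside the acquisition range are dropped.
    """
    chans = sorted(
        ((mz, grid, mask) for mz, grid, mask in channel_grids
         if ACQ_MZ_MIN <= mz <= ACQ_MZ_MAX),
        key=lambda c: c[0],
    )
    mz_axis = np.array([c[0] for c in chans])
    G = np.stack([c[1] for c in chans])  # (n_chan, rows, cols)
    M = np.stack([c[2] for c in chans])
    rows, cols = grid_shape
    pixels: list[Pixel] = []
    for y in range(rows):
        for x in range(cols):
            sel = M[:, y, x]
            pixels.append(Pixel(x=x, y=y, mz=mz_axis[sel],
                                intensity=G[sel, y, x]))
    return pixels


def generate_section(params: SectionSimParams) -> tuple[MSIDataset, SectionTruth]:
    """Generate one synthetic lung section and its ground-truth sidecar.

    Off-tissue pixels carry only background (and decoy matrix peaks);
    tissue pixels add endogenous TIC peaks and, where the per-pixel
    amount is non-zero, a peptide peak at the configured target m/z with
    log10 intensity ``background_mu + batch_offset + base_log10 +
    slope·amount`` plus Gaussian residual noise. Deterministic given the
    seed.
    """
    params.validate()
    rows, cols = params.grid_shape
    shape = (rows, cols)
    rng = _rng(params.seed, 0xA11CE)
    tissue = params.tissue_phantom.mask(params.grid_shape)
    profile, hotspot_centers = _spatial_profile(params, tissue, rng)
    ion_defs = params.resolved_ion_defs()

    bg_level = params.background_mu + params.batch_offset
    amounts = {
        ion.mz: np.where(tissue, ion.abundance * profile, 0.0)
        for ion in ion_defs
    }

    everywhere = np.ones(shape, dtype=bool)
    channels: list[tuple[float, np.ndarray, np.ndarray]] = []

    def lognormal_grid(mu: float) -> np.ndarray:
        return 10.0 ** rng.normal(mu, params.background_sigma, shape)

    if params.include_background:
        for mz in DECOY_MZS:
            channels.append((mz, lognormal_grid(bg_level), everywhere))
        for ion in ion_defs:
            channels.append((ion.mz + BACKGROUND_CHANNEL_OFFSET,
                             lognormal_grid(bg_level), everywhere))
        for mz in TISSUE_MZS:
            channels.append((mz,
                             lognormal_grid(params.tissue_tic_log10
                                            + params.batch_offset),
                             tissue))
    for ion in ion_defs:
        a = amounts[ion.mz]
        log10_sig = (bg_level + ion.base_log10 + params.signal_slope * a
                     + rng.normal(0.0, params.signal_sigma, shape))
        channels.append((ion.mz, 10.0**log10_sig, tissue & (a > 0)))

    pixels = _assemble_pixels(channels, shape)

    ds = MSIDataset(pixels=pixels, grid_shape=params.grid_shape,
                    pixel_pitch=params.pixel_pitch,
                    sample_id=params.sample_id, group=params.group)
    truth = SectionTruth(tissue_mask=tissue, amount=amounts,
                         hotspot_centers=hotspot_centers,
                         batch_offset=params.batch_offset,
                         background_mu=params.background_mu)
    return ds, truth


# ---------------------------------------------------------------------------
# calibration slides


@dataclass
class CalibSimParams:
    """Parameters of the calibration-slide experiment.

    Defaults mirror the study design: six amounts (1–50 ng per 0.5 μl
    spot, same amount of both peptides), a 6.25 ng melittin marker,
    three independent experiments with two replicate slides each, and a
    calibration law of 3.1 log10-intensity units per ng with intercept
    0.2 above the slide background.
    """

    amounts: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0)
    melittin_amount: float = 6.25
    n_experiments: int = 3
    n_replicates: int = 2
    slope: float = 3.1           # log10-intensity per ng
    intercept: float = 0.2       # log10-intensity above background
    exp_sd: float = 0.05         # between-experiment random-intercept SD
    pixel_sd: float = 0.1        # per-pixel residual SD
    spot_radius: float = 2.5     # pixels
    spot_spacing: float | None = None  # center-to-center; None = auto
    slide_margin: int = 10       # homogenate border around the spot row, pixels
    background_mu: float = 2.0   # homogenate chemical baseline, log10 a.u.
    background_sigma: float = 0.15
    slide_offset_sd: float = 0.2  # per-slide batch offset SD, log10 scale
    melittin_log10: float = 2.0   # marker level above slide background
    seed: int = 0

    def validate(self) -> None:
        a = np.asarray(self.amounts, dtype=float)
        if a.size < 2 or np.any(a <= 0) or np.any(np.diff(a) <= 0):
            raise ValueError("amounts must be strictly increasing and positive")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.exp_sd < 0 or self.pixel_sd < 0:
            raise ValueError("SDs must be >= 0")
        spacing = self.resolved_spacing()
        if spacing < 2 * self.spot_radius + 1:
            raise ValueError(
                f"spot spacing {spacing} overlaps spots of radius {self.spot_radius}"
            )

    def resolved_spacing(self) -> float:
        return (self.spot_spacing if self.spot_spacing is not None
                else 2 * self.spot_radius + 3)

    def grid_shape(self) -> tuple[int, int]:
        spacing = self.resolved_spacing()
        margin = int(math.ceil(self.spot_radius)) + 2 + self.slide_margin
        cols = int(math.ceil(spacing * (len(self.amounts) - 1))) + 2 * margin + 1
        rows = 2 * margin + 1
        return rows, cols


@dataclass
class CalibTruth:
    """Ground truth for one calibration slide."""

    spot_pixels: list[frozenset]  # one set per amount, deposition order
    amounts: tuple[float, ...]
    exp_effect: float
    slide_offset: float
    c_pixel: list[float]


def _spot_centers(params: CalibSimParams) -> list[tuple[float, float]]:
    rows, cols = params.grid_shape()
    spacing = params.resolved_spacing()
    margin = int(math.ceil(params.spot_radius)) + 2 + params.slide_margin
    cy = (rows - 1) / 2
    return [(cy, margin + i * spacing) for i in range(len(params.amounts))]


def generate_calibration_slide(
    params: CalibSimParams, experiment: int, replicate: int
) -> tuple[MSIDataset, CalibTruth]:
    """Generate one calibration slide (homogenate fully covering the grid).

    The experiment-level random intercept is shared by all replicate
    slides of the same experiment; the per-slide background offset and
    pixel noise differ per slide. Deterministic given (seed, experiment,
    replicate).
    """
    params.validate()
    if not (0 <= experiment < params.n_experiments):
        raise ValueError(f"experiment index {experiment} out of range")
    if not (0 <= replicate < params.n_replicates):
        raise ValueError(f"replicate index {replicate} out of range")
    exp_eff = float(_rng(params.seed, 0xE0, experiment).normal(0, params.exp_sd))
    rng = _rng(params.seed, 0xCA11B, experiment, replicate)
    slide_offset = float(rng.normal(0, params.slide_offset_sd))

    rows, cols = params.grid_shape()
    shape = (rows, cols)
    bg_level = params.background_mu + slide_offset
    centers = _spot_centers(params)
    yy, xx = np.mgrid[0:rows, 0:cols]
    spot_masks = []
    occupied = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= params.spot_radius**2
        if (m & occupied).any():
            raise ValueError("overlapping spot placement")
        occupied |= m
        spot_masks.append(m)

    c_pixels = [amt / int(m.sum()) for amt, m in zip(params.amounts, spot_masks)]
    c_grid = np.zeros(shape)
    for c, m in zip(c_pixels, spot_masks):
        c_grid[m] = c

    everywhere = np.ones(shape, dtype=bool)
    channels: list[tuple[float, np.ndarray, np.ndarray]] = []
    for mz in DECOY_MZS + TISSUE_MZS:
        channels.append(
            (mz, 10.0 ** rng.normal(bg_level, params.background_sigma, shape),
             everywhere)
        )
    # analyte/melittin channels: homogenate background off-spot, stamped
    # peak (suppressing the background) inside a spot
    for target in (MZ_SPC, MZ_SPB):
        channels.append(
            (target + BACKGROUND_CHANNEL_OFFSET,
             10.0 ** rng.normal(bg_level, params.background_sigma, shape),
             ~occupied)
        )
        sig = (bg_level + params.intercept + params.slope * c_grid + exp_eff
               + rng.normal(0.0, params.pixel_sd, shape))
        channels.append((target, 10.0**sig, occupied))
    channels.append(
        (MZ_MELITTIN + BACKGROUND_CHANNEL_OFFSET,
         10.0 ** rng.normal(bg_level, params.background_sigma, shape),
         ~occupied)
    )
    channels.append(
        (MZ_MELITTIN,
         10.0 ** (bg_level + params.melittin_log10
                  + rng.normal(0.0, params.pixel_sd, shape)),
         occupied)
    )
    pixels = _assemble_pixels(channels, shape)

    ds = MSIDataset(
        pixels=pixels, grid_shape=(rows, cols), pixel_pitch=350.0,
        sample_id=f"calib_e{experiment}_r{replicate}", group="calibration",
    )
    truth = CalibTruth(
        spot_pixels=[
            frozenset((int(x), int(y)) for y, x in np.argwhere(m))
            for m in spot_masks
        ],
        amounts=tuple(params.amounts),
        exp_effect=exp_eff,
        slide_offset=slide_offset,
        c_pixel=c_pixels,
    )
    return ds, truth


def generate_calibration_slides(
    params: CalibSimParams,
) -> list[tuple[int, int, MSIDataset, CalibTruth]]:
    """All experiment × replicate slides of the design."""
    return [
        (e, r, *generate_calibration_slide(params, e, r))
        for e in range(params.n_experiments)
        for r in range(params.n_replicates)
    ]


# ---------------------------------------------------------------------------
# animal cohorts


@dataclass
class CohortSimParams:
    """Synthetic cohort: treated and control animals with one latent
    peripheral-deposition factor per treated animal.

    ``effect_map`` gives the full-deposition, end-of-follow-up shift of
    each parameter: on the log10 scale for PaO2/PaCO2, on the natural
    scale otherwise (cmH2O for PIP, mL/kg/cmH2O for Cdyn, ...). Signs
    encode direction (PaO2/Cdyn up, PIP/PaCO2 down under treatment).
    """

    n_treated: int = 7
    n_control: int = 5
    timepoints: tuple[float, ...] = (0.0, 5.0, 30.0, 60.0, 90.0, 120.0)
    deposition_sigma: float = 0.5   # lognormal shape of the latent factor
    effect_map: dict[str, float] = field(default_factory=lambda: {
        "PaO2": 0.85, "PaCO2": -0.35, "pH": 0.25,
        "Cdyn": 0.25, "PIP": -12.0, "VT": 1.5, "MAP": -4.0, "HR": 0.0,
    })
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "PaO2": 0.05, "PaCO2": 0.04, "pH": 0.03,
        "Cdyn": 0.015, "PIP": 1.0, "VT": 0.4, "MAP": 1.0, "HR": 8.0,
    })
    baselines: dict[str, float] = field(default_factory=lambda: {
        "PaO2": 55.0, "PaCO2": 115.0, "pH": 7.05,
        "Cdyn": 0.13, "PIP": 34.0, "VT": 5.5, "MAP": 15.0, "HR": 170.0,
    })
    response_tau: float = 30.0      # minutes to ~63% of the full effect
    abundance_gain: float = 0.8     # SP-C ng/pixel per unit deposition
    section_grid: tuple[int, int] = (60, 60)
    section_kwargs: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("need >= 2 animals per group")


@dataclass
class CohortTruth:
    """Latent deposition factor per animal (0 for controls)."""

    deposition: dict[str, float]


#: parameters whose noise and effects act on the log10 scale
_LOG_SCALE = ("PaO2", "PaCO2")


def generate_cohort(
    params: CohortSimParams,
) -> tuple[list[PhysioSeries], list[SectionSimParams], CohortTruth]:
    """Generate per-animal physiology and matched section parameters.

    The latent deposition factor ``d`` of each treated animal scales
    both the peptide abundance of its section and the physiological
    improvement: value(t) = baseline ∘ (effect · d · (1 − e^{−t/τ})) +
    noise, applied on the log10 scale for PaO2/PaCO2 and additively
    otherwise. Controls have d = 0.
    """
    params.validate()
    rng = _rng(params.seed, 0xC0117)
    t = np.asarray(params.timepoints, dtype=float)
    response = 1.0 - np.exp(-t / params.response_tau)

    animals = [(f"SF{i+1:02d}", "treated") for i in range(params.n_treated)]
    animals += [(f"C{i+1:02d}", "control") for i in range(params.n_control)]

    deposition: dict[str, float] = {}
    series: list[PhysioSeries] = []
    section_params: list[SectionSimParams] = []
    for j, (aid, grp) in enumerate(animals):
        d = float(rng.lognormal(mean=0.0, sigma=params.deposition_sigma)) \
            if grp == "treated" else 0.0
        deposition[aid] = d
        for pname, base in params.baselines.items():
            gain = params.effect_map.get(pname, 0.0)
            sd = params.noise_sd.get(pname, 0.0)
            noise = rng.normal(0.0, sd, size=t.size) if sd > 0 else np.zeros(t.size)
            if pname in _LOG_SCALE:
                logv = np.log10(base) + gain * d * response + noise
                vals = 10.0**logv
            else:
                vals = base + gain * d * response + noise
                vals = np.maximum(vals, 1e-6)
            series.append(PhysioSeries(animal_id=aid, group=grp, parameter=pname,
                                       time_min=t.copy(), values=vals))
        section_params.append(SectionSimParams(
            grid_shape=params.section_grid,
            abundance=params.abundance_gain * d,
            sample_id=aid,
            group=grp,
            seed=int(_rng(params.seed, 0x5EC, j).integers(0, 2**31 - 1)),
            **params.section_kwargs,
        ))
    return series, section_params, CohortTruth(deposition=deposition)


# ---------------------------------------------------------------------------
# parameter files and sidecars


_PARAM_CLASSES = {
    "section": SectionSimParams,
    "calibration": CalibSimParams,
    "cohort": CohortSimParams,
}


def params_to_yaml(params, path: str | Path) -> None:
    """Serialize a parameter dataclass to YAML (with a ``kind`` tag)."""
    kind = {SectionSimParams: "section", CalibSimParams: "calibration",
            CohortSimParams: "cohort"}[type(params)]
    doc = {"kind": kind, **asdict(params)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def params_from_yaml(path: str | Path):
    """Load a parameter dataclass from a YAML file written by
    :func:`params_to_yaml` (or hand-edited)."""
    doc = yaml.safe_load(Path(path).read_text())
    kind = doc.pop("kind")
    cls = _PARAM_CLASSES[kind]
    if cls is SectionSimParams:
        if isinstance(doc.get("tissue_phantom"), dict):
            tp = doc["tissue_phantom"]
            doc["tissue_phantom"] = TissuePhantom(
                radii=tuple(tp.get("radii", (24.0, 26.0))),
                center=tuple(tp["center"]) if tp.get("center") else None,
                holes=tuple(tuple(h) for h in tp.get("holes", ())),
            )
        if doc.get("ion_defs") is not None:
            doc["ion_defs"] = tuple(IonDef(**d) for d in doc["ion_defs"])
        doc["grid_shape"] = tuple(doc["grid_shape"])
    if cls is CalibSimParams:
        doc["amounts"] = tuple(doc["amounts"])
    if cls is CohortSimParams:
        doc["timepoints"] = tuple(doc["timepoints"])
        doc["section_grid"] = tuple(doc["section_grid"])
    return cls(**doc)


def default_calibration_params() -> CalibSimParams:
    """The packaged default calibration design (study layout)."""
    from importlib.resources import files

    return params_from_yaml(files("surfmsi") / "data" / "calibration_default.yaml")


def write_truth_json(truth, path: str | Path) -> None:
    """Serialize a ground-truth sidecar (masks/amounts as nested lists)."""

    def conv(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(conv(asdict(truth))))
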