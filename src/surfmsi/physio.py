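"""Physiological time-course processing and MSI association.

Per-animal ventilation and gas-exchange parameters (PaO2, PaCO2, pH, BE,
Cdyn, PIP, VT, MAP, HR, SBP, DBP, MABP, SaO2, temperature) are sampled at
fixed times over a 120-minute follow-up. PaO2 and PaCO2 are
log10-transformed before analysis to compensate for their skewed
distributions. Each series is summarized by its trapezoidal area under
the curve (AUC) and the value at the final time point; groups are
compared with Student's t-test routed by Levene's (Brown–Forsythe)
test for equality of variances, and summaries are associated with
section-level MSI intensity metrics by Spearman correlation.

Dynamic lung compliance is ``Cdyn = ΔV / (ΔP · weight)`` with ΔV the
tidal volume in mL, ΔP the driving pressure (PIP − PEEP) in cmH2O and
weight in kg, giving mL/kg/cmH2O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KNOWN_PARAMETERS",
    "LOG_PARAMETERS",
    "PhysioSeries",
    "PhysioSummary",
    "GroupTest",
    "AssociationResult",
    "compute_cdyn",
    "transform_series",
    "compute_auc",
    "endpoint",
    "summarize_series",
    "group_compare",
    "associate",
    "read_physio_tsv",
    "write_physio_tsv",
]

KNOWN_PARAMETERS = (
    "PaO2", "PaCO2", "pH", "BE", "Cdyn", "PIP", "VT", "MAP", "HR",
    "SBP", "DBP", "MABP", "SaO2", "temperature",
)
#: parameters analysed on the log10 scale
LOG_PARAMETERS = ("PaO2", "PaCO2")

LEVENE_ALPHA = 0.05


@dataclass
class PhysioSeries:
    """One parameter's time course for one animal."""

    animal_id: str
    group: str  # "treated" | "control"
    parameter: str
    time_min: np.ndarray
    values: np.ndarray
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_min.shape != self.values.shape:
            raise ValueError("time and value arrays must have equal length")
        if self.time_min.size and np.any(np.diff(self.time_min) <= 0):
            raise ValueError(
                f"{self.animal_id}/{self.parameter}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.animal_id}/{self.parameter}: non-finite value")


@dataclass
class PhysioSummary:
    """AUC and final-time-point summary of one series (analysis scale)."""

    animal_id: str
    group: str
    parameter: str
    auc: float
    endpoint_120: float
    endpoint_time: float = 120.0


@dataclass
class GroupTest:
    """Two-group comparison of one summary statistic."""

    parameter: str
    summary: str  # "auc" | "endpoint"
    t: float
    p: float
    levene_p: float
    equal_var: bool


@dataclass
class AssociationResult:
    """Spearman association of a physiology summary with an MSI metric."""

    parameter: str
    msi_metric: str  # "avg_log10_I" | "sum_log10_I"
    ion: str
    rho: float
    n: int


def compute_cdyn(delta_v: float, delta_p: float, weight: float) -> float:
    """Dynamic compliance ΔV/(ΔP·weight) in mL/kg/cmH2O."""
    delta_p = float(delta_p)
    weight = float(weight)
    if delta_p <= 0:
        raise ValueError("ΔP must be positive")
    if weight <= 0:
        raise ValueError("weight must be positive")
    return float(delta_v) / (delta_p * weight)


def transform_series(series: PhysioSeries) -> PhysioSeries:
    """log10-transform PaO2/PaCO2 series; all others pass through.

    Refuses to transform twice — the returned series carries a
    ``log_transformed`` flag.
    """
    if series.parameter not in LOG_PARAMETERS:
        return series
    if series.log_transformed:
        raise ValueError(
            f"{series.animal_id}/{series.parameter} is already log-transformed"
        )
    bad = np.nonzero(series.values <= 0)[0]
    if bad.size:
        t = series.time_min[bad[0]]
        raise ValueError(
            f"non-positive {series.parameter} for animal {series.animal_id} "
            f"at t={t:g} min; cannot log-transform"
        )
    return replace(series, values=np.log10(series.values), log_transformed=True)


def compute_auc(series: PhysioSeries) -> float:
    """Trapezoidal area under the curve over the observed times."""
    if series.time_min.size < 2:
        raise ValueError("AUC needs at least 2 timepoints")
    return float(np.trapezoid(series.values, series.time_min))


def endpoint(series: PhysioSeries, t: float = 120.0) -> float:
    """Value at time ``t``; the exact time must be present (no interpolation)."""
    hit = np.nonzero(np.isclose(series.time_min, t))[0]
    if hit.size == 0:
        raise ValueError(
            f"time {t:g} min not sampled for {series.animal_id}/{series.parameter} "
            f"(have {series.time_min.tolist()})"
        )
    return float(series.values[hit[0]])


def summarize_series(series: PhysioSeries, endpoint_time: float = 120.0) -> PhysioSummary:
    """AUC + endpoint summary on the analysis scale (log10 for PaO2/PaCO2)."""
    s = transform_series(series) if (
        series.parameter in LOG_PARAMETERS and not series.log_transformed
    ) else series
    return PhysioSummary(
        animal_id=s.animal_id,
        group=s.group,
        parameter=s.parameter,
        auc=compute_auc(s),
        endpoint_120=endpoint(s, endpoint_time),
        endpoint_time=endpoint_time,
    )


def group_compare(
    treated: np.ndarray,
    control: np.ndarray,
    parameter: str = "",
    summary: str = "auc",
    alpha: float = LEVENE_ALPHA,
) -> GroupTest:
    """Student's t-test with Levene's test deciding the variance assumption.

    Levene's test uses median centering (Brown–Forsythe). If it rejects
    equality of variances at ``alpha``, Welch's unequal-variance t-test
    is used; otherwise the pooled-variance test. Two-sided p value.
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 animals per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero variance in both groups; t-test undefined")
    _lw, levene_p = stats.levene(a, b, center="median")
    equal_var = bool(levene_p >= alpha)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupTest(parameter=parameter, summary=summary, t=float(t),
                     p=float(p), levene_p=float(levene_p), equal_var=equal_var)


def associate(
    physio_summaries: pd.DataFrame,
    section_summaries: pd.DataFrame,
    parameters: tuple[str, ...] = ("PaO2", "Cdyn", "PIP"),
    summary: str = "auc",
) -> list[AssociationResult]:
    """Spearman correlation of physiology summaries with MSI metrics.

    ``physio_summaries``: columns animal_id, group, parameter, auc,
    endpoint_120. ``section_summaries``: columns sample_id, ion,
    avg_log10_I, sum_log10_I (one row per treated animal per ion).
    Only treated animals with both measurements enter; ties get average
    ranks (scipy default). Requires >= 3 matched animals.
    """
    phys = physio_summaries[physio_summaries["group"] == "treated"]
    out: list[AssociationResult] = []
    for param in parameters:
        pp = phys[phys["parameter"] == param].set_index("animal_id")[summary]
        for ion in sorted(section_summaries["ion"].unique()):
            sec = section_summaries[section_summaries["ion"] == ion].set_index("sample_id")
            common = pp.index.intersection(sec.index)
            if len(common) < 3:
                raise ValueError(
                    f"need >= 3 matched treated animals for {param}/{ion}, "
                    f"got {len(common)}"
                )
            for metric in ("avg_log10_I", "sum_log10_I"):
                rho, _p = stats.spearmanr(pp.loc[common], sec.loc[common, metric])
                out.append(AssociationResult(parameter=param, msi_metric=metric,
                                             ion=ion, rho=float(rho), n=len(common)))
    return out


def write_physio_tsv(series_list: list[PhysioSeries], path) -> None:
    """Long-format TSV: animal_id, group, time_min, parameter, value."""
    rows = [
        (s.animal_id, s.group, t, s.parameter, v)
        for s in series_list
        for t, v in zip(s.time_min, s.values)
    ]
    pd.DataFrame(rows, columns=["animal_id", "group", "time_min", "parameter", "value"]
                 ).to_csv(path, sep="\t", index=False)


def read_physio_tsv(path) -> list[PhysioSeries]:
    """Read the long-format physiology TSV back into series objects."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (aid, grp, param), sub in df.groupby(["animal_id", "group", "parameter"],
                                             sort=True):
        sub = sub.sort_values("time_min")
        out.append(PhysioSeries(animal_id=str(aid), group=str(grp), parameter=str(param),
                                time_min=sub["time_min"].to_numpy(),
                                values=sub["value"].to_numpy()))
    return out
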