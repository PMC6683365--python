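"""End-to-end helpers chaining the per-module operations.

These wrappers run the standard per-section and calibration flows so
scripts and tests do not re-plumb the same sequence: ion extraction →
log transform → tissue segmentation → background model → batch
correction → masks → summaries, and (for calibration) slide generation
→ spot processing → mixed-effects fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibrate, msi_io, preprocess, simgen, spatial_stats

__all__ = ["ProcessedSection", "process_section", "run_calibration"]


@dataclass
class ProcessedSection:
    """Everything the pipeline derives from one section and one ion."""

    sample_id: str
    group: str
    ion: str
    corrected: preprocess.LogIonImage
    model: preprocess.BackgroundModel
    tissue: np.ndarray


def process_section(
    dataset: msi_io.MSIDataset,
    target_mz: float,
    ion_label: str = "",
    tolerance: float = 1.0,
    pseudocount: float = preprocess.DEFAULT_PSEUDOCOUNT,
    mode_on: str = "all",
) -> ProcessedSection:
    """Extract one ion, segment tissue, fit the background model and
    batch-correct. The noise threshold is estimated separately from
    pooled control sections (see :func:`surfmsi.preprocess.
    estimate_noise_threshold`) because it must not see treated data."""
    image = msi_io.extract_ion_image(dataset, target_mz, tolerance)
    log_img = preprocess.log_transform(image, pseudocount)
    tissue = preprocess.segment_tissue(dataset)
    model = preprocess.estimate_background_model(log_img, mode_on=mode_on)
    corrected = preprocess.batch_correct(log_img, model)
    return ProcessedSection(sample_id=dataset.sample_id, group=dataset.group,
                            ion=ion_label or f"m/z {target_mz:g}",
                            corrected=corrected, model=model, tissue=tissue)


def masks_for(
    section: ProcessedSection, threshold: float
) -> preprocess.PixelMasks:
    """Assemble tissue / above-noise / background masks for a section."""
    above = preprocess.above_noise_mask(section.corrected, threshold,
                                        section.tissue)
    background = section.corrected.present & ~above
    masks = preprocess.PixelMasks(tissue=section.tissue, above_noise=above,
                                  background=background)
    masks.validate()
    return masks


def summarize_section(
    section: ProcessedSection, threshold: float
) -> spatial_stats.SectionSummary:
    masks = masks_for(section, threshold)
    return spatial_stats.section_summary(section.corrected, masks,
                                         sample_id=section.sample_id,
                                         ion=section.ion)


def cohort_association(
    params: simgen.CohortSimParams,
    target_mz: float = simgen.MZ_SPB,
    ion_label: str = "SP-B analog",
    parameters: tuple[str, ...] = ("PaO2", "Cdyn", "PIP"),
):
    """Full cohort flow: physiology summaries, per-animal MSI sections,
    control-pooled noise threshold, section summaries, Spearman
    associations (treated animals only).

    Returns ``(association results, physiology summary frame, section
    summary frame)``.
    """
    import pandas as pd

    from . import physio

    series, section_params, _truth = simgen.generate_cohort(params)
    rows = []
    for s in series:
        if s.parameter in parameters:
            summ = physio.summarize_series(s)
            rows.append((summ.animal_id, summ.group, summ.parameter,
                         summ.auc, summ.endpoint_120))
    phys = pd.DataFrame(rows, columns=["animal_id", "group", "parameter",
                                       "auc", "endpoint_120"])
    sections = []
    control_pool = []
    for p in section_params:
        ds, _ = simgen.generate_section(p)
        sec = process_section(ds, target_mz, ion_label)
        sections.append(sec)
        if p.group == "control":
            control_pool.append(sec.corrected.values[sec.corrected.present])
    threshold = preprocess.estimate_noise_threshold(np.concatenate(control_pool))
    summaries = spatial_stats.summaries_to_frame(
        [summarize_section(s, threshold) for s in sections
         if s.group == "treated"])
    results = physio.associate(phys, summaries, parameters=parameters,
                               summary="auc")
    return results, phys, summaries


def run_calibration(
    params: simgen.CalibSimParams,
    target_mz: float = simgen.MZ_SPC,
) -> tuple[calibrate.CalibrationFit, "object"]:
    """Generate the full slide design and run calibration steps 1–4.

    Returns the mixed-effects fit and the calibration table (one row per
    spot per slide).
    """
    spots: list[calibrate.CalibrationSpot] = []
    for e, r, ds, _truth in simgen.generate_calibration_slides(params):
        analyte = msi_io.extract_ion_image(ds, target_mz)
        melittin = msi_io.extract_ion_image(ds, simgen.MZ_MELITTIN)
        spots.extend(
            calibrate.process_calibration_slide(
                analyte, melittin, list(params.amounts),
                experiment_id=f"e{e}", replicate_id=f"r{r}",
            )
        )
    table = calibrate.build_calibration_table(spots)
    fit = calibrate.fit_calibration(table)
    return fit, table
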