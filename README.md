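# surfmsi

Label-free quantification of exogenous surfactant peptides in lung
sections by MALDI mass spectrometry imaging (MSI).

Surfactant replacement therapy for neonatal respiratory distress works
only as well as the surfactant distributes through the lung. `surfmsi`
implements an analysis pipeline for locating and quantifying the two
synthetic peptides of a peptide-containing synthetic surfactant — an
SP-C analog (monitored as its sodium adduct at m/z 3618) and an SP-B
analog (protonated ion at m/z 3886) — directly from imzML imaging
datasets of cryo-sectioned lung, with no radioactive or fluorescent
label. It also links the resulting section-level intensity summaries to
the physiological response of the treated animal (oxygenation,
compliance, ventilation pressures).

The pipeline is aimed at preclinical drug-distribution studies; because
raw imaging data of this kind are rarely shareable, the package ships a
first-class synthetic-data generator (`surfmsi.simgen`) that emulates
sections, calibration slides and animal cohorts with the statistical
structure the analysis assumes, so every stage is testable end to end.

## What it computes

**Ion images.** Each pixel's spectrum (full scan, 1200–4500 m/z) is
reduced to the summed intensity of all peaks within ±1 Da of the target
ion (closed window).

**Normalization.** Intensities are log10-transformed (pseudocount 1).
Tissue is segmented from total ion current. Per sample and per ion, the
mode of the log-intensity density (Gaussian KDE, Silverman bandwidth) is
subtracted — batch correction that sets the background mean to zero.
A hard noise threshold is the 99.5% quantile of the pooled corrected
intensities of untreated control sections.

**Quantification.** Calibration slides carry six spots (1–50 ng per
0.5 µl drop of each peptide) plus a 6.25 ng melittin marker that
localizes the deposition areas. After background-cluster subtraction and
melittin-based spot detection, the mean adjusted log10 signal of each
spot is modeled against the per-pixel spotted amount c_pixel (ng) with a
linear mixed-effects model (random intercept per experiment, REML):

    signal_pixel = b1 * c_pixel + b0  (+ u_experiment + noise)

Inverting the fitted line and its 95% confidence envelope converts
corrected section images into ng-per-pixel maps with confidence bounds.

**Summaries and associations.** Each section and ion is summarized by
`Avg_log10_I` (mean corrected intensity over tissue pixels) and
`Sum_log10_I` (sum over above-noise pixels); signal is also profiled by
binned Euclidean distance to the tissue border (default 15 bins over
0.7–35.5 px). Physiological time courses (PaO2, PaCO2, pH, Cdyn, PIP,
VT, MAP, HR, ...; PaO2/PaCO2 on the log10 scale) are summarized by
trapezoidal AUC and the 120-minute endpoint, compared between groups by
Student's t-test with Levene routing, and associated with the MSI
summaries by Spearman correlation. Dynamic compliance is
Cdyn = ΔV/(ΔP·weight) in mL/kg/cmH2O.

## Worked example

```python
import numpy as np
from dataclasses import replace
from surfmsi import simgen, preprocess, calibrate, workflow

# fit the calibration curve from a full synthetic slide design
params = simgen.default_calibration_params()
fit, table = workflow.run_calibration(replace(params, seed=7))

# quantify one treated section against two control sections
sect = simgen.SectionSimParams(seed=11, batch_offset=0.4, sample_id="SF01")
ds, truth = simgen.generate_section(sect)
sec = workflow.process_section(ds, simgen.MZ_SPC, "SP-C analog")
pool = [workflow.process_section(
            simgen.generate_section(replace(sect, seed=s, group="control"))[0],
            simgen.MZ_SPC).corrected for s in (101, 102)]
thr = preprocess.estimate_noise_threshold(
    np.concatenate([c.values[c.present] for c in pool]))
summary = workflow.summarize_section(sec, thr)
qm = calibrate.quantify(sec.corrected, fit,
                        workflow.masks_for(sec, thr).above_noise)
```

This prints (seed 7 / 11 as above):

```
calibration: slope = 3.103 (95% CI 3.095-3.111), intercept = 0.216 (95% CI 0.150-0.282)
background mode (log10) = 1.419; noise threshold = 0.377
section SF01: Avg_log10_I = 1.792, Sum_log10_I = 3526.3 over 1968/1968 pixels
total SP-C analog in section: 1000 ng (95% CI 955-1044)
```

The fitted slope/intercept recover the generating calibration law
(3.1 log10-intensity units per ng, intercept 0.2 above background); the
batch-correction mode absorbs the section's 0.4 log10 batch offset on
top of its background level; every tissue pixel of this strongly dosed
section clears the control-derived noise threshold; and summing the
inverted per-pixel amounts gives the section's total peptide load with
a confidence envelope propagated from the calibration fit.

## Layout

- `surfmsi.msi_io` — imzML/ibd read and write (continuous + processed), ion-image extraction
- `surfmsi.preprocess` — log transform, tissue segmentation, background clustering, KDE-mode batch correction, noise thresholding
- `surfmsi.calibrate` — spot detection, calibration table, mixed-effects fit, inverse prediction with CIs
- `surfmsi.spatial_stats` — section summaries, border-distance transform, binned profiles
- `surfmsi.physio` — time-course transforms, AUC/endpoint summaries, group tests, Spearman association
- `surfmsi.simgen` — synthetic sections, calibration slides and cohorts with ground-truth sidecars
- `surfmsi.workflow` — end-to-end helpers chaining the above
- `surfmsi.viz` — PNG ion maps and association heatmaps

See `docs/methods.md` for the modeling choices and their rationale.
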