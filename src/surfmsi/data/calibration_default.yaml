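# Default calibration-slide design: six-point curve (ng per 0.5 ul spot),
# melittin deposition marker, three independent experiments with two
# replicate slides each; signal law 3.1 log10-units per ng, intercept 0.2.
kind: calibration
amounts: [1.0, 2.5, 5.0, 10.0, 25.0, 50.0]
melittin_amount: 6.25
n_experiments: 3
n_replicates: 2
slope: 3.1
intercept: 0.2
exp_sd: 0.05
pixel_sd: 0.1
spot_radius: 2.5
spot_spacing: null
slide_margin: 10
background_mu: 2.0
background_sigma: 0.15
slide_offset_sd: 0.2
melittin_log10: 2.0
seed: 0
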