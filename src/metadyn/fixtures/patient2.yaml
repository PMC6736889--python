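# Virtual patient 2: lung squamous cell carcinoma, 53.7 mm at diagnosis.
# Calibrating from (53.7 mm, DT 104 d, K 1e12) reproduces the published
# patient-2 Gompertz pair (0.0858, 3.10e-3 per day) to printed precision.
histology: squamous
diameter_at_diagnosis_mm: 53.7
scenario_variant: dormancy
mu: 1.02e-12
gamma: 1.0
tau_days: 171.0
tgi_alpha1: 0.0101
tgi_kappa: 0.0439
tgi_t_res: 35.4
bm_visibility_mm: 3.0
ct_visibility_mm: 5.0
# 11 PT scans and 4 BM scan times (months 11-15; the model yields 16
# visible-lesion measurements over these 4 scans)
pt_scan_times_days: [0.0, 46.0, 91.0, 137.0, 183.0, 274.0, 365.0, 457.0, 548.0, 640.0, 731.0]
bm_scan_times_days: [334.8125, 395.6875, 425.25, 456.5625]
pt_diameter_cv: 0.0
bm_diameter_cv: 0.0
count_noise_sigma: 0.5
seed: 2
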