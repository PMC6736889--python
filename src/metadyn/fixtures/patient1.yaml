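# Virtual patient 1: lung adenocarcinoma, 36.0 mm at diagnosis.
# Parameter values are the published patient-1 estimates; growth is
# re-calibrated from (diameter, histology doubling time, carrying
# capacity), of which the published Gompertz pair is the rounded output.
histology: adenocarcinoma
diameter_at_diagnosis_mm: 36.0
scenario_variant: dormancy
mu: 2.00e-12
gamma: 1.0
tau_days: 133.0
tgi_alpha1: 5.72e-4
tgi_kappa: 4.46e-3
tgi_t_res: 149.0
bm_visibility_mm: 3.0
ct_visibility_mm: 5.0
# 10 PT scans and 6 BM scan times (months 20-38 post-diagnosis; the
# model yields 47 visible-lesion measurements over these 6 scans)
pt_scan_times_days: [0.0, 61.0, 122.0, 183.0, 274.0, 365.0, 548.0, 731.0, 1096.0, 1461.0]
bm_scan_times_days: [608.75, 760.9375, 913.125, 1004.4375, 1095.75, 1156.625]
pt_diameter_cv: 0.0
bm_diameter_cv: 0.0
count_noise_sigma: 0.5
seed: 1
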