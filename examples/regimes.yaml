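# Five-regime synthetic population for `bpcluster simulate --config regimes.yaml`.
#
# Each entry is one parameter regime: per-beat PTT (s), PIR (IH/IL ratio)
# and HR (bpm) are drawn from the stated means/SDs, and per-beat SBP/DBP
# follow the regime's response
#   BP = intercept + ptt*PTT + pir*PIR + hr*HR + inv_ptt/PTT + N(0, noise_sd_mmHg).
# This file reproduces the library's default_regimes() population.
- regime_id: 1
  hr_mean_bpm: 85.0
  hr_sd: 3.0
  ptt_mean_s: 0.22
  ptt_sd: 0.012
  pir_mean: 2.0
  pir_sd: 0.07
  sbp_coeffs:
    intercept: -493.5714
    inv_ptt: 44.3667
    pir: 114.2857
    hr: 2.3333
  dbp_coeffs:
    intercept: -485.7143
    inv_ptt: 39.93
    pir: 102.8571
    hr: 2.1
  noise_sd_mmHg: 3.0
  n_beats: 400
- regime_id: 2
  hr_mean_bpm: 91.0
  hr_sd: 3.0
  ptt_mean_s: 0.262
  ptt_sd: 0.012
  pir_mean: 2.245
  pir_sd: 0.07
  sbp_coeffs:
    intercept: -105.9286
    inv_ptt: 62.9237
    pir: -114.2857
    hr: 2.3333
  dbp_coeffs:
    intercept: -128.3357
    inv_ptt: 56.6313
    pir: -102.8571
    hr: 2.1
  noise_sd_mmHg: 3.0
  n_beats: 400
- regime_id: 3
  hr_mean_bpm: 98.5
  hr_sd: 3.0
  ptt_mean_s: 0.238
  ptt_sd: 0.012
  pir_mean: 1.79
  pir_sd: 0.07
  sbp_coeffs:
    intercept: 428.4286
    inv_ptt: -51.9237
    pir: 114.2857
    hr: -2.3333
  dbp_coeffs:
    intercept: 337.0857
    inv_ptt: -46.7313
    pir: 102.8571
    hr: -2.1
  noise_sd_mmHg: 3.0
  n_beats: 400
- regime_id: 4
  hr_mean_bpm: 97.0
  hr_sd: 3.0
  ptt_mean_s: 0.196
  ptt_sd: 0.012
  pir_mean: 2.21
  pir_sd: 0.07
  sbp_coeffs:
    intercept: 21.5714
    inv_ptt: 35.2147
    pir: -114.2857
    hr: 2.3333
  dbp_coeffs:
    intercept: -28.0857
    inv_ptt: 31.6932
    pir: -102.8571
    hr: 2.1
  noise_sd_mmHg: 3.0
  n_beats: 400
- regime_id: 5
  hr_mean_bpm: 77.5
  hr_sd: 3.0
  ptt_mean_s: 0.28
  ptt_sd: 0.012
  pir_mean: 1.895
  pir_sd: 0.07
  sbp_coeffs:
    intercept: 320.9286
    inv_ptt: -71.8667
    pir: 114.2857
    hr: -2.3333
  dbp_coeffs:
    intercept: 253.8357
    inv_ptt: -64.68
    pir: 102.8571
    hr: -2.1
  noise_sd_mmHg: 3.0
  n_beats: 400
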