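{
  "description": "Published summary statistics for the 133-kiwifruit reference dataset (three varieties; 88 calibration / 45 prediction at a 2:1 split) and the headline model results reported on it. SDs use divisor n-1; SEP/RPD as defined in the evaluation module.",
  "version": 1,
  "calibration_set": {
    "n": 88,
    "range": {"firmness": [44.086, 642.213], "ssc": [13.56, 18.69], "ph": [3.64, 4.04]},
    "mean": {"firmness": 228.559, "ssc": 16.02, "ph": 3.78},
    "sd": {"firmness": 200.688, "ssc": 1.20, "ph": 0.09}
  },
  "prediction_set": {
    "n": 45,
    "range": {"firmness": [47.756, 538.324], "ssc": [13.09, 18.04], "ph": [3.65, 3.81]},
    "mean": {"firmness": 220.682, "ssc": 15.90, "ph": 3.75},
    "sd": {"firmness": 189.78, "ssc": 1.33, "ph": 0.04}
  },
  "variety_counts": {"Xuxiang": 40, "Hongyang": 52, "Cuixiang": 41},
  "headline_models": [
    {"id": "plsr_full_firmness", "attribute": "firmness", "spectral_range_nm": [450, 1000],
     "model": "PLSR (full spectrum)", "sep": 40.3191, "rpd_printed": 4.71},
    {"id": "plsr_full_ssc", "attribute": "ssc", "spectral_range_nm": [450, 1000],
     "model": "PLSR (full spectrum)", "sep": 0.4260, "rpd_printed": 3.12},
    {"id": "plsr_full_ph", "attribute": "ph", "spectral_range_nm": [951, 1670],
     "model": "PLSR (full spectrum)", "sep": 0.0174, "rpd_printed": 2.30},
    {"id": "spa_mlr_firmness", "attribute": "firmness", "spectral_range_nm": [450, 1000],
     "model": "SPA-MLR", "sep": 36.7222, "rpd_printed": 5.17},
    {"id": "spa_mlr_ssc", "attribute": "ssc", "spectral_range_nm": [450, 1000],
     "model": "SPA-MLR", "sep": 0.4078, "rpd_printed": 3.26},
    {"id": "gapls_lssvm_ph", "attribute": "ph", "spectral_range_nm": [951, 1670],
     "model": "GAPLS-LS-SVM", "sep": 0.0154, "rpd_printed": 2.60}
  ],
  "full_spectrum_bands": {"visnir": 512, "nir": 256}
}
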