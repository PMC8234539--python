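{
  "_comment": "Published prostate-cancer point systems. CAPRA: Cooperberg et al., J Urol 2005 (preoperative, 0-10). CAPRA-S: Cooperberg et al., Cancer 2011 (postoperative, 0-12). NCCN three-tier localized risk groups. Edit here, not in code.",
  "capra": {
    "psa_points": [
      {"max": 6.0, "points": 0},
      {"max": 10.0, "points": 1},
      {"max": 20.0, "points": 2},
      {"max": 30.0, "points": 3},
      {"max": null, "points": 4}
    ],
    "gleason_group_points": {"1": 0, "2": 1, "3": 3, "4": 3, "5": 3},
    "ct_points": {"1": 0, "2": 0, "3": 1, "4": 1},
    "ppb_points": [
      {"max": 33.999, "points": 0},
      {"max": null, "points": 1}
    ],
    "age_points": [
      {"max": 49.999, "points": 0},
      {"max": null, "points": 1}
    ],
    "risk_bins": {"low_max": 2, "intermediate_max": 5}
  },
  "capra_s": {
    "psa_points": [
      {"max": 6.0, "points": 0},
      {"max": 10.0, "points": 1},
      {"max": 20.0, "points": 2},
      {"max": null, "points": 3}
    ],
    "gleason_group_points": {"1": 0, "2": 1, "3": 3, "4": 3, "5": 3},
    "sm_points": 2,
    "epe_points": 1,
    "svi_points": 2,
    "ln_points": 1,
    "risk_bins": {"low_max": 2, "intermediate_max": 5}
  },
  "nccn": {
    "low": {"ct_max": 2, "gg_max": 1, "psa_max": 10.0},
    "high_any": {"ct_min": 3, "gg_min": 4, "psa_min": 20.0}
  }
}
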