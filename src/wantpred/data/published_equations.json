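{
  "version": "1.0",
  "notes": "Published multiple-regression equations for Wingate peak power (PP) and mean power (MP) at 85/90/100% of age-predicted HRmax. Coefficients apply to z-scored predictors; intercepts are watts at the standardized origin. Untagged 'Predicted VO2' terms are read as the absolute (mL/min) value by parallelism with the tagged columns.",
  "equations": [
    {
      "outcome": "PP",
      "level": 0.85,
      "intercept": 644,
      "terms": [
        ["vo2_abs@85", 225],
        ["vo2_rel@85", -87],
        ["slope_speed_time@85", -26]
      ],
      "provenance": "peak-power table, 85% column"
    },
    {
      "outcome": "PP",
      "level": 0.9,
      "intercept": 642,
      "terms": [
        ["vo2_abs@90", 193],
        ["vo2_at_at_rel@90", -99],
        ["slope_speed_time@90", -25],
        ["vo2_at_at_abs@90", 34]
      ],
      "provenance": "peak-power table, 90% column"
    },
    {
      "outcome": "PP",
      "level": 1.0,
      "intercept": 645,
      "terms": [
        ["vo2_abs@100", 225],
        ["vo2_rel@100", -100],
        ["slope_speed@100", 67],
        ["slope_speed_time@100", -32]
      ],
      "provenance": "peak-power table, 100% column"
    },
    {
      "outcome": "MP",
      "level": 0.85,
      "intercept": 475,
      "terms": [
        ["vo2_abs@85", 154],
        ["vo2_at_at_rel@85", -93],
        ["time_at_level@85", 27],
        ["vo2_at_at_abs@85", 6]
      ],
      "provenance": "mean-power table, 85% column"
    },
    {
      "outcome": "MP",
      "level": 0.9,
      "intercept": 478,
      "terms": [
        ["vo2_abs@90", 167],
        ["vo2_at_at_rel@90", -101],
        ["time_at_level@90", 33]
      ],
      "provenance": "mean-power table, 90% column"
    },
    {
      "outcome": "MP",
      "level": 1.0,
      "intercept": 478,
      "terms": [
        ["vo2_abs@100", 156],
        ["vo2_rel@100", -39]
      ],
      "provenance": "mean-power table, 100% column"
    }
  ]
}
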