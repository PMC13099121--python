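{
  "description": "Synthetic, non-authoritative grading rule set. Round-number thresholds loosely modeled on Japanese health-screening (Ningen Dock style) conventions, for exercising the pipeline only; not institutional criteria.",
  "domains": {
    "glucose_metabolism": {
      "fpg": {"breakpoints": [100, 110, 126], "grades": ["A", "B", "C", "D"]},
      "hba1c": {"breakpoints": [5.6, 6.0, 6.5], "grades": ["A", "B", "C", "D"]}
    },
    "blood_pressure": {
      "sbp": {"breakpoints": [130, 140, 160], "grades": ["A", "B", "C", "D"]},
      "dbp": {"breakpoints": [85, 90, 100], "grades": ["A", "B", "C", "D"]}
    },
    "lipids": {
      "tg": {"breakpoints": [150, 300, 500], "grades": ["A", "B", "C", "D"]},
      "hdl": {"breakpoints": [30, 35, 40], "grades": ["D", "C", "B", "A"]},
      "ldl": {"breakpoints": [120, 140, 180], "grades": ["A", "B", "C", "D"]}
    },
    "liver": {
      "ast": {"breakpoints": [31, 41, 51], "grades": ["A", "B", "C", "D"]},
      "alt": {"breakpoints": [31, 41, 51], "grades": ["A", "B", "C", "D"]},
      "ggt": {"breakpoints": [51, 101, 201], "grades": ["A", "B", "C", "D"]}
    },
    "anthropometric": {
      "bmi": {"breakpoints": [25, 30, 35], "grades": ["A", "B", "C", "D"]},
      "waist": {
        "by_sex": {
          "male": {"breakpoints": [85, 90, 100], "grades": ["A", "B", "C", "D"]},
          "female": {"breakpoints": [90, 95, 105], "grades": ["A", "B", "C", "D"]}
        }
      }
    }
  }
}
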