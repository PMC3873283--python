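{
  "ILM": {
    "polarity": "dark_to_bright",
    "band": "vitreal",
    "anchor_edge": "top",
    "log_sigma": 2.0,
    "high_thresh": 0.2,
    "low_thresh": 0.05
  },
  "ISe": {
    "polarity": "dark_to_bright",
    "band": "posterior",
    "anchor_edge": "top",
    "log_sigma": 2.0,
    "high_thresh": 0.2,
    "low_thresh": 0.05
  },
  "RPE": {
    "polarity": "bright_to_dark",
    "band": "posterior",
    "anchor_edge": "bottom",
    "log_sigma": 2.0,
    "high_thresh": 0.2,
    "low_thresh": 0.05
  },
  "BM": {
    "polarity": "bright_to_dark",
    "band": "vitreal",
    "anchor_edge": "bottom",
    "log_sigma": 2.0,
    "high_thresh": 0.2,
    "low_thresh": 0.05
  }
}
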