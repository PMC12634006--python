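{
  "synthetic_gaze_correct_right.csv": {
    "side": "right",
    "expected": "correct",
    "seed": 101
  },
  "synthetic_gaze_incorrect_left.csv": {
    "side": "left",
    "expected": "incorrect",
    "seed": 102
  },
  "synthetic_gaze_tracking_loss.csv": {
    "side": "right",
    "expected": "invalid",
    "seed": 103
  }
}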