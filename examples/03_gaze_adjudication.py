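"""Score synthetic 65 Hz gaze streams with the AOI dwell rule.

A trial counts as correct when gaze stays inside a 4.4 degree square AOI
centred on the target for a sustained 0.8 s within the 4 s deadline.  Here
an observer's gaze is synthesized for an intended-correct and an
intended-incorrect trial, and a tracking-loss stream shows the invalid
branch that triggers re-presentation instead of a posterior update.
"""

from dataclasses import replace

import numpy as np

from etgcsf import (
    AdjudicationRule,
    CohortConfig,
    Stimulus,
    adjudicate_trial,
    aoi_for_stimulus,
    sample_cohort,
    synth_gaze,
)

observer = sample_cohort(CohortConfig(n_subjects=1, seed=20))[0]
rule = AdjudicationRule()  # dwell 0.8 s, deadline 4 s, 100 ms gap bridging
stim = Stimulus(sf=2.0, contrast=0.5, side="right")
aoi = aoi_for_stimulus("right")
print(f"AOI: centred {aoi.center_deg} deg, half-extents {aoi.half_extent_deg} deg")

for intended, seed in (("correct", 1), ("incorrect", 2)):
    stream = synth_gaze(observer, stim, intended, rng=np.random.default_rng(seed))
    out = adjudicate_trial(stream, aoi, rule)
    latency = f", dwell criterion met at {out.latency_ms:.0f} ms" if out.latency_ms else ""
    print(f"intended {intended:9s} -> adjudicated {out.result}{latency} "
          f"(in-AOI fraction {out.dwell_fraction:.2f})")

lossy = replace(observer, invalid_rate=0.7)
stream = synth_gaze(lossy, stim, "correct", rng=np.random.default_rng(3))
out = adjudicate_trial(stream, aoi, rule)
print(f"70% dropout stream -> {out.result} ({out.invalid_reason}); "
      "the session re-presents such trials without updating the posterior")
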