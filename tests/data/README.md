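# Synthetic test fixtures

All files here are synthetic, generated by `etgcsf.simulate` with the seeds
recorded in `labels.json` (observer drawn with `CohortConfig(n_subjects=1,
seed=20)`; the tracking-loss stream uses `invalid_rate=0.7`). The paired-score
table `synthetic_paired_scores.csv` is an arbitrary seeded draw (seed 104) of
8 subjects with shared subject effects plus independent session noise. No
human or hardware data is included anywhere in this repository.
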