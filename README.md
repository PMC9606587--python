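# cce-triage

Score-ranked review triage and evaluation for colon capsule endoscopy
(CCE) polyp screening.

A swallowed two-camera capsule records hours of colon video per head;
finding every polyp by watching it linearly is slow and error-prone.
When an upstream classifier assigns each frame a polyp probability
`p(frame)`, review can instead be *triaged*: frames are shown in order
of declining certainty, each as a candidate sequence (the proposed
center frame plus 4 context frames per side), under a fixed time budget.
This package provides, for anyone building or evaluating such a reader:

* **triage** — total score ranking with deterministic tie-breaks,
  greedy temporal non-maximum suppression per head, context windows,
  probability color bins;
* **cam** — class-activation maps `raw(x,y) = Σ_c w_c F_c(x,y)` from
  final-convolutional feature maps and classifier weights, min–max
  normalization, corner-aligned bilinear upsampling, RGB overlays;
* **evaluate** — lesion-level matching (a polyp counts as detected iff a
  "polyp" decision falls on its head inside its closed visibility
  interval `[first_ts, last_ts]`), sensitivity stratified by size /
  visibility / morphology, cumulative sensitivity-vs-time curves, the
  Super-Expert upper bound (a reader with `p_recognize = 1`,
  `p_false_call = 0`), time-to-parity and the speed-up factor
  `T_reference / T_parity`;
* **synthetic** — deterministic two-head study generation with planted
  lesion intervals, a Beta-mixture scorer calibrated to 92% frame
  sensitivity at 95% specificity, stochastic budgeted readers and a
  linear-review baseline, so the whole pipeline runs without clinical
  data. The packaged `table1` preset is a 52-lesion cohort
  (29 small / 23 large; 9 low / 15 normal / 28 high visibility;
  4 pedunculated / 25 sessile / 23 flat).

See `docs/methods.md` for the models and their assumptions.

## Worked example

```sh
cce-triage simulate --preset minimal --seed 3 --out run
cce-triage triage   --scores run/frames.csv --out run/cands.csv
cce-triage evaluate --candidates run/cands.csv --annotations run/annotations.csv \
                    --scores run/frames.csv --out run/rep --seed 3
cat run/rep/summary.json
```

prints

```json
{
  "overall_sensitivity_pct": 100.0,
  "n_candidates_reviewed": 513,
  "budget_s": 1800.0,
  "parity_time_s": 9.0,
  "speedup_factor": 25.77777777777778,
  "baseline_sensitivity_pct": 100.0,
  "baseline_review_time_s": 232.0
}
```

On this tiny 3-lesion study the simulated 30-minute triage reader
(`p_recognize` 0.85, 3 s per sequence) finds all three lesions
(`overall_sensitivity_pct`); its curve reaches the linear-review arm's
final sensitivity after 9 s of review (`parity_time_s`), against 232 s
for the baseline to watch the video at 5.17× real time — a speed-up of
≈ 26 on this study. `run/rep/` also contains the stratified sensitivity
table (`stratified.csv`) and the reader and Super-Expert curves
(`curve.csv`); `cce-triage report --report run/rep --out fig.png` plots
them.

The same steps run the full-scale preset with `--preset table1`.

Library use mirrors the CLI:

```python
from cce_triage import (load_preset, generate_study, simulate_scores,
                        calibrate_scorer, rank_frames, build_candidates)
frames, lesions = generate_study(load_preset("table1", seed=1))
frames = simulate_scores(frames, lesions, calibrate_scorer(seed=2))
candidates = build_candidates(rank_frames(frames))
```

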