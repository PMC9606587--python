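# Methods

## Problem and scope

Colon capsule endoscopy produces two long video streams (one per camera
head) that a clinician must scan for polyps. When an upstream classifier
assigns every frame a polyp probability, review can be *triaged*: instead
of watching the video in temporal order, the reader is shown candidate
frames in order of declining certainty, each wrapped in a few seconds of
temporal context, under a fixed time budget. This package implements that
review side — ranking, temporal suppression, context windows, probability
color bins, CAM heatmaps — together with the evaluation methodology for
comparing triaged against linear review: lesion-level matching, stratified
sensitivity, sensitivity-vs-time curves, a Super-Expert bound,
time-to-parity and the resulting speed-up factor. The classifier itself
(architecture, training) is out of scope; scores, feature maps and
classifier weights enter as plain inputs.

## Data model

* **Frames** carry `(study, head, frame_index, timestamp_s, score)`.
  Heads are independent coordinate spaces: a timestamp only ever matches
  an annotation on the same head.
* **Lesions** are annotated with the CLOSED interval
  `[first_ts, last_ts]` of their first and last visible frame on one
  head, a size in mm, a morphology (pedunculated / sessile / flat) and
  the number of frames in which they are visible. Derived classes use
  fixed boundaries: small < 6 mm ≤ large; visibility low < 4 frames,
  normal 4–10, high > 10. Values exactly on a boundary go to the
  higher/inclusive class (6.0 mm is large; 4 and 10 frames are normal).
* **Sensitivity is lesion-level throughout**: a lesion counts as detected
  when at least one "polyp" decision lands on its head inside its closed
  interval; "clear" and "other" decisions never count.

## Triage

`rank_frames` sorts by score descending with deterministic tie-breaks
(earlier timestamp first, then front head before rear), giving a total,
stable order. `build_candidates` walks that ranking greedily and accepts
a frame as a candidate center unless it lies within the temporal
suppression radius (default 2 s, closed comparison) of an already
accepted center on the same head — a minimal non-maximum-suppression
rule; radius 0 disables it. Accepted centers carry up to k = 4 context
frames per side, taken from adjacent frame indices and truncated at
video boundaries (nothing is padded). Heads are ranked jointly; whether
a deployed viewer interleaves heads or exhausts one first is a display
concern, not a ranking one. Only the center frame's interval membership
defines a "true" candidate — context frames are shown to the reader but
do not trigger detection by themselves, because one decision is made per
sequence and the sequence is identified by its center.

## CAM heatmaps

`compute_cam` is the classical class-activation map: the channel-weighted
sum of final-convolutional-layer feature maps,
`raw(x, y) = Σ_c w_c · F_c(x, y)`. Normalization is per-frame min–max to
[0, 1]; a constant (including all-zero) raw map normalizes to all zeros
so "no activation" renders as no overlay rather than dividing by zero.
Upsampling is bilinear with **corner alignment**: the output grid is
`linspace(0, H−1, H')` in source pixel coordinates, so corner values are
preserved exactly and interpolated values stay within the source range.
(CAM implementations differ on this convention; it is pinned here and in
the tests.) Overlays alpha-blend a matplotlib-colormapped heatmap over
the RGB frame; alpha 0 returns the input bit-exactly.

## Synthetic studies

The generator emulates the *structure* of a two-head capsule study, not
its appearance — no mucosa rendering, optics or motion blur. Defaults:

| parameter | default | rationale |
|---|---|---|
| duration | 15 000 s | ≈ 4 h 10 min, a typical colon transit |
| frame interval | 2 s | uniform grid, ~7 500 frames/head (the real device's adaptive frame rate is not modelled) |
| table1 preset | 52 lesions | 29 small / 23 large; 9 low / 15 normal / 28 high visibility; 4 pedunculated / 25 sessile / 23 flat; five lesions > 10 mm and one < 3 mm |

Lesion intervals are placed uniformly at random among non-overlapping
layouts on each head (free frames distributed multinomially into the
gaps), each spanning exactly `n_visible_frames` grid frames, so the count
of lesion-visible frames equals the sum of per-lesion frame counts — an
invariant the tests rely on.

**Scorer.** Frame scores are a two-component Beta mixture: background
frames draw from Beta(1, 10), lesion-visible frames from Beta(a, 1) with
`a` solved (by Brent root-finding on the Beta survival function, which is
monotone in `a`) so that lesion-frame sensitivity is 0.92 at 95%
specificity — the package assumes an upstream classifier operating above
90% sensitivity at 95% specificity, and 0.92 gives Monte-Carlo margin on
that bound at realistic frame counts. Beta is the minimal two-parameter
family on [0, 1]; no claim is made that real classifier scores are Beta.

**Readers.** A simulated reader walks the candidate list in display
order, charges a constant 3.0 s per sequence (≈ 600 sequences in a
30-minute budget; real per-sequence pacing is unreported, so any absolute
time from the simulator is conditional on this choice), and marks a shown
candidate "polyp" with probability `p_recognize` if its center is
lesion-visible, else `p_false_call` (defaults 0.85 / 0.02).
`p_recognize = 1, p_false_call = 0` defines the **Super-Expert**, whose
curve upper-bounds every stochastic reader on the same order and pacing.
The **linear-review baseline** models conventional software: both heads
watched in temporal order at 5.17× real time (11.6 min of review per
hour of video), with the same per-frame recognition probability. Because
it eventually sees *every* visible frame, this baseline is strong on
sensitivity and weak on time — which is exactly the trade-off the
sensitivity-vs-time analysis measures.

## Evaluation outputs

Stratified sensitivity reports detected/total per stratum with
per-lesion denominators from the provided annotations (empty strata get
n = 0 and a null percentage). Sensitivity-vs-time curves are step
functions jumping 1/total at each lesion's first detection time; means
across studies weight studies equally. `time_to_parity` interpolates
linearly between grid points and returns +∞ when the target is never
reached; `speedup_factor` is the reference arm's review time divided by
the parity time and refuses zero or infinite parity times.

In `scripts/acceptance.py` the reported parity quantity is the time for
the 30-minute triage curve to reach the linear arm's sensitivity *at
minute 30*. Under the default models the unlimited baseline ends near
100%, so a parity time against its final value can be undefined for
unlucky reader draws; the minute-30 comparison point is always attained
and measures the same "same accuracy, much sooner" effect.

## Numerical and degenerate-input choices

* CSV is a single dialect (comma, UTF-8, dot decimal, mandatory header);
  floats round-trip via `repr`, so report read-back is exact.
* All stochastic components take explicit integer seeds; the CLI fans a
  single seed out via `SeedSequence(seed).generate_state(4) % 2**31` in
  the fixed order (study, scorer, reader, baseline).
* Zero review budget yields an empty trace and a flat zero curve; a
  zero-lesion study is excluded from mean curves with a warning; an
  empty curve table refuses to serialize.

## What passing tests do and do not show

The synthetic generator reproduces the *composition and geometry* of a
capsule study and a scorer's *operating point*, not image content, score
autocorrelation along a lesion's frames, capsule dwell/speed variation,
or human reader behaviour (fatigue, context use, per-sequence time
variation). Results on synthetic studies therefore validate the
machinery — ordering, suppression, matching, curves, bounds and their
invariants — and the qualitative triage benefit, not clinical
performance on real videos.
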