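# Tiny three-lesion study for quick runs and examples.
study_id: minimal
duration_s: 1200.0
frame_interval_s: 2.0
polyps:
- {size_mm: 4.0, morphology: sessile, n_visible_frames: 3, head: front}
- {size_mm: 8.0, morphology: flat, n_visible_frames: 12, head: rear}
- {size_mm: 6.5, morphology: pedunculated, n_visible_frames: 6, head: front}
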