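# 52-lesion study preset matching the reference cohort composition:
# 29 small / 23 large; 9 low / 15 normal / 28 high visibility;
# 4 pedunculated / 25 sessile / 23 flat.
study_id: table1
duration_s: 15000.0
frame_interval_s: 2.0
polyps:
- {size_mm: 2.5, morphology: sessile, n_visible_frames: 1, head: front}
- {size_mm: 11.0, morphology: flat, n_visible_frames: 2, head: rear}
- {size_mm: 3.2, morphology: sessile, n_visible_frames: 3, head: front}
- {size_mm: 12.0, morphology: flat, n_visible_frames: 1, head: rear}
- {size_mm: 4.1, morphology: sessile, n_visible_frames: 2, head: front}
- {size_mm: 13.0, morphology: flat, n_visible_frames: 3, head: rear}
- {size_mm: 4.8, morphology: sessile, n_visible_frames: 1, head: front}
- {size_mm: 14.0, morphology: pedunculated, n_visible_frames: 2, head: rear}
- {size_mm: 5.4, morphology: flat, n_visible_frames: 3, head: front}
- {size_mm: 15.0, morphology: sessile, n_visible_frames: 4, head: rear}
- {size_mm: 5.0, morphology: flat, n_visible_frames: 5, head: front}
- {size_mm: 6.0, morphology: sessile, n_visible_frames: 6, head: rear}
- {size_mm: 3.8, morphology: flat, n_visible_frames: 7, head: front}
- {size_mm: 7.0, morphology: sessile, n_visible_frames: 8, head: rear}
- {size_mm: 4.5, morphology: flat, n_visible_frames: 9, head: front}
- {size_mm: 8.5, morphology: sessile, n_visible_frames: 10, head: rear}
- {size_mm: 3.2, morphology: flat, n_visible_frames: 4, head: front}
- {size_mm: 9.5, morphology: sessile, n_visible_frames: 5, head: rear}
- {size_mm: 4.1, morphology: flat, n_visible_frames: 6, head: front}
- {size_mm: 6.5, morphology: pedunculated, n_visible_frames: 7, head: rear}
- {size_mm: 4.8, morphology: sessile, n_visible_frames: 8, head: front}
- {size_mm: 7.5, morphology: flat, n_visible_frames: 9, head: rear}
- {size_mm: 5.4, morphology: sessile, n_visible_frames: 10, head: front}
- {size_mm: 8.0, morphology: flat, n_visible_frames: 4, head: rear}
- {size_mm: 5.0, morphology: sessile, n_visible_frames: 11, head: front}
- {size_mm: 9.0, morphology: flat, n_visible_frames: 13, head: rear}
- {size_mm: 3.8, morphology: sessile, n_visible_frames: 15, head: front}
- {size_mm: 6.0, morphology: flat, n_visible_frames: 17, head: rear}
- {size_mm: 4.5, morphology: sessile, n_visible_frames: 19, head: front}
- {size_mm: 7.0, morphology: flat, n_visible_frames: 21, head: rear}
- {size_mm: 3.2, morphology: sessile, n_visible_frames: 23, head: front}
- {size_mm: 8.5, morphology: pedunculated, n_visible_frames: 25, head: rear}
- {size_mm: 4.1, morphology: flat, n_visible_frames: 27, head: front}
- {size_mm: 9.5, morphology: sessile, n_visible_frames: 30, head: rear}
- {size_mm: 4.8, morphology: flat, n_visible_frames: 12, head: front}
- {size_mm: 6.5, morphology: sessile, n_visible_frames: 14, head: rear}
- {size_mm: 5.4, morphology: flat, n_visible_frames: 16, head: front}
- {size_mm: 7.5, morphology: sessile, n_visible_frames: 18, head: rear}
- {size_mm: 5.0, morphology: flat, n_visible_frames: 20, head: front}
- {size_mm: 8.0, morphology: sessile, n_visible_frames: 22, head: rear}
- {size_mm: 3.8, morphology: flat, n_visible_frames: 24, head: front}
- {size_mm: 9.0, morphology: sessile, n_visible_frames: 26, head: rear}
- {size_mm: 4.5, morphology: flat, n_visible_frames: 28, head: front}
- {size_mm: 6.0, morphology: pedunculated, n_visible_frames: 30, head: rear}
- {size_mm: 3.2, morphology: sessile, n_visible_frames: 11, head: front}
- {size_mm: 7.0, morphology: flat, n_visible_frames: 15, head: rear}
- {size_mm: 4.1, morphology: sessile, n_visible_frames: 20, head: front}
- {size_mm: 4.8, morphology: flat, n_visible_frames: 25, head: rear}
- {size_mm: 5.4, morphology: sessile, n_visible_frames: 30, head: front}
- {size_mm: 5.0, morphology: flat, n_visible_frames: 12, head: rear}
- {size_mm: 3.8, morphology: sessile, n_visible_frames: 18, head: front}
- {size_mm: 4.5, morphology: sessile, n_visible_frames: 24, head: rear}
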