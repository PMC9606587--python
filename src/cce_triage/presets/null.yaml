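# Lesion-free study: every frame is background.
study_id: 'null'
duration_s: 600.0
frame_interval_s: 2.0
polyps: []
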