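mode: voluntary
target_fraction: 0.50
onset_s: 1.0
offset_s: 13.0
duration_s: 14.0
name: submax_50
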