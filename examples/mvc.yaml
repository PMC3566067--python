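# 12-s maximal voluntary contraction: target 110% of estimated capacity
mode: voluntary
target_fraction: 1.10
onset_s: 1.0
offset_s: 13.0
duration_s: 14.0
name: mvc
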