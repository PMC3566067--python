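# constant-frequency electrical stimulation train (controller bypassed)
mode: stimulation
freq_hz: 20.0
onset_s: 0.2
offset_s: 2.5
duration_s: 2.5
name: stim_20hz
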