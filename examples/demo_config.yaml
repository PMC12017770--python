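# Demo: one synthetic 20 Hz recording, analysed end to end.
# Run with:  vasoreact run examples/demo_config.yaml
output_dir: scratch/demo_run
n_vessels: 2
seed: 1
duration_s: 1500.0
frequency_hz: 20.0
stim_onset_s: 300.0
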