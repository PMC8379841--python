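# Demo run configuration: a miniature screen plus the CE inference branch.
#   sulfoscreen run-all --config examples/demo.yaml
# All omitted keys take the documented defaults (see sulfoscreen.pipeline.RunConfig).
seed: 11
out_dir: demo
n_plates: 5
controls_per_plate: 16
timepoints: [1, 3, 6, 24, 30, 48]   # hours
noise_sd: 5.0                       # RFU, additive read noise
primary_sigma: 3.0
secondary_sigma: 6.0
scope: plate
assignment_tolerance_mtu: 1.0
decrease_threshold: 0.20
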