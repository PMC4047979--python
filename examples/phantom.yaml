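# Small three-group phantom with a shared case+sibling effect.
shape: [14, 14, 14]
n_control: 8
n_case: 8
n_sibling: 8
noise_sd: 0.1
smooth_sigma: 1.5
seed: 19
atlas_regions: 4
effects:
  - type: cube
    center: [7, 7, 7]
    side: 5
    affected_groups: [case, sibling]
    mode: mean_shift
    magnitude: 3.0
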