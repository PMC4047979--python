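# Full pipeline over the phantom written by `endolight simulate`.
manifest: phantom/manifest.tsv
output_dir: run
seed: 3
atlas: phantom/atlas.nii.gz
atlas_labels: phantom/atlas_labels.tsv
side: 3
folds: 4
n_permutations: 19
alpha: 0.05
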