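# Monomer pipeline: inertial defects of the two inversion sublevels,
# hyperfine-tensor analysis, and the type-II band spacing.
stages: [monomer, tensor, bands]
seed: 0
out_dir: results/amp-monomer
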