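# Cluster pipeline: synthetic fit self-check and the three-parameter r0
# structure fit to the nine experimental moments of inertia.
stages: [fit, structure-fit]
seed: 1
out_dir: results/amw-structure
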