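# Demo run: the default study conditions on a reduced bootstrap budget.
seed: 7
outdir: results/demo
n_boot: 100
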