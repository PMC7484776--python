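# Demo run: full-size synthetic cohort (32/23/17 recordings) with the
# study constants; seed fixed for a reproducible end-to-end example.
seed: 11
out_dir: fluidsense_demo
simulate: true
families: [svm_cubic]
task: two_class
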