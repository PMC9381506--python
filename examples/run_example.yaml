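# Full-pipeline config for a study directory produced by `phoscycle simulate`
# (paths are resolved relative to this file's location).
db_dir: demo/db
manifest: demo/manifest.tsv
samples: demo/samples.tsv
out_dir: demo/out
derep_threshold: 0.99
seed: 7
anosim_group: depth_zone
permutations: 999
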