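fasta:
- /tmp/pytest-of-root/pytest-3/test_run_command_failure_exit_0/*.fa
taxonomy: null
out_dir: kmerscape_run
k: 21
k_grid:
- 3
- 5
- 7
- 9
- 11
- 13
- 15
- 17
- 19
- 21
- 23
- 25
- 27
- 29
- 31
transform: one-minus
olo: true
thresholds:
- 0.0
- -0.05
- -0.1
- -0.5
genus_allowlist: []
save_kmer_sets: false
seed: 0
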