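2026-09-22 03:59:17,176 INFO kmerscape 0.1.0 seed=0
2026-09-22 03:59:17,177 ERROR pipeline failed
Traceback (most recent call last):
  File "/root/pkg/src/kmerscape/pipeline.py", line 147, in run_full
    raise PipelineError(stage, f"need >= 2 FASTA inputs, found {len(fasta_paths)}")
kmerscape.pipeline.PipelineError: stage 'input': need >= 2 FASTA inputs, found 0
2026-09-22 04:06:09,947 INFO kmerscape 0.1.0 seed=0
2026-09-22 04:06:09,949 ERROR pipeline failed
Traceback (most recent call last):
  File "/root/pkg/src/kmerscape/pipeline.py", line 147, in run_full
    raise PipelineError(stage, f"need >= 2 FASTA inputs, found {len(fasta_paths)}")
kmerscape.pipeline.PipelineError: stage 'input': need >= 2 FASTA inputs, found 0
2026-09-22 04:11:30,594 INFO kmerscape 0.1.0 seed=0
2026-09-22 04:11:30,595 ERROR pipeline failed
Traceback (most recent call last):
  File "/root/pkg/src/kmerscape/pipeline.py", line 147, in run_full
    raise PipelineError(stage, f"need >= 2 FASTA inputs, found {len(fasta_paths)}")
kmerscape.pipeline.PipelineError: stage 'input': need >= 2 FASTA inputs, found 0
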