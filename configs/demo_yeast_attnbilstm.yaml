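# Yeast constitutive promoter design at fixture scale:
# attention + bidirectional-LSTM predictor on 110 bp sequences,
# strong-selection weak-mutation optimization (no generator needed).
seed: 11
output_dir: runs/demo_yeast
simulate:
  n: 600
  length: 110
  plant_prob: 0.7
  motifs:
    - {consensus: TATAAA, offset: 78, weight: 1.0, match_prob: 0.85}
  gc_weight: 2.0
  noise_sd: 0.2
predictor:
  arch: attnbilstm
  epochs: 4
  learning_rate: 0.002
  hidden: 12
optimizer:
  algorithm: sswm
  max_steps: 8
evaluation:
  kmer_k: 3
  motif_k_min: 6
  motif_k_max: 6
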