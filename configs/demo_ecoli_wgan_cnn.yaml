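# E. coli constitutive promoter design at fixture scale:
# WGAN-GP generator + CNN predictor on 50 bp sequences, virtual screening.
seed: 7
output_dir: runs/demo_ecoli
simulate:
  n: 2000
  length: 50
  plant_prob: 0.8
  motifs:
    - {consensus: TATAAT, offset: 22, weight: 1.0, match_prob: 0.85}
    - {consensus: TTGACA, offset: 3, weight: 0.7, match_prob: 0.85}
  gc_weight: 2.0
  noise_sd: 0.3
generator:
  model: wgan
  epochs: 12
  latent_dim: 32
  hidden: 128
predictor:
  arch: cnn
  epochs: 10
optimizer:
  algorithm: filter
  n_candidates: 500
  top_k: 50
evaluation:
  kmer_k: 4
  motif_k_min: 6
  motif_k_max: 6
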