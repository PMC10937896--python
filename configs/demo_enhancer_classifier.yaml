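# Tissue-specific enhancer design at fixture scale: binary classification
# (element active = 1 / inactive = 0) with a VAE generator and virtual
# screening by predicted class probability.  Labels are the upper half of
# the simulated activity distribution.
seed: 19
output_dir: runs/demo_enhancer
simulate:
  n: 1000
  length: 50
  plant_prob: 0.5
  motifs:
    - {consensus: GGGCGG, offset: 18, weight: 1.5, match_prob: 0.9}
  gc_weight: 1.0
  noise_sd: 0.0
  binarize_quantile: 0.5
generator:
  model: vae
  epochs: 10
  latent_dim: 32
predictor:
  arch: cnn
  task: binary_classification
  epochs: 10
optimizer:
  algorithm: filter
  n_candidates: 300
  top_k: 30
evaluation:
  kmer_k: 4
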