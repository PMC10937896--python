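# Methods

`promoterlab` implements a standardized promoter-design pipeline over
fixed-length DNA: estimate the training-sequence distribution with a
generative model, learn a sequence → activity map, search sequence space
for high predicted activity, and audit the resulting designs. This note
documents the models, the synthetic world the package is tested on, the
numerical choices, and the limits of what the tests demonstrate.

## Data model and codec

All stages exchange datasets of equal-length sequences over the strict
alphabet {A, C, G, T}, optionally paired with one real-valued activity per
sequence (arbitrary units — MPRA counts, RNA-seq-derived strengths,
log-ratios; the package never rescales user activities except internally
during regression training). Sequences are encoded as L×4 one-hot matrices
with the fixed column order A=0, C=1, G=2, T=3 and 0-based positions;
decoding is row-argmax with ties broken toward the lowest column index.
`promoterlab.seqio` is the single owner of this convention.

Ambiguity codes (N, R, Y, …) are rejected with a position report rather
than randomly resolved: the generative models are categorical over four
letters, and silent resolution would inject spurious bases into the
training distribution. The TXT dialects are strict — one sequence or one
finite real per line, no blanks, no comments — so a malformed file always
fails loudly instead of producing a silently truncated dataset. Activity
files are paired with sequence files by line order; there are no ids to
join on, which matches the minimal two-text-file input contract.

## The neural-network core

All models run on a small reverse-mode automatic-differentiation engine
(`promoterlab.nn`) over float64 numpy arrays. Vector-Jacobian products are
expressed in traced operations, so gradients of gradients are available —
this is what makes the WGAN gradient penalty (a derivative of a gradient
norm with respect to the critic weights) and latent-space ascent exact
rather than approximated. First- and second-order correctness is verified
against central finite differences in the test suite. The engine is
deliberately minimal (the ~25 operations the sequence models need) and
CPU-oriented; convolution is implemented as gather + matrix multiply, and
recurrence as an explicit per-step loop.

## Generators

Three families over per-position categorical outputs:

- **WGAN-GP** — generator: MLP from a `latent_dim`-dimensional Gaussian to
  L×4 logits; critic: MLP on the flattened relaxed one-hot. Critic loss is
  the Kantorovich estimate plus `gp_lambda · (‖∇_x̂ D(x̂)‖₂ − 1)²` at
  uniform interpolates between real and generated batches
  (`gp_lambda = 10`, `n_critic = 5` critic updates per generator update,
  Adam(β₁=0.5, β₂=0.9)). During training the critic sees a Gumbel-softmax
  relaxation of the generator logits at temperature 1.0 (annealing off);
  at sampling time logits are decoded by per-position argmax, which is the
  natural decoder for a continuous-relaxation generator.
- **VAE** — Gaussian encoder (μ, log σ²), categorical cross-entropy
  reconstruction, β-weighted KL toward N(0, I) (β = 1 by default; β = 0
  turns the model into a deterministic autoencoder, which the tests use as
  a capacity sanity check: ≥99 % base-identity reconstruction of a
  50-sequence training set). Sampling draws z ~ N(0, I) and samples each
  position from the decoder categorical.
- **Multinomial diffusion** — forward kernel
  q(x_t | x_{t−1}) = (1 − β_t)·x_{t−1} + β_t/4 with a linear β schedule
  from 0.01 to 0.30 over T = 100 steps, chosen so the cumulative
  ᾱ_T = Π(1 − β_t) < 1e−4 and the terminal marginal is uniform to well
  under the 2 % tolerance the tests assert. The reverse model predicts x₀
  from (x_t, t) (an MLP conditioned on sinusoidal time features) and is
  trained with the x₀-parameterized cross-entropy surrogate of the
  variational bound — the standard simplification for categorical
  diffusion; sampling walks the exact categorical posterior
  q(x_{t−1} | x_t, x̂₀) ∝ [α_t x_t + (1−α_t)/4] ⊙ [ᾱ_{t−1} x̂₀ + (1−ᾱ_{t−1})/4].

Defaults (latent_dim 64, hidden 128, 2–3 layer MLPs) are desk-scale: every
model trains in seconds on one CPU at the fixture sizes used throughout
(L ≈ 20–110, n ≈ 500–5000). Seeding order is fixed — parameter
initialization, then data shuffling, then in-training sampling — so
"deterministic under seed" is well-defined, and `sample(n, seed)` is
reproducible independently of training. Checkpoints are directories
(`spec.json`, `weights.npz`, `training_report.csv`) and round-trip to
bit-identical samples.

## Predictors

A registry of five architectures covers the families used in published
promoter-strength models: `cnn` (two conv/pool stages + dense), `cnn_k15`
(one wide width-15 convolution — a soft motif scanner), `attnbilstm`
(conv front end → bidirectional LSTM → softmax attention pooling → dense),
`densenet` (densely connected conv blocks), and `dual_head` (shared trunk,
two regression heads, head 0 returned by default). The names follow the
field's naming of these families; the internals are this package's own
CPU-scale realizations, not claimed replicas of any published network.
All activations are smooth (tanh, sigmoid), so input gradients exist
everywhere and the saliency/finite-difference agreement checks hold to
high precision; pooling is mean pooling for the same reason.

Regression standardizes activities internally (predictions are returned on
the original scale; the mean/SD live in the checkpoint); classification
trains on the numerically stable logistic loss and predicts probabilities.
The train/validation split is the last `val_fraction` of a seeded shuffle;
the held-out ids are stored in the checkpoint so the reported Pearson r
(or accuracy) can be recomputed exactly after reload. Prediction is a
pure, order-preserving function of the sequence; batching changes results
only at float-accumulation level (< 1e−9).

## Optimizers

Seven algorithms share one scoring protocol (`L`,
`predict_strings(seqs) → scores`), so a trained predictor and a
ground-truth oracle are interchangeable — the tests exploit this to verify
each algorithm against exact combinatorial oracles:

- **filter** (virtual screening): sample `n_candidates`, keep `top_k` by
  score; by construction identical to sort-and-slice, which the tests
  assert against an independent sort every run.
- **genetic_algorithm**: tournament selection (size 3), single-point
  crossover (p = 0.8), per-base mutation (p = 0.02), elitism ≥ 1 — the
  elite guarantee makes the best-so-far trajectory provably monotone.
- **simulated_annealing**: uniform single-base proposals, Metropolis
  acceptance exp(Δ/T_t), geometric cooling T_t = T₀·γ^t. T₀ = 0 is a pure
  hill climb. Defaults T₀ = 2, γ = 0.995, 5000 steps solve an L=6
  landscape whose optimum is verified by enumerating all 4⁶ sequences.
- **gradient**: ascent on the predictor through the generator's latent
  space (keeping outputs on the learned manifold), or directly on relaxed
  position logits when no generator is supplied. Backtracking line search
  (on by default) makes the relaxed objective monotone. Diffusion
  generators are rejected with a typed error: their sampler is a discrete
  Markov chain with no differentiable latent.
- **feedback**: per round, retrain the generator from scratch on the
  current pool, sample, score, and replace the worst `replacement_fraction`
  of the pool with the top-scoring samples. Retraining from scratch at
  fixture scale avoids fine-tuning pathologies; the pool mean is logged
  per round.
- **genetic_drift**: ε-neutral random walk — accept any single-base change
  whose predicted drop is ≤ ε, returning the distinct visited set. This is
  the standard drift-on-neutral-network semantics; ε is exposed because
  the name alone does not pin down an algorithm.
- **sswm** (strong-selection weak-mutation): fix strictly improving single
  mutants (best-of-all-3L or random-proposal mode) until a local optimum,
  which is certified by an exhaustive re-enumeration of all 3L mutants at
  termination.

Ties are everywhere broken by earliest index under a stable sort after the
seeded shuffle that produced the candidates, so equal scores cannot break
determinism. Every run returns the full per-iteration trajectory
(iteration, best-so-far, population mean, best sequence) as CSV.

## Evaluators

- **k-mer spectra**: overlapping k-mer frequencies of designs vs training;
  Jensen–Shannon divergence in log base 2 (range exactly [0, 1],
  0·log 0 ≡ 0) plus the Pearson correlation of the two 4^k vectors.
- **nearest-training identity**: for each design, the best global-alignment
  percent identity against the training set (match +1, mismatch −1, linear
  gap −2; identity = matches / alignment length × 100, via Biopython's
  `PairwiseAligner`). This is the novelty-vs-memorization criterion: 100
  iff an exact training duplicate exists. An external BLAST dependency is
  deliberately avoided; the scoring scheme is fixed so numbers are
  reproducible.
- **sequence logo**: column frequencies and information content
  IC_i = 2 − H_i bits, no small-sample correction (fixture datasets are
  large; a correction is a possible future option).
- **motif discovery**: enumerative k-mer enrichment,
  z = (observed − expected)/√expected against the uniform rate 4^−k or an
  empirical background set, overlapping occurrences counted, default
  threshold z > 5. Enumeration (rather than EM-style PWM inference) keeps
  the criterion exactly testable: the planted motif must rank first, and a
  null fixture must stay empty across seeds up to the documented
  multiple-testing allowance (4^6 hypotheses ⇒ the occasional tail
  crossing is tolerated, never more than a couple).
- **saliency** is defined as the predictor's input gradient (one shared
  definition with the gradient optimizer); **ISM** scores all 3L
  single-base substitutions, with wild-type entries exactly zero. For a
  linear scorer, ISM(i, b) = w(i, b) − w(i, wt_i) exactly, and the ISM
  argmax coincides with the first SSWM step — both are asserted.

## The synthetic world

Tests and demos run on simulated promoter data with a known activity
oracle: activity(s) = Σ_m w_m · max_o [LLR_m(s, o) − 0.1·|o − o_m|]
+ w_gc·GC(s) + N(0, σ²), where LLR is the log-likelihood ratio of the
window under the motif PWM versus a uniform background. The 0.1 per-base
offset discount makes the oracle position-sensitive (so saliency and ISM
have spatial structure to find); it is small relative to per-position LLR
contributions (~log 4 ≈ 1.39 per matching base) so it never dominates.
PWM probabilities are floored at 1e−9 inside the log, keeping one-hot
(match_prob = 1) motifs finite. Backgrounds are uniform, which keeps every
expected count closed-form.

Default study conditions: the generator fixture is a fully planted exact
TATAAT in L = 20, n = 2000; the predictor fixture is a two-motif σ⁷⁰-style
world (TATAAT at −10-like offset 22 weight 1.0, TTGACA at offset 5 weight
0.7, match_prob 0.8, plant probability 0.6, GC weight 2.0) at L = 50,
n = 5000, with noise at 10 % of the noise-free activity SD — "low noise"
in the sense that the measurement term is a small fraction of the
biological variance. These sizes were chosen once as the smallest worlds
in which distribution learning and r ≥ 0.9 recovery are cleanly
demonstrable on one CPU.

What this world does **not** emulate: dinucleotide or GC-skewed
backgrounds, variable spacer energetics between motif boxes, strand
effects, and measurement error structure beyond i.i.d. Gaussian noise.
Passing tests therefore demonstrate that the machinery is correct and that
the models can learn planted regulatory structure — not that any
architecture will reach a particular accuracy on real MPRA data.

## Pipeline and demos

`pipeline.run` executes simulate/inputs → generator → predictor →
optimizer → evaluation from a strict YAML config (unknown keys are
rejected with their field path). The optimization stage is optional:
generator-only (sample + score) and screen-only pipelines are valid. Three
demo configs ship with the package: a 50 bp WGAN-GP + CNN constitutive
design (filter screening), a 110 bp attention-BiLSTM design (SSWM), and a
binary-classification enhancer design (activities thresholded at the
median into labels). Each runs end-to-end in well under a minute on one
CPU and is byte-identical under a repeated seed. The manifest records the
config snapshot, per-stage timings, and every artifact path; it is written
atomically at run end.

The library functions are the primary interface; the `promoterlab` CLI is
a thin wrapper (one subcommand per stage) for shell use.

## Known limitations

- The WGAN decodes by argmax, so sample diversity at low temperature is
  bounded by the generator's logit landscape; mode collapse on tiny
  fixtures is mitigated by Gumbel noise during training but not
  eliminated.
- The gradient optimizer's relaxed objective is measured on the simplex,
  not on decoded sequences; the logged decoded score can lag the relaxed
  objective.
- `dual_head` trains only head 0 by default; true multi-task training is
  out of scope.
- Alignment identity is O(designs × training × L²); for large training
  sets users should subsample the training side.
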