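"""Model-guided sequence optimization.

Seven interchangeable algorithms search sequence space for high predicted
activity.  Every algorithm consumes a *scorer* — any object exposing
``L`` and ``predict_strings(list[str]) -> ndarray`` (a trained
:class:`~promoterlab.predictors.PredictorModel`, or a ground-truth oracle
in tests) — and returns an :class:`OptimizationRun` holding the full
per-iteration trajectory and the final designs.

=====================  =================================================
``filter``             virtual screening: sample a candidate pool from a
                       generator, keep the top-k by predicted activity
``genetic_algorithm``  tournament selection, single-point crossover,
                       per-base mutation, elitist survival
``simulated_annealing``single-base proposals, Metropolis acceptance
                       exp(delta / T_t) with geometric cooling T_t =
                       T0 * gamma^t
``gradient``           ascent on the predictor through a generator's
                       latent space (or directly on relaxed one-hots)
``feedback``           alternate generator (re)training on a pool with
                       replacement of the worst members by top-scoring
                       samples
``genetic_drift``      epsilon-neutral random walk: accept any single-base
                       change whose predicted drop is at most epsilon
``sswm``               strong-selection weak-mutation: fix strictly
                       improving single mutants until a local optimum,
                       certified by exhaustive re-enumeration
=====================  =================================================

All runs are exactly reproducible from their seed; ties are broken by the
earliest index after the seeded shuffle that produced the candidates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .nn import autodiff as ad
from .seqio import ALPHABET, SequenceDataset, SequenceRecord

__all__ = [
    "FilterParams",
    "GAParams",
    "SAParams",
    "GradientParams",
    "FeedbackParams",
    "DriftParams",
    "SSWMParams",
    "IterationRecord",
    "OptimizationRun",
    "filter_screen",
    "genetic_algorithm",
    "simulated_annealing",
    "gradient_ascent",
    "feedback_loop",
    "genetic_drift",
    "sswm",
    "ALGORITHM_NAMES",
]

ALGORITHM_NAMES = (
    "filter",
    "genetic_algorithm",
    "simulated_annealing",
    "gradient",
    "feedback",
    "genetic_drift",
    "sswm",
)


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    best_score: float
    mean_score: float
    best_sequence: str


@dataclass
class OptimizationRun:
    algorithm: str
    records: list[IterationRecord]
    designs: SequenceDataset
    seed: int
    certificate: Optional[bool] = None  # sswm local-optimum certificate

    def __post_init__(self):
        best = -np.inf
        for r in self.records:
            if r.best_score < best - 1e-12:
                raise ValueError("best-so-far trajectory must be non-decreasing")
            best = max(best, r.best_score)

    @property
    def best_score(self) -> float:
        return self.records[-1].best_score if self.records else float("nan")

    @property
    def best_sequence(self) -> str:
        return self.records[-1].best_sequence

    def write_trajectory(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["iteration", "best_score", "mean_score", "best_sequence"])
            for r in self.records:
                w.writerow([r.iteration, f"{r.best_score:.6g}",
                            f"{r.mean_score:.6g}", r.best_sequence])


def _designs(seqs, scores, prefix="design") -> SequenceDataset:
    width = max(4, len(str(len(seqs))))
    recs = tuple(
        SequenceRecord(f"{prefix}_{i + 1:0{width}d}", s, float(v))
        for i, (s, v) in enumerate(zip(seqs, scores))
    )
    return SequenceDataset(recs)


def _mutate_base(seq: str, pos: int, rng: np.random.Generator) -> str:
    alternatives = [b for b in ALPHABET if b != seq[pos]]
    return seq[:pos] + alternatives[rng.integers(0, 3)] + seq[pos + 1 :]


# -- virtual screening -------------------------------------------------


@dataclass(frozen=True)
class FilterParams:
    n_candidates: int = 1000
    top_k: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_candidates < 1 or self.top_k < 1:
            raise ValueError("counts must be >= 1")
        if self.top_k > self.n_candidates:
            raise ValueError("top_k must be <= n_candidates")


def filter_screen(gen, scorer, p: FilterParams) -> OptimizationRun:
    """Sample a pool from the generator and keep the top-k by score.

    Ties are broken by sampling order (stable sort)."""
    pool = gen.sample(p.n_candidates, p.seed)
    if pool.length != scorer.L:
        raise ValueError(f"generator L={pool.length} != scorer L={scorer.L}")
    seqs = pool.sequences
    scores = np.asarray(scorer.predict_strings(seqs), dtype=float)
    order = np.argsort(-scores, kind="stable")[: p.top_k]
    best = int(order[0])
    rec = IterationRecord(0, float(scores[best]), float(scores.mean()), seqs[best])
    return OptimizationRun(
        "filter",
        [rec],
        _designs([seqs[i] for i in order], scores[order]),
        p.seed,
    )


# -- genetic algorithm -------------------------------------------------


@dataclass(frozen=True)
class GAParams:
    population: int = 50
    generations: int = 100
    tournament: int = 3
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02
    elitism: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.population, self.generations, self.tournament) < 1:
            raise ValueError("counts must be >= 1")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.elitism < 0:
            raise ValueError("elitism must be >= 0")


def genetic_algorithm(scorer, init: SequenceDataset, p: GAParams) -> OptimizationRun:
    if len(init) == 0:
        raise ValueError("initial population must be non-empty")
    if init.length != scorer.L:
        raise ValueError(f"init L={init.length} != scorer L={scorer.L}")
    if p.tournament > p.population:
        raise ValueError("tournament size exceeds population size")
    rng = np.random.default_rng(p.seed)
    L = init.length
    pool = [init.sequences[i] for i in rng.integers(0, len(init), size=p.population)]
    records = []
    best_seq, best_score = None, -np.inf
    for gen_i in range(p.generations):
        scores = np.asarray(scorer.predict_strings(pool), dtype=float)
        top = int(np.argsort(-scores, kind="stable")[0])
        if scores[top] > best_score:
            best_score, best_seq = float(scores[top]), pool[top]
        records.append(
            IterationRecord(gen_i, best_score, float(scores.mean()), best_seq)
        )
        elite_idx = np.argsort(-scores, kind="stable")[: p.elitism]
        nxt = [pool[i] for i in elite_idx]
        while len(nxt) < p.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, p.population, size=p.tournament)
                winner = contenders[np.argmax(scores[contenders])]
                parents.append(pool[winner])
            a, b = parents
            if rng.random() < p.crossover_prob and L > 1:
                cut = int(rng.integers(1, L))
                a = a[:cut] + b[cut:]
            child = list(a)
            for pos in range(L):
                if rng.random() < p.mutation_prob:
                    child[pos] = ALPHABET[rng.integers(0, 4)]
            nxt.append("".join(child))
        pool = nxt
    scores = np.asarray(scorer.predict_strings(pool), dtype=float)
    order = np.argsort(-scores, kind="stable")
    return OptimizationRun(
        "genetic_algorithm",
        records,
        _designs([pool[i] for i in order], scores[order]),
        p.seed,
    )


# -- simulated annealing -----------------------------------------------


@dataclass(frozen=True)
class SAParams:
    steps: int = 5000
    t0: float = 2.0
    cooling: float = 0.995
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling rate must be in (0, 1)")


def metropolis_accept(delta: float, temp: float, rng: np.random.Generator) -> bool:
    """Accept iff delta >= 0, else with probability exp(delta / temp)
    (never, at temp = 0)."""
    if delta >= 0:
        return True
    if temp <= 0:
        return False
    return bool(rng.random() < np.exp(delta / temp))


def simulated_annealing(scorer, init_seq: str, p: SAParams) -> OptimizationRun:
    """Metropolis walk over single-base substitutions with geometric cooling.

    At ``t0 = 0`` this is a pure hill climb (only non-decreasing moves)."""
    if len(init_seq) != scorer.L:
        raise ValueError(f"init length {len(init_seq)} != scorer L {scorer.L}")
    rng = np.random.default_rng(p.seed)
    current = init_seq
    cur_score = float(scorer.predict_strings([current])[0])
    best_seq, best_score = current, cur_score
    records = [IterationRecord(0, best_score, cur_score, best_seq)]
    for t in range(p.steps):
        pos = int(rng.integers(0, scorer.L))
        proposal = _mutate_base(current, pos, rng)
        prop_score = float(scorer.predict_strings([proposal])[0])
        delta = prop_score - cur_score
        temp = p.t0 * p.cooling**t
        if metropolis_accept(delta, temp, rng):
            current, cur_score = proposal, prop_score
            if cur_score > best_score:
                best_seq, best_score = current, cur_score
        records.append(IterationRecord(t + 1, best_score, cur_score, best_seq))
    return OptimizationRun(
        "simulated_annealing",
        records,
        _designs([best_seq], [best_score]),
        p.seed,
    )


# -- gradient ascent ---------------------------------------------------


@dataclass(frozen=True)
class GradientParams:
    steps: int = 50
    step_size: float = 0.5
    restarts: int = 4
    line_search: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.steps < 0 or self.restarts < 1:
            raise ValueError("steps must be >= 0 and restarts >= 1")


def gradient_ascent(gen, pred, p: GradientParams) -> OptimizationRun:
    """Ascent on the predictor through the generator's latent space.

    With ``gen=None`` the relaxed one-hot (position logits) is optimized
    directly.  ``line_search=True`` backtracks the step until the relaxed
    objective does not decrease, so the logged objective is monotone.
    """
    if not hasattr(pred, "forward_relaxed"):
        raise TypeError("gradient ascent needs a differentiable predictor")
    if gen is not None and not hasattr(gen, "relaxed_sample"):
        raise TypeError("gradient ascent needs a differentiable generator (or None)")
    rng = np.random.default_rng(p.seed)
    L = pred.L
    records = []
    finals, final_scores = [], []
    best_seq, best_score = None, -np.inf
    it = 0
    for _ in range(p.restarts):
        if gen is not None:
            z = rng.standard_normal((1, gen.spec.latent_dim))
            forward = lambda zt: pred.forward_relaxed(gen.relaxed_sample(zt))
        else:
            z = 0.1 * rng.standard_normal((1, L, 4))
            forward = lambda zt: pred.forward_relaxed(ad.softmax(zt, axis=-1))

        def objective(zdata):
            zt = ad.Tensor(zdata, requires_grad=True)
            out = ad.tsum(forward(zt))
            return out, zt

        step = p.step_size
        out, zt = objective(z)
        obj = float(out.data)
        for _ in range(p.steps):
            g = ad.grad(out, zt).data
            moved = False
            trial_step = step
            for _ in range(12 if p.line_search else 1):
                z_new = z + trial_step * g
                out_new, zt_new = objective(z_new)
                if (not p.line_search) or float(out_new.data) >= obj:
                    z, out, zt = z_new, out_new, zt_new
                    obj = float(out.data)
                    step = trial_step * 1.2
                    moved = True
                    break
                trial_step *= 0.5
            if gen is not None:
                x = gen.relaxed_sample(ad.Tensor(z)).data[0]
            else:
                xz = np.exp(z[0] - z[0].max(axis=-1, keepdims=True))
                x = xz / xz.sum(axis=-1, keepdims=True)
            seq = "".join(ALPHABET[i] for i in np.argmax(x, axis=-1))
            score = float(pred.predict_strings([seq])[0])
            if score > best_score:
                best_seq, best_score = seq, score
            records.append(IterationRecord(it, best_score, obj, best_seq))
            it += 1
            if p.line_search and not moved:
                break
        if gen is not None:
            x = gen.relaxed_sample(ad.Tensor(z)).data[0]
        else:
            xz = np.exp(z[0] - z[0].max(axis=-1, keepdims=True))
            x = xz / xz.sum(axis=-1, keepdims=True)
        seq = "".join(ALPHABET[i] for i in np.argmax(x, axis=-1))
        finals.append(seq)
        final_scores.append(float(pred.predict_strings([seq])[0]))
        if final_scores[-1] > best_score:
            best_seq, best_score = seq, final_scores[-1]
        if not records:
            records.append(IterationRecord(it, best_score, best_score, best_seq))
            it += 1
    order = np.argsort(-np.asarray(final_scores), kind="stable")
    return OptimizationRun(
        "gradient",
        records,
        _designs([finals[i] for i in order], [final_scores[i] for i in order]),
        p.seed,
    )


# -- feedback ----------------------------------------------------------


@dataclass(frozen=True)
class FeedbackParams:
    rounds: int = 3
    samples_per_round: int = 200
    replacement_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1 or self.samples_per_round < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.replacement_fraction < 1.0:
            raise ValueError("replacement_fraction must be in [0, 1)")


def feedback_loop(gen_spec, scorer, init_ds: SequenceDataset,
                  p: FeedbackParams, train_fn=None) -> OptimizationRun:
    """Iterate: (re)train generator on the pool -> sample -> score ->
    replace the worst fraction of the pool with the best samples.

    ``train_fn(dataset, spec)`` defaults to
    :func:`promoterlab.generators.train_generator`; the generator is
    retrained from scratch each round.
    """
    from . import generators as _g
    from dataclasses import replace as _replace

    if train_fn is None:
        train_fn = _g.train_generator
    if init_ds.length != scorer.L:
        raise ValueError(f"init L={init_ds.length} != scorer L={scorer.L}")
    rng = np.random.default_rng(p.seed)
    pool = list(init_ds.sequences)
    n_replace = int(p.replacement_fraction * len(pool))
    records = []
    best_seq, best_score = None, -np.inf
    for rnd in range(p.rounds):
        spec = _replace(gen_spec, seed=int(rng.integers(0, 2**31 - 1)))
        gen = train_fn(SequenceDataset.from_sequences(pool), spec)
        samples = gen.sample(p.samples_per_round, seed=int(rng.integers(0, 2**31 - 1)))
        if n_replace > 0:
            s_scores = np.asarray(scorer.predict_strings(samples.sequences), dtype=float)
            p_scores = np.asarray(scorer.predict_strings(pool), dtype=float)
            top_samples = np.argsort(-s_scores, kind="stable")[:n_replace]
            worst_pool = np.argsort(p_scores, kind="stable")[:n_replace]
            for slot, samp in zip(worst_pool, top_samples):
                pool[slot] = samples.sequences[samp]
        pool_scores = np.asarray(scorer.predict_strings(pool), dtype=float)
        top = int(np.argsort(-pool_scores, kind="stable")[0])
        if pool_scores[top] > best_score:
            best_score, best_seq = float(pool_scores[top]), pool[top]
        records.append(
            IterationRecord(rnd, best_score, float(pool_scores.mean()), best_seq)
        )
    pool_scores = np.asarray(scorer.predict_strings(pool), dtype=float)
    order = np.argsort(-pool_scores, kind="stable")
    return OptimizationRun(
        "feedback",
        records,
        _designs([pool[i] for i in order], pool_scores[order]),
        p.seed,
    )


# -- genetic drift -----------------------------------------------------


@dataclass(frozen=True)
class DriftParams:
    steps: int = 1000
    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0 (use float('inf') for a free walk)")


def genetic_drift(scorer, init_seq: str, p: DriftParams) -> OptimizationRun:
    """Epsilon-neutral random walk: accept a single-base change iff the
    predicted score drops by at most epsilon.  Returns the distinct
    sequences visited."""
    if len(init_seq) != scorer.L:
        raise ValueError(f"init length {len(init_seq)} != scorer L {scorer.L}")
    rng = np.random.default_rng(p.seed)
    current = init_seq
    cur_score = float(scorer.predict_strings([current])[0])
    visited = {current: cur_score}
    best_seq, best_score = current, cur_score
    records = [IterationRecord(0, best_score, cur_score, best_seq)]
    for t in range(p.steps):
        pos = int(rng.integers(0, scorer.L))
        proposal = _mutate_base(current, pos, rng)
        prop_score = float(scorer.predict_strings([proposal])[0])
        if prop_score >= cur_score - p.epsilon:
            current, cur_score = proposal, prop_score
            visited.setdefault(current, cur_score)
            if cur_score > best_score:
                best_seq, best_score = current, cur_score
        records.append(IterationRecord(t + 1, best_score, cur_score, best_seq))
    seqs = list(visited)
    scores = [visited[s] for s in seqs]
    order = np.argsort(-np.asarray(scores), kind="stable")
    return OptimizationRun(
        "genetic_drift",
        records,
        _designs([seqs[i] for i in order], [scores[i] for i in order]),
        p.seed,
    )


# -- strong-selection weak-mutation ------------------------------------


@dataclass(frozen=True)
class SSWMParams:
    max_steps: int = 100
    mode: str = "best_of_all_single_mutants"
    seed: int = 0

    def __post_init__(self):
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.mode not in ("best_of_all_single_mutants", "random_single_mutant"):
            raise ValueError(f"unknown SSWM mode {self.mode!r}")


def _all_single_mutants(seq: str) -> list[str]:
    out = []
    for pos in range(len(seq)):
        for b in ALPHABET:
            if b != seq[pos]:
                out.append(seq[:pos] + b + seq[pos + 1 :])
    return out


def sswm(scorer, init_seq: str, p: SSWMParams) -> OptimizationRun:
    """Greedy adaptive walk: fix strictly improving single-base mutants
    until none exists (local optimum) or the step budget runs out.

    The returned run carries ``certificate=True`` iff a final exhaustive
    enumeration of all 3L single mutants confirms no strict improvement.
    """
    if len(init_seq) != scorer.L:
        raise ValueError(f"init length {len(init_seq)} != scorer L {scorer.L}")
    rng = np.random.default_rng(p.seed)
    current = init_seq
    cur_score = float(scorer.predict_strings([current])[0])
    records = [IterationRecord(0, cur_score, cur_score, current)]
    it = 0
    at_optimum = False
    while it < p.max_steps:
        if p.mode == "best_of_all_single_mutants":
            mutants = _all_single_mutants(current)
            scores = np.asarray(scorer.predict_strings(mutants), dtype=float)
            best = int(np.argmax(scores))
            if scores[best] > cur_score:
                current, cur_score = mutants[best], float(scores[best])
            else:
                at_optimum = True
                break
        else:
            pos = int(rng.integers(0, scorer.L))
            proposal = _mutate_base(current, pos, rng)
            prop_score = float(scorer.predict_strings([proposal])[0])
            if prop_score > cur_score:
                current, cur_score = proposal, prop_score
        it += 1
        records.append(IterationRecord(it, cur_score, cur_score, current))
    if not at_optimum:
        final_scores = np.asarray(
            scorer.predict_strings(_all_single_mutants(current)), dtype=float
        )
        at_optimum = bool((final_scores <= cur_score).all())
    return OptimizationRun(
        "sswm",
        records,
        _designs([current], [cur_score]),
        p.seed,
        certificate=at_optimum,
    )
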