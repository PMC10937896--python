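"""Config-driven orchestration: train -> optimize -> evaluate.

A pipeline is described by a strict YAML file (unknown keys are rejected
with their field path, preventing silent typo-driven misconfiguration):

.. code-block:: yaml

    seed: 1
    output_dir: runs/demo
    simulate:            # optional: generate inputs with a known oracle
      n: 2000
      length: 50
      plant_prob: 0.8
      motifs: [{consensus: TATAAT, offset: 22, weight: 1.0, match_prob: 0.85}]
      gc_weight: 2.0
      noise_sd: 0.3
    # inputs: {sequences: seqs.fasta, activities: acts.txt}   # alternative
    generator: {model: wgan, epochs: 20}        # or skip
    predictor: {arch: cnn, epochs: 15}          # or skip
    optimizer: {algorithm: filter, n_candidates: 500, top_k: 50}  # or skip
    evaluation: {kmer_k: 4}                     # or skip
    n_designs: 100

Artifacts land under ``output_dir``: ``data/`` (simulated inputs),
``generator/`` and ``predictor/`` (weights + training reports),
``designs/`` (FASTA + CSV + trajectory), ``evaluation/`` and a
``manifest.json`` recording the config snapshot, timings, artifact paths
and seed.  The optimization stage is optional by design: generator-only
and filter-only pipelines are valid.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import evaluators, generators, optimizers, predictors, seqio, synthetic

__all__ = ["ConfigError", "PipelineError", "PipelineConfig", "RunManifest", "run"]

log = logging.getLogger("promoterlab")


class ConfigError(ValueError):
    """Invalid pipeline configuration (message includes the field path)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_OPTIMIZER_PARAMS = {
    "filter": optimizers.FilterParams,
    "genetic_algorithm": optimizers.GAParams,
    "simulated_annealing": optimizers.SAParams,
    "gradient": optimizers.GradientParams,
    "feedback": optimizers.FeedbackParams,
    "genetic_drift": optimizers.DriftParams,
    "sswm": optimizers.SSWMParams,
}


def _check_keys(d: dict, allowed: set, path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(
            f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _dataclass_from(d: dict, cls, path: str, **overrides):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(d, fields, path)
    try:
        return cls(**{**d, **overrides})
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from None


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    simulate: dict | None
    inputs: dict | None
    generator: dict | str
    predictor: dict | str
    optimizer: dict | str
    evaluation: dict | str
    n_designs: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: not valid YAML: {e}") from None
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        allowed = {"seed", "output_dir", "simulate", "inputs", "generator",
                   "predictor", "optimizer", "evaluation", "n_designs"}
        _check_keys(raw, allowed, "config")
        for key in ("seed", "output_dir"):
            if key not in raw:
                raise ConfigError(f"config: missing required key {key!r}")
        cfg = cls(
            seed=int(raw["seed"]),
            output_dir=str(raw["output_dir"]),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            generator=raw.get("generator", "skip"),
            predictor=raw.get("predictor", "skip"),
            optimizer=raw.get("optimizer", "skip"),
            evaluation=raw.get("evaluation", "skip"),
            n_designs=int(raw.get("n_designs", 100)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config: need either 'simulate' or 'inputs'")
        if self.simulate is not None and self.inputs is not None:
            raise ConfigError("config: 'simulate' and 'inputs' are exclusive")
        if self.inputs is not None:
            _check_keys(self.inputs, {"sequences", "activities"}, "config.inputs")
            if "sequences" not in self.inputs:
                raise ConfigError("config.inputs: missing 'sequences'")
        if self.simulate is not None:
            _check_keys(
                self.simulate,
                {"n", "length", "plant_prob", "motifs", "gc_weight", "noise_sd",
                 "binarize_quantile"},
                "config.simulate",
            )
        for name in ("generator", "predictor", "optimizer", "evaluation"):
            v = getattr(self, name)
            if isinstance(v, str) and v != "skip":
                raise ConfigError(f"config.{name}: string value must be 'skip'")
        if isinstance(self.optimizer, dict):
            algo = self.optimizer.get("algorithm")
            if algo not in optimizers.ALGORITHM_NAMES:
                raise ConfigError(
                    f"config.optimizer.algorithm: {algo!r} is not one of "
                    f"{list(optimizers.ALGORITHM_NAMES)}"
                )
            params = {k: v for k, v in self.optimizer.items() if k != "algorithm"}
            fields = {f.name for f in dataclasses.fields(_OPTIMIZER_PARAMS[algo])}
            _check_keys(params, fields, "config.optimizer")
            needs_gen = algo in ("filter", "gradient", "feedback")
            if needs_gen and self.generator == "skip":
                raise ConfigError(
                    f"config.optimizer: algorithm {algo!r} requires a generator stage"
                )
            # every algorithm needs something to score with
            if self.predictor == "skip" and self.simulate is None:
                raise ConfigError(
                    "config.optimizer: needs a predictor (or simulated inputs, "
                    "whose oracle can score)"
                )


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    timings: dict[str, float]
    artifacts: dict[str, str]

    def write(self, path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        os.replace(tmp, path)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except (ConfigError, PipelineError):
                raise
            except Exception as e:
                raise PipelineError(f"stage '{name}' failed: {e}") from e
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out, time.time() - t0
        return wrapped
    return deco


def run(config_path) -> RunManifest:
    """Execute the enabled stages of a pipeline config; returns the manifest."""
    cfg = PipelineConfig.from_yaml(config_path)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")
    log.info("promoterlab %s  seed=%d  output=%s", __version__, cfg.seed, outdir)

    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    oracle_cfg = None

    # ---- inputs ------------------------------------------------------
    if cfg.simulate is not None:
        (ds, oracle_cfg), dt = _stage("simulate")(_do_simulate)(cfg, outdir)
        timings["simulate"] = dt
        artifacts["sequences"] = str(outdir / "data" / "sequences.fasta")
        artifacts["activities"] = str(outdir / "data" / "activities.txt")
        artifacts["oracle"] = str(outdir / "data" / "oracle.json")
    else:
        seq_path = cfg.inputs["sequences"]
        ds = seqio.read_sequences(seq_path)
        if cfg.inputs.get("activities"):
            ds = seqio.attach_activities(ds, cfg.inputs["activities"])
        artifacts["sequences"] = str(seq_path)

    # ---- training ----------------------------------------------------
    gen = None
    if isinstance(cfg.generator, dict):
        gen, dt = _stage("generator")(_do_generator)(cfg, ds, outdir)
        timings["generator"] = dt
        artifacts["generator_checkpoint"] = str(outdir / "generator")
    pred = None
    if isinstance(cfg.predictor, dict):
        pred, dt = _stage("predictor")(_do_predictor)(cfg, ds, outdir)
        timings["predictor"] = dt
        artifacts["predictor_checkpoint"] = str(outdir / "predictor")

    scorer = pred
    if scorer is None and oracle_cfg is not None:
        scorer = synthetic.OraclePredictor(oracle_cfg)

    # ---- optimization / design --------------------------------------
    designs = None
    if isinstance(cfg.optimizer, dict):
        designs, dt = _stage("optimizer")(_do_optimizer)(cfg, ds, gen, scorer, outdir)
        timings["optimizer"] = dt
        artifacts["designs_fasta"] = str(outdir / "designs" / "designs.fasta")
        artifacts["designs_csv"] = str(outdir / "designs" / "designs.csv")
        artifacts["trajectory"] = str(outdir / "designs" / "trajectory.csv")
    elif gen is not None:
        designs, dt = _stage("generate")(_do_generate)(cfg, gen, scorer, outdir)
        timings["generate"] = dt
        artifacts["designs_fasta"] = str(outdir / "designs" / "designs.fasta")
        if (outdir / "designs" / "designs.csv").exists():
            artifacts["designs_csv"] = str(outdir / "designs" / "designs.csv")

    # ---- evaluation --------------------------------------------------
    if isinstance(cfg.evaluation, dict):
        target = designs if designs is not None else ds
        evald, dt = _stage("evaluation")(_do_evaluation)(cfg, target, ds, pred, outdir)
        timings["evaluation"] = dt
        for key, val in evald.items():
            artifacts[f"evaluation_{key}"] = val

    manifest = RunManifest(
        config=yaml.safe_load(Path(config_path).read_text()),
        version=__version__,
        seed=cfg.seed,
        timings=timings,
        artifacts=artifacts,
    )
    manifest.write(outdir / "manifest.json")
    log.info("manifest written: %s", outdir / "manifest.json")
    return manifest


def _setup_logging(logfile: Path) -> None:
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in list(log.handlers):
        log.removeHandler(h)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    fh = logging.FileHandler(logfile)
    fh.setFormatter(fmt)
    log.addHandler(fh)


def _do_simulate(cfg: PipelineConfig, outdir: Path):
    s = cfg.simulate
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    motifs = []
    for m in s.get("motifs", []):
        pwm = synthetic.make_pwm(m["consensus"], float(m.get("match_prob", 0.85)))
        motifs.append((pwm, int(m["offset"]), float(m.get("weight", 1.0))))
    oracle = synthetic.OracleConfig(
        L=int(s["length"]),
        motifs=tuple(motifs),
        gc_weight=float(s.get("gc_weight", 0.0)),
        noise_sd=float(s.get("noise_sd", 0.0)),
        seed=cfg.seed,
    )
    ds = synthetic.write_simulation(
        oracle, int(s["n"]), float(s.get("plant_prob", 1.0)),
        datadir / "sequences.fasta", datadir / "activities.txt",
        datadir / "oracle.json",
    )
    if "binarize_quantile" in s:
        # classification demos: label = activity above the given quantile
        q = float(s["binarize_quantile"])
        thr = float(np.quantile(ds.activities, q))
        labels = (ds.activities > thr).astype(float)
        ds = seqio.SequenceDataset(tuple(
            seqio.SequenceRecord(r.id, r.seq, float(v))
            for r, v in zip(ds.records, labels)
        ))
        with open(datadir / "activities.txt", "w") as fh:
            for v in labels:
                fh.write(f"{v:.0f}\n")
        # a thresholded oracle is no longer the scoring oracle
        oracle = None
    return ds, oracle


def _do_generator(cfg, ds, outdir):
    spec = _dataclass_from(
        dict(cfg.generator), generators.GeneratorSpec, "config.generator",
        L=ds.length, seed=int(cfg.generator.get("seed", cfg.seed)),
    )
    gen = generators.train_generator(ds, spec)
    generators.save_generator(gen, outdir / "generator")
    return gen


def _do_predictor(cfg, ds, outdir):
    spec = _dataclass_from(
        dict(cfg.predictor), predictors.PredictorSpec, "config.predictor",
        L=ds.length, seed=int(cfg.predictor.get("seed", cfg.seed + 1)),
    )
    pred = predictors.train_predictor(ds, spec)
    predictors.save_predictor(pred, outdir / "predictor")
    log.info("predictor metrics: %s", pred.metrics)
    return pred


def _best_training_seq(ds) -> str:
    if ds.has_activity:
        return ds.sequences[int(np.argmax(ds.activities))]
    return ds.sequences[0]


def _do_optimizer(cfg, ds, gen, scorer, outdir):
    if scorer is None:
        raise PipelineError("stage 'optimizer' failed: no predictor or oracle to score with")
    opt = dict(cfg.optimizer)
    algo = opt.pop("algorithm")
    params = _dataclass_from(
        opt, _OPTIMIZER_PARAMS[algo], "config.optimizer",
        seed=int(opt.get("seed", cfg.seed + 2)),
    )
    if algo == "filter":
        run_ = optimizers.filter_screen(gen, scorer, params)
    elif algo == "genetic_algorithm":
        run_ = optimizers.genetic_algorithm(scorer, ds, params)
    elif algo == "simulated_annealing":
        run_ = optimizers.simulated_annealing(scorer, _best_training_seq(ds), params)
    elif algo == "gradient":
        run_ = optimizers.gradient_ascent(gen, scorer, params)
    elif algo == "feedback":
        gen_spec = gen.spec if gen is not None else generators.GeneratorSpec(
            model="vae", L=ds.length, epochs=5, seed=cfg.seed
        )
        run_ = optimizers.feedback_loop(gen_spec, scorer, ds, params)
    elif algo == "genetic_drift":
        run_ = optimizers.genetic_drift(scorer, _best_training_seq(ds), params)
    else:
        run_ = optimizers.sswm(scorer, _best_training_seq(ds), params)
    ddir = outdir / "designs"
    ddir.mkdir(parents=True, exist_ok=True)
    seqio.write_design_outputs(run_.designs, ddir / "designs.fasta", ddir / "designs.csv")
    run_.write_trajectory(ddir / "trajectory.csv")
    log.info("optimizer %s: best score %.4g", algo, run_.best_score)
    return run_.designs


def _do_generate(cfg, gen, scorer, outdir):
    designs = gen.sample(cfg.n_designs, seed=cfg.seed + 3)
    if scorer is not None:
        scores = scorer.predict_strings(designs.sequences)
        designs = seqio.SequenceDataset(
            tuple(
                seqio.SequenceRecord(r.id, r.seq, float(v))
                for r, v in zip(designs.records, scores)
            )
        )
        ddir = outdir / "designs"
        ddir.mkdir(parents=True, exist_ok=True)
        seqio.write_design_outputs(
            designs, ddir / "designs.fasta", ddir / "designs.csv"
        )
    else:
        ddir = outdir / "designs"
        ddir.mkdir(parents=True, exist_ok=True)
        with open(ddir / "designs.fasta", "w") as fh:
            for r in designs.records:
                fh.write(f">{r.id}\n{r.seq}\n")
    return designs


def _do_evaluation(cfg, designs, training, pred, outdir):
    ev = dict(cfg.evaluation)
    _check_keys(ev, {"kmer_k", "motif_k_min", "motif_k_max", "plots"}, "config.evaluation")
    return evaluators.write_evaluation_report(
        outdir / "evaluation",
        designs,
        training=training,
        pred=pred,
        k=int(ev.get("kmer_k", 4)),
        motif_k=(int(ev.get("motif_k_min", 6)), int(ev.get("motif_k_max", 6))),
        plots=bool(ev.get("plots", True)),
    )
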