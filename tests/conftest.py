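"""Shared fixtures: tiny oracle worlds and closed-form scorers."""

import numpy as np
import pytest

from promoterlab import synthetic
from promoterlab.seqio import ALPHABET, BASE_INDEX, SequenceDataset


class MatchCountScorer:
    """Additive per-position fitness: number of bases matching a target.

    The global optimum is the target itself, so optimizer behaviour is
    exactly checkable."""

    def __init__(self, target: str):
        self.target = target
        self.L = len(target)

    def predict_strings(self, seqs):
        return np.array(
            [sum(a == b for a, b in zip(s, self.target)) for s in seqs], dtype=float
        )


class LinearProbeScorer:
    """score(s) = sum_i w[i, base_i] + b — every optimizer/ISM closed form
    is exact for this landscape."""

    def __init__(self, weights: np.ndarray, bias: float = 0.0):
        self.w = np.asarray(weights, dtype=float)
        self.b = float(bias)
        self.L = self.w.shape[0]

    def predict_strings(self, seqs):
        return np.array(
            [self.w[np.arange(self.L), [BASE_INDEX[c] for c in s]].sum() + self.b
             for s in seqs]
        )


def random_dna(rng, L, n=1):
    seqs = ["".join(ALPHABET[i] for i in rng.integers(0, 4, L)) for _ in range(n)]
    return seqs[0] if n == 1 else seqs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tataat_world():
    """100%-planted exact TATAAT at offset 7 in L=20 — generator fixture."""
    pwm = synthetic.make_pwm("TATAAT", 1.0)
    cfg = synthetic.OracleConfig(L=20, motifs=((pwm, 7, 1.0),), noise_sd=0.0, seed=3)
    return cfg, synthetic.sample_dataset(cfg, 2000, plant_prob=1.0)


@pytest.fixture(scope="session")
def oracle_world_l50():
    """Two-motif + GC world at L=50 with 10%-of-signal noise — predictor fixture."""
    motifs = (
        (synthetic.make_pwm("TATAAT", 0.8), 22, 1.0),
        (synthetic.make_pwm("TTGACA", 0.8), 5, 0.7),
    )
    noise_free = synthetic.OracleConfig(L=50, motifs=motifs, gc_weight=2.0,
                                        noise_sd=0.0, seed=11)
    sd = float(np.std(synthetic.sample_dataset(noise_free, 500, 0.6).activities))
    cfg = synthetic.OracleConfig(L=50, motifs=motifs, gc_weight=2.0,
                                 noise_sd=0.1 * sd, seed=11)
    return cfg


@pytest.fixture(scope="session")
def oracle_dataset_l50(oracle_world_l50):
    return synthetic.sample_dataset(oracle_world_l50, 5000, plant_prob=0.6)


@pytest.fixture(scope="session")
def trained_cnn_l50(oracle_dataset_l50):
    from promoterlab import predictors
    spec = predictors.PredictorSpec(arch="cnn", L=50, epochs=15, seed=2)
    return predictors.train_predictor(oracle_dataset_l50, spec)


@pytest.fixture(scope="session")
def trained_attnbilstm_l50(oracle_dataset_l50):
    from promoterlab import predictors
    spec = predictors.PredictorSpec(
        arch="attnbilstm", L=50, epochs=15, learning_rate=2e-3, seed=2
    )
    return predictors.train_predictor(oracle_dataset_l50, spec)
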