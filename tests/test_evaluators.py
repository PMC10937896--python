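"""Sequence-quality criteria and model interpretation."""

import numpy as np
import pytest

from promoterlab import evaluators as ev
from promoterlab import optimizers as opt
from promoterlab import synthetic
from promoterlab.seqio import ALPHABET, SequenceDataset

from conftest import LinearProbeScorer, random_dna
from test_predictors import linear_probe_model


class TestKmerReport:
    def test_identical_sets(self, rng):
        ds = SequenceDataset.from_sequences(random_dna(rng, 20, 30))
        rep = ev.kmer_report(ds, ds, k=3)
        assert rep.jsd == pytest.approx(0.0, abs=1e-12)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_disjoint_supports_give_jsd_one(self):
        a = SequenceDataset.from_sequences(["AAAA", "AAAA"])
        b = SequenceDataset.from_sequences(["TTTT"])
        assert ev.kmer_report(a, b, k=1).jsd == pytest.approx(1.0, abs=1e-12)

    def test_hand_counted_two_sequence_sets(self):
        # set A: ACGT (ACG->no; 2-mers AC,CG,GT), AAAA (AA x3)
        # set B: ACAC (AC,CA,AC), GTGT (GT,TG,GT)
        a = SequenceDataset.from_sequences(["ACGT", "AAAA"])
        b = SequenceDataset.from_sequences(["ACAC", "GTGT"])
        rep = ev.kmer_report(a, b, k=2)
        fa = np.zeros(16)
        fa[0] = 3    # AA
        fa[1] = 1    # AC
        fa[6] = 1    # CG
        fa[11] = 1   # GT
        fa /= 6
        fb = np.zeros(16)
        fb[1] = 2    # AC
        fb[4] = 1    # CA
        fb[11] = 2   # GT
        fb[14] = 1   # TG
        fb /= 6
        assert np.allclose(rep.freqs_a, fa, atol=1e-12)
        assert np.allclose(rep.freqs_b, fb, atol=1e-12)
        m = (fa + fb) / 2

        def h(p):
            p = p[p > 0]
            return -(p * np.log2(p)).sum()

        jsd_hand = h(m) - 0.5 * h(fa) - 0.5 * h(fb)
        assert rep.jsd == pytest.approx(jsd_hand, abs=1e-9)

    def test_symmetry(self, rng):
        a = SequenceDataset.from_sequences(random_dna(rng, 15, 10))
        b = SequenceDataset.from_sequences(random_dna(rng, 15, 10))
        assert ev.kmer_report(a, b, 2).jsd == pytest.approx(
            ev.kmer_report(b, a, 2).jsd, abs=1e-12
        )

    def test_jsd_bounded(self, rng):
        for _ in range(5):
            a = SequenceDataset.from_sequences(random_dna(rng, 12, 5))
            b = SequenceDataset.from_sequences(random_dna(rng, 12, 5))
            assert 0.0 <= ev.kmer_report(a, b, 3).jsd <= 1.0

    def test_k_too_large(self):
        ds = SequenceDataset.from_sequences(["ACGT"])
        with pytest.raises(ValueError):
            ev.kmer_report(ds, ds, k=5)


class TestNearestIdentity:
    def test_training_duplicate_scores_100(self):
        d = SequenceDataset.from_sequences(["ACGTACGT"])
        t = SequenceDataset.from_sequences(["TTTTTTTT", "ACGTACGT"])
        assert ev.nearest_identity(d, t)[0] == 100.0

    def test_fully_mismatched_scores_zero(self):
        # global alignment of AAAA vs TTTT: 4 mismatches beat any gapping
        # under (+1, -1, -2), so 0 matches over alignment length 4
        d = SequenceDataset.from_sequences(["AAAA"])
        t = SequenceDataset.from_sequences(["TTTT"])
        assert ev.nearest_identity(d, t)[0] == 0.0

    def test_monotone_in_shared_bases(self):
        t = SequenceDataset.from_sequences(["ACGTACGT"])
        designs = ["TTTTTTTT", "ACTTTTTT", "ACGTTTTT", "ACGTACTT", "ACGTACGT"]
        vals = [
            ev.nearest_identity(SequenceDataset.from_sequences([d]), t)[0]
            for d in designs
        ]
        assert all(x <= y for x, y in zip(vals, vals[1:]))

    def test_bounded(self, rng):
        d = SequenceDataset.from_sequences(random_dna(rng, 10, 5))
        t = SequenceDataset.from_sequences(random_dna(rng, 10, 5))
        vals = ev.nearest_identity(d, t)
        assert ((vals >= 0) & (vals <= 100)).all()


class TestSequenceLogo:
    def test_identical_sequences_give_two_bits(self):
        ds = SequenceDataset.from_sequences(["ACGT"] * 10)
        freqs, ic = ev.sequence_logo(ds)
        assert np.allclose(ic, 2.0)
        assert np.allclose(freqs.sum(axis=1), 1.0)

    def test_uniform_column_gives_zero_bits(self):
        ds = SequenceDataset.from_sequences(["AA", "CA", "GA", "TA"])
        _, ic = ev.sequence_logo(ds)
        assert ic[0] == pytest.approx(0.0, abs=1e-12)
        assert ic[1] == pytest.approx(2.0)

    def test_planted_motif_columns_informative(self):
        pwm = synthetic.make_pwm("TATAAT", 1.0)
        cfg = synthetic.OracleConfig(L=20, motifs=((pwm, 7, 1.0),), seed=30)
        ds = synthetic.sample_dataset(cfg, 1000, plant_prob=1.0)
        _, ic = ev.sequence_logo(ds)
        assert (ic[7:13] > 1.9).all()
        background = np.concatenate([ic[:7], ic[13:]])
        assert (background < 0.1).all()


class TestMotifDiscovery:
    def test_expected_count_formula(self):
        # n=10 sequences of L=10, k=3: windows = 10*8 = 80, per 3-mer 80/64
        ds = SequenceDataset.from_sequences(["ACGTACGTAC"] * 10)
        df = ev.motif_discovery(ds, 3, 3, z_threshold=-np.inf)
        assert np.allclose(df["expected"], 80 / 64)

    def test_planted_sixmer_ranked_first(self):
        pwm = synthetic.make_pwm("TATAAT", 1.0)
        cfg = synthetic.OracleConfig(L=30, motifs=((pwm, 11, 1.0),), seed=31)
        ds = synthetic.sample_dataset(cfg, 300, plant_prob=0.9)
        df = ev.motif_discovery(ds, 6, 6)
        assert df.iloc[0]["kmer"] == "TATAAT"

    @pytest.mark.parametrize("seed", range(5))
    def test_null_fixture_reports_no_strong_hits(self, seed):
        cfg = synthetic.OracleConfig(L=50, motifs=(), seed=100 + seed)
        ds = synthetic.sample_dataset(cfg, 1000, plant_prob=0.0)
        df = ev.motif_discovery(ds, 6, 6, z_threshold=5.0)
        # 4096 hypotheses: allow the occasional tail crossing, nothing more
        assert len(df) <= 2

    def test_background_set_expected_counts(self):
        ds = SequenceDataset.from_sequences(["AAAA"] * 5)
        bg = SequenceDataset.from_sequences(["AAAA", "TTTT"])
        df = ev.motif_discovery(ds, 2, 2, background=bg, z_threshold=-np.inf)
        row = df[df.kmer == "AA"].iloc[0]
        assert row["observed"] == 15
        assert row["expected"] == pytest.approx(7.5)  # bg rate 0.5 x 15 windows


class TestInterpretation:
    def test_ism_wildtype_entries_exactly_zero(self, rng):
        w = rng.normal(size=(10, 4))
        pred = linear_probe_model(w)
        pred.y_mean, pred.y_std = 0.0, 1.0
        seq = random_dna(rng, 10)
        mat = ev.ism(pred, seq)
        for i, b in enumerate(seq):
            assert mat.deltas[i, ALPHABET.index(b)] == 0.0

    def test_ism_linear_probe_closed_form(self, rng):
        w = rng.normal(size=(10, 4))
        pred = linear_probe_model(w)
        pred.y_mean, pred.y_std = 0.0, 1.0
        seq = random_dna(rng, 10)
        mat = ev.ism(pred, seq)
        for i, wt in enumerate(seq):
            for b in range(4):
                expected = w[i, b] - w[i, ALPHABET.index(wt)]
                assert mat.deltas[i, b] == pytest.approx(expected, abs=1e-9)

    def test_ism_constant_predictor_all_zero(self, rng):
        pred = linear_probe_model(np.zeros((10, 4)), b=3.0)
        pred.y_mean, pred.y_std = 0.0, 1.0
        mat = ev.ism(pred, random_dna(rng, 10))
        assert np.allclose(mat.deltas, 0.0)

    def test_ism_argmax_agrees_with_sswm_first_step(self, rng):
        w = rng.normal(size=(10, 4))
        pred = linear_probe_model(w)
        pred.y_mean, pred.y_std = 0.0, 1.0
        seq = random_dna(rng, 10)
        mat = ev.ism(pred, seq)
        i, b = np.unravel_index(np.argmax(mat.deltas), mat.deltas.shape)
        best_mutant = seq[:i] + ALPHABET[b] + seq[i + 1 :]
        run = opt.sswm(pred, seq, opt.SSWMParams(max_steps=1, seed=0))
        assert run.records[1].best_sequence == best_mutant

    def test_saliency_is_input_gradient_alias(self, rng):
        w = rng.normal(size=(10, 4))
        pred = linear_probe_model(w)
        pred.y_mean, pred.y_std = 0.0, 1.0
        seq = random_dna(rng, 10)
        assert np.array_equal(ev.saliency_map(pred, seq), w)

    def test_saliency_highlights_oracle_motif_columns(self, trained_cnn_l50,
                                                      oracle_dataset_l50):
        sal = np.abs(ev.saliency_map(trained_cnn_l50,
                                     oracle_dataset_l50.sequences[0]))
        motif_cols = list(range(22, 28)) + list(range(5, 11))
        other = [i for i in range(50) if i not in motif_cols]
        assert sal[motif_cols].mean() > sal[other].mean()


def test_report_writer_produces_expected_artifacts(tmp_path, rng):
    designs = SequenceDataset.from_sequences(random_dna(rng, 20, 10))
    training = SequenceDataset.from_sequences(random_dna(rng, 20, 20))
    pred = linear_probe_model(rng.normal(size=(20, 4)))
    pred.y_mean, pred.y_std = 0.0, 1.0
    artifacts = ev.write_evaluation_report(tmp_path, designs, training=training,
                                           pred=pred, k=3, plots=False)
    for key in ("logo", "motifs", "kmer", "nearest_identity", "saliency", "ism"):
        assert key in artifacts
    import os
    assert {f for f in os.listdir(tmp_path) if f.endswith(".csv")} >= {
        "logo_pfm.csv", "motifs.csv", "kmer_k3.csv", "nearest_identity.csv",
        "saliency.csv", "ism.csv",
    }
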