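"""Quality criteria and model interpretation for designed sequence sets.

Sequence-quality criteria compare designed sequences against the training
set: k-mer spectra (Jensen-Shannon divergence and Pearson correlation),
nearest-training-neighbor alignment identity (novelty vs similarity),
per-position sequence logos, and enumerative motif discovery by k-mer
enrichment z-scores.  Model-interpretation methods explain a trained
predictor: saliency maps (input gradients) and in-silico mutagenesis
(the predicted effect of every single-base substitution).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from scipy.spatial.distance import jensenshannon

from . import predictors as _pred
from .seqio import ALPHABET, BASE_INDEX, SequenceDataset

__all__ = [
    "KmerReport",
    "IsmMatrix",
    "kmer_report",
    "nearest_identity",
    "sequence_logo",
    "motif_discovery",
    "saliency_map",
    "ism",
    "write_evaluation_report",
]


def _kmer_vector(ds: SequenceDataset, k: int) -> np.ndarray:
    """Normalized frequencies of all overlapping k-mers, indexed base-4."""
    counts = np.zeros(4**k)
    mult = 4 ** np.arange(k - 1, -1, -1)
    for seq in ds.sequences:
        idx = np.array([BASE_INDEX[b] for b in seq])
        for o in range(len(seq) - k + 1):
            counts[int(idx[o : o + k] @ mult)] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"k={k} larger than every sequence")
    return counts / total


def _kmer_labels(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(ALPHABET, repeat=k)]


@dataclass(frozen=True)
class KmerReport:
    k: int
    freqs_a: np.ndarray
    freqs_b: np.ndarray
    jsd: float  # Jensen-Shannon divergence, log base 2, in [0, 1]
    pearson_r: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"kmer": _kmer_labels(self.k), "freq_a": self.freqs_a, "freq_b": self.freqs_b}
        )


def kmer_report(a: SequenceDataset, b: SequenceDataset, k: int) -> KmerReport:
    """Compare the k-mer spectra of two sequence sets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sequence sets must be non-empty")
    if k < 1 or k > min(a.length, b.length):
        raise ValueError(f"k={k} out of range for these sequences")
    fa, fb = _kmer_vector(a, k), _kmer_vector(b, k)
    jsd = float(jensenshannon(fa, fb, base=2) ** 2)
    if np.std(fa) == 0 or np.std(fb) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(fa, fb)[0, 1])
    return KmerReport(k, fa, fb, jsd, r)


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -2
        a.extend_gap_score = -2
        _aligner = a
    return _aligner


def _percent_identity(a: str, b: str) -> float:
    aligner = _get_aligner()
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y for x, y in zip(s1, s2))
    return 100.0 * matches / len(s1)


def nearest_identity(designs: SequenceDataset, training: SequenceDataset) -> np.ndarray:
    """Per design, the best global-alignment percent identity against any
    training sequence (match +1, mismatch -1, gap -2; identity = matches /
    alignment length x 100).  An exact training duplicate scores 100."""
    if len(designs) == 0 or len(training) == 0:
        raise ValueError("both sequence sets must be non-empty")
    train_set = set(training.sequences)
    out = np.empty(len(designs))
    for i, d in enumerate(designs.sequences):
        if d in train_set:
            out[i] = 100.0
            continue
        out[i] = max(_percent_identity(d, t) for t in training.sequences)
    return out


def sequence_logo(ds: SequenceDataset) -> tuple[np.ndarray, np.ndarray]:
    """Column base frequencies (L x 4) and information content per column.

    IC_i = 2 - H_i bits, H_i the Shannon entropy of column i; no
    small-sample correction is applied."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    counts = np.zeros((ds.length, 4))
    for seq in ds.sequences:
        for i, b in enumerate(seq):
            counts[i, BASE_INDEX[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(freqs > 0, freqs * np.log2(freqs), 0.0).sum(axis=1)
    return freqs, 2.0 - h


def motif_discovery(ds: SequenceDataset, k_min: int, k_max: int,
                    background: SequenceDataset = None,
                    z_threshold: float = 5.0) -> pd.DataFrame:
    """Enumerate k-mers enriched over the background rate.

    For each k-mer, z = (observed - expected) / sqrt(expected) where the
    expected count is ``n_windows * rate`` (uniform rate 4^-k by default,
    or the background set's empirical per-k-mer frequency).  Overlapping
    occurrences are counted.  Returns k-mers with z above the threshold,
    ranked by z."""
    if k_min < 1 or k_max < k_min or k_max > ds.length:
        raise ValueError("invalid k range")
    rows = []
    for k in range(k_min, k_max + 1):
        n_windows = sum(len(s) - k + 1 for s in ds.sequences)
        counts = _kmer_vector(ds, k) * n_windows
        if background is not None:
            rate = _kmer_vector(background, k)
        else:
            rate = np.full(4**k, 4.0**-k)
        expected = n_windows * rate
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(expected > 0, (counts - expected) / np.sqrt(expected), np.nan)
        labels = _kmer_labels(k)
        for i in np.flatnonzero(z > z_threshold):
            rows.append(
                {"kmer": labels[i], "k": k, "observed": counts[i],
                 "expected": expected[i], "z": z[i]}
            )
    df = pd.DataFrame(rows, columns=["kmer", "k", "observed", "expected", "z"])
    return df.sort_values("z", ascending=False, kind="stable").reset_index(drop=True)


def saliency_map(pred, seq: str) -> np.ndarray:
    """Gradient of the prediction with respect to the one-hot input.

    Thin alias of :func:`promoterlab.predictors.input_gradient`, so the
    interpretation report and the gradient optimizer share one definition.
    """
    return _pred.input_gradient(pred, seq)


@dataclass(frozen=True)
class IsmMatrix:
    """In-silico mutagenesis deltas: entry (i, b) is the predicted change
    from substituting base b at position i; wild-type entries are 0."""

    wildtype: str
    deltas: np.ndarray  # L x 4

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.deltas, columns=list(ALPHABET))
        df.insert(0, "pos", np.arange(len(self.wildtype)))
        df.insert(1, "wt", list(self.wildtype))
        return df


def ism(pred, seq: str) -> IsmMatrix:
    """Score all 3L single-base substitutions of ``seq`` with the predictor."""
    if len(seq) != pred.L:
        raise ValueError(f"sequence length {len(seq)} != predictor L {pred.L}")
    wt_score = float(pred.predict_strings([seq])[0])
    mutants, slots = [], []
    for i, wt_base in enumerate(seq):
        for b in ALPHABET:
            if b == wt_base:
                continue
            mutants.append(seq[:i] + b + seq[i + 1 :])
            slots.append((i, BASE_INDEX[b]))
    scores = np.asarray(pred.predict_strings(mutants), dtype=float)
    deltas = np.zeros((len(seq), 4))
    for (i, bi), s in zip(slots, scores):
        deltas[i, bi] = s - wt_score
    return IsmMatrix(seq, deltas)


def write_evaluation_report(outdir, designs: SequenceDataset,
                            training: SequenceDataset = None,
                            pred=None, k: int = 4,
                            motif_k: tuple[int, int] = (6, 6),
                            plots: bool = True) -> dict[str, str]:
    """Run the applicable criteria and write CSVs (and optionally plots).

    Returns {criterion: path} for every artifact produced."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    freqs, ic = sequence_logo(designs)
    pfm = pd.DataFrame(freqs, columns=list(ALPHABET))
    pfm.insert(0, "pos", np.arange(designs.length))
    pfm["information_content"] = ic
    p = outdir / "logo_pfm.csv"
    pfm.to_csv(p, index=False)
    artifacts["logo"] = str(p)

    motifs = motif_discovery(designs, motif_k[0], motif_k[1],
                             background=training)
    p = outdir / "motifs.csv"
    motifs.to_csv(p, index=False)
    artifacts["motifs"] = str(p)

    if training is not None and len(training) > 0:
        rep = kmer_report(designs, training, k)
        df = rep.to_dataframe()
        p = outdir / f"kmer_k{k}.csv"
        df.to_csv(p, index=False)
        artifacts["kmer"] = str(p)
        artifacts["kmer_jsd"] = f"{rep.jsd:.6f}"

        ident = nearest_identity(designs, training)
        p = outdir / "nearest_identity.csv"
        pd.DataFrame({"id": [r.id for r in designs.records],
                      "identity_pct": ident}).to_csv(p, index=False)
        artifacts["nearest_identity"] = str(p)
        if plots:
            fig, ax = plt.subplots(figsize=(5, 3))
            ax.scatter(rep.freqs_b, rep.freqs_a, s=6, alpha=0.6)
            lim = max(rep.freqs_a.max(), rep.freqs_b.max()) * 1.05
            ax.plot([0, lim], [0, lim], "k--", lw=0.7)
            ax.set_xlabel("training k-mer freq")
            ax.set_ylabel("designs k-mer freq")
            ax.set_title(f"k={k}  JSD={rep.jsd:.3f}  r={rep.pearson_r:.3f}")
            fig.tight_layout()
            fig.savefig(outdir / "kmer_scatter.png", dpi=120)
            plt.close(fig)
            fig, ax = plt.subplots(figsize=(5, 3))
            ax.hist(ident, bins=20)
            ax.set_xlabel("nearest training identity (%)")
            ax.set_ylabel("designs")
            fig.tight_layout()
            fig.savefig(outdir / "identity_hist.png", dpi=120)
            plt.close(fig)

    if plots:
        fig, ax = plt.subplots(figsize=(max(4, designs.length / 8), 2.5))
        bottoms = np.zeros(designs.length)
        colors = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839"}
        heights = freqs * ic[:, None]
        for bi, base in enumerate(ALPHABET):
            ax.bar(np.arange(designs.length), heights[:, bi], bottom=bottoms,
                   color=colors[base], width=0.9, label=base)
            bottoms += heights[:, bi]
        ax.set_ylim(0, 2)
        ax.set_ylabel("bits")
        ax.set_xlabel("position")
        ax.legend(ncol=4, fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "logo.png", dpi=120)
        plt.close(fig)

    if pred is not None and len(designs) > 0:
        seq = designs.sequences[0]
        sal = saliency_map(pred, seq)
        df = pd.DataFrame(sal, columns=list(ALPHABET))
        df.insert(0, "pos", np.arange(len(seq)))
        p = outdir / "saliency.csv"
        df.to_csv(p, index=False)
        artifacts["saliency"] = str(p)
        mat = ism(pred, seq)
        p = outdir / "ism.csv"
        mat.to_dataframe().to_csv(p, index=False)
        artifacts["ism"] = str(p)
        if plots:
            fig, ax = plt.subplots(figsize=(max(4, len(seq) / 8), 2.2))
            im = ax.imshow(mat.deltas.T, aspect="auto", cmap="coolwarm")
            ax.set_yticks(range(4), list(ALPHABET))
            ax.set_xlabel("position")
            fig.colorbar(im, ax=ax, label="predicted delta")
            fig.tight_layout()
            fig.savefig(outdir / "ism_heatmap.png", dpi=120)
            plt.close(fig)
    return artifacts
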