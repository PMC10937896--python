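"""Generative models over fixed-length one-hot DNA.

Three families are provided, selected by :class:`GeneratorSpec.model`:

``wgan``
    Wasserstein GAN with gradient penalty.  The generator maps a Gaussian
    latent vector to per-position base logits; during training the critic
    receives a Gumbel-softmax relaxation (temperature 1.0) of those logits
    so the whole pipeline stays differentiable.  The critic loss is the
    usual Kantorovich estimate plus ``gp_lambda * (||grad_xhat D|| - 1)^2``
    evaluated at random interpolates between real and generated batches;
    ``n_critic`` critic updates are taken per generator update.  Sampling
    decodes logits by per-position argmax.

``vae``
    Variational auto-encoder with Gaussian latent, categorical
    cross-entropy reconstruction and a ``beta``-weighted KL term.
    Sampling draws z ~ N(0, I) and samples each position from the decoder
    categorical.

``diffusion``
    Multinomial diffusion: the forward kernel mixes the categorical state
    toward uniform, q(x_t | x_{t-1}) = (1 - beta_t) x_{t-1} + beta_t / 4,
    so the closed-form marginal is q(x_t | x_0) = abar_t x_0 +
    (1 - abar_t)/4 with abar_t = prod(1 - beta_s).  The reverse model
    predicts x_0 from (x_t, t) and is trained with the x_0-parameterized
    cross-entropy surrogate of the variational bound; sampling walks the
    exact categorical posterior q(x_{t-1} | x_t, x_hat_0) from t = T down
    to 0.

All models are CPU-sized by default (MLP trunks, latent_dim 64, T = 100).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import autodiff as ad
from .seqio import SequenceDataset, one_hot_many, decode_many

__all__ = [
    "GeneratorSpec",
    "GeneratorModel",
    "CheckpointError",
    "train_generator",
    "sample",
    "save_generator",
    "load_generator",
    "diffusion_schedule",
    "diffusion_forward_marginal",
]

_MODELS = ("wgan", "vae", "diffusion")


class CheckpointError(RuntimeError):
    """Raised for unreadable, truncated or incompatible checkpoints."""


@dataclass(frozen=True)
class GeneratorSpec:
    model: str
    L: int
    latent_dim: int = 64
    hidden: int = 128
    diffusion_steps: int = 100
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    # wgan-specific
    n_critic: int = 5
    gp_lambda: float = 10.0
    gumbel_tau: float = 1.0
    # vae-specific
    beta: float = 1.0

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.L < 8:
            raise ValueError("L must be >= 8")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.model == "diffusion" and self.diffusion_steps < 10:
            raise ValueError("diffusion_steps must be >= 10")


def _categorical_sample(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one-hot states from (B, L, 4) probabilities."""
    c = np.cumsum(probs, axis=-1)
    c /= c[..., -1:]
    u = rng.random(probs.shape[:-1] + (1,))
    idx = (u > c).sum(axis=-1)
    out = np.zeros(probs.shape)
    B, L = probs.shape[:2]
    out[np.arange(B)[:, None], np.arange(L)[None, :], idx] = 1.0
    return out


def diffusion_schedule(T: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear beta schedule and cumulative alpha-bar for T steps (1-based t)."""
    betas = np.linspace(0.01, 0.30, T)
    abar = np.cumprod(1.0 - betas)
    return betas, abar


def diffusion_forward_marginal(x0: np.ndarray, t: int, T: int) -> np.ndarray:
    """Closed-form q(x_t | x_0) = abar_t x_0 + (1 - abar_t)/4."""
    _, abar = diffusion_schedule(T)
    a = abar[t - 1]
    return a * x0 + (1.0 - a) / 4.0


class GeneratorModel:
    """Trained (or freshly initialised) generator handle."""

    def __init__(self, spec: GeneratorSpec, modules: dict[str, nn.Module],
                 training_report: list[dict] | None = None):
        self.spec = spec
        self.modules = modules
        self.training_report = training_report or []

    # -- sampling ------------------------------------------------------
    def sample(self, n: int, seed: int) -> SequenceDataset:
        if n < 0:
            raise ValueError("n must be >= 0")
        if n == 0:
            return SequenceDataset(())
        rng = np.random.default_rng(seed)
        if self.spec.model == "wgan":
            z = rng.standard_normal((n, self.spec.latent_dim))
            logits = self.modules["generator"](ad.Tensor(z)).data
            seqs = decode_many(logits)
        elif self.spec.model == "vae":
            z = rng.standard_normal((n, self.spec.latent_dim))
            logits = self.modules["decoder"](ad.Tensor(z)).data
            logits = logits.reshape(n, self.spec.L, 4)
            probs = _softmax_np(logits)
            seqs = decode_many(_categorical_sample(probs, rng))
        else:
            seqs = decode_many(self._diffusion_sample(n, rng))
        return SequenceDataset.from_sequences(seqs, id_prefix="gen")

    def relaxed_sample(self, z: ad.Tensor) -> ad.Tensor:
        """Differentiable (B, L, 4) simplex output from latent z (wgan/vae)."""
        if self.spec.model == "wgan":
            return ad.softmax(self.modules["generator"](z), axis=-1)
        if self.spec.model == "vae":
            B = z.shape[0]
            logits = ad.reshape(self.modules["decoder"](z), (B, self.spec.L, 4))
            return ad.softmax(logits, axis=-1)
        raise TypeError(
            "diffusion sampling is a discrete Markov chain and exposes no "
            "differentiable latent; use wgan or vae for gradient-based design"
        )

    def reconstruct(self, seqs: list[str]) -> list[str]:
        """VAE only: encode each sequence to the posterior mean and decode
        back by argmax — the autoencoding sanity path."""
        if self.spec.model != "vae":
            raise TypeError("reconstruct() is defined for the vae model only")
        X = one_hot_many(seqs)
        B, L = X.shape[0], self.spec.L
        h = self.modules["encoder"](ad.Tensor(X.reshape(B, L * 4)))
        mu = self.modules["enc_mu"](h)
        logits = self.modules["decoder"](mu).data.reshape(B, L, 4)
        return decode_many(logits)

    def _diffusion_sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        T = self.spec.diffusion_steps
        betas, abar = diffusion_schedule(T)
        L = self.spec.L
        x = _categorical_sample(np.full((n, L, 4), 0.25), rng)
        net = self.modules["denoiser"]
        for t in range(T, 0, -1):
            logits = _diffusion_net_forward(net, x, t, T).data.reshape(n, L, 4)
            x0 = _softmax_np(logits)
            a_t = 1.0 - betas[t - 1]
            abar_prev = abar[t - 2] if t >= 2 else 1.0
            fac1 = a_t * x + (1.0 - a_t) / 4.0
            fac2 = abar_prev * x0 + (1.0 - abar_prev) / 4.0
            post = fac1 * fac2
            post /= post.sum(axis=-1, keepdims=True)
            x = _categorical_sample(post, rng)
        return x


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _time_features(t: int, T: int) -> np.ndarray:
    tau = t / T
    return np.array(
        [tau, np.sin(2 * np.pi * tau), np.cos(2 * np.pi * tau),
         np.sin(4 * np.pi * tau), np.cos(4 * np.pi * tau),
         np.sin(8 * np.pi * tau), np.cos(8 * np.pi * tau), 1.0 - tau]
    )


def _diffusion_net_forward(net: nn.Module, x: np.ndarray, t, T: int) -> ad.Tensor:
    B, L, _ = x.shape
    flat = x.reshape(B, L * 4)
    if np.isscalar(t):
        feats = np.tile(_time_features(t, T), (B, 1))
    else:
        feats = np.stack([_time_features(ti, T) for ti in t])
    inp = ad.Tensor(np.concatenate([flat, feats], axis=1))
    return net(inp)


# -- model builders ----------------------------------------------------


def _build_modules(spec: GeneratorSpec, rng: np.random.Generator) -> dict[str, nn.Module]:
    h, L, z = spec.hidden, spec.L, spec.latent_dim
    if spec.model == "wgan":
        gen = nn.Sequential(
            nn.Dense(z, h, rng), ad.relu,
            nn.Dense(h, h, rng), ad.relu,
            nn.Dense(h, L * 4, rng),
            lambda x: ad.reshape(x, (x.shape[0], L, 4)),
        )
        critic = nn.Sequential(
            lambda x: ad.reshape(x, (x.shape[0], L * 4)),
            nn.Dense(L * 4, h, rng), ad.relu,
            nn.Dense(h, h, rng), ad.relu,
            nn.Dense(h, 1, rng),
        )
        return {"generator": gen, "critic": critic}
    if spec.model == "vae":
        enc = nn.Sequential(nn.Dense(L * 4, h, rng), ad.tanh)
        return {
            "encoder": enc,
            "enc_mu": nn.Dense(h, z, rng),
            "enc_logvar": nn.Dense(h, z, rng),
            "decoder": nn.Sequential(
                nn.Dense(z, h, rng), ad.tanh, nn.Dense(h, L * 4, rng)
            ),
        }
    denoiser = nn.Sequential(
        nn.Dense(L * 4 + 8, h, rng), ad.relu,
        nn.Dense(h, h, rng), ad.relu,
        nn.Dense(h, L * 4, rng),
    )
    return {"denoiser": denoiser}


def _all_params(modules: dict[str, nn.Module]) -> list[ad.Tensor]:
    out = []
    for name in sorted(modules):
        out.extend(modules[name].parameters())
    return out


# -- training ----------------------------------------------------------


def train_generator(ds: SequenceDataset, spec: GeneratorSpec) -> GeneratorModel:
    """Fit the requested generative model to ``ds``.

    Seeding order is fixed (parameter init, then data shuffling, then any
    in-training sampling), so identical inputs give identical models.
    """
    if ds.length != spec.L:
        raise ValueError(f"dataset length {ds.length} != spec.L {spec.L}")
    if len(ds) < spec.batch_size:
        raise ValueError(
            f"dataset ({len(ds)}) smaller than one batch ({spec.batch_size})"
        )
    rng = np.random.default_rng(spec.seed)
    modules = _build_modules(spec, rng)
    X = one_hot_many(ds.sequences)
    report: list[dict] = []
    if spec.epochs > 0:
        if spec.model == "wgan":
            _train_wgan(modules, X, spec, rng, report)
        elif spec.model == "vae":
            _train_vae(modules, X, spec, rng, report)
        else:
            _train_diffusion(modules, X, spec, rng, report)
    return GeneratorModel(spec, modules, report)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n - batch_size + 1, batch_size):
        yield order[start : start + batch_size]


def _gumbel_softmax(logits: ad.Tensor, tau: float, rng: np.random.Generator) -> ad.Tensor:
    g = -np.log(-np.log(rng.random(logits.shape) + 1e-12) + 1e-12)
    return ad.softmax((logits + ad.Tensor(g)) * (1.0 / tau), axis=-1)


def _train_wgan(modules, X, spec, rng, report):
    gen, critic = modules["generator"], modules["critic"]
    gp_params = gen.parameters()
    cr_params = critic.parameters()
    opt_g = nn.Adam(gp_params, lr=spec.learning_rate, betas=(0.5, 0.9))
    opt_d = nn.Adam(cr_params, lr=spec.learning_rate, betas=(0.5, 0.9))
    n = X.shape[0]
    for epoch in range(spec.epochs):
        d_losses, g_losses, gps = [], [], []
        for step, idx in enumerate(_batches(n, spec.batch_size, rng)):
            real = ad.Tensor(X[idx])
            z = rng.standard_normal((len(idx), spec.latent_dim))
            fake_logits = gen(ad.Tensor(z))
            fake = _gumbel_softmax(fake_logits, spec.gumbel_tau, rng)
            fake_detached = ad.Tensor(fake.data)
            # critic update with gradient penalty at random interpolates
            eps = rng.random((len(idx), 1, 1))
            xhat = ad.Tensor(
                eps * real.data + (1 - eps) * fake_detached.data, requires_grad=True
            )
            d_hat = ad.tmean(critic(xhat))
            gx = ad.grad(d_hat, xhat)
            norm = ad.sqrt(ad.tsum(gx * gx, axis=(1, 2)) + 1e-12)
            gp = ad.tmean((norm - 1.0) ** 2)
            d_loss = (
                ad.tmean(critic(fake_detached))
                - ad.tmean(critic(real))
                + spec.gp_lambda * gp
            )
            grads = ad.grad(d_loss, cr_params)
            opt_d.step([g.data for g in grads])
            d_losses.append(float(d_loss.data))
            gps.append(float(gp.data))
            if (step + 1) % spec.n_critic == 0:
                z = rng.standard_normal((spec.batch_size, spec.latent_dim))
                fake = _gumbel_softmax(gen(ad.Tensor(z)), spec.gumbel_tau, rng)
                g_loss = -ad.tmean(critic(fake))
                grads = ad.grad(g_loss, gp_params)
                opt_g.step([g.data for g in grads])
                g_losses.append(float(g_loss.data))
        report.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(d_losses)),
                "critic_loss": float(np.mean(d_losses)),
                "generator_loss": float(np.mean(g_losses)) if g_losses else np.nan,
                "gradient_penalty": float(np.mean(gps)),
            }
        )


def _train_vae(modules, X, spec, rng, report):
    params = _all_params(modules)
    opt = nn.Adam(params, lr=spec.learning_rate)
    n, L = X.shape[0], spec.L
    enc, dec = modules["encoder"], modules["decoder"]
    enc_mu, enc_lv = modules["enc_mu"], modules["enc_logvar"]
    for epoch in range(spec.epochs):
        rec_losses, kl_losses = [], []
        for idx in _batches(n, spec.batch_size, rng):
            x = ad.Tensor(X[idx])
            B = len(idx)
            h = enc(ad.reshape(x, (B, L * 4)))
            mu, logvar = enc_mu(h), enc_lv(h)
            noise = rng.standard_normal((B, spec.latent_dim))
            zlat = mu + ad.exp(logvar * 0.5) * ad.Tensor(noise)
            logits = ad.reshape(dec(zlat), (B, L, 4))
            logp = ad.log_softmax(logits, axis=-1)
            rec = -ad.tmean(ad.tsum(x * logp, axis=(1, 2)))
            kl = 0.5 * ad.tmean(
                ad.tsum(ad.exp(logvar) + mu * mu - 1.0 - logvar, axis=1)
            )
            loss = rec + spec.beta * kl
            grads = ad.grad(loss, params)
            opt.step([g.data for g in grads])
            rec_losses.append(float(rec.data))
            kl_losses.append(float(kl.data))
        report.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(rec_losses) + spec.beta * np.mean(kl_losses)),
                "reconstruction": float(np.mean(rec_losses)),
                "kl": float(np.mean(kl_losses)),
            }
        )


def _train_diffusion(modules, X, spec, rng, report):
    net = modules["denoiser"]
    params = net.parameters()
    opt = nn.Adam(params, lr=spec.learning_rate)
    n, L, T = X.shape[0], spec.L, spec.diffusion_steps
    _, abar = diffusion_schedule(T)
    for epoch in range(spec.epochs):
        losses = []
        for idx in _batches(n, spec.batch_size, rng):
            x0 = X[idx]
            B = len(idx)
            t = rng.integers(1, T + 1, size=B)
            a = abar[t - 1][:, None, None]
            xt = _categorical_sample(a * x0 + (1.0 - a) / 4.0, rng)
            logits = ad.reshape(_diffusion_net_forward(net, xt, t, T), (B, L, 4))
            logp = ad.log_softmax(logits, axis=-1)
            loss = -ad.tmean(ad.tsum(ad.Tensor(x0) * logp, axis=(1, 2)))
            grads = ad.grad(loss, params)
            opt.step([g.data for g in grads])
            losses.append(float(loss.data))
        report.append({"epoch": epoch, "loss": float(np.mean(losses))})


def sample(gen: GeneratorModel, n: int, seed: int) -> SequenceDataset:
    """Draw ``n`` sequences from a generator (module-level convenience)."""
    return gen.sample(n, seed)


# -- checkpointing -----------------------------------------------------


def save_generator(gen: GeneratorModel, path) -> None:
    """Checkpoint = directory with spec.json + weights.npz + training_report.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "spec.json").write_text(json.dumps(asdict(gen.spec), indent=2) + "\n")
    state = {}
    for name in sorted(gen.modules):
        for k, v in gen.modules[name].state_dict().items():
            state[f"{name}.{k}"] = v
    np.savez(path / "weights.npz", **state)
    _write_report(path / "training_report.csv", gen.training_report)


def _write_report(path: Path, report: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        if not report:
            fh.write("epoch,loss\n")
            return
        w = csv.DictWriter(fh, fieldnames=list(report[0].keys()), lineterminator="\n")
        w.writeheader()
        w.writerows(report)


def load_generator(path, expected_L: int = None) -> GeneratorModel:
    path = Path(path)
    spec_file = path / "spec.json"
    if not spec_file.exists():
        raise CheckpointError(f"{path}: no spec.json (not a generator checkpoint)")
    try:
        spec = GeneratorSpec(**json.loads(spec_file.read_text()))
    except (json.JSONDecodeError, TypeError, ValueError) as e:
        raise CheckpointError(f"{path}: bad spec.json: {e}") from None
    if expected_L is not None and spec.L != expected_L:
        raise CheckpointError(
            f"{path}: checkpoint L={spec.L} does not match requested L={expected_L}"
        )
    rng = np.random.default_rng(spec.seed)
    modules = _build_modules(spec, rng)
    try:
        with np.load(path / "weights.npz") as npz:
            state = {k: npz[k] for k in npz.files}
    except Exception as e:
        raise CheckpointError(f"{path}: unreadable weights: {e}") from None
    try:
        for name in sorted(modules):
            prefix = name + "."
            sub = {
                k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)
            }
            modules[name].load_state_dict(sub)
    except ValueError as e:
        raise CheckpointError(f"{path}: corrupt checkpoint: {e}") from None
    report = []
    report_file = path / "training_report.csv"
    if report_file.exists():
        with open(report_file) as fh:
            for row in csv.DictReader(fh):
                report.append({k: _maybe_float(v) for k, v in row.items()})
    return GeneratorModel(spec, modules, report)


def _maybe_float(v: str):
    try:
        return float(v)
    except (TypeError, ValueError):
        return v
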