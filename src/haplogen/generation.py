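"""Wasserstein GAN over concatenated per-section latent codes.

The generator maps a 1000-dimensional standard-normal noise vector to a full
latent profile (all sections at once), so cross-section structure is learned
jointly.  The critic scores realness; training follows the classic
weight-clipped WGAN recipe: RMSProp at 5e-5 for both networks, five critic
updates per generator update, weights clipped after every critic step.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import MLP, RMSProp
from .compression import LatentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WGANConfig",
    "Checkpoint",
    "WGANResult",
    "generator_hidden_dims",
    "critic_hidden_dims",
    "sample_noise",
    "critic_loss",
    "generator_loss",
    "train_wgan",
    "generate",
]


@dataclass(frozen=True)
class WGANConfig:
    """Training hyperparameters for the latent-space WGAN.

    An epoch is one generator update cycle: ``n_critic`` critic steps on fresh
    batches followed by one generator step.
    """

    noise_dim: int = 1000
    learning_rate: float = 5e-5
    n_critic: int = 5
    clip_value: float = 0.01
    checkpoint_every: int = 10_000
    total_epochs: int = 30_000
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.clip_value <= 0:
            raise ValueError("clip_value must be > 0")
        if self.checkpoint_every > self.total_epochs:
            raise ValueError("checkpoint_every must not exceed total_epochs")


def _floored_dims(target_dim: int, divisors: tuple[int, int, int]) -> tuple[int, int, int]:
    dims = tuple(target_dim // d for d in divisors)
    if any(d < 1 for d in dims):
        warnings.warn(f"latent dimension {target_dim} makes a hidden layer round to 0; flooring at 1",
                      stacklevel=3)
        dims = tuple(max(1, d) for d in dims)
    return dims


def generator_hidden_dims(target_dim: int) -> tuple[int, int, int]:
    """Generator hidden widths: target/10, target/5, target/2 (floored at 1)."""
    return _floored_dims(target_dim, (10, 5, 2))


def critic_hidden_dims(target_dim: int) -> tuple[int, int, int]:
    """Critic hidden widths: target/10, target/50, target/100 (floored at 1)."""
    return _floored_dims(target_dim, (10, 50, 100))


def suggested_clip_value(latent_dim: int) -> float:
    """Clip bound scaled so the critic can represent unit-slope functions.

    With uniform weight clipping at c, a relu critic's slope is bounded by
    prod(c * fan_in) over its dense layers; solving for slope 1 gives
    c = (prod fan_in)^(-1/4).  At the classic scale (latent_dim ~ 1000, wide
    hidden layers) this reproduces the usual 0.01; for narrow desk-scale
    critics it loosens the bound so the Wasserstein estimate does not vanish.
    """
    c1, c2, c3 = critic_hidden_dims(latent_dim)
    prod = float(latent_dim * c1 * c2 * c3)
    return float(prod ** -0.25)


def sample_noise(n: int, noise_dim: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """n x noise_dim i.i.d. draws from N(0, 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n, noise_dim))


def critic_loss(scores_real: np.ndarray, scores_fake: np.ndarray) -> float:
    """Wasserstein critic loss: mean(fake scores) - mean(real scores)."""
    scores_real = np.asarray(scores_real, dtype=float)
    scores_fake = np.asarray(scores_fake, dtype=float)
    if scores_real.size == 0 or scores_fake.size == 0:
        raise ValueError("score vectors must be non-empty")
    return float(scores_fake.mean() - scores_real.mean())


def generator_loss(scores_fake: np.ndarray) -> float:
    """Generator loss: -1 times the critic's mean score on generated samples."""
    scores_fake = np.asarray(scores_fake, dtype=float)
    if scores_fake.size == 0:
        raise ValueError("score vector must be non-empty")
    return float(-scores_fake.mean())


def _positive_bias_init(mlp: MLP, value: float = 0.01) -> MLP:
    # narrow relu layers can be born dead (all units inactive for every input),
    # which kills all gradient flow; a small positive bias keeps them live at
    # init, and one- or two-unit funnels additionally get sign-coherent
    # (non-negative) weights so a single unlucky sign cannot sever the network
    for layer in mlp.layers[:-1]:
        layer.b[:] = value
        if layer.W.shape[1] <= 2:
            np.abs(layer.W, out=layer.W)
    return mlp


def _build_generator(noise_dim: int, target_dim: int, activation: str,
                     rng: np.random.Generator) -> MLP:
    g1, g2, g3 = generator_hidden_dims(target_dim)
    return _positive_bias_init(MLP([noise_dim, g1, g2, g3, target_dim],
                                   ["relu", "relu", "relu", activation], rng=rng))


def _build_critic(target_dim: int, rng: np.random.Generator) -> MLP:
    c1, c2, c3 = critic_hidden_dims(target_dim)
    return _positive_bias_init(MLP([target_dim, c1, c2, c3, 1],
                                   ["relu", "relu", "relu", "linear"], rng=rng))


@dataclass
class Checkpoint:
    """Frozen generator/critic weights at a training epoch, plus decoding metadata."""

    epoch: int
    generator_weights: list[np.ndarray]
    critic_weights: list[np.ndarray]
    noise_dim: int
    latent_dim: int
    activation: str
    section_offsets: list[tuple[int, int]]
    critic_loss: float
    generator_loss: float

    def save(self, path: str | Path) -> None:
        meta = {
            "epoch": int(self.epoch),
            "noise_dim": int(self.noise_dim),
            "latent_dim": int(self.latent_dim),
            "activation": self.activation,
            "section_offsets": [[int(a), int(b)] for a, b in self.section_offsets],
            "critic_loss": self.critic_loss,
            "generator_loss": self.generator_loss,
            "n_gen": len(self.generator_weights),
            "n_crit": len(self.critic_weights),
        }
        arrays = {f"g{i}": w for i, w in enumerate(self.generator_weights)}
        arrays.update({f"c{i}": w for i, w in enumerate(self.critic_weights)})
        np.savez(str(path), meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(str(path)) as npz:
            meta = json.loads(str(npz["meta"]))
            gen = [npz[f"g{i}"] for i in range(meta["n_gen"])]
            crit = [npz[f"c{i}"] for i in range(meta["n_crit"])]
        return cls(epoch=meta["epoch"], generator_weights=gen, critic_weights=crit,
                   noise_dim=meta["noise_dim"], latent_dim=meta["latent_dim"],
                   activation=meta["activation"],
                   section_offsets=[tuple(t) for t in meta["section_offsets"]],
                   critic_loss=meta["critic_loss"], generator_loss=meta["generator_loss"])


@dataclass
class WGANResult:
    checkpoints: list[Checkpoint]
    critic_loss_history: np.ndarray
    generator_loss_history: np.ndarray
    generator: MLP = field(repr=False)
    critic: MLP = field(repr=False)


def train_wgan(latent: LatentMatrix, cfg: WGANConfig = WGANConfig()) -> WGANResult:
    """Train the WGAN on latent rows; checkpoints every ``checkpoint_every`` epochs.

    Each epoch runs ``n_critic`` critic updates (fresh real batch, fresh fake
    batch, weights clipped to +/-clip_value after each step) followed by one
    generator update.
    """
    x = latent.values
    n, t = x.shape
    if n < cfg.batch_size:
        raise ValueError("latent matrix needs at least batch_size rows")
    rng = np.random.default_rng(cfg.seed)
    gen = _build_generator(cfg.noise_dim, t, latent.activation, rng)
    crit = _build_critic(t, rng)
    opt_g = RMSProp(cfg.learning_rate)
    opt_c = RMSProp(cfg.learning_rate)
    b = cfg.batch_size
    c_hist = np.empty(cfg.total_epochs)
    g_hist = np.empty(cfg.total_epochs)
    checkpoints: list[Checkpoint] = []
    for epoch in range(1, cfg.total_epochs + 1):
        c_loss = 0.0
        for _ in range(cfg.n_critic):
            real = x[rng.integers(0, n, b)]
            fake = gen.forward(rng.standard_normal((b, cfg.noise_dim)))
            s_fake = crit.forward(fake)
            crit.backward(np.full((b, 1), 1.0 / b))
            fake_grads = [g.copy() for g in crit.gradients()]
            s_real = crit.forward(real)
            crit.backward(np.full((b, 1), -1.0 / b))
            grads = crit.gradients()
            for g, gf in zip(grads, fake_grads):
                g += gf
            c_loss = critic_loss(s_real, s_fake)
            opt_c.step(crit.parameters(), grads)
            for p in crit.parameters():
                np.clip(p, -cfg.clip_value, cfg.clip_value, out=p)
        z = rng.standard_normal((b, cfg.noise_dim))
        fake = gen.forward(z)
        s_fake = crit.forward(fake)
        g_loss = generator_loss(s_fake)
        grad_fake = crit.backward(np.full((b, 1), -1.0 / b))
        gen.backward(grad_fake)
        opt_g.step(gen.parameters(), gen.gradients())
        c_hist[epoch - 1] = c_loss
        g_hist[epoch - 1] = g_loss
        if epoch % cfg.checkpoint_every == 0 or epoch == cfg.total_epochs:
            if not checkpoints or checkpoints[-1].epoch != epoch:
                checkpoints.append(Checkpoint(
                    epoch=epoch,
                    generator_weights=gen.get_weights(),
                    critic_weights=crit.get_weights(),
                    noise_dim=cfg.noise_dim, latent_dim=t,
                    activation=latent.activation,
                    section_offsets=list(latent.section_offsets),
                    critic_loss=c_loss, generator_loss=g_loss,
                ))
                logger.info("checkpoint at epoch %d (critic loss %.4f)", epoch, c_loss)
    return WGANResult(checkpoints=checkpoints, critic_loss_history=c_hist,
                      generator_loss_history=g_hist, generator=gen, critic=crit)


def generate(checkpoint: Checkpoint, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` novel latent profiles from a checkpointed generator.

    Deterministic given ``seed``; columns align with the checkpoint's
    ``section_offsets`` so they can be decoded section by section.
    """
    rng = np.random.default_rng(0)
    gen = _build_generator(checkpoint.noise_dim, checkpoint.latent_dim,
                           checkpoint.activation, rng)
    gen.set_weights(checkpoint.generator_weights)
    z = sample_noise(n, checkpoint.noise_dim, seed)
    return gen.forward(z)
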