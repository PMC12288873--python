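"""Per-section autoencoders: sizing rules, models, training, latent codes.

Each genomic section is compressed independently.  The bottleneck width is the
input width divided by 100 (rounded up) and the three hidden layers sit on a
geometric progression between input and bottleneck.  The classical autoencoder
(AE) trains on mean binary cross-entropy; the variational autoencoder (VAE)
adds a KL divergence to a standard normal over a linear mean / log-variance
bottleneck, which keeps the latent space locally continuous so a generative
model can be trained on the per-haplotype latent means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._nn import MLP, Adam, Dense, bce_grad, bce_matrix

__all__ = [
    "NetSpec",
    "TrainConfig",
    "TrainResult",
    "LatentMatrix",
    "bottleneck_size",
    "hidden_sizes",
    "make_netspec",
    "build_autoencoder",
    "train_autoencoder",
    "binarize",
    "reconstruction_accuracy",
    "encode_sections",
    "decode_sections",
]

HIDDEN_ACTIVATIONS = ("relu", "sigmoid", "tanh", "leaky_relu")

# log-variances are clipped to keep exp() finite during early training
_LOGVAR_BOUND = 30.0


def _init_output_bias(decoder: MLP, hidden_activation: str) -> None:
    # the capped-relu output has zero gradient outside (0, 1); with saturating
    # hidden activations (whose unit statistics barely move early in training)
    # a zero output bias leaves roughly half the variants born dead, so start
    # those networks at the midpoint of the active band.  relu stacks
    # reorganise their sign patterns quickly and do better from zero.
    if hidden_activation in ("sigmoid", "tanh"):
        decoder.layers[-1].b[:] = 0.5


def bottleneck_size(input_dim: int) -> int:
    """Bottleneck width: input size divided by 100, rounded up."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    return math.ceil(input_dim / 100)


def hidden_sizes(input_dim: int, bottleneck_dim: int) -> tuple[int, int, int]:
    """Three hidden widths on a geometric progression from input to bottleneck.

    These are the interior points of a 5-point geometric spacing:
    h_i = round(input * (bottleneck/input)^(i/4)), floored at 1.
    """
    if not (input_dim >= bottleneck_dim >= 1):
        raise ValueError("need input_dim >= bottleneck_dim >= 1")
    ratio = bottleneck_dim / input_dim
    return tuple(max(1, round(input_dim * ratio ** (i / 4))) for i in (1, 2, 3))


@dataclass(frozen=True)
class NetSpec:
    """Architecture of one section's autoencoder (decoder mirrors the encoder)."""

    input_dim: int
    hidden_dims: tuple[int, int, int]
    bottleneck_dim: int
    hidden_activation: str = "relu"
    variational: bool = False
    dropout_rate: float | None = None  # default 0.4 for VAE, 0.2 for AE
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.hidden_activation not in HIDDEN_ACTIVATIONS:
            raise ValueError(f"hidden_activation must be one of {HIDDEN_ACTIVATIONS}")
        if not (self.input_dim >= self.bottleneck_dim >= 1):
            raise ValueError("need input_dim >= bottleneck_dim >= 1")
        dims = (self.input_dim, *self.hidden_dims, self.bottleneck_dim)
        if any(d < 1 for d in dims):
            raise ValueError("all layer widths must be >= 1")
        if any(a < b for a, b in zip(dims, dims[1:])):
            raise ValueError("hidden widths must be non-increasing toward the bottleneck")
        if self.dropout_rate is None:
            object.__setattr__(self, "dropout_rate", 0.4 if self.variational else 0.2)
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def bottleneck_activation(self) -> str:
        return "linear" if self.variational else self.hidden_activation

    @property
    def output_activation(self) -> str:
        return "relu1"  # ReLU capped at 1


def make_netspec(input_dim: int, variational: bool = False, activation: str = "relu", **kwargs) -> NetSpec:
    """Apply the sizing rules to build a NetSpec for a section of ``input_dim`` variants."""
    b = bottleneck_size(input_dim)
    return NetSpec(input_dim=input_dim, hidden_dims=hidden_sizes(input_dim, b),
                   bottleneck_dim=b, hidden_activation=activation,
                   variational=variational, **kwargs)


@dataclass(frozen=True)
class TrainConfig:
    """Early-stopping training configuration.

    ``patience`` defaults to 10 epochs, or 30 for the slower-converging sigmoid
    and tanh activations, matching how the models are monitored on the 20%
    validation split.
    """

    validation_fraction: float = 0.2
    patience: int | None = None
    max_epochs: int = 1000
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be >= 1")

    def resolved_patience(self, activation: str) -> int:
        if self.patience is not None:
            return self.patience
        return 30 if activation in ("sigmoid", "tanh") else 10


class Autoencoder:
    """Classical autoencoder; bottleneck uses the hidden activation."""

    variational = False

    def __init__(self, spec: NetSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        h1, h2, h3 = spec.hidden_dims
        act = spec.hidden_activation
        dr = spec.dropout_rate
        slope = spec.leaky_slope
        # dropout only between consecutive hidden layers
        self.encoder = MLP(
            [spec.input_dim, h1, h2, h3, spec.bottleneck_dim],
            [act, act, act, spec.bottleneck_activation],
            [dr, dr, 0.0, 0.0], rng=rng, leaky_slope=slope,
        )
        self.decoder = MLP(
            [spec.bottleneck_dim, h3, h2, h1, spec.input_dim],
            [act, act, act, spec.output_activation],
            [dr, dr, 0.0, 0.0], rng=rng, leaky_slope=slope,
        )
        _init_output_bias(self.decoder, act)

    def n_parameters(self) -> int:
        return self.encoder.n_parameters() + self.decoder.n_parameters()

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(np.asarray(x, dtype=float))

    def decode(self, z: np.ndarray, mode: str = "mean",
               log_var: np.ndarray | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
        if mode == "sample":
            raise ValueError("sampling requires a variational autoencoder")
        if mode != "mean":
            raise ValueError("mode must be 'mean' or 'sample'")
        z = np.asarray(z, dtype=float)
        if z.shape[1] != self.spec.bottleneck_dim:
            raise ValueError("latent dimension mismatch")
        return self.decoder.forward(z)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(x))

    def train_step(self, x: np.ndarray, opt: Adam, rng: np.random.Generator) -> float:
        z = self.encoder.forward(x, training=True, rng=rng)
        yhat = self.decoder.forward(z, training=True, rng=rng)
        loss = float(bce_matrix(yhat, x).mean())
        g = bce_grad(yhat, x) / yhat.size
        self.encoder.backward(self.decoder.backward(g))
        params = self.encoder.parameters() + self.decoder.parameters()
        grads = self.encoder.gradients() + self.decoder.gradients()
        opt.step(params, grads)
        return loss

    def val_loss(self, x: np.ndarray) -> float:
        return float(bce_matrix(self.reconstruct(x), x).mean())

    def get_weights(self) -> list[np.ndarray]:
        return self.encoder.get_weights() + self.decoder.get_weights()

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        k = len(self.encoder.parameters())
        self.encoder.set_weights(weights[:k])
        self.decoder.set_weights(weights[k:])


class VariationalAutoencoder:
    """VAE with linear mean / log-variance heads and BCE + KL loss.

    Reconstruction loss is binary cross-entropy summed over variants and the
    KL term is summed over latent dimensions (both averaged over the batch),
    the standard formulation of the evidence lower bound.
    """

    variational = True

    def __init__(self, spec: NetSpec, rng: np.random.Generator) -> None:
        if not spec.variational:
            raise ValueError("spec is not variational")
        self.spec = spec
        h1, h2, h3 = spec.hidden_dims
        act = spec.hidden_activation
        dr = spec.dropout_rate
        slope = spec.leaky_slope
        self.trunk = MLP([spec.input_dim, h1, h2, h3], [act, act, act],
                         [dr, dr, 0.0], rng=rng, leaky_slope=slope)
        self.mu_head = Dense(h3, spec.bottleneck_dim, "linear", rng=rng)
        self.logvar_head = Dense(h3, spec.bottleneck_dim, "linear", rng=rng)
        # start near-deterministic (sigma ~ 0.08): with unit-variance sampling noise
        # from the first step the decoder learns to ignore the latent code and the
        # posterior collapses to the prior; KL then inflates the variance only
        # where the data can afford it
        self.logvar_head.b[:] = -5.0
        self.decoder = MLP(
            [spec.bottleneck_dim, h3, h2, h1, spec.input_dim],
            [act, act, act, spec.output_activation],
            [dr, dr, 0.0, 0.0], rng=rng, leaky_slope=slope,
        )
        _init_output_bias(self.decoder, act)

    def n_parameters(self) -> int:
        return (self.trunk.n_parameters() + self.decoder.n_parameters()
                + self.mu_head.W.size + self.mu_head.b.size
                + self.logvar_head.W.size + self.logvar_head.b.size)

    def encode_full(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Latent means and log-variances for each row of x."""
        h = self.trunk.forward(np.asarray(x, dtype=float))
        mu = self.mu_head.forward(h)
        log_var = np.clip(self.logvar_head.forward(h), -_LOGVAR_BOUND, _LOGVAR_BOUND)
        return mu, log_var

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encode_full(x)[0]

    def decode(self, z: np.ndarray, mode: str = "mean",
               log_var: np.ndarray | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.shape[1] != self.spec.bottleneck_dim:
            raise ValueError("latent dimension mismatch")
        if mode == "sample":
            if log_var is None:
                raise ValueError("mode='sample' requires log_var")
            if rng is None:
                rng = np.random.default_rng()
            lv = np.clip(np.asarray(log_var, dtype=float), -_LOGVAR_BOUND, _LOGVAR_BOUND)
            z = z + rng.standard_normal(z.shape) * np.exp(0.5 * lv)
        elif mode != "mean":
            raise ValueError("mode must be 'mean' or 'sample'")
        return self.decoder.forward(z)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(x))

    def train_step(self, x: np.ndarray, opt: Adam, rng: np.random.Generator) -> float:
        h = self.trunk.forward(x, training=True, rng=rng)
        mu = self.mu_head.forward(h)
        log_var = np.clip(self.logvar_head.forward(h), -_LOGVAR_BOUND, _LOGVAR_BOUND)
        eps = rng.standard_normal(mu.shape)
        sigma = np.exp(0.5 * log_var)
        z = mu + eps * sigma
        yhat = self.decoder.forward(z, training=True, rng=rng)
        n = x.shape[0]
        recon = float(bce_matrix(yhat, x).sum(axis=1).mean())
        kl = float(0.5 * (np.exp(log_var) + mu**2 - 1.0 - log_var).sum(axis=1).mean())
        g_y = bce_grad(yhat, x) / n
        g_z = self.decoder.backward(g_y)
        g_mu = g_z + mu / n
        g_lv = g_z * eps * 0.5 * sigma + 0.5 * (np.exp(log_var) - 1.0) / n
        g_h = self.mu_head.backward(g_mu) + self.logvar_head.backward(g_lv)
        self.trunk.backward(g_h)
        params = (self.trunk.parameters() + [self.mu_head.W, self.mu_head.b]
                  + [self.logvar_head.W, self.logvar_head.b] + self.decoder.parameters())
        grads = (self.trunk.gradients() + [self.mu_head.dW, self.mu_head.db]
                 + [self.logvar_head.dW, self.logvar_head.db] + self.decoder.gradients())
        opt.step(params, grads)
        return recon + kl

    def val_loss(self, x: np.ndarray) -> float:
        """Deterministic ELBO monitor: mean-decoded reconstruction plus KL."""
        mu, log_var = self.encode_full(x)
        yhat = self.decoder.forward(mu)
        recon = float(bce_matrix(yhat, x).sum(axis=1).mean())
        kl = float(0.5 * (np.exp(log_var) + mu**2 - 1.0 - log_var).sum(axis=1).mean())
        return recon + kl

    def get_weights(self) -> list[np.ndarray]:
        return (self.trunk.get_weights()
                + [self.mu_head.W.copy(), self.mu_head.b.copy(),
                   self.logvar_head.W.copy(), self.logvar_head.b.copy()]
                + self.decoder.get_weights())

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        k = len(self.trunk.parameters())
        self.trunk.set_weights(weights[:k])
        self.mu_head.W[...] = weights[k]
        self.mu_head.b[...] = weights[k + 1]
        self.logvar_head.W[...] = weights[k + 2]
        self.logvar_head.b[...] = weights[k + 3]
        self.decoder.set_weights(weights[k + 4:])


def build_autoencoder(spec: NetSpec, seed: int = 0) -> Autoencoder | VariationalAutoencoder:
    """Instantiate the model described by ``spec`` with seeded initial weights."""
    rng = np.random.default_rng(seed)
    cls = VariationalAutoencoder if spec.variational else Autoencoder
    return cls(spec, rng)


def binarize(matrix: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Map values >= threshold to 1, else 0."""
    return (np.asarray(matrix) >= threshold).astype(np.uint8)


def reconstruction_accuracy(model, x: np.ndarray) -> float:
    """Fraction of matrix entries reproduced after deterministic decode + binarize."""
    x = np.asarray(x, dtype=np.uint8)
    return float((binarize(model.reconstruct(x)) == x).mean())


@dataclass
class TrainResult:
    model: Autoencoder | VariationalAutoencoder
    val_accuracy: float
    best_epoch: int
    stopped_epoch: int
    history: list[float] = field(default_factory=list)  # per-epoch validation loss


def train_autoencoder(model, section: np.ndarray, cfg: TrainConfig = TrainConfig()) -> TrainResult:
    """Train with early stopping on a held-out validation split.

    Rows are split 80/20 (seeded permutation); training halts once the
    validation loss has not improved for ``patience`` epochs and the best
    weights are restored.  Returns the validation reconstruction accuracy
    (entries matching after binarization at 0.5).
    """
    x = np.asarray(section, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("section matrix must be non-empty and 2-D")
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 haplotypes for an 80/20 split")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    x_val, x_train = x[perm[:n_val]], x[perm[n_val:]]
    patience = cfg.resolved_patience(model.spec.hidden_activation)
    opt = Adam(cfg.learning_rate)
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    wait = 0
    history: list[float] = []
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_train))
        for lo in range(0, len(x_train), cfg.batch_size):
            batch = x_train[order[lo:lo + cfg.batch_size]]
            model.train_step(batch, opt, rng)
        vl = model.val_loss(x_val)
        history.append(vl)
        if vl < best_loss:
            best_loss = vl
            best_weights = model.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    model.set_weights(best_weights)
    acc = reconstruction_accuracy(model, x_val.astype(np.uint8))
    return TrainResult(model=model, val_accuracy=acc, best_epoch=best_epoch,
                       stopped_epoch=epoch, history=history)


@dataclass
class LatentMatrix:
    """Concatenated per-section latent means for a haplotype population.

    ``section_offsets[k]`` is the half-open column range of section k inside
    ``values``; ``activation`` tags the bottleneck activation so the generator
    can mirror it on its output layer.
    """

    values: np.ndarray
    section_offsets: list[tuple[int, int]]
    activation: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = self.values.shape[1]
        expected = 0
        for start, end in self.section_offsets:
            if start != expected or end <= start:
                raise ValueError("section_offsets must partition the latent columns")
            expected = end
        if expected != d:
            raise ValueError("section_offsets do not cover all latent columns")

    @property
    def total_dim(self) -> int:
        return self.values.shape[1]


def encode_sections(models: Sequence, sections: Sequence[np.ndarray]) -> LatentMatrix:
    """Encode each section with its model and concatenate latent means columnwise."""
    if len(models) != len(sections):
        raise ValueError("one model per section required")
    blocks = []
    offsets = []
    col = 0
    for model, sec in zip(models, sections):
        z = model.encode(np.asarray(sec, dtype=float))
        blocks.append(z)
        offsets.append((col, col + z.shape[1]))
        col += z.shape[1]
    activation = "linear" if models[0].variational else models[0].spec.hidden_activation
    return LatentMatrix(values=np.hstack(blocks), section_offsets=offsets, activation=activation)


def decode_sections(models: Sequence, latent: np.ndarray | LatentMatrix,
                    section_offsets: Sequence[tuple[int, int]] | None = None,
                    mode: str = "mean",
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Decode concatenated latent codes section by section into one [0,1] matrix."""
    if isinstance(latent, LatentMatrix):
        values = latent.values
        section_offsets = latent.section_offsets
    else:
        values = np.asarray(latent, dtype=float)
        if section_offsets is None:
            raise ValueError("section_offsets required for a raw latent array")
    if len(models) != len(section_offsets):
        raise ValueError("one model per section required")
    blocks = []
    for model, (start, end) in zip(models, section_offsets):
        z = values[:, start:end]
        if mode == "sample" and model.variational:
            blocks.append(model.decode(z, mode="sample", log_var=np.zeros_like(z), rng=rng))
        else:
            blocks.append(model.decode(z, mode="mean"))
    return np.hstack(blocks)
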