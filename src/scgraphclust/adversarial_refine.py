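"""Adversarial refinement of cluster labels.

A conditional generator maps [x_real ‖ z] (a high-confidence cell
embedding concatenated with Gaussian noise) through 1024-, 512- and
256-unit hidden layers (LeakyReLU, slope 0.2) into a tanh-bounded
pseudo-cell.  The discriminator shares a trunk between two heads: a
logistic real/fake score D̂(x) and a K-way class head D̂_CLS(x).

Losses (expectations realized as batch means):

    L_D = −E[log D̂(x)] − E[log(1 − D̂(Ĝ(z)))] + E[CE(D̂_CLS(x), y_real)]
    L_G = −E[log D̂(Ĝ(z))] + E[CE(D̂_CLS(Ĝ(z)), y_fake)]

where y_fake is the label of the conditioning real sample.  Both
networks use Adam with the learning rate halved every five epochs.
After training, every cell embedding is scored by the class head and
re-labeled by the argmax of its class probabilities.

Cell embeddings are min-max rescaled to [−1, 1] per dimension before
training so real samples share the tanh range of generated ones; the
scaler is part of the trained state and is re-applied at relabel time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_softmax, softmax

from ._nn import Adam, Dense, LeakyReLU, Sequential, Tanh, accumulate
from .confidence import ConfidenceSet

_PROB_FLOOR = 1e-12


@dataclass
class GANConfig:
    noise_dim: int | None = None  # None -> embedding dimension d
    hidden_dims_g: tuple[int, ...] = (1024, 512, 256)
    hidden_dims_d: tuple[int, ...] = (256, 128)
    leaky_slope: float = 0.2
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 64
    lr_halve_every: int = 5
    adam_betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_dims_g = tuple(int(d) for d in self.hidden_dims_g)
        self.hidden_dims_d = tuple(int(d) for d in self.hidden_dims_d)
        self.adam_betas = tuple(float(b) for b in self.adam_betas)
        if any(a <= b for a, b in zip(self.hidden_dims_g, self.hidden_dims_g[1:])):
            raise ValueError("hidden_dims_g must be strictly decreasing")
        if self.lr_halve_every < 1:
            raise ValueError("lr_halve_every must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class DiscriminatorOutput:
    """Batched discriminator scores: adv_prob (B,), class_logits (B, K)."""

    adv_prob: np.ndarray
    class_logits: np.ndarray


@dataclass
class RefinedAssignment:
    """Stage-two labels with the full class-probability matrix."""

    labels: np.ndarray
    class_probabilities: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(self.labels, np.argmax(self.class_probabilities, axis=1)):
            raise ValueError("labels must be the row argmax of class_probabilities")


def scheduled_lr(lr0: float, epoch: int, halve_every: int) -> float:
    """lr at epoch e = lr0 · 0.5^⌊e / halve_every⌋ (non-increasing)."""
    return lr0 * 0.5 ** (epoch // halve_every)


class _MinMaxScaler:
    """Per-dimension affine map onto [−1, 1]; constant dims map to 0."""

    def __init__(self, x: np.ndarray):
        self.lo = x.min(axis=0)
        self.hi = x.max(axis=0)
        span = self.hi - self.lo
        self._span = np.where(span == 0, 1.0, span)
        self._flat = span == 0

    def transform(self, x: np.ndarray) -> np.ndarray:
        y = 2.0 * (x - self.lo) / self._span - 1.0
        y[:, self._flat] = 0.0
        return y


class Generator:
    """Conditional generator: [x_real ‖ z] -> tanh-bounded pseudo-cell."""

    def __init__(self, d: int, noise_dim: int, cfg: GANConfig, rng: np.random.Generator):
        self.d = d
        self.noise_dim = noise_dim
        dims = [d + noise_dim, *cfg.hidden_dims_g]
        layers = []
        for i in range(len(cfg.hidden_dims_g)):
            layers += [Dense(dims[i], dims[i + 1], rng), LeakyReLU(cfg.leaky_slope)]
        layers += [Dense(dims[-1], d, rng), Tanh()]
        self.net = Sequential(*layers)

    @property
    def hidden_widths(self) -> tuple[int, ...]:
        return tuple(layer.W.shape[1] for layer in self.net.layers if isinstance(layer, Dense))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g)

    @property
    def params(self):
        return self.net.params

    @property
    def grads(self):
        return self.net.grads


class Discriminator:
    """Shared trunk with adversarial (logistic) and K-way class heads."""

    def __init__(self, d: int, K: int, cfg: GANConfig, rng: np.random.Generator):
        self.K = K
        dims = [d, *cfg.hidden_dims_d]
        layers = []
        for i in range(len(cfg.hidden_dims_d)):
            layers += [Dense(dims[i], dims[i + 1], rng), LeakyReLU(cfg.leaky_slope)]
        self.trunk = Sequential(*layers)
        self.adv_head = Dense(dims[-1], 1, rng)
        self.cls_head = Dense(dims[-1], K, rng)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = self.trunk.forward(x)
        return self.adv_head.forward(t)[:, 0], self.cls_head.forward(t)

    def backward(self, g_adv: np.ndarray, g_cls: np.ndarray) -> np.ndarray:
        g_t = self.adv_head.backward(g_adv[:, np.newaxis]) + self.cls_head.backward(g_cls)
        return self.trunk.backward(g_t)

    @property
    def params(self):
        return self.trunk.params + self.adv_head.params + self.cls_head.params

    @property
    def grads(self):
        return self.trunk.grads + self.adv_head.grads + self.cls_head.grads


@dataclass
class TrainedDiscriminator:
    """Discriminator plus the embedding scaler it was trained under."""

    disc: Discriminator
    scaler: _MinMaxScaler
    K: int


def generator_forward(x_real: np.ndarray, z: np.ndarray, gen: Generator) -> np.ndarray:
    """Generate pseudo-cells conditioned on real embeddings and noise."""
    x_real = np.atleast_2d(np.asarray(x_real, dtype=float))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if not (np.isfinite(x_real).all() and np.isfinite(z).all()):
        raise ValueError("non-finite generator input")
    out = gen.forward(np.hstack([x_real, z]))
    return out[0] if out.shape[0] == 1 and x_real.shape[0] == 1 else out


def discriminator_forward(x: np.ndarray, disc: Discriminator) -> DiscriminatorOutput:
    """Score samples: real/fake probability and class logits."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("non-finite discriminator input")
    adv_logit, cls_logits = disc.forward(x)
    adv_prob = np.clip(expit(adv_logit), _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    return DiscriminatorOutput(adv_prob=adv_prob, class_logits=cls_logits)


def _cross_entropy(class_logits: np.ndarray, y: np.ndarray, K: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.min() < 0 or y.max() >= K:
        raise ValueError(f"labels must lie in 0..{K - 1}")
    return -log_softmax(class_logits, axis=1)[np.arange(y.size), y]


def discriminator_loss(
    real: DiscriminatorOutput,
    fake: DiscriminatorOutput,
    y_real: np.ndarray,
) -> float:
    """Batch-mean adversarial + classification loss of the discriminator."""
    if real.adv_prob.size == 0 or fake.adv_prob.size == 0:
        raise ValueError("batches must be nonempty")
    p_r = np.clip(real.adv_prob, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    p_f = np.clip(fake.adv_prob, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    ce = _cross_entropy(real.class_logits, y_real, real.class_logits.shape[1])
    return float(-np.mean(np.log(p_r)) - np.mean(np.log1p(-p_f)) + ce.mean())


def generator_loss(fake: DiscriminatorOutput, y_fake: np.ndarray) -> float:
    """Non-saturating adversarial term plus class loss on generated samples."""
    if fake.adv_prob.size == 0:
        raise ValueError("batch must be nonempty")
    p_f = np.clip(fake.adv_prob, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    ce = _cross_entropy(fake.class_logits, y_fake, fake.class_logits.shape[1])
    return float(-np.mean(np.log(p_f)) + ce.mean())


def _onehot(y: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros((y.size, K))
    out[np.arange(y.size), y] = 1.0
    return out


def train_gan(
    conf: ConfidenceSet,
    K: int,
    cfg: GANConfig,
) -> tuple[TrainedDiscriminator, Generator, dict[str, list[float]]]:
    """Alternating minibatch training of the conditional GAN.

    Each epoch is one shuffled pass over the confidence set; every
    minibatch takes one discriminator update followed by one generator
    update, both with Adam at the scheduled learning rate.  Returns the
    trained discriminator (with its embedding scaler), the generator,
    and per-epoch traces of both losses, the real-sample classification
    cross-entropy, and the learning rate.
    """
    y = np.asarray(conf.y_real, dtype=int)
    present = np.unique(y)
    if not np.array_equal(present, np.arange(K)):
        missing = sorted(set(range(K)) - set(present.tolist()))
        raise ValueError(f"confidence set misses classes {missing}; cannot supervise them")

    rng = np.random.default_rng(cfg.seed)
    d = conf.x_real.shape[1]
    noise_dim = cfg.noise_dim if cfg.noise_dim is not None else d
    scaler = _MinMaxScaler(conf.x_real)
    xr = scaler.transform(conf.x_real)
    n_real = xr.shape[0]

    gen = Generator(d, noise_dim, cfg, rng)
    disc = Discriminator(d, K, cfg, rng)
    opt_g = Adam(gen.params, cfg.learning_rate, cfg.adam_betas)
    opt_d = Adam(disc.params, cfg.learning_rate, cfg.adam_betas)
    onehot_y = _onehot(y, K)

    traces: dict[str, list[float]] = {"d_loss": [], "g_loss": [], "real_ce": [], "lr": []}
    for epoch in range(cfg.epochs):
        lr = scheduled_lr(cfg.learning_rate, epoch, cfg.lr_halve_every)
        order = rng.permutation(n_real)
        d_losses, g_losses = [], []
        for start in range(0, n_real, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb, ohb = xr[idx], y[idx], onehot_y[idx]
            B = xb.shape[0]
            z = rng.standard_normal((B, noise_dim))
            fake = gen.forward(np.hstack([xb, z]))

            # -- discriminator step (generator output treated as constant)
            adv_r, cls_r = disc.forward(xb)
            p_r = expit(adv_r)
            g_adv_r = (p_r - 1.0) / B                  # d/da of -mean log σ(a)
            g_cls_r = (softmax(cls_r, axis=1) - ohb) / B
            disc.backward(g_adv_r, g_cls_r)
            total = accumulate(None, disc.grads)

            adv_f, cls_f = disc.forward(fake)
            p_f = expit(adv_f)
            g_adv_f = p_f / B                          # d/da of -mean log(1-σ(a))
            disc.backward(g_adv_f, np.zeros_like(cls_f))
            total = accumulate(total, disc.grads)
            opt_d.step(total, lr)

            d_losses.append(
                discriminator_loss(
                    DiscriminatorOutput(np.clip(p_r, _PROB_FLOOR, 1 - _PROB_FLOOR), cls_r),
                    DiscriminatorOutput(np.clip(p_f, _PROB_FLOOR, 1 - _PROB_FLOOR), cls_f),
                    yb,
                )
            )

            # -- generator step (discriminator params fixed, gradients flow through)
            adv_f2, cls_f2 = disc.forward(fake)
            p_f2 = expit(adv_f2)
            g_adv = (p_f2 - 1.0) / B                   # non-saturating generator term
            g_cls = (softmax(cls_f2, axis=1) - ohb) / B
            g_fake = disc.backward(g_adv, g_cls)
            gen.backward(g_fake)
            opt_g.step(gen.grads, lr)

            g_losses.append(
                generator_loss(
                    DiscriminatorOutput(np.clip(p_f2, _PROB_FLOOR, 1 - _PROB_FLOOR), cls_f2),
                    yb,
                )
            )

        _, cls_all = disc.forward(xr)
        traces["d_loss"].append(float(np.mean(d_losses)))
        traces["g_loss"].append(float(np.mean(g_losses)))
        traces["real_ce"].append(float(_cross_entropy(cls_all, y, K).mean()))
        traces["lr"].append(lr)

    return TrainedDiscriminator(disc=disc, scaler=scaler, K=K), gen, traces


def relabel_all(
    z_cells: np.ndarray,
    trained: TrainedDiscriminator,
    K: int | None = None,
) -> RefinedAssignment:
    """Score every cell with the class head; label = argmax probability.

    Exact ties resolve to the lower class index (argmax convention).
    """
    K = trained.K if K is None else K
    if K != trained.K:
        raise ValueError(f"discriminator was trained with K={trained.K}, got {K}")
    x = trained.scaler.transform(np.asarray(z_cells, dtype=float))
    _, cls_logits = trained.disc.forward(x)
    probs = softmax(cls_logits, axis=1)
    return RefinedAssignment(labels=np.argmax(probs, axis=1), class_probabilities=probs)
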