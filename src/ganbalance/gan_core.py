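"""Penalised Wasserstein GAN core: architectures, losses, sampling.

The generator maps standard-normal noise of dimension ``n_features`` through a
progressively grown stack of fully-connected SELU layers back to
``n_features`` outputs (no squashing activation; data live on a transformed,
unbounded scale).  The critic mirrors the generator with the hidden widths
reversed and a scalar, activation-free output.

Losses::

    L_critic = mean(y_F) - mean(y_R) + penalty
    L_gen    = -mean(y_F) - alpha * log ||X_F||

where ``||X_F||`` is the Frobenius norm of the generated batch.  The
``alpha``-weighted dispersion term rewards batches that spread out, pushing
against mode collapse when the training sample is tiny.  The Lipschitz
constraint on the critic is enforced softly with the gradient penalty of
Gulrajani et al. (penalise squared deviation of the critic's input-gradient
norm from 1 on random real/fake interpolates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, grad
from .nn import AlphaDropout, Dense, selu

__all__ = [
    "NetworkSchedule", "GanHyperparams", "Generator", "Critic",
    "build_generator", "build_critic",
    "critic_loss", "generator_loss", "lipschitz_penalty", "generate_samples",
]

DEFAULT_HIDDEN_SIZES = (50, 100, 200)


@dataclass
class NetworkSchedule:
    """Hidden-layer widths and the currently active growth stage."""

    hidden_sizes: tuple = DEFAULT_HIDDEN_SIZES
    active_stage: int = 1

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 1 <= self.active_stage <= len(self.hidden_sizes):
            raise ValueError("active_stage out of range")

    @property
    def n_stages(self) -> int:
        return len(self.hidden_sizes)


@dataclass
class GanHyperparams:
    """Loss and regularisation knobs shared by generator and critic.

    alpha
        Weight of the log-Frobenius-norm dispersion term in the generator
        loss (0 disables it).
    penalty_coefficient
        Weight (lambda) of the gradient penalty; 10 is the conventional value
        for penalised Wasserstein critics.
    """

    alpha: float = 0.0
    penalty_coefficient: float = 10.0
    dropout_prob: float = 0.5
    iter_critic: int = 4
    batch_size: int = 30
    beta: float = 0.0          # SGD momentum; 0 = plain gradient steps
    log_norm_penalty: bool = True
    spectral_norm: bool = False
    weight_clipping: float | None = None   # alternative to the gradient penalty

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.penalty_coefficient < 0:
            raise ValueError("penalty_coefficient must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")


class _StagedNet:
    """Shared progressive-growing machinery for generator and critic."""

    def __init__(self, n_features: int, schedule: NetworkSchedule, dropout_prob: float):
        if n_features <= 0:
            raise ValueError(f"n_features must be positive, got {n_features}")
        self.n_features = int(n_features)
        self.schedule = schedule
        self.stage = schedule.active_stage
        self.dropout = AlphaDropout(dropout_prob)

    def grow(self) -> None:
        """Enable the next hidden layer; existing weights are untouched."""
        if self.stage >= self.schedule.n_stages:
            raise ValueError("network is already at its final stage")
        self.stage += 1

    @property
    def parameters(self):
        return [p for layer in self._active_layers() for p in layer.parameters]

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_parameters for layer in self._active_layers())

    def state(self):
        return {"stage": self.stage,
                "layers": [lyr.state() for lyr in self._all_layers()]}

    def load_state(self, state):
        self.stage = int(state["stage"])
        for lyr, st in zip(self._all_layers(), state["layers"]):
            lyr.load_state(st)


class Generator(_StagedNet):
    """Noise -> data network: n_features -> h_1 -> ... -> h_s -> n_features."""

    def __init__(self, n_features, schedule, dropout_prob, rng: np.random.Generator):
        super().__init__(n_features, schedule, dropout_prob)
        h = schedule.hidden_sizes
        # all stages' layers are materialised up front so that construction is
        # a single deterministic draw; `stage` controls which path is active
        self.in_layer = Dense(n_features, h[0], rng)
        self.links = [Dense(h[i - 1], h[i], rng) for i in range(1, len(h))]
        self.heads = [Dense(h[s], n_features, rng) for s in range(len(h))]

    def _all_layers(self):
        return [self.in_layer, *self.links, *self.heads]

    def _active_layers(self):
        return [self.in_layer, *self.links[: self.stage - 1], self.heads[self.stage - 1]]

    def __call__(self, z: Tensor, rng=None, training: bool = False) -> Tensor:
        h = self.dropout(selu(self.in_layer(z)), rng, training)
        for link in self.links[: self.stage - 1]:
            h = self.dropout(selu(link(h)), rng, training)
        return self.heads[self.stage - 1](h)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` rows in evaluation mode (dropout off); transformed scale."""
        z = Tensor(rng.standard_normal((n, self.n_features)))
        return self(z, training=False).data


class Critic(_StagedNet):
    """Data -> score network: n_features -> h_s -> ... -> h_1 -> 1."""

    def __init__(self, n_features, schedule, dropout_prob, rng: np.random.Generator):
        super().__init__(n_features, schedule, dropout_prob)
        h = schedule.hidden_sizes
        self.entries = [Dense(n_features, h[s], rng) for s in range(len(h))]
        # chain[i] maps h_{i+1} -> h_i; the tail ...-> h_1 -> h_0 -> 1 is stable
        self.chain = [Dense(h[i + 1], h[i], rng) for i in range(len(h) - 1)]
        self.head = Dense(h[0], 1, rng)

    def _all_layers(self):
        return [*self.entries, *self.chain, self.head]

    def _active_layers(self):
        return [self.entries[self.stage - 1], *self.chain[: self.stage - 1][::-1], self.head]

    def __call__(self, x: Tensor, rng=None, training: bool = False) -> Tensor:
        h = self.dropout(selu(self.entries[self.stage - 1](x)), rng, training)
        for i in range(self.stage - 2, -1, -1):
            h = self.dropout(selu(self.chain[i](h)), rng, training)
        return self.head(h)


def build_generator(n_features: int, schedule: NetworkSchedule,
                    hyper: GanHyperparams, rng: np.random.Generator) -> Generator:
    return Generator(n_features, schedule, hyper.dropout_prob, rng)


def build_critic(n_features: int, schedule: NetworkSchedule,
                 hyper: GanHyperparams, rng: np.random.Generator) -> Critic:
    return Critic(n_features, schedule, hyper.dropout_prob, rng)


# ---------------------------------------------------------------------------
# losses


def _mean(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(x)
    if t.data.size == 0:
        raise ValueError("empty batch")
    return t.mean()


def critic_loss(y_fake, y_real, penalty_term=0.0) -> Tensor:
    """mean(y_F) - mean(y_R) + penalty."""
    pen = penalty_term if isinstance(penalty_term, Tensor) else Tensor(penalty_term)
    return _mean(y_fake) - _mean(y_real) + pen


def generator_loss(y_fake, x_fake, alpha: float,
                   log_norm: bool = True, spectral: bool = False) -> Tensor:
    """-mean(y_F) - alpha * log ||X_F|| (Frobenius norm by default)."""
    loss = -_mean(y_fake)
    if alpha > 0:
        xf = x_fake if isinstance(x_fake, Tensor) else Tensor(x_fake)
        if spectral:
            norm = Tensor(np.linalg.norm(xf.data, ord=2))
        else:
            norm = (xf * xf).sum().sqrt()
        if norm.data <= 0:
            raise FloatingPointError("degenerate generated batch: zero matrix norm")
        term = norm.log() if log_norm else norm
        loss = loss - float(alpha) * term
    return loss


def lipschitz_penalty(critic, real_batch, fake_batch, lam: float,
                      rng: np.random.Generator | None = None) -> Tensor:
    """Gradient penalty on real/fake interpolates.

    lam * mean_i (||d critic / d x (x_hat_i)||_2 - 1)^2 with
    x_hat_i = eps_i x_R,i + (1 - eps_i) x_F,i, eps_i ~ U(0, 1).
    The result stays on the autodiff tape, so it can be differentiated with
    respect to the critic weights (grad-of-grad).
    """
    if lam < 0:
        raise ValueError("penalty coefficient must be >= 0")
    xr = real_batch.data if isinstance(real_batch, Tensor) else np.asarray(real_batch, float)
    xf = fake_batch if isinstance(fake_batch, Tensor) else Tensor(fake_batch)
    if xr.shape != xf.shape:
        raise ValueError("real and fake batches must have the same shape")
    if lam == 0:
        return Tensor(0.0)
    if rng is None:
        rng = np.random.default_rng()
    eps = rng.random((xr.shape[0], 1))
    x_hat = Tensor(eps) * Tensor(xr) + Tensor(1.0 - eps) * xf.detach()
    x_hat.requires_grad = True
    score = critic(x_hat).sum()
    g = grad(score, x_hat, create_graph=True)
    norms = ((g * g).sum(axis=1) + 1e-12).sqrt()
    dev = norms - 1.0
    return float(lam) * (dev * dev).mean()


def generate_samples(generator: Generator, n: int, rng: np.random.Generator,
                     transformer=None) -> np.ndarray:
    """Draw ``n`` samples and map them back to the original feature scale."""
    if n <= 0:
        raise ValueError("n must be positive")
    x = generator.sample(n, rng)
    if transformer is not None:
        x = transformer.inverse_transform(x)
    return x
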