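"""GAN training loops: progressive pre-training on external data and
per-class transfer re-training, with automated learning-rate and stopping
epoch selection.

Each growth stage (and each re-training run) uses a two-phase schedule:

1. a larger learning rate ``lr_1`` trained for ``max_epochs_1`` epochs; the
   candidate whose trace attains the smallest critic loss still above
   ``max_loss_1`` wins;
2. a smaller ``lr_2`` trained for ``n_epochs_2`` epochs; after truncating the
   trace at the first out-of-bounds critic loss, the candidate minimising
   ``instab_constant * instability - speed`` wins, and the stopping epoch is
   the knee of the fitted loss decay.

The winner's trajectory is replayed from the cached phase-1 state up to the
selected epoch (bit-identical, since every phase draws from its own seeded
stream), so the returned weights are exactly the knee-epoch weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, grad
from .gan_core import (Critic, GanHyperparams, Generator, NetworkSchedule,
                       build_critic, build_generator, critic_loss,
                       generator_loss, lipschitz_penalty)
from .heuristics import (LossTrace, select_epoch, select_lr1, select_lr2,
                         truncate_trace)
from .nn import SGD, AlphaDropout
from .simulate import LabeledMatrix

__all__ = ["PhaseConfig", "TrainingConfig", "ClassGANPair", "PretrainedGAN",
           "pretrain_progressive", "retrain_class_gans"]


@dataclass
class PhaseConfig:
    """Hyperparameters of one training context (pre-training or re-training)."""

    max_epochs_1: int = 500
    max_loss_1: float = 3.0
    n_epochs_2: int = 1000
    lr_1: tuple = (5e-4, 1e-4, 1e-3)
    lr_2: tuple = (1e-5, 5e-5, 1e-4)
    rate_save: int = 20
    diff_epochs: int = 500
    max_loss_2: float = 15.0
    min_loss_2: float = -10.0
    instab_constant: float = 3.0
    iter_critic: int = 4
    dropout_prob: float = 0.5
    batch_size: int = 30
    top_k_apex_diffs: int = 50

    def __post_init__(self):
        if not self.lr_1 or not self.lr_2:
            raise ValueError("learning-rate candidate lists must be non-empty")
        if self.max_loss_2 <= self.min_loss_2:
            raise ValueError("max_loss_2 must exceed min_loss_2")
        if self.rate_save <= 0:
            raise ValueError("rate_save must be positive")


def default_pretrain_config() -> PhaseConfig:
    return PhaseConfig()


def default_retrain_config() -> PhaseConfig:
    return PhaseConfig(n_epochs_2=5000, lr_1=(5e-4, 1e-4), lr_2=(1e-5, 5e-5),
                       rate_save=10, min_loss_2=-15.0, iter_critic=2,
                       dropout_prob=0.7, batch_size=10)


@dataclass
class TrainingConfig:
    """Both training contexts plus the re-training batch-size split
    (10 for the under-represented class, 20 for the over-represented)."""

    pretrain: PhaseConfig = field(default_factory=default_pretrain_config)
    retrain: PhaseConfig = field(default_factory=default_retrain_config)
    batch_size_minor: int = 10
    batch_size_major: int = 20

    def scaled(self, factor: float) -> "TrainingConfig":
        """A cheaper configuration with epoch budgets scaled by ``factor``
        (learning-rate grids and loss bounds untouched)."""
        def shrink(cfg: PhaseConfig) -> PhaseConfig:
            return replace(cfg,
                           max_epochs_1=max(int(cfg.max_epochs_1 * factor), 4 * cfg.rate_save),
                           n_epochs_2=max(int(cfg.n_epochs_2 * factor), 8 * cfg.rate_save),
                           diff_epochs=max(int(cfg.diff_epochs * factor), cfg.rate_save))
        return TrainingConfig(shrink(self.pretrain), shrink(self.retrain),
                              self.batch_size_minor, self.batch_size_major)


def _sample_batch(data: np.ndarray, batch_size: int, rng: np.random.Generator):
    n = data.shape[0]
    replace_draw = n < batch_size
    idx = rng.choice(n, size=batch_size, replace=replace_draw)
    return data[idx]


def _train(gen: Generator, critic: Critic, data: np.ndarray, n_epochs: int,
           lr: float, cfg: PhaseConfig, hyper: GanHyperparams, alpha: float,
           batch_size: int, seed: int) -> LossTrace:
    """Train for ``n_epochs`` generator cycles, recording losses every
    ``rate_save`` epochs.  One epoch = ``iter_critic`` critic updates then
    one generator update."""
    rng = np.random.default_rng(seed)
    opt_c = SGD(critic.parameters, lr, hyper.beta)
    opt_g = SGD(gen.parameters, lr, hyper.beta)
    p = gen.n_features
    epochs, c_losses, g_losses = [], [], []
    loss_c_val = loss_g_val = np.nan
    for epoch in range(1, n_epochs + 1):
        for _ in range(cfg.iter_critic):
            xr = _sample_batch(data, batch_size, rng)
            z = rng.standard_normal((batch_size, p))
            xf = gen(Tensor(z), rng, training=True).detach()
            y_f = critic(xf, rng, training=True)
            y_r = critic(Tensor(xr), rng, training=True)
            if hyper.weight_clipping is not None:
                pen = Tensor(0.0)
            else:
                pen = lipschitz_penalty(critic, xr, xf,
                                        hyper.penalty_coefficient, rng)
            loss_c = critic_loss(y_f, y_r, pen)
            opt_c.step(grad(loss_c, critic.parameters))
            if hyper.weight_clipping is not None:
                c = hyper.weight_clipping
                for prm in critic.parameters:
                    np.clip(prm.data, -c, c, out=prm.data)
            loss_c_val = float(loss_c.data)
        z = rng.standard_normal((batch_size, p))
        xf = gen(Tensor(z), rng, training=True)
        y_f = critic(xf, rng, training=True)
        loss_g = generator_loss(y_f, xf, alpha, log_norm=hyper.log_norm_penalty,
                                spectral=hyper.spectral_norm)
        opt_g.step(grad(loss_g, gen.parameters))
        loss_g_val = float(loss_g.data)
        if epoch % cfg.rate_save == 0:
            epochs.append(epoch)
            c_losses.append(loss_c_val)
            g_losses.append(loss_g_val)
    return LossTrace(np.array(epochs, dtype=int), np.array(c_losses),
                     np.array(g_losses))


@dataclass
class StageResult:
    lr_1: float
    lr_2: float
    epoch: int
    trace_lr1: LossTrace
    trace_lr2: LossTrace


def _net_state(gen, critic):
    return gen.state(), critic.state()


def _restore(gen, critic, state):
    gen.load_state(state[0])
    critic.load_state(state[1])


def _two_phase(gen: Generator, critic: Critic, data: np.ndarray,
               cfg: PhaseConfig, hyper: GanHyperparams, alpha: float,
               batch_size: int, ss: np.random.SeedSequence) -> StageResult:
    """Run the lr_1 / lr_2 tuned schedule in place; returns the selections."""
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
             for s in ss.spawn(len(cfg.lr_1) + len(cfg.lr_2))]
    lr1_seeds = dict(zip(cfg.lr_1, seeds[: len(cfg.lr_1)]))
    lr2_seeds = dict(zip(cfg.lr_2, seeds[len(cfg.lr_1):]))

    start = _net_state(gen, critic)
    traces1, states1 = {}, {}
    for lr in cfg.lr_1:
        _restore(gen, critic, start)
        traces1[lr] = _train(gen, critic, data, cfg.max_epochs_1, lr, cfg,
                             hyper, alpha, batch_size, lr1_seeds[lr])
        states1[lr] = _net_state(gen, critic)
    lr_1 = select_lr1(traces1, floor=cfg.max_loss_1)

    traces2 = {}
    for lr in cfg.lr_2:
        _restore(gen, critic, states1[lr_1])
        traces2[lr] = _train(gen, critic, data, cfg.n_epochs_2, lr, cfg,
                             hyper, alpha, batch_size, lr2_seeds[lr])
    lr_2 = select_lr2(traces2, instab_constant=cfg.instab_constant,
                      top_k=cfg.top_k_apex_diffs, window=cfg.diff_epochs,
                      upper=cfg.max_loss_2, lower=cfg.min_loss_2)
    best = truncate_trace(traces2[lr_2], cfg.max_loss_2, cfg.min_loss_2)
    if len(best) == 0:
        raise RuntimeError("training diverged: trace empty after truncation")
    if len(best) >= 4:
        epoch = select_epoch(best)
    else:
        warnings.warn("trace too short for a knee fit; using min-loss epoch")
        epoch = int(best.epochs[int(np.argmin(best.critic_loss))])

    # replay the winning phase-2 run up to the selected epoch
    _restore(gen, critic, states1[lr_1])
    _train(gen, critic, data, epoch, lr_2, cfg, hyper, alpha, batch_size,
           lr2_seeds[lr_2])
    return StageResult(lr_1, lr_2, epoch, traces1[lr_1], traces2[lr_2])


def _set_dropout(gen, critic, p: float):
    gen.dropout = AlphaDropout(p)
    critic.dropout = AlphaDropout(p)


@dataclass
class PretrainedGAN:
    generator: Generator
    critic: Critic
    stage_results: list


def pretrain_progressive(external: LabeledMatrix | np.ndarray,
                         config: TrainingConfig, hyper: GanHyperparams,
                         seed: int = 0,
                         schedule: NetworkSchedule | None = None) -> PretrainedGAN:
    """Grow the network one hidden layer at a time on the (already
    transformed) external data; alpha is forced to 0 throughout.

    When the final hidden layer is enabled, the critic:generator ratio drops
    to 2:1 and dropout rises to 0.7 to stabilise training.
    """
    data = external.values if isinstance(external, LabeledMatrix) else np.asarray(external)
    cfg = config.pretrain
    schedule = schedule or NetworkSchedule(active_stage=1)
    ss = np.random.SeedSequence(seed)
    init_ss, *stage_ss = ss.spawn(schedule.n_stages + 1)
    rng_init = np.random.default_rng(init_ss.generate_state(1)[0] % (2 ** 31 - 1))
    sched = NetworkSchedule(schedule.hidden_sizes, active_stage=1)
    gen = build_generator(data.shape[1], sched, hyper, rng_init)
    critic = build_critic(data.shape[1], sched, hyper, rng_init)
    _set_dropout(gen, critic, cfg.dropout_prob)

    results = []
    for stage in range(1, schedule.n_stages + 1):
        if stage > 1:
            gen.grow()
            critic.grow()
        stage_cfg = cfg
        if stage == schedule.n_stages and schedule.n_stages > 1:
            stage_cfg = replace(cfg, iter_critic=2, dropout_prob=0.7)
            _set_dropout(gen, critic, 0.7)
        results.append(_two_phase(gen, critic, data, stage_cfg, hyper,
                                  alpha=0.0, batch_size=cfg.batch_size,
                                  ss=stage_ss[stage - 1]))
    return PretrainedGAN(gen, critic, results)


@dataclass
class ClassGANPair:
    """Trained per-class generators plus the real-data transformer used to
    map generated rows back to the original feature scale."""

    generators: dict
    transformer: object = None
    stage_results: dict = field(default_factory=dict)
    minor_label: int = None
    major_label: int = None

    def generator_for(self, label) -> Generator:
        return self.generators[int(label)]


def _clone_net(template, builder, n_features, schedule, hyper, rng):
    net = builder(n_features, schedule, hyper, rng)
    net.load_state(template.state())
    return net


def retrain_class_gans(pretrained: PretrainedGAN | None, real: LabeledMatrix,
                       config: TrainingConfig, hyper: GanHyperparams,
                       seed: int = 0, alphas: tuple = (0.0, 0.0),
                       transformer=None) -> ClassGANPair:
    """Re-train a copy of the pre-trained network on each class of the (already
    transformed) real data.

    ``alphas`` is (under-represented, over-represented).  With
    ``pretrained=None`` fresh networks are initialised at the final stage with
    no growing — the classic penalised Wasserstein GAN configuration.
    """
    if real.labels is None:
        raise ValueError("real data must be labeled")
    counts = real.class_counts()
    if len(counts) != 2:
        raise ValueError("both classes must be present in the real data")
    minor_label = min(counts, key=lambda c: (counts[c], c))
    major_label = next(c for c in counts if c != minor_label)
    cfg = config.retrain
    ss = np.random.SeedSequence(seed)
    init_minor, init_major, minor_ss, major_ss = ss.spawn(4)

    p = real.n_features
    generators, stage_results = {}, {}
    for label, alpha, batch, init_ss, child in (
            (minor_label, alphas[0], config.batch_size_minor, init_minor, minor_ss),
            (major_label, alphas[1], config.batch_size_major, init_major, major_ss)):
        rng_init = np.random.default_rng(init_ss.generate_state(1)[0] % (2 ** 31 - 1))
        if pretrained is None:
            sched = NetworkSchedule()
            sched = NetworkSchedule(sched.hidden_sizes,
                                    active_stage=sched.n_stages)
            gen = build_generator(p, sched, hyper, rng_init)
            critic = build_critic(p, sched, hyper, rng_init)
        else:
            sched = pretrained.generator.schedule
            gen = _clone_net(pretrained.generator, build_generator, p, sched,
                             hyper, rng_init)
            critic = _clone_net(pretrained.critic, build_critic, p, sched,
                                hyper, rng_init)
        _set_dropout(gen, critic, cfg.dropout_prob)
        data = real.values[real.labels == label]
        if data.shape[0] < batch:
            warnings.warn(f"class {label} has {data.shape[0]} samples, fewer "
                          f"than batch size {batch}; sampling with replacement")
        stage_results[int(label)] = _two_phase(gen, critic, data, cfg, hyper,
                                               alpha, batch, child)
        generators[int(label)] = gen
    return ClassGANPair(generators, transformer, stage_results,
                        int(minor_label), int(major_label))
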