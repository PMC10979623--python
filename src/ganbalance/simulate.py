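"""Two-cluster simulated microarray data and the experiment-design splits.

The simulator emulates a clustered microarray engine on the log-expression
scale with a fully specified hierarchical model:

* features are partitioned into consecutive latent blocks of ``block_size``;
* every feature carries a baseline level ``mu_j ~ N(baseline_mean, baseline_sd^2)``;
* each block has a discriminative loading ``g_b ~ N(0, 1)``, with the
  loading vector rescaled to unit root-mean-square; members of cluster 1
  are shifted by ``cluster_separation * g_b`` on every feature of block
  ``b`` (some blocks separate the clusters strongly, some barely, while the
  overall separability stays a design constant across seeds);
* a per-sample, per-block latent ``t_ib ~ N(0, block_sd^2)`` induces
  within-block correlation;
* independent additive gamma(noise_shape, noise_scale) noise is added to
  every entry.

The default separation makes the clusters imperfectly separable, so class
balancing has something to contribute.

Experiment designs follow the convention that the case count is the control
count multiplied by the class-imbalance ratio (rounded half-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .heuristics import LossTrace

__all__ = [
    "SimulationConfig", "ExperimentDesign", "LabeledMatrix",
    "simulate_two_cluster_dataset", "split_experiment",
    "make_loss_trace_fixture", "table1_designs", "round_half_up",
]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class LabeledMatrix:
    """Samples x features matrix with optional binary labels."""

    values: np.ndarray
    labels: np.ndarray | None = None
    feature_names: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if np.isnan(self.values).any():
            raise ValueError("values must not contain missing entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels must align with rows of values")
            classes = np.unique(self.labels)
            if len(classes) not in (1, 2):
                raise ValueError("labels must be binary")
        if self.feature_names is None:
            self.feature_names = [f"feature_{j}" for j in range(self.values.shape[1])]
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names must align with columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict:
        if self.labels is None:
            raise ValueError("matrix is unlabeled")
        classes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))

    def subset(self, idx) -> "LabeledMatrix":
        labels = None if self.labels is None else self.labels[idx]
        return LabeledMatrix(self.values[idx], labels, self.feature_names)

    def without_labels(self) -> "LabeledMatrix":
        return LabeledMatrix(self.values, None, self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabeledMatrix":
        if "label" in df.columns:
            labels = df["label"].to_numpy()
            values = df.drop(columns="label")
        else:
            labels = None
            values = df
        return cls(values.to_numpy(dtype=float), labels, list(values.columns))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledMatrix":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class SimulationConfig:
    """Parameters of the two-cluster simulator (log-expression scale)."""

    n_samples: int = 1500
    n_features: int = 150
    n_validation: int = 700
    n_external: int = 300
    cluster_separation: float = 0.3
    block_size: int = 10
    block_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    noise_shape: float = 2.0
    noise_scale: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.noise_shape <= 0 or self.noise_scale <= 0:
            raise ValueError("gamma noise parameters must be positive")
        for name in ("n_samples", "n_validation", "n_external", "block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_separation < 0 or self.block_sd < 0 or self.baseline_sd < 0:
            raise ValueError("scale parameters must be non-negative")


@dataclass
class ExperimentDesign:
    """A row of the experiment grid: control count and imbalance ratio.

    The case count is ``round(n_controls * class_imbalance)`` (half-up), per
    the convention that the imbalance ratio multiplies the control count.
    """

    experiment_id: int
    n_controls: int
    class_imbalance: float

    def __post_init__(self):
        if self.n_controls <= 0:
            raise ValueError("n_controls must be positive")
        if not 0 < self.class_imbalance < 1:
            raise ValueError("class_imbalance must lie in (0, 1) so that "
                             "cases stay the minority")
        if self.n_cases >= self.n_controls:
            raise ValueError("case count must stay below the control count")

    @property
    def n_cases(self) -> int:
        return round_half_up(self.n_controls * self.class_imbalance)


def table1_designs() -> list[ExperimentDesign]:
    """The standard nine-design grid: 40/80/120 controls x 0.4/0.5/0.6."""
    grid = [(n, r) for r in (0.4, 0.5, 0.6) for n in (40, 80, 120)]
    return [ExperimentDesign(i + 1, n, r) for i, (n, r) in enumerate(grid)]


def simulate_two_cluster_dataset(config: SimulationConfig) -> LabeledMatrix:
    """Draw the full simulated dataset (both clusters, labeled)."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features
    n_blocks = math.ceil(p / config.block_size)
    block_of = np.minimum(np.arange(p) // config.block_size, n_blocks - 1)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    block_loading = rng.normal(0.0, 1.0, size=n_blocks)
    # rescale to unit root-mean-square so the overall cluster separability is
    # a design constant; which blocks discriminate still varies by seed
    block_loading *= np.sqrt(n_blocks) / np.linalg.norm(block_loading)
    shift = config.cluster_separation * block_loading[block_of]

    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    rng.shuffle(labels)

    latent = rng.normal(0.0, config.block_sd, size=(n, n_blocks))
    noise = rng.gamma(config.noise_shape, config.noise_scale, size=(n, p))
    values = mu[None, :] + labels[:, None] * shift[None, :] + latent[:, block_of] + noise
    names = [f"gene_{j:03d}" for j in range(p)]
    return LabeledMatrix(values, labels, names)


def split_experiment(dataset: LabeledMatrix, design: ExperimentDesign,
                     config: SimulationConfig, seed: int):
    """Split into (real, external, validation).

    Validation and external sets are fixed prefixes of the dataset, so they
    are identical across experiment designs; the external set is a mixture of
    both clusters with the labels stripped.  The real set is drawn from the
    remaining pool with exactly ``n_controls`` controls (label 0) and the
    design's case count (label 1).
    """
    if dataset.labels is None:
        raise ValueError("dataset must be labeled")
    n_val, n_ext = config.n_validation, config.n_external
    n_fixed = n_val + n_ext
    if dataset.n_samples <= n_fixed:
        raise ValueError("dataset too small for the validation/external splits")
    validation = dataset.subset(np.arange(n_val))
    external = dataset.subset(np.arange(n_val, n_fixed)).without_labels()

    pool = np.arange(n_fixed, dataset.n_samples)
    pool_labels = dataset.labels[pool]
    rng = np.random.default_rng(seed)
    controls = pool[pool_labels == 0]
    cases = pool[pool_labels == 1]
    if len(controls) < design.n_controls or len(cases) < design.n_cases:
        raise ValueError(
            f"pool has {len(controls)} controls / {len(cases)} cases; design "
            f"needs {design.n_controls} / {design.n_cases}")
    chosen = np.concatenate([
        rng.choice(controls, size=design.n_controls, replace=False),
        rng.choice(cases, size=design.n_cases, replace=False)])
    real = dataset.subset(np.sort(chosen))
    return real, external, validation


def make_loss_trace_fixture(kind: str, n_epochs: int, params: dict | None = None,
                            seed: int = 0, rate_save: int = 1) -> LossTrace:
    """Deterministic synthetic critic-loss traces for exercising the
    training-control heuristics.

    kinds: ``decay`` (a*exp(-b*t)+c plus optional Gaussian noise),
    ``sawtooth`` (alternating +/- amplitude around a baseline),
    ``diverging`` (ramp first exceeding ``bound`` at ``crossing_epoch``),
    ``constant``.
    """
    if n_epochs <= 0:
        raise ValueError("n_epochs must be positive")
    params = dict(params or {})
    t = np.arange(n_epochs) * rate_save
    rng = np.random.default_rng(seed)
    if kind == "decay":
        a = params.get("a", 10.0)
        b = params.get("b", 0.01)
        c = params.get("c", 1.0)
        sd = params.get("noise_sd", 0.0)
        y = a * np.exp(-b * t) + c
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=n_epochs)
    elif kind == "sawtooth":
        amplitude = params.get("amplitude", 1.0)
        baseline = params.get("baseline", 0.0)
        y = baseline + amplitude * np.where(np.arange(n_epochs) % 2 == 0, 1.0, -1.0)
    elif kind == "diverging":
        bound = params.get("bound", 15.0)
        crossing = params.get("crossing_epoch", n_epochs // 2)
        slope = params.get("slope", 1.0)
        y = bound + slope * (t - crossing) + 0.5 * slope
    elif kind == "constant":
        y = np.full(n_epochs, float(params.get("value", 0.0)))
    else:
        raise ValueError(f"unknown trace kind: {kind!r}")
    return LossTrace(t, y, -y)
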