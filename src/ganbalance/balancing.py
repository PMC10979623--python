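"""Class balancing: target-count arithmetic and the four oversampling modes.

``gan_balance`` / ``smote`` / ``random_oversample`` raise the minority class
to the majority count.  ``gan_expand`` raises *both* classes to a common
target above the majority count::

    T = n_major + round(multiplier * n_major)

so a multiplier of 1.0 doubles the over-represented class.  Generated rows
are appended to the untouched original rows with the label of the class they
were generated for.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .gan_core import generate_samples
from .simulate import LabeledMatrix, round_half_up

__all__ = ["BalancePlan", "target_counts", "apply_balancing",
           "smote_oversample", "MODES"]

MODES = ("gan_balance", "gan_expand", "smote", "random_oversample")


@dataclass
class BalancePlan:
    mode: str
    multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown balancing mode {self.mode!r}")
        if self.mode == "gan_expand" and not 0.0 < self.multiplier <= 1.0:
            raise ValueError("expand multiplier must lie in (0, 1]")


def target_counts(n_minor: int, n_major: int, mode: str,
                  multiplier: float = 1.0) -> tuple[int, int]:
    """Rows to generate per class: ``(minority, majority)``."""
    if n_minor <= 0 or n_major <= 0 or n_minor > n_major:
        raise ValueError("need 0 < n_minor <= n_major")
    if mode == "gan_expand":
        if not 0.0 < multiplier <= 1.0:
            raise ValueError("expand multiplier must lie in (0, 1]")
        target = n_major + round_half_up(multiplier * n_major)
        return target - n_minor, target - n_major
    if mode in ("gan_balance", "smote", "random_oversample"):
        return n_major - n_minor, 0
    raise ValueError(f"unknown balancing mode {mode!r}")


def smote_oversample(minority: np.ndarray, n_new: int,
                     rng: np.random.Generator, k: int = 5) -> np.ndarray:
    """Synthetic minority rows by interpolation towards one of the ``k``
    nearest minority neighbours; ``k`` shrinks when the class is tiny."""
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, neighbours = nn.kneighbors(minority)  # column 0 is the point itself
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    partner = neighbours[base, pick]
    gap = rng.random((n_new, 1))
    return minority[base] + gap * (minority[partner] - minority[base])


def _class_split(real: LabeledMatrix):
    if real.labels is None:
        raise ValueError("real data must be labeled")
    counts = real.class_counts()
    if len(counts) != 2:
        raise ValueError("both classes must be present")
    (c0, n0), (c1, n1) = sorted(counts.items())
    if n0 >= n1:
        major_label, minor_label = c0, c1
    else:
        major_label, minor_label = c1, c0
    return minor_label, major_label


def apply_balancing(real: LabeledMatrix, plan: BalancePlan,
                    gans=None) -> LabeledMatrix:
    """Balance (or expand) ``real`` according to ``plan``.

    GAN modes draw from the per-class generators of ``gans`` (a
    :class:`~ganbalance.training.ClassGANPair`) and inverse-transform to the
    original feature scale; SMOTE and random oversampling resample/interpolate
    the minority rows directly.
    """
    minor_label, major_label = _class_split(real)
    counts = real.class_counts()
    n_minor, n_major = counts[minor_label], counts[major_label]
    gen_minor, gen_major = target_counts(n_minor, n_major, plan.mode, plan.multiplier)
    rng = np.random.default_rng(plan.seed)

    new_rows, new_labels = [], []
    if plan.mode in ("gan_balance", "gan_expand"):
        if gans is None:
            raise ValueError("GAN balancing modes require trained class GANs")
        for label, count in ((minor_label, gen_minor), (major_label, gen_major)):
            if count <= 0:
                continue
            x = generate_samples(gans.generator_for(label), count, rng,
                                 gans.transformer)
            new_rows.append(x)
            new_labels.append(np.full(count, label))
    else:
        minority = real.values[real.labels == minor_label]
        if gen_minor > 0:
            if plan.mode == "smote":
                x = smote_oversample(minority, gen_minor, rng)
            else:  # random oversampling: duplicate minority rows
                x = minority[rng.integers(0, len(minority), size=gen_minor)]
            new_rows.append(x)
            new_labels.append(np.full(gen_minor, minor_label))

    if not new_rows:
        warnings.warn("nothing to generate; classes already at target counts")
        return real
    values = np.vstack([real.values, *new_rows])
    labels = np.concatenate([real.labels, *new_labels])
    return LabeledMatrix(values, labels, real.feature_names)
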