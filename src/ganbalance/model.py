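"""Model/Results facade over the full balancing pipeline.

``ClassBalancingGAN`` is constructed from the labeled "real" matrix and the
unlabeled "external" matrix; ``fit`` runs skewness-gated scaling, progressive
pre-training on the external data and per-class transfer re-training, and
returns a :class:`ClassBalancingGANResults` carrying the trained class
generators, the selected learning rates and stopping epochs, the loss traces
and balancing/generation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balancing import BalancePlan, apply_balancing
from .evaluation import (ClassifierGrid, compare_methods, evaluate_balancing,
                         select_alpha_combination, tune_classifier)
from .gan_core import GanHyperparams, generate_samples
from .preprocessing import (ROBUST, choose_feature_transforms, fit_transformer)
from .simulate import LabeledMatrix
from .training import (ClassGANPair, PretrainedGAN, TrainingConfig,
                       pretrain_progressive, retrain_class_gans)

__all__ = ["ClassBalancingGAN", "ClassBalancingGANResults"]


class ClassBalancingGAN:
    """Penalised Wasserstein GAN pair for balancing a small labeled matrix.

    Parameters
    ----------
    real : LabeledMatrix
        The small labeled sample whose classes are to be balanced.
    external : LabeledMatrix
        Unlabeled data of the same modality and feature set, used for
        transfer pre-training (ignored when ``classic=True``).
    alphas : (float, float)
        Dispersion-term weights for the under- and over-represented class
        GANs (the pre-training loop always runs with alpha 0).
    classic : bool
        Skip pre-training and progressive growing; all layers initialised
        together and alpha forced to 0 (the plain penalised Wasserstein GAN).
    """

    def __init__(self, real: LabeledMatrix, external: LabeledMatrix | None = None,
                 config: TrainingConfig | None = None,
                 hyper: GanHyperparams | None = None,
                 alphas: tuple = (0.0, 0.0), classic: bool = False,
                 skew_alpha: float = 0.05, nonskew_scaler: str = ROBUST,
                 n_external_fit: int = 200):
        if real.labels is None:
            raise ValueError("real data must be labeled")
        if external is None and not classic:
            raise ValueError("external data is required unless classic=True")
        self.real = real
        self.external = external
        self.config = config or TrainingConfig()
        self.hyper = hyper or GanHyperparams()
        self.alphas = (0.0, 0.0) if classic else tuple(alphas)
        self.classic = classic
        self.skew_alpha = skew_alpha
        self.nonskew_scaler = nonskew_scaler
        self.n_external_fit = n_external_fit

    @classmethod
    def from_dataframes(cls, real: pd.DataFrame, external: pd.DataFrame | None = None,
                        **kwargs) -> "ClassBalancingGAN":
        ext = None if external is None else LabeledMatrix.from_dataframe(external)
        return cls(LabeledMatrix.from_dataframe(real), ext, **kwargs)

    def fit(self, seed: int = 0,
            pretrained: PretrainedGAN | None = None) -> "ClassBalancingGANResults":
        """Run the full training pipeline.

        A previously fitted ``pretrained`` network (from another design on the
        same external data) can be supplied to share the pre-training stage.
        """
        ss = np.random.SeedSequence(seed)
        s_ext, s_pre, s_re = ss.spawn(3)

        external_transformer = None
        if not self.classic and pretrained is None:
            plan_ext = choose_feature_transforms(self.external, self.skew_alpha,
                                                 self.nonskew_scaler)
            rng = np.random.default_rng(s_ext.generate_state(1)[0] % (2 ** 31 - 1))
            n_fit = min(self.n_external_fit, self.external.n_samples)
            external_transformer = fit_transformer(self.external, plan_ext, n_fit, rng)
            ext_t = external_transformer.transform(self.external.values)
            pretrained = pretrain_progressive(
                ext_t, self.config, self.hyper,
                seed=int(s_pre.generate_state(1)[0] % (2 ** 31 - 1)))

        plan_real = choose_feature_transforms(self.real, self.skew_alpha,
                                              self.nonskew_scaler)
        real_transformer = fit_transformer(self.real, plan_real)
        real_t = LabeledMatrix(real_transformer.transform(self.real.values),
                               self.real.labels, self.real.feature_names)
        pair = retrain_class_gans(
            None if self.classic else pretrained, real_t, self.config,
            self.hyper, seed=int(s_re.generate_state(1)[0] % (2 ** 31 - 1)),
            alphas=self.alphas, transformer=real_transformer)
        return ClassBalancingGANResults(self, pair, pretrained,
                                        real_transformer, external_transformer)


@dataclass
class ClassBalancingGANResults:
    """Fitted class generators plus diagnostics and downstream helpers."""

    model: ClassBalancingGAN
    gan_pair: ClassGANPair
    pretrained: PretrainedGAN | None
    real_transformer: object
    external_transformer: object = None

    def generate(self, label: int, n: int, seed: int = 0) -> np.ndarray:
        """Draw ``n`` synthetic rows for ``label`` on the original scale."""
        rng = np.random.default_rng(seed)
        return generate_samples(self.gan_pair.generator_for(label), n, rng,
                                self.gan_pair.transformer)

    def balance(self, mode: str = "gan_balance", multiplier: float = 1.0,
                seed: int = 0) -> LabeledMatrix:
        plan = BalancePlan(mode, multiplier=multiplier, seed=seed)
        return apply_balancing(self.model.real, plan, self.gan_pair)

    def validate(self, validation: LabeledMatrix, method: str = "gan_balance",
                 n_iterations: int = 100, seed: int = 0,
                 multiplier: float = 1.0, grid: ClassifierGrid | None = None,
                 params: dict | None = None):
        """Tune the classifier (unless ``params`` given) and run the repeated
        balanced-training auroc protocol for one method."""
        if params is None:
            first = self.balance(method, multiplier, seed=seed)
            params = tune_classifier(first, grid, seed=seed)
        return evaluate_balancing(self.model.real, validation, method,
                                  self.gan_pair, params,
                                  n_iterations=n_iterations, seed=seed,
                                  multiplier=multiplier)

    def summary(self) -> str:
        lines = ["Class-balancing penalised Wasserstein GAN", "=" * 42]
        counts = self.model.real.class_counts()
        lines.append(f"real data: {self.model.real.n_samples} samples x "
                     f"{self.model.real.n_features} features; classes {counts}")
        lines.append(f"alpha (under/over): {self.model.alphas[0]:g}/"
                     f"{self.model.alphas[1]:g}"
                     + ("  [classic: no pre-training, no growing]"
                        if self.model.classic else ""))
        if self.pretrained is not None and not self.model.classic:
            lines.append("pre-training stages (lr_1, lr_2, stop epoch):")
            for i, sr in enumerate(self.pretrained.stage_results, start=1):
                lines.append(f"  stage {i}: lr_1={sr.lr_1:g} lr_2={sr.lr_2:g} "
                             f"epoch={sr.epoch}")
        lines.append("re-training (per class):")
        for label, sr in sorted(self.gan_pair.stage_results.items()):
            role = "under" if label == self.gan_pair.minor_label else "over"
            lines.append(f"  class {label} ({role}-represented): "
                         f"lr_1={sr.lr_1:g} lr_2={sr.lr_2:g} epoch={sr.epoch} "
                         f"final critic loss="
                         f"{sr.trace_lr2.critic_loss[-1]:.3f}")
        return "\n".join(lines)
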