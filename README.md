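# ganbalance

Wasserstein-GAN class balancing for small-sample, high-dimensional omics
matrices (bulk microarray, lipidomics and similar tabular profiles).

## The problem

Case/control omics studies are routinely imbalanced: one class outnumbers
the other several-fold, and classifiers trained on such data learn the
over-represented class at the expense of sensitivity on the rare one.
Classical fixes oversample the minority class by duplication (random
oversampling, RO) or nearest-neighbour interpolation (SMOTE); both operate
row-locally and ignore the joint feature distribution. `ganbalance`
implements a generative alternative: a penalised Wasserstein GAN, one
generator per class, that learns the feature distribution and synthesises
new samples to balance — or expand — the training set.

## The model

The critic `f` and generator `G` are fully-connected SELU networks (hidden
widths 50 → 100 → 200 for the generator, reversed for the critic, input and
output width equal to the feature count). Training minimises

```
L_critic = mean f(X_F) - mean f(X_R) + λ · mean (‖∇_x f(x̂)‖₂ − 1)²
L_gen    = − mean f(X_F) − α · log ‖X_F‖_F
```

where `x̂` are uniform real/fake interpolates (gradient penalty, λ = 10) and
`‖X_F‖_F` is the Frobenius norm of the generated batch — the α-weighted
dispersion term rewards spread-out batches, countering mode collapse when
the training sample is tiny. Because the sample is tiny, the network is
first **pre-trained** on an unlabeled "external" dataset of the same
modality (progressively, one hidden layer at a time), then **transfer
re-trained** on each class of the labeled "real" data. Learning rates and
stopping epochs are chosen automatically from the critic-loss traces
(two-phase schedule, instability/speed scoring, knee-point detection on a
fitted exponential decay).

Balanced data is produced in four modes: `gan_balance` and `smote` /
`random_oversample` raise the minority class to the majority count;
`gan_expand` raises *both* classes to `n_major + round(multiplier ×
n_major)`. The validation protocol repeatedly re-balances, refits a tuned
histogram gradient-boosted classifier and scores auroc on a held-out
validation split; methods are compared with Welch's t-test under
Benjamini-Hochberg adjustment.

A built-in simulator emulates a two-cluster microarray dataset (150
features, correlated latent blocks, additive gamma(2, 0.5) noise) with the
standard experiment grid of 40/80/120 control samples at class-imbalance
ratios 0.4/0.5/0.6.

## Worked example

```python
from ganbalance import (ClassBalancingGAN, ExperimentDesign, SimulationConfig,
                        TrainingConfig, simulate_two_cluster_dataset,
                        split_experiment)

cfg = SimulationConfig(seed=7)
dataset = simulate_two_cluster_dataset(cfg)
design = ExperimentDesign(9, n_controls=120, class_imbalance=0.6)
real, external, validation = split_experiment(dataset, design, cfg, seed=42)

model = ClassBalancingGAN(real, external,
                          config=TrainingConfig().scaled(0.1),  # short demo budget
                          alphas=(0.0, 0.0))
results = model.fit(seed=1)
print(results.summary())

report = results.validate(validation, "gan_balance", n_iterations=10, seed=0)
print(report.summary())
```

prints (abridged):

```
Class-balancing penalised Wasserstein GAN
==========================================
real data: 192 samples x 150 features; classes {0: 120, 1: 72}
alpha (under/over): 0/0
pre-training stages (lr_1, lr_2, stop epoch):
  stage 1: lr_1=0.0001 lr_2=5e-05 epoch=80
  stage 2: lr_1=0.0001 lr_2=5e-05 epoch=120
  stage 3: lr_1=0.0001 lr_2=1e-05 epoch=80
re-training (per class):
  class 0 (over-represented): lr_1=0.0001 lr_2=5e-05 epoch=440 final critic loss=0.417
  class 1 (under-represented): lr_1=0.0005 lr_2=5e-05 epoch=190 final critic loss=0.258
gan_balance: mean auroc 0.846 (sd 0.009, AUC diff +0.346, n=10)
```

The summary lists the learning rates and stopping epochs the training
heuristics selected per stage and per class; the validation report gives the
mean auroc over repeated re-balancing runs, its standard deviation, and the
difference from the 0.5 chance baseline.

The same pipeline is scriptable from the shell:

```bash
ganbalance simulate --n-controls 120 --imbalance 0.6 --seed 1 --out-dir run/
ganbalance pretrain --external run/external.csv --out run/pretrained.json
ganbalance retrain --real run/real.csv --pretrained run/pretrained.json --out run/pair.json
ganbalance balance --real run/real.csv --method gan --gans run/pair.json --out run/balanced.csv
ganbalance validate --real run/real.csv --validation run/validation.csv \
    --methods gan,expandgan,smote,ro --gans run/pair.json --report run/report.json
```

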