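# Methods

## Model

`ganbalance` trains a penalised Wasserstein GAN pair to oversample the
classes of a small labeled sample × feature matrix. The critic scores
realness on an unbounded scale; its loss is the Wasserstein surrogate
`mean f(X_F) − mean f(X_R)` plus a gradient penalty
`λ · mean (‖∇_x f(x̂)‖ − 1)²` on uniform real/fake interpolates, the soft
form of the 1-Lipschitz constraint. λ defaults to 10, the conventional
value for penalised Wasserstein critics; plain weight clipping is available
behind `GanHyperparams.weight_clipping` for comparison. The generator loss
is `−mean f(X_F) − α · log ‖X_F‖_F`: with α > 0, batches with a larger
Frobenius norm are rewarded, pushing the generator to disperse and
countering mode collapse on tiny training sets. The log form is used
because the raw norm grows without bound and would dominate the critic
term; a `log_norm_penalty=False` switch reproduces the raw-norm variant,
and `spectral_norm=True` swaps the Frobenius norm for the spectral norm.
The Frobenius default was chosen because it is the cheap, smooth matrix
norm and treats all batch directions alike.

Architectures are fully connected with SELU activations, Kaiming-normal
initialisation (std = 1/√fan_in) and alpha-dropout; self-normalisation
removes the need for batch normalisation. Generator widths are
`n_features → 50 → 100 → 200 → n_features`; the critic mirrors them in
reverse and ends in a single linear unit with no output activation. The
generator's noise prior is standard normal with dimension equal to the
feature count, and its output has no squashing activation, since data live
on an unbounded transformed scale. Generated values are *not* clipped to
the observed data range; only the Yeo-Johnson inverse clips into its
mathematical domain (see below).

### Autodiff core

No GPU tensor library is assumed: the networks run on a small reverse-mode
autodiff engine (`ganbalance.autodiff`) written on numpy. Its
vector-Jacobian products are themselves expressed as graph operations, so
gradients are differentiable — required because the gradient penalty puts
the critic's input gradient inside the training objective (grad-of-grad
with respect to the weights). The engine is validated against
finite-difference oracles, including a second-order check.

## Training procedure

**Pre-training (transfer learning).** The network is first trained on an
unlabeled "external" matrix with the same features, growing progressively:
stage 1 enables one hidden layer, later stages add the next layer plus a
fresh output head (generator) or entry layer (critic); previously trained
layers are preserved bit-exactly at growth. α is forced to 0 throughout
pre-training. The critic:generator update ratio starts at 4:1 with dropout
0.5 and switches to 2:1 with dropout 0.7 when the final layer is enabled,
to stabilise the larger network. Optimisers are re-initialised at growth
events, since the active parameter set changes.

**Re-training.** Two copies of the pre-trained network are re-trained, one
per class of the labeled "real" data, with batch sizes 10 (under-
represented class) / 20 (over-represented), ratio 2:1, dropout 0.7 and
per-class α taken from the requested combination (0/0, 1/0 or 1/1; 0/1 is
not part of the protocol). A `classic=True` switch skips pre-training and
growing entirely (all layers initialised together, α = 0) — the plain
penalised Wasserstein GAN baseline.

**Two-phase learning-rate schedule.** Each stage/run first trains with a
larger rate lr₁ (candidates {5e-4, 1e-4, 1e-3} in pre-training, {5e-4,
1e-4} in re-training) for `max_epochs_1 = 500` epochs; the candidate whose
trace attains the smallest critic loss still above `max_loss_1 = 3` wins.
If no candidate ever exceeds that floor — common when the critic converges
quickly — the smallest final loss wins, with a warning. Training continues
with a smaller rate lr₂ ({1e-5, 5e-5, 1e-4} / {1e-5, 5e-5}) for
`n_epochs_2` epochs (1000 pre-training, 5000 re-training). Traces are
sampled every `rate_save` epochs (20 / 10) and truncated at the first
critic loss above `max_loss_2 = 15` or below `min_loss_2` (−10 pre-training,
−15 re-training), the offending entry excluded since it is already out of
bounds. lr₂ minimises `3 × instability − speed`, where *instability* is the
mean of the 50 largest absolute differences between consecutive apexes of
the critic-loss series (all strict local extrema, plateaus collapsed,
endpoints included) and *speed* is the mean loss over the first 500 epochs
minus the mean over the last 500. Ties prefer the smaller rate. The
stopping epoch is the knee — the point of maximum deviation from the chord
after min–max normalisation — of a three-parameter exponential decay
`a·exp(−bt)+c` fitted to the truncated trace by nonlinear least squares;
the exponential was chosen because it matches the expected critic-loss
shape and yields a well-defined knee. A fitted curve whose maximum chord
deviation is below 1% of the normalised range is treated as knee-less
(e.g. linear traces), falling back to the minimum-loss epoch with a
warning. The winning trajectory is replayed from the cached phase-1 state
up to the selected epoch, which is bit-identical because every phase draws
from its own seeded stream.

An "epoch" throughout is one generator update cycle (iter_critic critic
steps followed by one generator step, batches drawn with replacement only
when a class is smaller than its batch size). Per Table-2-style defaults,
`beta` (SGD momentum) is 0 — plain gradient steps; it is exposed as a
config field because momentum materially accelerates convergence on easy
problems (the toy tests use 0.9).

## Preprocessing

Each feature is assigned a scaler by a two-sided D'Agostino skewness test
against normality: p < 0.05 → Yeo-Johnson power transform
(maximum-likelihood λ, then standardisation), otherwise a robust
median/IQR scaler. The robust scaler is the declared non-skew component; a
`nonskew_scaler="standard_scale"` switch provides the plain z-score
alternative. Constant features (skewness undefined) get the non-skew
scaler with a unit-scale fallback and a warning — features are never
dropped silently. Two transformers are fitted: the external one on 200
random external rows, the real one on all real rows; generated samples are
inverse-transformed with the real transformer. The Yeo-Johnson image is
one-sided-bounded when λ < 0 or λ > 2, so arbitrary generated values are
clipped into the open domain (margin 1e-3) before inversion — without this
the inverse is undefined (NaN) for tail draws.

Feature filtering keeps the k most significant features by adjusted
p-value (ties broken by name), then removes features with missing values
in any provided dataset. Stability selection refits L1 and elastic-net
(mixing 0.5, configurable) logistic models on random 75% splits, tuning
each penalty by 10-fold inner CV per iteration, and returns the
intersection of the top-⌈25%⌉ appearance-frequency rankings of the two
methods; the per-iteration re-tuning reflects the systematic penalty
optimisation the protocol prescribes.

## Balancing and validation

Target-count arithmetic: balance modes generate `n_major − n_minor`
minority rows; expanded generation targets `T = n_major +
round_half_up(multiplier × n_major)` per class, multiplier ∈ (0, 1].
Original rows are always preserved verbatim; generated rows take the label
of their generating GAN. SMOTE uses k = 5 neighbours (the original
convention; the protocol leaves k unstated), auto-reduced for tiny
minorities. Validation: hyperparameters of a histogram gradient-boosted
classifier are tuned once per balanced dataset by stratified 5-fold CV
auroc over learning rates {1e-4, 1e-3, 1e-2, 1, 10} × min-samples-per-leaf
{1, 10, 25, 50, 75} (ties keep the first grid cell); then the training set
is re-balanced afresh for each of 100 iterations, the classifier refitted
and scored on the held-out validation split. Welch's unequal-variance
t-test compares the per-iteration auroc vectors pairwise — these vectors
are the only per-method samples the protocol produces — with
Benjamini-Hochberg adjustment across the pair family within one
experiment (a `pooled` comparison across experiments is possible by
concatenating reports before `compare_methods`). Zero-variance pairs with
equal means report p = 1 by convention, flagged with a warning. The α
combination with the greatest mean auroc represents the GAN methods in
cross-method comparisons; ties prefer the lower α (simpler model).

## Simulator

The built-in generator emulates a clustered microarray engine on the
log-expression scale with a fully specified hierarchical model: features
partition into consecutive blocks of `block_size = 10`; baselines are
N(6, 1); each block carries a discriminative loading g_b ~ N(0, 1), with
the loading vector rescaled to unit root-mean-square so that overall
separability is a design constant rather than a per-seed draw, and
cluster-1 members shift by `cluster_separation × g_b` on every feature of
the block; a per-sample block latent N(0, 0.5²) induces within-block
correlation; independent gamma(shape 2, scale 0.5) noise is added to every
entry. Defaults: 150 features, 1500 samples (700 validation + 300
unlabeled external drawn at the overall 50/50 cluster proportions + a pool
for the per-design real splits), `cluster_separation = 0.3`. The
separation was fixed once so the clusters are imperfectly separable — an
oracle gradient-boosted classifier trained on abundant data reaches auroc
≈ 0.93 — because balancing is only informative when the problem is neither
trivial nor hopeless. Case counts follow the convention that the imbalance
ratio multiplies the control count (round-half-up; exact for the standard
grid). What the simulator does *not* emulate: batch effects,
heavy-tailed outliers, feature-specific variance structure or the
gene-signature machinery of real microarray pipelines — so green tests
here show the pipeline's mechanics and relative method behaviour, not
performance on real tissue data.

## Problem sizes used in the checks

The test suite rebuilds three designs (40/0.4, 80/0.5, 120/0.6) with epoch
budgets at 0.15× the defaults, 8 balancing iterations and a 2×2 classifier
grid — the largest configuration that keeps the whole suite inside a
practical runtime. `scripts/acceptance.py` runs the 120/0.6 design with
budgets at 0.5× the defaults, the full classifier grid and the full 100
iterations. Both are the package's reduced-problem-size choices; results
under them are noisier than a full-budget run but use the identical code
path.

## Known limitations

* Plain SGD at the default learning rates converges slowly; the transfer
  and heuristic machinery is faithful, but generator quality at reduced
  epoch budgets is modest. Momentum (`GanHyperparams.beta`) helps when
  fidelity to the default optimiser is not required.
* The dispersion weight α cannot be tuned from training losses alone — it
  barely moves the loss curves — so selecting it requires validation
  scores, with the attendant risk of optimistic bias noted in the
  protocol itself.
* The simulator's separability is a design constant; quantities that
  depend on the *absolute* difficulty of the classification problem (such
  as printed auroc levels of a different simulation engine) transfer only
  approximately.
* Binary classes only; no batch-effect correction; features must match
  exactly between real and external data.
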