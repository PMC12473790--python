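# Methods

## Input representation and conventions

The unit of data is a differential-entropy (DE) feature tensor
`[N, C, F]` — `N` samples, `C` EEG channels (62 for SEED-family layouts,
configurable for synthetic data), `F = 5` bands in the fixed order delta,
theta, alpha, beta, gamma.  Flat `N × (C·F)` matrices are channel-major:
flat column `c·5 + f` holds channel `c`, band `f`, matching the usual
"62×5" convention.  All indices (subjects, sessions, trials, classes) are
0-based; trial ids are per subject-session, and every sample of a trial
carries the trial's label.

Normalisation is per-feature z-scoring with the population (1/N) standard
deviation.  During fine-tuning the statistics are computed on the
fine-tune split only and reused on the test split, so no test information
leaks into the transform; zero-variance columns have their std clamped to
1 (logged).  Pre-training consumes the raw DE values: the views are
defined on the physical band-power scale (the adaptive noise scale is a
function of `mean|X|`), and the backbone's internal LayerNorm makes the
downstream features insensitive to the input's affine scale.

## Stage 1: dual-view self-supervised pre-training

**Noise view.** `X + N(0, I)·s` with `s = min(cap, slope·mean|X| + eps)`,
`cap = 0.05`, `slope = 0.1`, `eps = 1e-8`.  The scale is a single scalar
per batch (the literal mean over the whole tensor), so the view is a
homogeneous, magnitude-aware corruption; the cap keeps it from swamping
the signal.

**Wavelet view.** Per sample-channel, the 5-band profile is padded to
length 6 by repeating the gamma value, analysed with the orthogonal Haar
matrix (`cA_k = (x_{2k}+x_{2k+1})/√2`, `cD_k = (x_{2k}−x_{2k+1})/√2`),
perturbed, synthesised, and truncated back to 5 bands.  The pad/truncate
pair makes the μ = 0 round trip exact to machine precision, which the
tests pin at 1e-10.  Perturbation draws three independent Bernoulli masks
with rates (μ/2, μ, μ/2), μ = 0.05 by default:

- approximation coefficients are scaled by `1 + μ·M_A·ε_A` with
  standard-normal `ε_A` (the amplitude constant is exposed as `amp_a`,
  default μ);
- detail coefficients are multiplied by 0.5 where the suppress mask
  fires, by `1 + ε_D·σ_D` where the enhance mask fires (suppress wins on
  collisions), and by 1 elsewhere.  `σ_D` is the population std of the
  channel's three detail coefficients; for a flat profile it is 0 and the
  enhance branch is a no-op.

The "multiply by 1 elsewhere" choice is deliberate: reading the masked
multiplier literally as `0.5·M_sup + M_enh·(1+ε·σ)` zeroes ≈92.5 % of
detail coefficients at μ = 0.05 and destroys the view's structure, and it
breaks the natural requirement that μ → 0 recover the identity.  The
piecewise form implements the suppress/enhance semantics those masks are
named for.  The literal behaviour remains selectable via
`MaskConfig(eq6_literal=True)` for comparison.

**Backbone and objective.**  The shared extractor is
`LayerNorm(GELU(W₁x+b₁))W₂+b₂` (GELU exact/erf form; LayerNorm over the
feature axis with variance epsilon 1e-5 and no learnable affine — the
formulas use it purely as a normaliser).  Both views pass through the same
parameters.  The loss is `λ_align·L_align + λ_style·L_style` with
`λ_align = 1.0`, `λ_style = 0.01` (no published values exist for these;
both are config fields).  `L_align = 2 − 2·mean cos` is bounded in [0, 4]
and invariant to positive row rescaling.  `L_style` is computed on
row-normalised embeddings by default, so the Gram diagonal is exactly 1
and only cross-sample similarity is penalised; inside the training
objective it is additionally divided by B² to make the effective weight
batch-size stable (the public `style_diversity_loss` returns the raw
Frobenius quantity).  Optimisation is Adam (lr 1e-3) for 200 epochs at
batch size 256 by default.

## Stage 2: supervised fine-tuning

The pre-trained weights initialise the backbones of two parallel encoders
(copied, then trained independently).  Each DE vector is a length-one
token sequence, so multi-head attention (h = 4 heads by default) is
formally present but collapses to the affine `H·W_V·W_O` path — the
architecture keeps the attention/pooling stages for structural fidelity
and for inputs with L > 1, and the tests assert the L = 1 degeneracy
explicitly.  The noise-view encoder computes
`z = LayerNorm(pool(LayerNorm(H + α·MHA(H))))`; the wavelet-view encoder
inserts `H ← H + α·FFN(H)` with
`FFN = Dropout(W₂·GELU(Dropout(W₁·x)))` (hidden width 4·d_model, dropout
0.1) before the final normalisation; α = 0.1 damps both residuals.  The
two embeddings are averaged and an MLP head
(`W₂·Dropout(GELU(LayerNorm(W₁z+b₁)))+b₂`, hidden width 128) produces
logits.  No augmentation is applied at fine-tune time; the encoders see
the same normalised input and differentiate through their weights (a flag
can re-enable augmented inputs, off by default).

Training: cross-entropy on the target corpus' fine-tune trials only
(source labels are not used; a flag can include them), Adam (lr 1e-4
default), 20 epochs at batch size 128, gradient clipping
`g ← g·min(1, 1/‖g‖₂)` over the global parameter vector at every step
(zero gradients pass through unscaled), and a reduce-on-plateau schedule
(factor 0.5, patience 5) monitoring the epoch-mean training loss — on a
flat loss trace it fires exactly once after six non-improving epochs.

The ablation variants are configurations, not code paths: `no-nerm` /
`no-wtrm` replace the corresponding pre-training view with the clean
input, `no-pretrain` initialises the backbones randomly.

## Numerical core

All training runs on a small reverse-mode autodiff engine over float64
NumPy arrays (`cate.nn`): broadcast arithmetic, batched matmul, erf-GELU,
LayerNorm, softmax, fused cross-entropy, inverted dropout, Adam,
global-norm clipping and the plateau schedule.  Gradients are verified
against central finite differences in the test suite.  Everything is
single-threaded and seeded: every stage takes an explicit seed and
reproduces its metrics bitwise on re-run.

## Synthetic study conditions

The generator emulates the statistical skeleton of a multi-subject DE
corpus: per class k, channel c, band f a sample is
`gain_f·(m[k,f] + u_s + v_c) + offset_f + N(0, σ)` with class-band means
`m`, subject offset `u_s ~ N(0, 0.15)`, channel offset `v_c ~ N(0, 0.10)`
and sample noise σ.  Trials are contiguous blocks of equal size with
round-robin class labels.  The default class means are synthetic design
values (slow-band-heavy, flat, and beta/gamma-elevated profiles around
~1 in log-power units), not estimates from any real corpus.  The default
pair applies a per-band affine shift (gains 0.90–1.15, offsets ±0.25) and
20 % extra noise to the target.  The sample noise default σ = 0.8 was
calibrated once so that the full pipeline's target accuracy lands in the
60–80 % band where cross-corpus EEG transfer realistically operates,
rather than at ceiling where method comparisons are uninformative; it was
then frozen.

Default experiment sizes are desk-scale: 3 subjects, 15 trials × 20
samples, 62 channels, d_model 64, 30 pre-training and 15 fine-tuning
epochs — small enough that the full four-variant, five-seed acceptance
run completes in minutes on one CPU while leaving enough signal for the
qualitative ordering (full ≥ random-init in most paired seeds) to be
measurable.

**What the synthetic experiments show and do not show.**  They exercise
every stage of the method end to end — the views, the objective, the
transfer protocol, the ablations — under a controlled affine-plus-noise
domain shift, and they demonstrate that pre-training helps under those
conditions.  They do not reproduce real EEG properties (electrode
geometry and spatial correlation, non-stationarity within trials,
label noise, non-affine inter-dataset shifts), so passing results here do
not certify performance on real corpora; they certify the implementation
and the method's behaviour in a shift family it is designed to handle.

## Degenerate inputs and tie-breaks

- LayerNorm of a constant row returns zeros (variance epsilon), so a
  zero-weight first layer maps every input to `b₂`.
- L2 normalisation guards zero rows (they stay zero) without perturbing
  nonzero rows, keeping the loss anchor values exact.
- Suppress beats enhance on mask collisions; `σ_D = 0` disables the
  enhance branch.
- Zero-variance features are z-scored to zero with std recorded as
  clamped.
- A single subject aggregates with sd 0 and a warning; empty prediction
  sets are rejected.
- Mixed-precision is accepted as a flag for interface parity only;
  arithmetic is always float64.

## Known limitations

- L = 1 sequences make the attention stage an affine map; the mechanism
  only becomes informative for multi-token inputs, which the data model
  does not currently produce.
- The pre-training corpus composition (source ∪ target fine-tune trials,
  labels ignored) is one defensible choice among several; it is
  config-selectable.
- Hyperparameters with no published values (λs, d_model, optimizers,
  learning rates, head count, hidden widths, dropout) use the defaults
  stated above and are all exposed in the config dataclasses.
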