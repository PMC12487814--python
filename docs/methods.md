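# Methods

## Model

`chronovae` fits one conditional variational autoencoder per data modality.
Each cell contributes four factors:

* **Identity embedding `z`** (default dimension 50): a diagonal-Gaussian
  posterior produced by a two-hidden-layer MLP encoder from the cell's
  depth-normalised `log1p` counts concatenated with the time, condition and
  batch factors. The prior is `N(0, I)`, independent of time — the only
  prior consistent with a time-invariant identity.
* **Time factor**: a sinusoidal encoding of collection time in days,
  `[sin(w_i t'), cos(w_i t')]` with `w_i = 2π/10000^{2i/d}`,
  `i = 0…d/2−1`, `d = 50`, and `t' = t / min_wavelength`. The minimum
  wavelength (default 1 day) rescales time rather than reshaping the
  frequency ladder, so the fastest coordinate pair repeats exactly once per
  `min_wavelength` and the slowest has period `10000^{(d−2)/d}` days.
* **Condition and batch factors**: one-hot encodings. Condition enters the
  encoder and the temporal interaction layer; batch enters the encoder and
  the decoder. Where exactly the batch factor should enter was an open
  design point; we include it on both sides since removing it from either
  measurably degrades cross-batch alignment.

A **temporal interaction layer** maps `[z ⊕ enc(t) ⊕ condition]` to a
time-aware embedding of the same dimension as `z` (one tanh hidden layer).
The decoder (two hidden layers, ReLU) maps `[e ⊕ batch]` to likelihood
parameters. Hidden widths are the rounded geometric mean of the input and
latent dimensions.

**Likelihoods.** scRNA-seq counts follow a zero-inflated negative binomial
in the scVI convention: softmax mean fractions scaled by the observed
per-cell library size, a free per-gene dispersion shared across cells, and
per-gene-per-cell dropout logits emitted by the decoder. Binarised
scATAC-seq peaks follow a Bernoulli whose logits get a per-cell scalar
offset linear in the centred log total accessible-peak count, absorbing
coverage differences. Both likelihoods are implemented in numerically
stable logit form and are checked in the tests against brute-force pmf
summation.

**Adversarial time invariance.** A discriminator (one hidden layer) is
trained by cross-entropy to predict the discretised collection time from
`z`; the generator objective subtracts that loss (weight 1, configurable).
Updates alternate 1:1; the discriminator sees detached embeddings, and the
generator sees a frozen discriminator, so neither update leaks gradients
into the other's parameters. Time classes are the distinct observed training
times — time is modelled continuously everywhere except in this classifier.

**Optimisation.** Adam (lr 1e-3), minibatch 128, early stopping on the
validation reconstruction loss with patience 10 (larger in the test
fixtures). The KL term is annealed linearly over the first
`kl_warmup_epochs` (default 50) epochs; without warm-up the posterior
collapses (all latent dimensions die and predictions degenerate to a
per-time mean — we observed exactly this, and warm-up resolves it). Early
stopping is suspended during warm-up. Every entry point takes an integer
seed controlling initialisation, shuffling and sampling; training is
bit-reproducible given the seed.

**Splits.** Whole time points are held out as the test set; remaining cells
split 1:4 validation:training per time point, with at most 2000 validation
cells per time point.

## Multimodal coupling

The RNA model (denser time sampling) is the reference. The ATAC model is
trained afterwards with (i) its temporal interaction layer *shared by
reference* with the RNA model's and frozen, (ii) an MSE pull of coassay
cells' ATAC embeddings toward their RNA partners' embeddings (weight λ,
default 100, grid {1, 100, 10000}), and (iii) translation losses in both
directions (encode one modality, decode the other through the shared
interaction layer, score the observed partner profile). Because the RNA
objective does not depend on any ATAC parameter, one pass of step 1 (RNA)
followed by step 2 (ATAC) is already the fixed point of the stepwise
schedule; the implementation therefore runs a single pass. Embedding
pulling uses posterior means, not samples. Cross-modality prediction runs
the RNA encoder, the shared interaction layer at the target time, and the
ATAC decoder; probabilities are clamped to (1e-6, 1−1e-6).

## Model selection and ensembles

The hyperparameter grid is latent dimension {25, 50, 100} (× λ
{1, 100, 10000} for multimodal), hidden layers fixed at 2, time dimension
fixed at 50, minimum wavelength fixed at 1 day. Candidates are ranked per
validation metric (cross-time pseudobulk Pearson, LISI between neighbouring
time points, LISI around the held-out time, plus batch/cross-modality LISI
and translation losses when available), the ranks are summed and rescaled so
the best model has summed rank exactly 1; ties break toward the smaller
latent dimension, then the smaller λ. Metrics that are unavailable for a
given data set (e.g. batch LISI with one batch) are simply omitted from the
sum. Downstream analyses train 10-model ensembles — with distinct seeds
and, for the sex analysis, a random time point held out from each member —
and aggregate predictions or statistics by the median. The random-holdout
strategy matters: single models occasionally *invert* the condition-swap
prediction at boundary time points where only one condition was sampled,
and the ensemble median removes these inversions (sensitivity of
consistent-gene calling rose from ~0.2 to ~0.9 on the sex fixture when we
switched from three seed-only models to the 10-model random-holdout
ensemble).

## Downstream statistics

**Sex-bias score.** For each cell of a cell type (pooled, by default, with
the previous and subsequent time points), the profile is predicted under
both condition factors at the same time and identity; the per-gene score is
`W⁺/(n(n+1)/2)` of the paired differences (midranks for ties, zero
differences dropped; 0.5 returned when all differences vanish). Scores are
only computed with more than 50 cells; consistent sex-biased genes must stay
strictly on one side of 0.5 at every retained time point (>25 cells), within
the top half of genes by predicted mean expression at every time point.
Note one compositional caveat: because predicted profiles are fractions, a
true effect on some genes necessarily depresses all other genes' fractions,
so "null" genes sit slightly below 0.5 in the presence of a real
female-side effect; exchangeability (scores centred at 0.5) holds exactly
when the programmed effect is zero, and the recovery AUROC is unaffected.

**PPI odds ratio.** The odds of protein-interaction edges linking
female-biased autosomal genes to female-biased X-linked genes, relative to
non-female-biased autosomal genes; the null resamples equal-size autosomal
sets 100 times and the p-value is plus-one corrected. The test refuses to
run with fewer than 50 relevant interactions.

**TLCC.** Trajectories are predicted directly on a 0.01-day grid over
[7.5, 9] days (ensemble medians), so shifting is exact index arithmetic.
`TLCC(τ) = corr(expr(t), acc(t + τ))` over the core window [8, 8.5] for τ in
−0.5…0.5 (101 shifts): accessibility leading expression peaks at negative τ
("before"/priming), trailing at positive τ ("after"). Argmax ties break to
the smallest |shift|; an exact ± tie is uncategorised. Query cells are
extended with four consensus neighbours (per model, top 25 by Euclidean
distance on identity embeddings; ranks summed across models with absent
cells charged rank 26; cells absent from every model's list excluded). Pairs
with maximum correlation below 0.5 or surviving in fewer than two cells are
dropped; a pair's class requires all retained cells to agree in sign,
otherwise it is flagged discordant. Peak–gene pairing is strand-aware:
a peak pairs with a gene when it overlaps the single 200-kb window on the
upstream side of the TSS (read literally as upstream-only, not ±200 kb —
the looser reading would roughly double the candidate pairs).

## Synthetic data

The generators produce the statistical structure the model assumes, not
biological realism. Per (cell type, gene), a log-rate combines a global
baseline `N(0,1)`, a cell-type offset `N(0,1)`, and a temporal signal from
one of five families (flat, linear, sigmoid, pulse, sinusoid) with random
amplitude (1.5–3), centre, width (pulses 0.15–0.25 d) and period (sinusoids
1–2 d). Expression fractions are the softmax over genes; counts are Poisson
at log-normal library sizes (median ≈ 2000). Gaussian noise of SD 1 or 3 is
added per cell per gene on the log-rate scale, and cells within a (type,
time) block carry pseudotime offsets in 0.002-day steps (99 × 0.002 =
0.198 d across the default 100 cells — the literal per-neighbour step, which
rounds to the commonly quoted 0.2 d). Named presets fix the two standard
regimes (`sim-noise3`: SD 3, synchronised; `sim-pseudotime`: SD 1,
0.002-day steps), the alternating-sex design (`sex`: 8 effect genes at
2-fold in females, two double-sex time points) and the paired design
(`multimodal`, below). Sampling is a pure function of the config seed.

The multimodal generator links peaks to dedicated well-expressed genes
(base log-rate 0.5–1.5) carrying sign-balanced pulses constrained so that
both the gene bump and its lag-shifted peak bump lie inside [8.1, 8.4];
peak probability is a logistic transform (steepness 1.2) of the gene signal
shifted by the programmed lag (−0.2, −0.1, 0.1 or 0.2 d), plus a flat
background. ATAC is observed at four of the seven RNA time points and half
of those cells are coassays. Two deliberate width regimes exist: narrow
pulses (0.05–0.09 d) make the TLCC argmax recover the programmed lag to
±0.02 d on noise-free trajectories but are invisible to a model trained on
0.25-day-spaced samples, while the default 0.10–0.14 d pulses are learnable
and support before/after classification through the trained ensemble at the
cost of a small windowing bias in the exact argmax. No single width gives
both sub-grid argmax precision and learnability at these sampling rates —
the sampling interval, not the estimator, is the limit.

What the generators do *not* emulate: gene–gene regulatory structure,
doublets and ambient contamination, per-cell identity beyond the block
structure (cells within a (type, time) block are exchangeable up to
pseudotime microsteps — which is why exact coassay partners cannot be
re-identified among block peers and alignment is validated as distance
contraction instead), and the Bernoulli ceiling on per-peak AUROC (even the
true generating probability only reaches ≈0.59 against realised binary
outcomes on the default design). Passing tests therefore demonstrate that
the estimators recover the structure they model, at desk scale, not that
the model captures real chromatin biology.

## Numerical choices

ZINB and Bernoulli likelihoods run in logit space with `logaddexp`; means
and dispersions are floored at 1e-8; encoder log-variances are clamped to
±10 with straight-through gradients inside the bounds. The softmax
subtracts a detached row maximum. The gradient engine is a ~300-line
reverse-mode tape over numpy verified against central finite differences;
Adam is the only optimiser. Hidden widths are rounded geometric means with
a floor of 2. Zero-total-count cells are dropped at load time with a logged
warning (depth scaling is undefined for them). `make_split` matches holdout
times with `isclose` to survive float-formatted metadata.

## Problem sizes

Tests and the acceptance script run desk-scale versions of the standard
conditions: 2,700-cell RNA fixtures (3 types × 9 times × 100 cells,
30 genes), a 1,320-cell alternating-sex fixture (40 genes, 10-model
ensemble), and a 1,400-RNA/800-ATAC-cell multimodal fixture (60 genes,
30 peaks, 5-model ensemble), with latent dimension 16. The full suite runs
in about five minutes on one CPU; the acceptance script in about five to
seven minutes.

## Known limitations

* Cross-entropy discretises time for the discriminator; very dense time
  courses would need binning.
* The adversarial game is weak relative to reconstruction (≈2 vs ≈130
  nats), so single models can retain probe-detectable time information;
  invariance claims are made seed-averaged, as is standard for adversarial
  objectives.
* The ATAC side inherits its temporal resolution from the coassay time
  points; features changing faster than that spacing are interpolated by
  the network, not constrained by data.
* No modelling of proliferation or death rates, RNA velocity, or trainable
  time embeddings.
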