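# Methods

## Simulated cells

Three static response models generate ground truth on a 10×10 pixel field.
Each is built from Gabor kernels

G(x, y) = A·exp(−(x′²/2σ₁² + y′²/2σ₂²))·cos(k₀ y′ + τ),
(x′, y′) = R(θ)(x − x₀, y − y₀),

with pixel coordinates (x, y) = (column, row), 0-based integer centres, θ
counter-clockwise from the x-axis. The carrier varies along y′, so the
stripe ("orientation") axis is x′; all downstream orientation logic uses
this convention, and orientations are treated as axial (period π).

* **simple**: R = max(s·f₁, 0) + ε — a rectified linear-nonlinear cascade;
* **complex**: R = √((s·f₁)² + (s·f₂)²) + ε — the energy model, f₂
  identical to f₁ with τ shifted by π/2. The amplitude is sampled once and
  shared by both filters;
* **rotation-invariant**: R = maxᵢ(s·fᵢ) + ε over 36 filters whose θ step
  by 5°; the subunit outputs are not rectified before the max (the model is
  taken literally as stated).

Parameters are uniform over: x₀/Lₓ, y₀/L_y ∈ [0.1, 0.9]; A ∈ [0, 1];
σ₁/Lₓ, σ₂/L_y ∈ [0.1, 0.2]; k₀ ∈ [π/3, π]; θ, τ ∈ [0, 2π] (rotation-
invariant cells: σ/L ∈ [0.15, 0.2], k₀ ∈ [π/3, 2π/3], centre fixed at the
field centre, θ base 0). Noise ε is Gaussian, mean 0, SD 1, drawn
independently for each of 4 trials and each stimulus, *before* trial
averaging; the trial mean is then min-max scaled to [0, 1] over the full
stimulus set (computed once, before any CV split).

## Stimuli

Stimuli are small grey-scale images down-sampled to 10×10 by non-overlapping
block averaging (area-weighted for non-integer ratios — exact on integer
ratios and anti-aliasing by construction) and standardised per pixel
position (mean 0, SD 1 across the set; the stored statistics invert the
transform). Two generators ship:

* **white noise** — independent standard-normal pixels (used for
  white-noise RF-mapping analyses);
* **natural surrogate** — Gaussian noise shaped to a 1/f amplitude
  spectrum (power ∝ 1/f²), the canonical second-order statistic of natural
  scenes. It stands in for calibrated natural-image databases; it has no
  phase structure (no edges/objects), so analyses that depend on
  higher-order image statistics are outside what the simulated experiments
  can test. Pipelines generate surrogates at 40×40 and down-sample, so the
  10×10 stimuli carry genuine coarse-scale correlations.

The presentation-pipeline details of a physical display (circular masking,
contrast normalisation, grey-scaling) are folded into the surrogate
generator; they affect only raw pixels that the preprocessing discards.

## CNN encoding model

Per cell: input 10×10 → four valid 3×3 convolutions (32 filters, ReLU;
feature maps 8, 6, 4, 2) → 2×2 max-pool (1×1×32) → fully connected ReLU
layer (32 units, dropout 0.5 at training time) → sigmoid scalar.
Glorot-uniform initialisation. Training minimises MSE by minibatch momentum
SGD: v ← m·v + ε_t·∇E, w ← w − v, with m = 0.9, ε₀ = 0.1 and
ε_t = ε₀/(1 + 5·10⁻⁵·t) per update (the conventional reading of a "decay
coefficient"; Adam with published defaults is available but SGD is the
tested default). Batch size 5 when the training set has ≤ 400 stimuli,
else 30. A 90/10 train/validation split monitors the validation Pearson
similarity; "saturation" early stopping is operationalised as patience = 10
epochs without improvement, restoring the best-epoch parameters.
`fc_units = 32` is a package choice (matching the 1×1×32 flattened input);
it is config-exposed.

The network is implemented directly on numpy (im2col convolutions,
hand-derived backprop, float32). This keeps the dependency footprint small
and exposes exact input gradients for the RF synthesis below.

Cross-validation: seeded k-fold (default 5), per-fold Pearson r between
held-out predictions and responses, averaged. Pearson r of a (numerically)
constant vector is reported as 0 with a warning, never NaN, so the ≤ 0.3
exclusion gate behaves deterministically. Baselines (Lasso α = 0.01, Ridge
α = 10⁴, RBF-SVR γ = C = 0.01) run through scikit-learn under the same CV
protocol. Nonlinearity index = 1 − R_Lasso/R_CNN, undefined (flagged) when
R_CNN ≤ 0.

Before RF synthesis the CNN is refit on *all* data for 120 fixed epochs
(no validation split). The refit is intentionally run past the
early-stopping point: the sigmoid must saturate enough that a synthesised
optimum can reach ≥ 99% of the maximum observed response; early-stopped
refits cap the reachable output around 0.97–0.99 and starve the acceptance
gate.

## RF synthesis (activation maximisation)

Objective: E(I) = f(I; W\*) − (λ₁/M)Σ|I|^α − (λ₂/M)Σ((∂I/∂x)² +
(∂I/∂y)²)^{β/2}, with λ₁ = 10, λ₂ = 2, α = 6, β = 1, M = pixel count.
Spatial derivatives are forward differences with replicate boundary (the
scalar test oracle uses the same convention). The α-norm term bounds pixel
amplitudes (its gradient 0.6·|I|⁵ at λ₁/M = 0.1 overwhelms the model
gradient beyond |I| ≈ 1); the TV term shapes smoothness.

Ascent is RMSprop: r ← γr + (1−γ)g², I ← I + lr·g/√(r + 10⁻⁷), γ = 0.95.
Because RMSprop normalises each pixel's step to roughly ±lr, the learning
rate is the per-step displacement in standardised pixel units. The package
default is **300 steps at lr = 0.05**: a few unit-size steps amount to
per-pixel sign flips dominated by the penalty gradient and do not converge
(measured: predicted response ~0.4–0.5 of maximum, no Gabor structure),
whereas 300 sub-pixel steps settle into the penalty-bounded optimum
(predicted response ≥ 0.99 of maximum, Gabor fit similarity 0.7–0.96).
Both knobs are config fields.

Each repeat starts from a standard-normal random image with its own derived
seed; the ascended image is standardised to mean 0/SD 1 and accepted when
the model's prediction *on the standardised image* reaches
`accept_fraction` (0.95 by library default; the simulated-cell pipeline
uses 0.99) of the cell's maximum actual response — the gate is evaluated on
the same image the downstream statistics use. Failures retry with fresh
seeds up to `max_attempts` = 20; an exhausted repeat returns its best
attempt flagged below-threshold. Ensembles batch all repeats through the
network per attempt round (outputs are per-sample independent, so one
backward pass yields every image's own gradient); results are reproducible
for a fixed master seed.

## Gabor fitting and linear RFs

Gabor fits minimise the summed pixelwise absolute error by bounded SLSQP,
multistarted over a 7×7 grid of initial centres at L·{1/8, …, 7/8} (the
grid count is prescribed; the positions are a package choice), with the
initial orientation and frequency taken from the image's spectral peak.
Bounds: 0 ≤ x₀/Lₓ, y₀/L_y ≤ 1; σ/L ∈ (0.02, 0.2]; π/3 ≤ k₀ ≤ π. Parameter
degeneracies ((θ+π, τ) ≡ (θ, −τ); (−A, τ) ≡ (A, τ+π)) are canonicalised to
A ≥ 0, θ ∈ [0, π). Fit quality is the pixelwise Pearson correlation; a fit
failing on all 49 starts is flagged with similarity −1.

The linear RF uses the ridge form of the regularised pseudoinverse,
w = (SᵀS + λI)⁻¹Sᵀr, with λ grid-searched (13 log-spaced values
10⁻³…10³ by default) under 10-fold CV on the Pearson prediction similarity
and refit on all data at the best λ. The smoothness-penalised variant of
the pseudoinverse is a possible alternative; the ridge form is the default
because the penalty actually used by the upstream literature is not pinned
down.

## Shift detection and complexness

ZNCC between two RF images at integer shift (u, v) is evaluated on the
overlap region, with means and norms computed over that region; the search
window keeps |u|, |v| ≤ L/2 with ≥ 50% area overlap (larger shifts on a
10×10 field leave degenerate overlaps).

**Threshold choice.** The library default for declaring a pair "shifted" is
ZNCC > 0.95 at some (u, v) ≠ (0, 0). The simulated-cell pipeline instead
uses 0.7 for both the shifted-image set and the population shifted-pair
statistic, and this is deliberate: two matched-phase Gabors with envelope
SD σ translated by one pixel correlate as exp(−1/(4σ²)) ≈ 0.89–0.94 for
the σ ∈ [1, 2] px the generators draw, so a 0.95 criterion detects nothing
on converged 10×10 RF images (measured maximum over 1,225 complex-cell
pairs: 0.92) and complexness would degenerate to 0 for every cell. At 0.7
the classifier separates cleanly. The strict-0.95 pair fraction is still
reported per cell, and both thresholds are config options.

Two shift statistics are distinguished. The *shifted image set* uses the
strict criterion — ZNCC above threshold at some (u, v) ≠ (0, 0) — because
its purpose is to collect genuinely translated RF copies. The *population
shifted-pair fraction* counts pairs whose peak ZNCC over the search window
**including (0, 0)** exceeds the threshold: it asks whether two RF images
are explained by a translation at all, and identical images (zero shift)
trivially are; only pairs differing beyond any translation are excluded.
Cells whose RF synthesis cannot reach the acceptance gate for at least
half of the repeats are excluded from RF-based analysis with a logged
`rf_below_threshold` status.

The shifted image set grows greedily: seeded by the pair with the largest
shift distance orthogonal to the Gabor stripe axis (projection onto
(−sin θ, cos θ); ties broken towards the higher summed activation
fraction), any image shifted relative to a collected image joins, to
closure. With no shifted pair the set is the single RF with the highest
predicted response — the complex model then equals the simple model by
construction.

Simple model: response ≈ cosine(stimulus, RF), best single RF from the set.
Complex model: per-stimulus max cosine over the set. "Normalised dot
product" is implemented as the cosine of the flattened standardised images.
Complexness = 1 − R_simple/R_complex; cells with Gabor-fit similarity
≤ 0.6, R_simple < 0 or R_complex < 0 stay unclassified; otherwise
complexness ≤ 0 → simple, > 0 → complex-like. R_complex ≥ R_simple is not
guaranteed — the max-predictor can fit worse than the best single RF — and
simple cells indeed land at small negative complexness.

## Spatial organisation

All unordered cell pairs contribute (distance, |Δcomplexness|) rows and a
Pearson r. The cluster test permutes labels over the observed positions
(simple-cell positions re-sampled uniformly, the rest complex-like,
1,000 permutations by default) and builds per-bin 1st/99th-percentile
envelopes of the cumulative within-class pair-distance curves on a fixed
grid of 50 bins spanning 0 to the plane diameter. "Normalised by the area"
divides the cumulative count at distance d by the disc area πd² (a pair-
density correction); plain CDF normalisation is config-selectable, and the
output records which was used. A synthetic-plane generator (uniform
positions, optional planted cluster) ships for end-to-end tests.

## Problem sizes and runtimes

Full-scale defaults mirror the reference experiment (30 simple + 70
complex + 10 rotation-invariant cells, 2,200 stimuli, 100 RF estimations
per cell, 1,000 for rotation-invariant cells, 5-fold CV). The
`ExperimentConfig.scaled()` configuration used by the test suite and by
`scripts/acceptance.py` keeps the study conditions (2,200 stimuli, 4
trials, unit noise, the full synthesis recipe) but runs 12 simple + 24 complex
cells (the reference simple:complex design ratio at reduced scale), 50 RF estimations per cell, 2-fold CV with early-stopped fold
training capped at 60 epochs, and a 100-epoch refit; one experiment takes
~15–17 minutes on a single CPU core. Fold training length trades runtime
against gate fidelity: an undertrained fold model biases the similarity
estimate low — high-frequency cells (k₀ > 2 rad/px) learn slowly on 1/f
stimuli because the response rides on the weak high-frequency stimulus
components — and the bias inflates the gate-out rate, so folds train to
validation saturation within the cap. Statistics quoted from scaled runs
carry the correspondingly wider binomial error bars.

## Known limitations

* The surrogate stimuli match natural images only up to second-order
  statistics; conclusions about responses to real natural scenes require
  real stimuli through the documented CSV/HDF5 interfaces.
* All responses are static scalars per stimulus: no spiking dynamics,
  calcium kinetics, or temporal RFs.
* The 0.7 shift threshold is calibrated to 10×10 fields with σ/L ∈
  [0.1, 0.2]; other geometries may warrant a different value (it is a
  config option).
* Complexness of a rotation-invariant cell is not meaningful (its RF
  ensemble varies in orientation, not position); the pipeline still fits
  Gabors and reports per-cell rows, but classification is designed for the
  simple/complex axis.
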