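# cnnrf

Nonlinear receptive-field (RF) characterisation of visual neurons with CNN
encoding models.

## The problem

Classical RF estimators for visual neurons assume a response model: the
spike-triggered average assumes linearity, spike-triggered covariance handles
second-order nonlinearity at most. Yet many neurons — V1 complex cells above
all — are strongly nonlinear: their response is invariant to the spatial
phase of the preferred grating, so no single linear filter describes them.

`cnnrf` implements an assumption-free alternative for people who model
stimulus–response data (computational neuroscientists, systems
neuroscientists with imaging data):

1. **Encoding model.** For each cell, a small CNN (four valid 3×3
   convolutional layers of 32 filters with ReLU, one 2×2 max-pool, one fully
   connected ReLU layer with dropout 0.5, sigmoid output) is trained by
   momentum SGD (m = 0.9, ε₀ = 0.1, decay 5·10⁻⁵ per update) to predict the
   trial-averaged, [0, 1]-scaled response *t* to a 10×10 stimulus *I*,
   minimising mean squared error. Prediction quality is the cross-validated
   Pearson correlation ("prediction similarity"); Lasso (α = 0.01), Ridge
   (α = 10⁴) and RBF-SVR (γ = C = 0.01) baselines share the protocol, and
   the *nonlinearity index* 1 − R_Lasso/R_CNN measures the CNN's gain.
2. **RF synthesis by activation maximisation.** An image is ascended with
   RMSprop (γ = 0.95) to maximise

   E(I) = f(I; W\*) − (λ₁/M)‖I‖α^α − (λ₂/M)∫((∂I/∂x)² + (∂I/∂y)²)^{β/2}

   with λ₁ = 10, λ₂ = 2, α = 6, β = 1, M the pixel count; the result is
   standardised (mean 0, SD 1) and accepted only if the model's predicted
   response reaches ≥ 99% of the cell's maximum actual response. Repeating
   the synthesis independently (100×) maps the *set* of optimal stimuli.
3. **Complexness.** Pairs of RF images related by a pixel shift (zero-mean
   normalised cross-correlation above threshold at some (u, v) ≠ (0, 0))
   are collected greedily into a "shifted image set". A *simple model*
   predicts responses as the cosine between stimulus and one RF; a *complex
   model* takes the max cosine over the set. Complexness
   = 1 − R_simple/R_complex classifies cells as simple (≤ 0) or
   complex-like (> 0).
4. **Spatial organisation.** Pairwise distance vs complexness difference,
   and a 1,000-fold position-permutation envelope test for label
   clustering.

Ground truth comes from the built-in simulators: simple cells
R = max(s·f₁, 0) + noise, energy-model complex cells
R = √((s·f₁)² + (s·f₂)²) + noise (f₂ phase-shifted 90°), and
rotation-invariant cells R = maxᵢ(s·fᵢ) + noise over 36 filters 5° apart,
all with Gabor filters drawn from published parameter ranges, 4 trials,
unit-SD Gaussian noise.

## Worked example

```python
import warnings
from cnnrf.pipeline import ExperimentConfig, run_experiment, summarise

cfg = ExperimentConfig.scaled(master_seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_experiment(cfg)
cols = ["cell_id", "true_type", "status", "label", "r_cnn",
        "gabor_fit_similarity", "complexness"]
print(bundle.cells.loc[bundle.cells.status == "analysed", cols].round(3))
print(summarise(bundle).round(3))
```

prints (≈14 minutes on one core):

```
    cell_id true_type    status  ...  r_cnn  gabor_fit_similarity  complexness
0         0    simple  analysed  ...  0.497                 0.905       -0.140
4         4    simple  analysed  ...  0.330                 0.604       -0.211
5         5    simple  analysed  ...  0.766                 0.903       -0.119
7         7    simple  analysed  ...  0.711                 0.872       -0.062
8         8    simple  analysed  ...  0.495                 0.875       -0.100
12       12   complex  analysed  ...  0.356                 0.765        0.628
18       18   complex  analysed  ...  0.339                 0.844        0.825
20       20   complex  analysed  ...  0.868                 0.918        0.933
21       21   complex  analysed  ...  0.605                 0.897        0.779
22       22   complex  analysed  ...  0.852                 0.955        0.912
27       27   complex  analysed  ...  0.726                 0.931        0.833
28       28   complex  analysed  ...  0.779                 0.876        0.885

[12 rows x 7 columns]
n_cells                             36.000
n_analysed                          12.000
n_gated_out                         19.000
n_rf_below_threshold                 5.000
n_failed                             0.000
sensitivity_simple                   1.000
n_classified_simple                  5.000
sensitivity_complex                  1.000
n_classified_complex                 7.000
orientation_circular_correlation     0.960
mean_fraction_shifted_pairs          0.671
sd_fraction_shifted_pairs            0.296
share_activation_ge_99               0.962
```

Reading this: of the 36 simulated cells, 12 reach full analysis — the rest
are gated out by the cross-validated prediction criterion (> 0.3; unit-SD
noise over 4 trials makes low-amplitude and very-high-frequency cells
honestly unpredictable) or excluded because RF synthesis cannot reach the
99% acceptance gate. The elided `label` column classifies every analysed
simple cell as simple (complexness ≤ 0, sensitivity 1.0 at n = 5) and every
analysed complex cell as complex-like (complexness 0.63–0.93, sensitivity
1.0 at n = 7): the max-cosine complex model out-predicts the single-RF
simple model exactly when the RF ensemble contains phase-shifted copies.
Fitted RF orientations track the generator filters (circular correlation
0.96), and 96% of synthesised RF images drive the model to ≥ 99% of the
cell's maximum observed response.

A CLI mirrors the library: `cnnrf simulate`, `cnnrf fit`,
`cnnrf estimate-rf`, `cnnrf complexness`, `cnnrf spatial`,
`cnnrf run-all`, `cnnrf summarise` (see `--help`).

## Layout

| module | contents |
| --- | --- |
| `cnnrf.stimuli` | white-noise / 1-f surrogate stimulus generation, down-sampling, per-pixel standardisation |
| `cnnrf.simcells` | Gabor kernels, simulated cell models, noisy trial responses |
| `cnnrf.encoders` | CNN encoding model + baselines, CV prediction similarity, nonlinearity index |
| `cnnrf.rfmax` | regularised activation maximisation, RF ensembles |
| `cnnrf.rfanalysis` | Gabor fitting, regularised-pseudoinverse linear RF, similarity metrics |
| `cnnrf.complexness` | ZNCC shift detection, shifted image set, simple/complex models, classification |
| `cnnrf.spatial` | distance–complexness relation, permutation cluster test |
| `cnnrf.pipeline` | end-to-end experiment, summaries |

See `docs/methods.md` for the modelling and numerical choices.
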