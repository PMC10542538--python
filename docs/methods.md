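# Methods

## Model

A recording session consists of K trials, each divided into T equal time
bins.  Spike detection and localization (performed upstream, outside this
package) yield one feature vector per spike, s_itk ∈ R^D — by default the
spike's estimated position along the probe width (x) and depth (z) plus its
maximum peak-to-peak amplitude — and y_k denotes the behavior in trial k,
either a binary scalar (e.g. a left/right choice) or a length-T continuous
trace (e.g. wheel speed).

The generative model is a mixture of C Gaussians over spike features whose
mixing proportions are modulated by behavior:

    λ_ctk = g(θ_cᵀ u_tk),             θ_c ~ p(θ_c)
    z_itk ~ Categorical(π_tk),        π_ctk = λ_ctk / Σ_c' λ_c'tk
    s_itk ~ N(μ_{z_itk}, Σ_{z_itk})

where u_tk is a GLM design vector (intercept + current behavior value by
default; lagged behavior and time-bin one-hot terms are optional), and g is
a strictly positive inverse link.  The behavior thus shifts probability
mass between components over time without ever assigning spikes to units.

Spike counts n_tk are conditioned on throughout inference (the likelihood
is over feature values and assignments given the observed counts).  The
simulator, by contrast, draws counts from a Poisson whose mean is
proportional to the summed component rates, so that counts alone also carry
behavioral information — mirroring what multi-unit thresholding exploits —
with a fixed-budget mode available for controlled tests.

### Link function

The default inverse link is the softplus, g(a) = log(1 + e^a), chosen over
the exponential for optimization stability: its log-derivative is bounded,
so gradient steps on θ cannot blow up the rates.  The exponential link is
available by configuration.  Note that with softplus the intercepts are
only weakly identified — the likelihood depends on θ only through the
normalized proportions π — so intercept point estimates should not be
interpreted; only the behavior-weight directions and the resulting π are
meaningful.

### Feature standardization

Probe coordinates (µm) and amplitudes (standard units) live on different
scales, so the mixture is always fit on per-dimension z-scored features.
Standardization is affine, hence exactly invertible, and the fitted
components are reported in original units; responsibilities are invariant
under this change of variables, so no downstream quantity depends on it.

## Inference

The posterior over assignments z and coefficients θ is approximated with a
mean-field factorization q(z, θ) = Π q(z_itk) Π q(θ_c) (each spike gets its
own assignment factor — the E step requires per-spike responsibilities).
Both fitters share the E step: r_itk(c) ∝ π_{c,t,k} N(s_itk; μ_c, Σ_c),
computed with log-sum-exp stabilization.

**CAVI** (used for binary behaviors by default) alternates three blocks:

1. E step — exact responsibilities (above).
2. Mixture M step — closed-form responsibility-weighted means and
   covariances, identical to Gaussian-mixture EM.  Component parameters are
   point-estimated in the default mode; this keeps the standard-EM analogy
   exact.
3. θ block — the coupling term Σ_ctk R_ctk log π_ctk(θ) (+ log prior), with
   R_ctk the responsibilities summed within each bin, is maximized by
   L-BFGS over all components jointly with analytic gradients.  The update
   is accepted only if it improves the objective, so the ELBO trace is
   non-decreasing by construction.  Variational variances for θ come from
   the inverse diagonal curvature at the optimum (a Laplace approximation;
   the model admits no conjugate update).  When behavior weights are frozen
   and the prior is flat, the block optimum has the closed form
   softplus(b_c) ∝ Σ R_c, which makes the behavior-free reduction
   iterate-for-iterate identical to textbook EM — a property the test suite
   checks against an independent EM implementation.

The default iteration cap is 50, which is ample at these problem sizes;
convergence is declared when the relative ELBO change drops below 1e-6.
Empty components (total responsibility ≈ 0) are reseeded at the
lowest-likelihood spike and the event is logged in the fit report.
Covariances are floored at 1e-4·I (in z-scored units) to prevent collapse
onto single spikes.

**ADVI** (used for continuous behaviors by default) places a
diagonal-Gaussian variational factor on each θ_c and ascends a
reparameterized Monte-Carlo ELBO with Adam — learning rate 0.001,
minibatches of 6 trials, 1000 iterations by default.  The gradients are
computed analytically (the GLM coupling term has closed-form derivatives),
so no automatic-differentiation framework is needed.  Trials are the
minibatch unit because they are the exchangeable unit of the model; the
minibatch data term is rescaled by K/|batch|.  Mixture means and
covariances are refreshed by full-data M steps every 25 iterations, which
keeps their updates exact while θ is learned stochastically.  If the
objective turns non-finite the fitter aborts and returns the last finite
snapshot.

Initialization: k-means centroids (10 restarts, seeded) with within-cluster
scatter for covariances; a random-spike initializer is available.  The
number of components C is user-set; a held-out-ELBO utility path is the
recommended way to choose it.

## Decoding

At test time θ is frozen at its variational mean and the behavior is
unknown.  Two routes are provided:

* **Weight-matrix route (default).**  Posterior proportions π̂ are computed
  from the rate model using observed behavior for training trials and a
  provisional estimate ŷ for test trials, obtained from multi-unit
  thresholding: spikes are grouped into proxy channels by equal-width bins
  of the depth coordinate (feature tables carry no electrode indices, and
  depth is the axis along which channels are laid out), a one-hot count
  matrix is built per group, and a baseline decoder fit on the training
  trials predicts ŷ.  Responsibilities under π̂ are then summed into the
  K × C × T weight matrix W_kct = Σ_i r_itk(c), which conserves spike
  counts exactly: Σ_c W_kct = n_tk.  Flattened rows of W feed the final
  decoder — logistic regression for binary behavior, ridge regression for
  traces (one linear head per output bin sharing the full flattened W,
  the simplest faithful linear head).  Regularization is selected by inner
  3-fold CV over powers of ten, 1e-3..1e3.  Hard assignments (sorted units
  or thresholded channels) produce integer one-hot W, so every baseline
  runs through the identical downstream pipeline.

* **Latent-variational route.**  Mean-field q(z, y): for binary y the
  coordinate updates are exact (y takes two values) and return a Bernoulli
  posterior per trial; for continuous y a MAP trace under a squared-
  exponential GP prior is found per trial by L-BFGS.  This route is
  retained for completeness and diagnostics; the weight-matrix route is
  more robust and is the default everywhere.

Test-time π̂ uses the variational mean of θ rather than samples — the mean
is the standard plug-in and avoids injecting Monte-Carlo noise into W.

## Evaluation harness

Cross-validation splits trials (the exchangeable unit), 5 folds by
default, seeded.  Binary behaviors are scored by accuracy, continuous by
R² pooled over bins and trials within a fold (pooling weights every bin
equally, rather than averaging per-bin R² values which can be dominated by
low-variance bins).  Per-fold metrics, their mean and standard deviation,
fold assignments, and a config hash are reported.  Test-trial behavior is
used exclusively for scoring — a leakage test verifies that corrupting it
leaves test predictions bit-identical.

Baselines: multi-unit thresholding (depth-binned proxy channels, above);
sorted units, emulated by degrading the simulator's true labels with a
configurable contamination fraction (spikes relabeled to a wrong unit) and
miss rate (spikes dropped); and "good" sorted units, restricted to a random
subset of units to emulate quality-control filtering.

## What the simulator does and does not emulate

The simulator is exact ancestral sampling from the generative model, so
parameter-recovery and conservation tests have unambiguous ground truth.
Defaults: T = 30 bins per trial (a 1.5 s trial at 50 ms bins), unit
component covariances with means spaced `separation` apart along the depth
axis (6 SDs by default — well separated; the end-to-end evaluations also
use 2.5 SDs, the overlapping regime where soft assignment genuinely
matters), behavior weights ±1.5 alternating across components (strong
modulation), Bernoulli(0.5) choices or GP traces with a 5-bin lengthscale.

Real recordings differ in ways the simulator does not model: spike feature
clouds are non-Gaussian and drift over time, firing-rate modulation is not
GLM-shaped, spike detection itself has misses and collisions, and counts
are over-dispersed relative to Poisson.  Passing tests therefore establish
the correctness of the inference and decoding machinery under the model's
own assumptions, not decoding performance on any real dataset.

## Numerical choices

- Responsibilities and mixture likelihoods via log-sum-exp; Gaussian
  densities via Cholesky factorization (failure names the component).
- Covariance floor 1e-4 (z-scored units); EM-equivalence tests disable it.
- θ block optimizer: L-BFGS-B, gtol 1e-9, update accepted only on
  improvement; closed form used when available (see above).
- Laplace variances by finite-difference curvature (step 1e-4), floored at
  machine-scale positivity.
- CSV I/O uses %.17g floats and round-trip parsing, so write→read→write is
  byte-idempotent; deterministic row order (trial, bin, insertion).
- Ties in k-fold splitting are resolved by a seeded permutation.

## Problem sizes

The test and example workloads use sessions of 20-40 trials × 30 bins,
2-5 components, and 5-20k spikes — sizes at which CAVI converges in a few
seconds and ADVI's 1000 iterations take a couple of seconds on one CPU.
All statistical checks (recovery within 3 standard errors, sign tests
across 10 seeds, binomial 3σ bands) are computed at these sizes.

## Known limitations

- The GLM rate function is linear in the design; neural-network rate
  models are out of scope.
- Components are independent; correlated firing across components is not
  modeled.
- The latent-variational continuous decoder uses a MAP/Laplace
  approximation rather than full posterior inference; it is a diagnostic
  path, not the default.
- The "good units" baseline emulates quality control by random unit
  subsetting, not by computing real contamination/miss metrics.
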