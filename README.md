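# density-decode

Spike-sorting-free neural decoding from high-density extracellular
recordings.  Instead of assigning each detected spike to a putative neuron
and decoding from sorted spike trains, `density-decode` models the
distribution of per-spike features — spike location along the probe width
and depth plus maximum peak-to-peak amplitude — with a mixture of Gaussians
whose mixing proportions are modulated by behavior, and decodes behavior
from the posterior soft assignments.  This keeps the uncertainty that spike
sorting discards and degrades gracefully when sorting would be unreliable
(drift, contamination, overlapping units).

It is aimed at systems neuroscientists and BCI researchers working with
Neuropixels-class probes who have spike features (from detection +
localization pipelines) and trial-structured behavior, and want decoding
that does not depend on sorting quality.

## Model

For K trials × T time bins with spike features s_itk ∈ R^D and behavior
y_k (binary per trial, or a length-T trace):

    λ_ctk = softplus(θ_cᵀ u_tk)          — per-component firing rate (GLM)
    π_ctk = λ_ctk / Σ_c' λ_c'tk          — behavior-driven mixing proportion
    z_itk ~ Categorical(π_tk)            — latent spike assignment
    s_itk ~ N(μ_c, Σ_c), c = z_itk       — Gaussian feature model

The encoder fits (μ_c, Σ_c) and a variational posterior over θ_c by
coordinate-ascent (CAVI) or stochastic-gradient (ADVI) variational
inference.  The decoder sums the posterior assignment probabilities into a
trials × components × bins weight matrix

    W_kct = Σ_i q(z_itk = c),      with   Σ_c W_kct = n_tk  exactly,

and feeds its flattened rows to a logistic- (binary) or ridge-regression
(continuous) behavior decoder.  Hard spike-to-unit assignments (sorted
units, thresholded channels) are the special case of one-hot W, so
baselines share the identical downstream pipeline.  See
[docs/methods.md](docs/methods.md) for the full treatment.

## Worked example

Simulate a session from the generative model, then run a 5-fold
cross-validated comparison of the density decoder against multi-unit
thresholding:

```python
import density_decode as dd

cfg = dd.SimulationConfig(K=24, T=30, C=4, D=2, behavior_kind="continuous",
                          separation=2.5, base_rate=2.0, seed=100)
session = dd.simulate_session(cfg)           # ~8.8k spikes, ground truth known
results = dd.run_experiment(session, dd.ExperimentConfig(
    C=4, n_channels=4, folds=5, seed=0,
    methods=("density", "thresholded")))
for name, r in results.items():
    print(f"{name}: {r.metric} = {r.mean:.3f} ± {r.std:.3f}")
```

prints

```
density: r2 = 0.820 ± 0.020
thresholded: r2 = 0.650 ± 0.055
```

The density decoder explains ~82% of the variance of the smooth behavior
trace on held-out trials; depth-binned multi-unit thresholding — which
collapses overlapping components into shared channels — explains ~65%.
The gap is the information retained by modeling assignment uncertainty
instead of hard-binning spikes.

The same pipeline is available from the shell:

```bash
density-decode simulate --out session/ --seed 4
density-decode fit --session session/ --C 2 --method cavi --seed 0 --out model/
density-decode decode --session session/ --C 2 --folds 5 --seed 0 --out results/
```

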