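# Methods

`bntpet` estimates transient competition effects — endogenous
neurotransmitter release or displacement by a cold drug — from a single
dynamic PET scan, using only regional time-activity curves (TACs): a target
region rich in the receptor of interest and a receptor-free reference
region. Two estimators of the same kinetic model are provided: a Bayesian
MCMC solver that samples the full joint posterior, and the classic
basis-function / weighted-least-squares solver used as the field's
reference method. A synthetic-data generator reproduces a simulated
[11C]raclopride bolus-infusion study at TAC level so the whole pipeline can
be validated without scanner data.

## The kinetic model

The steady-state part is the simplified reference tissue model (SRTM): the
target curve C_T is driven by the reference curve C_R through

    C_T(t) = R1·C_R(t) + k2·∫₀ᵗ C_R − k2a·∫₀ᵗ C_T ,

with R1 the relative delivery, k2 the reference efflux rate (1/min) and k2a
the target efflux rate (1/min). Competition is modelled as a transient
elevation of the target efflux, k2a(t) = k2a + γ·h(t), where

    h(t) = ((t−tD)/(tP−tD))^α · exp(α·(1 − (t−tD)/(tP−tD)))   for t > tD,
    h(t) = 0                                                  for t ≤ tD,

a gamma-variate normalized to 1 at its peak tP. Four parameters describe
the displacement: magnitude γ (1/min), onset tD (min), peak time tP (min)
and sharpness α. Internally the model is reparameterized with Δt = tP − tD
so the constraint tP > tD becomes a simple positivity bound. Adding the
transient term to the integral equation gives the operational model

    C_T(t) = R1·C_R + k2·∫C_R − k2a·∫C_T − γ·∫C_T·h ,

which the forward solver integrates in differential form,
dC_T/dt = R1·dC_R/dt + k2·C_R − (k2a + γ·h)·C_T with C_T(0) = R1·C_R(0)
(the initial condition forced by the integral equation at t = 0), using
Heun's method on a uniform fine grid (default 1 s). At this step size the
solution satisfies the integral equation to ≈1e-4 relative residual and is
grid-converged to well below 0.1%.

A derived summary, k2a%baseline(t) = 100·(k2a + γ·h(t))/k2a, expresses the
efflux time-course as percent of baseline.

## Likelihood and noise model

Frames are conditionally independent Gaussians around the model value at
the frame mid-time Θ(n), with variance

    ω²_n = ω² · Θ(n) / (t_n · d_n),

where d_n is the frame duration and t_n = exp(−ln2·t_mid/T_half) the
radioactive-decay factor (carbon-11 default T_half = 20.4 min; the factor
can be disabled). A single scale ω² thus describes the whole TAC, and it is
estimated jointly with the kinetic parameters. Model values are floored at
ε = 1e-6·max|y| inside the variance so degenerate proposals cannot produce
non-positive variances.

## Priors

Kinetic parameters get independent uniform box priors; the shipped presets
are deliberately wide (e.g. R1 ∈ [1,2], k2 ∈ [0,0.5], k2a ∈ [0,0.1],
γ ∈ [−0.5,0.5], tD ∈ [40,60] min, Δt ∈ [5,25] min, α ∈ [10,20] for the
simulated-study protocol) so the data dominate.

The noise scale gets a conjugate inverse-gamma prior IG(a0, b0). By default
a0 = 1.01 and b0 = 0.01·s², where s² is an empirical residual scale from a
quick SRTM fit of the TAC (mean weighted squared residual under the
frame-variance model). This centers the prior mean at s² while its variance
is infinite, and — important in practice — keeps b0 small enough that the
conjugate posterior rate b0 + WRSS/2 is data-dominated even when the
residuals are tiny. An earlier parameterization with a0 ≈ 2 floored the
posterior of ω² near s²/17 and visibly mis-calibrated noiseless fits.

The prior is additionally truncated at ω² ≤ 100·s² (configurable;
`omega2_cap_factor=None` disables). The joint posterior otherwise contains
a spurious metastable branch: a poor fit makes the conjugate update throw
ω² to enormous values, the huge ω² flattens the misfit term, and the chain
settles into an "all signal is noise" corner that single-parameter moves
cannot leave (observed in ~2% of randomly initialized chains, which then
stay stuck indefinitely). Because s² is computed from SRTM residuals that
still contain any unmodelled displacement, it overestimates the true noise,
so the cap is guaranteed loose for the target posterior mass.

## Sampler

A Metropolis-within-Gibbs scheme. Each sweep updates the seven kinetic
parameters one at a time (fixed order R1, k2, k2a, γ, tD, Δt, α) with
Gaussian random-walk Metropolis, then draws ω² exactly from its truncated
inverse-gamma conditional

    ω² | Y, Θ ~ IG(a0 + N/2, b0 + ½·Σ (y_n − Θ(n))²·t_n·d_n/Θ(n)) ,

the weighted squared-residual form required for conjugacy under the
frame-variance model above. Proposals outside the prior box (including
Δt ≤ 0) are rejected outright. Chains are initialized uniformly inside the
prior box and ω² at its prior center.

Per-parameter step sizes start at 5% of the prior width and are calibrated
during burn-in toward an acceptance rate of ½: every 50 sweeps, log ε_k
moves by (rate_k − ½)·gain with gain decaying as 1/√(adaptation count);
adaptation is frozen after burn-in so the retained chain is a valid Markov
chain. On study data the post-burn-in acceptance rates land in 0.43–0.55.
Defaults are 55,000 sweeps with 5,000 of burn-in (≈1 min per TAC on one
CPU); the posterior summaries are stable with far fewer draws.

## Inference

Point estimates come from three estimators on the retained draws:

* **HPD** (the default): per parameter, the shortest contiguous
  order-statistic window containing 10% of the draws is located on the
  marginal, and the samples inside are averaged. This tracks the dominant
  mode and is robust to skewed or multimodal marginals. Ties between
  equal-width windows resolve to the smallest lower bound. The 10% mass is
  exposed as a parameter.
* **MMSE**: column means.
* **MAP**: the single retained draw with the highest recorded joint
  log-posterior (likelihood plus the ω² prior; flat box terms drop out).

Convergence is monitored with the Gelman–Rubin potential scale reduction
factor computed from m ≥ 2 equal-length chains:
R̂ = sqrt(V̂/W) with W the mean within-chain variance, B/n the variance of
chain means, and V̂ = (n−1)/n·W + (1 + 1/m)·B/n. Identical chains give
R̂ = sqrt((n−1)/n) < 1.

Evaluation helpers compute the recovered release curve γ̂·h(t; t̂D, Δ̂t, α̂),
the mean squared error between release curves on a shared grid, and signed
per-parameter relative errors in percent (undefined for zero truth, e.g. γ
in a placebo condition, and then reported as absent).

## The basis-function reference solver

With (tD, tP, α) fixed, the operational equation is linear in
(R1, k2, k2a, γ), so the classic solver scans a discretized library —
default steps 30 s for tD and tP, 0.5 for α, bounds taken from the same
prior box — solving a weighted least-squares problem per basis and keeping
the smallest weighted residual sum of squares. Ties break toward the
smallest tD, then tP, then α. Default weights are w_n = t_n·d_n/max(y_n, ε)
(the inverse of the frame-variance model with the measurement standing in
for the model value); uniform weights and a non-negative-γ (bounded least
squares) variant are available. A plain 3-parameter SRTM fit serves to
establish baseline kinetics.

### Quadrature for the design matrix

The design regressors contain running integrals of the *measured* curves
evaluated at frame mid-times. Integrating straight trapezoids on the frame
grid is too coarse here: with 3-min frames, an early bolus peak and a
sub-frame transient, that convention biases the recovered rate constants by
2–3% and mis-selects the transient basis. The default quadrature therefore
integrates a shape-preserving PCHIP interpolant of the frame samples
(anchored at an implicit (0, 0) point) on a 3-s grid. A natural cubic
spline tracks the unobserved reference peak slightly better but rings at
the transient onset and destabilizes basis selection; the coarse trapezoid
is retained as an option (`quadrature="trapezoid"`). The same PCHIP
reconstruction (1-s grid) supplies the fine reference curve for the
Bayesian forward model, where it roughly halves the model-data mismatch
relative to linear interpolation.

## Synthetic-data generator

The generator reproduces a simulated 100-min bolus-infusion
[11C]raclopride protocol at TAC level:

* 33 frames of 3 min;
* plasma input: three exponentials with half-times (4.28, 735.5, 183.5) s
  and amplitudes (288.6, 1.1, 409.7) Bq/ml decaying from a peak at 110 s,
  with a linear ramp from zero before the peak (the post-peak model is
  standard; the ramp is this package's bolus-arrival convention and only
  affects the generator);
* reference region: one-tissue compartment model dC_ref/dt = K1ref·Cp −
  k2ref·C_ref with K1ref = 0.0918 mL/(min·g), k2ref = 0.242 /min, scaled by
  an amplitude calibration factor of 10 after solving (scaling input or
  output is equivalent here by linearity);
* target regions: the competition model with R1 = 1.1540, k2 = 0.242,
  k2a = 0.0653, tD = 42 min, tP = 51 min, α = 15 and five release
  magnitudes γ = 0, 0.035, 0.078, 0.1284, 0.3 /min (named placebo, DR05,
  DR10, DR15, DR25 after their displacement ratios);
* model curves are sampled at frame mid-times by default (a frame-average
  convention is available but off by default);
* noise: the per-frame Gaussian model above, seeded and reproducible.
  Two presets set ω² so the relative noise on the last (most decayed) frame
  of the noiseless placebo target is 5% ("caudate", a large region) or 15%
  ("accumbens", a small one). Cohorts share the noiseless truth per
  condition and differ only in the noise realization; by default both the
  target and the reference TAC of a subject receive noise.

What the generator does **not** emulate: scanner physics and image
reconstruction (attenuation, scatter, partial-volume effects), anatomical
variability, motion, or reconstruction-induced bias in the "noiseless"
curves. Ground truth here equals the generator input exactly, so recovery
tests validate the estimators against the model's own forward map — they
say nothing about reconstruction-induced bias in real images.

## Numerical choices and degenerate inputs

* All kinetics run in minutes; plasma-input constants are stored in seconds
  as printed and converted internally.
* ODE integration: Heun (explicit trapezoid) with 1-s default step; the
  reference derivative on the fine grid comes from central finite
  differences of the reconstructed curve.
* Vectorized basis search: the shared 3-column SRTM block is factored out
  and each basis solved through its Schur complement; the winning triple is
  re-solved explicitly for full precision. Bases whose transient lies
  beyond the scan (degenerate fourth column) fall back to γ = 0.
* Rank-deficient designs are flagged invalid rather than raising.
* Negative measured activities are permitted (real PET TACs dip below
  zero); weights and variances floor the activity at ε.
* Reproducibility: every stochastic component takes an explicit seed;
  identical seeds give bit-identical TACs, chains and output files.

## Known limitations

* At 3-min framing the unobserved inter-frame shape of the curves is the
  accuracy bottleneck: noiseless-recovery biases are ≈0.3% (R1), ≈0.6%
  (k2a) and ≈1.3% (k2), and the basis solver's placebo γ̂ is ≈−0.005 rather
  than 0. These are reconstruction artifacts of the TAC-level pipeline, not
  estimator defects; they shrink with shorter frames.
* The onset/width pair (tD, Δt) is strongly anticorrelated (their sum, the
  peak time, is what the data pin down), so the one-parameter-at-a-time
  sampler mixes slowly along that ridge. With low-noise data,
  multi-chain PSRF needs on the order of 10³ retained draws to fall below
  1.1; single-chain point estimates are nevertheless stable because the
  estimators average over the ridge.
* The MAP estimator inherits the sparsity of draws in 8 dimensions and is
  reported for completeness; HPD is the recommended point estimator.
* Multivariate HPD over the joint 8-D sample cloud is deliberately not
  implemented (univariate HPD per marginal only).
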