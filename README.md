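# bntpet

Bayesian estimation of single-scan PET competition models: detect and
characterize a transient displacement of a radiotracer — an endogenous
neurotransmitter surge or a competing cold drug — from one dynamic PET
acquisition, using only a target-region and a reference-region
time-activity curve (TAC).

The package is aimed at PET kinetic modellers. It implements

* **the competition model**: the simplified reference tissue model (SRTM;
  parameters R1, k2, k2a) extended with a time-varying efflux
  k2a(t) = k2a + γ·h(t), where h is a gamma-variate transient with onset
  tD, peak tP and sharpness α, normalized so h(tP) = 1;
* **a Bayesian solver** (`BayesianNtpet`): Metropolis-within-Gibbs sampling
  of the joint posterior p(R1, k2, k2a, γ, tD, Δt, α, ω² | Y) with uniform
  box priors, a conjugate (truncated) inverse-gamma prior on the noise
  scale ω², per-frame variances ω²·Θ(n)/(t_n·d_n), burn-in step-size
  calibration, and HPD / MMSE / MAP estimators with credible intervals;
* **the classic solver** (`LinearNtpet`, `Srtm`): a discretized
  gamma-variate basis library resolved by weighted least squares, the
  field's reference method;
* **a synthetic-study generator** (`bntpet.simulate`): a simulated
  [11C]raclopride bolus-infusion protocol — three-exponential plasma
  input, one-tissue reference region, 33×3-min frames, five release
  magnitudes γ ∈ {0, 0.035, 0.078, 0.1284, 0.3}/min, and the
  frame-dependent Gaussian noise model — so everything can be validated
  end-to-end without scanner data.

The model/estimator background and all numerical conventions are described
in [docs/methods.md](docs/methods.md).

## Worked example

Generate the noiseless strongest-release condition (DR25, γ = 0.3/min) and
fit it with both solvers:

```python
import numpy as np
from bntpet import BayesianNtpet, LinearNtpet, default_study, generate_noiseless

study = default_study()
target, reference = generate_noiseless(study.condition("DR25"), study)

lp = LinearNtpet(target, reference).fit()        # basis-function / WLS
print("lp basis (tD, tP, alpha):", lp.fit_result.basis)
print("lp gamma:", round(lp.fit_result.gamma, 4))

bayes = BayesianNtpet(target, reference).fit(
    n_samples=55_000, n_burnin=5_000, seed=1)
print(bayes.summary().to_string(index=False))
```

Output:

```
lp basis (tD, tP, alpha): (42.0, 51.0, 15.0)
lp gamma: 0.2908
parameter  estimate   hpd_low  hpd_high estimator  post_mean  post_sd
       R1  1.146228  1.145441  1.147012       HPD   1.146286 0.006567
       k2  0.246197  0.246011  0.246389       HPD   0.246324 0.001549
      k2a  0.066064  0.066006  0.066123       HPD   0.066144 0.000491
    gamma  0.298367  0.295236  0.301434       HPD   0.301724 0.025555
      t_D 41.960096 41.810068 42.112783       HPD  42.007117 1.041062
  delta_t  9.118312  8.958213  9.283061       HPD   9.058117 1.131984
    alpha 18.635650 18.213908 19.053309       HPD  15.368567 2.816938
   omega2  0.063282  0.061140  0.065382       HPD   0.072088 0.020199
```

The basis search identifies the generating transient exactly — onset 42
min, peak 51 min, sharpness 15 — and the Bayesian highest-posterior-density
estimate recovers the release magnitude (γ̂ = 0.298 vs. the true 0.3/min,
with a credible interval) and the onset and peak times to a fraction of a
minute. The sharpness α is only weakly identified — its marginal is broad,
as expected for this model — and ω² here reflects the small residual
reconstruction mismatch of a noiseless TAC rather than counting noise.
`bayes.release_curve(t)` returns the recovered release time-course γ̂·h(t),
and `bntpet.k2a_baseline_curve(bayes.params, t)` the efflux as percent of
baseline.

## Command line

A thin CLI wraps the same pipeline:

```sh
bntpet simulate --preset raclopride_sim --subjects 3 --noise caudate --seed 7 --out cohort/
bntpet fit-lp    --tac cohort/sub000_DR25.tsv --preset raclopride_sim --out fit_lp.tsv
bntpet fit-bayes --tac cohort/sub000_DR25.tsv --preset raclopride_sim --seed 1 --out fit_bayes
bntpet diagnose  chain1_samples.tsv chain2_samples.tsv
```

TAC tables are delimited text (`frame_start`, `frame_end` in minutes plus
one activity column per region); presets ship the prior boxes and basis
grids of the three protocols the package targets (`raclopride_sim`,
`mppf_cat`, `raclopride_tdcs`).

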