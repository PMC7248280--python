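"""Synthetic study generator: noiseless ground-truth TACs for the five
dopamine-release conditions of a 100-min bolus-infusion [11C]raclopride
protocol, plus frame-dependent Gaussian noise and cohort realizations.

The study configuration mirrors a published simulation design: 33 frames of
3 min; a three-exponential plasma input feeding a one-tissue reference
region; target regions generated from the competition model with shared
kinetics (R1=1.1540, k2=0.242, k2a=0.0653, tD=42 min, tP=51 min, alpha=15)
and five release magnitudes gamma = 0, 0.035, 0.078, 0.1284, 0.3 /min
(labelled placebo, DR05, DR10, DR15, DR25 after their displacement ratios).

Noise follows the per-frame variance model var_n = omega2 * C(n) / (t_n d_n)
with t_n the radioactive-decay factor at the frame mid-time and d_n the frame
duration, so late (decayed) frames are noisier — the standard PET weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    FrameSchedule,
    ModelParams,
    PlasmaInputParams,
    ReferenceModelParams,
    TimeActivityCurve,
    sample_on_schedule,
    simulate_reference_fine,
    simulate_target_fine,
)

__all__ = [
    "ConditionSpec",
    "NoiseSpec",
    "StudyConfig",
    "CohortEntry",
    "default_study",
    "generate_noiseless",
    "decay_factors",
    "add_noise",
    "noise_preset",
    "generate_cohort",
]

C11_HALF_LIFE_MIN = 20.4


@dataclass(frozen=True)
class ConditionSpec:
    """A release condition: a name and its release magnitude gamma [1/min].
    All conditions of a study share the non-gamma kinetic parameters."""

    name: str
    gamma: float

    def params(self, base: ModelParams) -> ModelParams:
        return base.replace(gamma=self.gamma)


@dataclass(frozen=True)
class NoiseSpec:
    """Frame-dependent Gaussian noise: overall scale omega2
    [activity^2 · min], isotope half-life [min] for the decay factor
    (None disables decay weighting, t_n = 1), and a seed."""

    omega2: float
    decay_half_life: float | None = C11_HALF_LIFE_MIN
    seed: int | None = None

    def __post_init__(self):
        if self.omega2 < 0:
            raise ValueError("omega2 must be non-negative")
        if self.decay_half_life is not None and self.decay_half_life <= 0:
            raise ValueError("decay_half_life must be positive")


@dataclass(frozen=True)
class StudyConfig:
    schedule: FrameSchedule
    plasma: PlasmaInputParams
    reference: ReferenceModelParams
    base_params: ModelParams
    conditions: tuple

    def condition(self, name: str) -> ConditionSpec:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(f"unknown condition {name!r}")


def default_study() -> StudyConfig:
    """The default simulated raclopride study configuration."""
    schedule = FrameSchedule.uniform(33, 3.0)
    plasma = PlasmaInputParams(amplitudes=(288.6, 1.1, 409.7),
                               half_times=(4.28, 735.5, 183.5), t_peak=110.0)
    reference = ReferenceModelParams(k1_ref=0.0918, k2_ref=0.242,
                                     calibration=10.0)
    base = ModelParams(r1=1.1540, k2=0.242, k2a=0.0653, gamma=0.0,
                       t_d=42.0, delta_t=9.0, alpha=15.0)
    conditions = (
        ConditionSpec("placebo", 0.0),
        ConditionSpec("DR05", 0.035),
        ConditionSpec("DR10", 0.078),
        ConditionSpec("DR15", 0.1284),
        ConditionSpec("DR25", 0.3),
    )
    return StudyConfig(schedule, plasma, reference, base, conditions)


def generate_noiseless(condition: ConditionSpec, study: StudyConfig,
                       fine_dt: float = 1.0, convention: str = "mid"):
    """Deterministic noiseless (target, reference) TAC pair for a condition."""
    t_fine, cr_fine = simulate_reference_fine(
        study.plasma, study.reference, study.schedule.end[-1], fine_dt)
    params = condition.params(study.base_params)
    ct_fine = simulate_target_fine(t_fine, cr_fine, params)
    target = TimeActivityCurve(
        study.schedule,
        sample_on_schedule(t_fine, ct_fine, study.schedule, convention),
        label=condition.name)
    reference = TimeActivityCurve(
        study.schedule,
        sample_on_schedule(t_fine, cr_fine, study.schedule, convention),
        label="reference")
    return target, reference


def decay_factors(schedule: FrameSchedule,
                  half_life: float | None) -> np.ndarray:
    """Decay factor t_n = exp(-ln2 * t_mid / half_life), or 1 if disabled."""
    if half_life is None:
        return np.ones(schedule.n_frames)
    return np.exp(-np.log(2.0) / half_life * schedule.mid)


def add_noise(tac: TimeActivityCurve, noise: NoiseSpec,
              rng: np.random.Generator | None = None) -> TimeActivityCurve:
    """Add independent Gaussian noise with per-frame variance
    omega2 * max(C(n), eps) / (t_n * d_n)."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if noise.omega2 == 0:
        return tac
    tn = decay_factors(tac.schedule, noise.decay_half_life)
    floor = 1e-6 * max(np.max(np.abs(tac.activity)), 1e-30)
    var = noise.omega2 * np.maximum(tac.activity, floor) / (tn * tac.schedule.duration)
    return tac.with_activity(tac.activity + rng.standard_normal(tac.activity.size)
                             * np.sqrt(var))


def noise_preset(name: str, study: StudyConfig | None = None,
                 seed: int | None = None) -> NoiseSpec:
    """Noise presets for large ("caudate") and small ("accumbens") regions.

    omega2 is set so the relative noise on the last (most decayed) frame of
    the noiseless placebo target is ~5% for caudate-like and ~15% for
    accumbens-like regions.
    """
    frac = {"caudate": 0.05, "accumbens": 0.15}.get(name)
    if frac is None:
        raise ValueError(f"unknown noise preset {name!r}")
    if study is None:
        study = default_study()
    target, _ = generate_noiseless(study.condition("placebo"), study)
    tn = decay_factors(study.schedule, C11_HALF_LIFE_MIN)
    theta_last = target.activity[-1]
    omega2 = (frac ** 2) * theta_last * tn[-1] * study.schedule.duration[-1]
    return NoiseSpec(omega2=float(omega2), decay_half_life=C11_HALF_LIFE_MIN,
                     seed=seed)


@dataclass(frozen=True)
class CohortEntry:
    subject: int
    condition: str
    target: TimeActivityCurve
    reference: TimeActivityCurve
    truth: ModelParams
    seed: int


def generate_cohort(n_subjects: int, conditions, noise: NoiseSpec,
                    study: StudyConfig | None = None,
                    noisy_reference: bool = True) -> list:
    """Noisy cohort realizations: every subject shares the same noiseless
    truth per condition and differs only in the noise draw."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if study is None:
        study = default_study()
    ss = np.random.SeedSequence(noise.seed)
    entries = []
    noiseless = {c.name: generate_noiseless(c, study) for c in conditions}
    children = ss.spawn(n_subjects * len(conditions))
    i = 0
    for subject in range(n_subjects):
        for cond in conditions:
            child = children[i]
            i += 1
            rng = np.random.default_rng(child)
            target, reference = noiseless[cond.name]
            noisy_t = add_noise(target, noise, rng)
            noisy_r = add_noise(reference, noise, rng) if noisy_reference else reference
            entries.append(CohortEntry(
                subject=subject, condition=cond.name,
                target=noisy_t, reference=noisy_r,
                truth=cond.params(study.base_params),
                seed=int(child.generate_state(1)[0] % (2 ** 31))))
    return entries
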