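"""Modelling objects: a Model is built from a target and a reference TAC,
``fit()`` returns a Results object carrying estimates, uncertainties and a
``summary()`` table.

Three models are exposed:

* :class:`BayesianNtpet` — the MCMC estimator of the full competition model
  (jointly with the noise scale omega2);
* :class:`LinearNtpet`  — the classic basis-function / WLS solver;
* :class:`Srtm`         — the steady-state three-parameter reference model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bayes, inference, lp_ntpet
from .bayes import McmcConfig, PosteriorSamples, PriorSpec
from .kinetics import ModelParams, TimeActivityCurve, model_tac
from .lp_ntpet import BasisGrid, LinearFit
from .simulate import C11_HALF_LIFE_MIN

__all__ = ["BayesianNtpet", "BayesianNtpetResults",
           "LinearNtpet", "Srtm", "LinearNtpetResults"]


def _tacs_from_frame(data: pd.DataFrame, target: str, reference: str):
    from .io import TacTable
    tt = TacTable(data)
    return tt.tac(target), tt.tac(reference)


class BayesianNtpet:
    """Bayesian competition-model estimator for a single target TAC.

    Parameters
    ----------
    target, reference : TimeActivityCurve
        Measured target- and reference-region TACs on a shared schedule.
    priors : PriorSpec, optional
        Uniform box priors; defaults to the simulated-raclopride preset.
    decay_half_life : float or None
        Isotope half-life [min] for the frame-variance decay factor
        (default 20.4, carbon-11); None disables decay weighting.
    fine_dt : float
        Integration step [s] for the forward model (default 1 s).
    """

    def __init__(self, target: TimeActivityCurve, reference: TimeActivityCurve,
                 priors: PriorSpec | None = None,
                 decay_half_life: float | None = C11_HALF_LIFE_MIN,
                 fine_dt: float = 1.0):
        self.target = target
        self.reference = reference
        self.priors = priors if priors is not None else PriorSpec.default()
        self.decay_half_life = decay_half_life
        self.fine_dt = fine_dt

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, target: str = "target",
                       reference: str = "reference", **kw) -> "BayesianNtpet":
        y, cr = _tacs_from_frame(data, target, reference)
        return cls(y, cr, **kw)

    def fit(self, n_samples: int = 55_000, n_burnin: int = 5_000,
            seed: int | None = None, **config_kw) -> "BayesianNtpetResults":
        config = McmcConfig(n_samples=n_samples, n_burnin=n_burnin, seed=seed,
                            fine_dt=self.fine_dt,
                            decay_half_life=self.decay_half_life, **config_kw)
        samples = bayes.run_sampler(self.target, self.reference,
                                    self.priors, config)
        return BayesianNtpetResults(self, samples)


class BayesianNtpetResults:
    """Posterior draws plus the inference layer over them."""

    def __init__(self, model: BayesianNtpet, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    def estimate(self, method: str = "hpd", mass: float = 0.10) -> inference.Estimate:
        method = method.lower()
        if method == "hpd":
            return inference.estimate_hpd(self.samples, mass)
        if method == "mmse":
            return inference.estimate_mmse(self.samples)
        if method == "map":
            return inference.estimate_map(self.samples)
        raise ValueError(f"unknown estimator {method!r}")

    @property
    def params(self) -> ModelParams:
        return self.estimate("hpd").params

    def fitted_curve(self) -> TimeActivityCurve:
        return model_tac(self.params, self.model.reference,
                         self.model.fine_dt)

    def release_curve(self, t=None) -> np.ndarray:
        if t is None:
            t = self.model.target.schedule.mid
        return inference.release_curve(self.estimate("hpd"), t)

    def summary(self, mass: float = 0.10) -> pd.DataFrame:
        est = self.estimate("hpd", mass)
        df = est.to_frame()
        df["post_mean"] = self.samples.samples.mean(axis=0)
        df["post_sd"] = self.samples.samples.std(axis=0, ddof=1)
        df.attrs["n_draws"] = self.samples.n_draws
        df.attrs["acceptance"] = self.samples.acceptance
        return df

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        sched = self.model.target.schedule
        ax.plot(sched.mid, self.model.target.activity, "k.", label="measured")
        ax.plot(sched.mid, self.fitted_curve().activity, "-", label="model fit")
        ax.plot(sched.mid, self.model.reference.activity, ":", label="reference")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity")
        ax.legend()
        return ax

    def plot_posterior(self, axes=None):
        import matplotlib.pyplot as plt
        if axes is None:
            _, axes = plt.subplots(2, 4, figsize=(12, 5))
        for ax, name in zip(np.ravel(axes), self.samples.names):
            ax.hist(self.samples.column(name), bins=60, density=True)
            ax.set_title(name)
        return axes


class LinearNtpet:
    """Classic basis-function solver: exhaustive library search with WLS."""

    def __init__(self, target: TimeActivityCurve, reference: TimeActivityCurve,
                 grid: BasisGrid | None = None,
                 weights: np.ndarray | str = "frame",
                 decay_half_life: float | None = C11_HALF_LIFE_MIN):
        self.target = target
        self.reference = reference
        self.grid = grid if grid is not None else BasisGrid()
        if isinstance(weights, str):
            if weights == "frame":
                weights = lp_ntpet.default_weights(target, decay_half_life)
            elif weights == "uniform":
                weights = np.ones(target.schedule.n_frames)
            else:
                raise ValueError(f"unknown weighting scheme {weights!r}")
        self.weights = np.asarray(weights, dtype=float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, target: str = "target",
                       reference: str = "reference", **kw) -> "LinearNtpet":
        y, cr = _tacs_from_frame(data, target, reference)
        return cls(y, cr, **kw)

    def fit(self, nonneg_gamma: bool = False) -> "LinearNtpetResults":
        fit = lp_ntpet.fit_lp_ntpet(self.reference, self.target, self.grid,
                                    self.weights, nonneg_gamma=nonneg_gamma)
        return LinearNtpetResults(self, fit)


class Srtm(LinearNtpet):
    """Plain SRTM (no transient term); used to set baseline kinetics."""

    def __init__(self, target, reference, weights="frame",
                 decay_half_life: float | None = C11_HALF_LIFE_MIN):
        super().__init__(target, reference, grid=BasisGrid(),
                         weights=weights, decay_half_life=decay_half_life)

    def fit(self) -> "LinearNtpetResults":
        fit = lp_ntpet.fit_srtm(self.reference, self.target, self.weights)
        return LinearNtpetResults(self, fit)


class LinearNtpetResults:
    def __init__(self, model: LinearNtpet, fit: LinearFit):
        self.model = model
        self.fit_result = fit

    @property
    def params(self) -> ModelParams:
        f = self.fit_result
        if f.basis is None:
            # SRTM: no transient; report gamma=0 with placeholder shape
            return ModelParams(f.r1, f.k2, f.k2a, 0.0,
                               t_d=self.model.target.schedule.end[-1],
                               delta_t=1.0, alpha=0.0)
        t_d, t_p, alpha = f.basis
        return ModelParams(f.r1, f.k2, f.k2a, f.gamma,
                           t_d=t_d, delta_t=t_p - t_d, alpha=alpha)

    def fitted_curve(self) -> TimeActivityCurve:
        design = lp_ntpet.design_matrix(self.model.reference, self.model.target,
                                        self.fit_result.basis)
        k = design.shape[1]
        return self.model.target.with_activity(design @ self.fit_result.coef[:k],
                                               label="lp fit")

    def release_curve(self, t=None) -> np.ndarray:
        if t is None:
            t = self.model.target.schedule.mid
        if self.fit_result.basis is None:
            return np.zeros(np.asarray(t, dtype=float).shape)
        return inference.release_curve(self.params, t)

    def summary(self) -> pd.DataFrame:
        f = self.fit_result
        rows = {"R1": f.r1, "k2": f.k2, "k2a": f.k2a, "gamma": f.gamma}
        if f.basis is not None:
            rows.update({"t_D": f.basis[0], "t_P": f.basis[1],
                         "alpha": f.basis[2]})
        df = pd.DataFrame({"parameter": list(rows), "estimate": list(rows.values())})
        df.attrs["wrss"] = f.wrss
        df.attrs["valid"] = f.valid
        return df
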