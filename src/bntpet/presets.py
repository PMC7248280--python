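"""Shipped study presets: prior intervals and basis-grid steps for the three
protocols the package targets (simulated raclopride bolus-infusion, the MPPF
cat challenge protocol, and the human raclopride tDCS protocol).

All three share R1~U(1,2), k2~U(0,0.5), k2a~U(0,0.1), gamma~U(-0.5,0.5) and
delta_t~U(5,25); they differ in the onset-time window and the sharpness
range.  Basis grids use 30-s steps for tD and tP and 0.5 for alpha.
"""

from __future__ import annotations

from .bayes import PriorSpec
from .lp_ntpet import BasisGrid

__all__ = ["PRESETS", "preset_priors", "preset_grid"]

_SHARED = dict(r1=(1.0, 2.0), k2=(0.0, 0.5), k2a=(0.0, 0.1),
               gamma=(-0.5, 0.5), delta_t=(5.0, 25.0))

PRESETS = {
    "raclopride_sim": dict(_SHARED, t_d=(40.0, 60.0), alpha=(10.0, 20.0)),
    "mppf_cat": dict(_SHARED, t_d=(45.0, 70.0), alpha=(0.0, 20.0)),
    "raclopride_tdcs": dict(_SHARED, t_d=(35.0, 90.0), alpha=(0.0, 20.0)),
}


def preset_priors(name: str) -> PriorSpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PriorSpec.from_bounds(**PRESETS[name])


def preset_grid(name: str, step_t: float = 0.5,
                step_alpha: float = 0.5) -> BasisGrid:
    """Basis grid replicating a preset's prior box at the standard steps.

    alpha grids with a zero lower bound start at ``step_alpha`` (an alpha of
    exactly 0 makes the transient a step function whose onset tP is
    meaningless as a basis label)."""
    p = PRESETS.get(name)
    if p is None:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    alpha_min = p["alpha"][0] if p["alpha"][0] > 0 else step_alpha
    return BasisGrid(t_d_min=p["t_d"][0], t_d_max=p["t_d"][1],
                     delta_min=p["delta_t"][0], delta_max=p["delta_t"][1],
                     alpha_min=alpha_min, alpha_max=p["alpha"][1],
                     step_t=step_t, step_alpha=step_alpha)
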