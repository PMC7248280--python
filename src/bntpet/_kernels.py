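"""Numba-compiled inner loops for the kinetic forward models.

The target-region ODE has to be solved once per Metropolis proposal, so the
integrator lives here as a tight jitted loop.  Both kernels use Heun's method
(explicit trapezoidal rule) on a uniform fine grid; with the default 1-s step
and rate constants below ~0.4 min^-1 the scheme is far inside its stability
region and accurate to well under 0.1%.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gamma_variate_scalar(t, t_d, t_p, alpha):
    """Gamma-variate response h(t), normalized to 1 at its peak t_p.

    h(t) = ((t-tD)/(tP-tD))^alpha * exp(alpha*(1 - (t-tD)/(tP-tD))) for t > tD,
    and 0 for t <= tD.
    """
    if t <= t_d:
        return 0.0
    x = (t - t_d) / (t_p - t_d)
    return x ** alpha * np.exp(alpha * (1.0 - x))


@njit(cache=True)
def solve_one_tissue(t, cp, k1, k2):
    """One-tissue compartment: dC/dt = K1*Cp(t) - k2*C, C(0)=0, Heun scheme."""
    n = t.size
    c = np.empty(n)
    c[0] = 0.0
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        f0 = k1 * cp[i] - k2 * c[i]
        cpred = c[i] + dt * f0
        f1 = k1 * cp[i + 1] - k2 * cpred
        c[i + 1] = c[i] + 0.5 * dt * (f0 + f1)
    return c


@njit(cache=True)
def solve_target(t, cr, dcr, r1, k2, k2a, gamma, t_d, t_p, alpha):
    """Target-region competition model in differential form.

    dCT/dt = R1*dCR/dt + k2*CR - (k2a + gamma*h(t))*CT,  CT(0) = R1*CR(0).
    """
    n = t.size
    ct = np.empty(n)
    ct[0] = r1 * cr[0]
    h1 = gamma_variate_scalar(t[0], t_d, t_p, alpha)
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        h0 = h1
        h1 = gamma_variate_scalar(t[i + 1], t_d, t_p, alpha)
        f0 = r1 * dcr[i] + k2 * cr[i] - (k2a + gamma * h0) * ct[i]
        cpred = ct[i] + dt * f0
        f1 = r1 * dcr[i + 1] + k2 * cr[i + 1] - (k2a + gamma * h1) * cpred
        ct[i + 1] = ct[i] + 0.5 * dt * (f0 + f1)
    return ct
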