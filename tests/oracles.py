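"""Independent numerical oracles used by the tests.

These deliberately avoid the package's eigendecomposition solver: the
master equation is integrated by a brute-force fixed-step RK4 scheme so
that agreement between the two routes is a genuine cross-check.
"""

import numpy as np


def rk4_master(k_off, k_on, n_R, n_L, t_end, dt=1e-4):
    """Fixed-step RK4 integration of the full master equation.

    Returns the state distribution P_m(t_end) for m = 0..min(n_R, n_L),
    starting from all mass at maximum bond formation.
    """
    M = min(n_R, n_L)
    m = np.arange(M + 1)
    r = m * k_off
    g = np.where(m >= 1, (n_R - m) * (n_L - m) * k_on, 0.0)  # g(0) = 0

    def deriv(P):
        d = -(r + g) * P
        d[:-1] += r[1:] * P[1:]
        d[1:] += g[:-1] * P[:-1]
        return d

    P = np.zeros(M + 1)
    P[M] = 1.0
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = deriv(P)
        k2 = deriv(P + dt / 2 * k1)
        k3 = deriv(P + dt / 2 * k2)
        k4 = deriv(P + dt * k3)
        P = P + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return P


def rk4_survival(k_off, k_on, n_R, n_L, t_end, dt=1e-4):
    """Survival probability S(t_end) = 1 - P_0(t_end) from the RK4 oracle."""
    return 1.0 - rk4_master(k_off, k_on, n_R, n_L, t_end, dt)[0]
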