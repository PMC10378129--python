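"""Shared test helpers: independent oracles kept deliberately separate from
the library code paths they check."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp


def heun_ivp_oracle(params, z_target: float, rtol: float = 1e-11) -> float:
    """Integrate the Heun ODE as an initial-value problem along the real axis.

    Starts a small step away from the regular singular point at z = 0 using
    the hand-expanded Taylor seed y = 1 + C1 z + C2 z^2 (C1 and C2 follow
    from the first two recurrence rows, which are themselves hand-derivable
    from the ODE), then integrates with an adaptive RK method.  Completely
    independent of the package's series machinery.
    """
    from recspec.heun import GeneralHeunParameters

    general = isinstance(params, GeneralHeunParameters)
    if general:
        a, q = params.a, params.q
        al, be, ga, de, ep = (params.alpha, params.beta, params.gamma,
                              params.delta, params.epsilon)
        C1 = q / (a * ga)
        Q1 = ga * (1 + a) + a * de + ep
        C2 = ((Q1 + q) * C1 - al * be) / (2 * a * (1 + ga))

        def rhs(z, y):
            f, fp = y
            fpp = -((ga / z + de / (z - 1) + ep / (z - a)) * fp
                    + (al * be * z - q) / (z * (z - 1) * (z - a)) * f)
            return [fp, fpp]
    else:
        q, al, ga, de, ep = (params.q, params.alpha, params.gamma,
                             params.delta, params.epsilon)
        C1 = q / ga
        Q1 = ga + de - ep
        C2 = ((Q1 + q) * C1 - al) / (2 * (1 + ga))

        def rhs(z, y):
            f, fp = y
            fpp = -((ep + ga / z + de / (z - 1)) * fp
                    - (al * z - q) / (z * (z - 1)) * f)
            return [fp, fpp]

    z0 = 1e-4 * abs(z_target)
    sgn = 1.0 if z_target > 0 else -1.0
    z0 *= sgn
    y0 = [1 + C1 * z0 + C2 * z0**2, C1 + 2 * C2 * z0]
    sol = solve_ivp(rhs, (z0, z_target), y0, rtol=rtol, atol=1e-14, method="DOP853")
    assert sol.success
    return sol.y[0, -1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def constant_recurrence(mode="exact"):
    """The Qt=2, R=1, P=1 family with C_i = i + 1 (hand-derived)."""
    from recspec import ThreeTermRecurrence

    return ThreeTermRecurrence(P=lambda j: 1, Qt=lambda j: 2, R=lambda j: 1, mode=mode)
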