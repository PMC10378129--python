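"""Frobenius series of the general and confluent Heun equations.

The general Heun equation

    y'' + (gamma/z + delta/(z-1) + epsilon/(z-a)) y'
        + (alpha*beta*z - q) / (z(z-1)(z-a)) y = 0

has regular singularities at 0, 1, a, infinity; the exponent parameters obey
the Fuchs relation alpha + beta + 1 = gamma + delta + epsilon.  The analytic
(Frobenius index 0) solution at z = 0 with y(0) = 1 has power-series
coefficients satisfying the three-term recurrence

    R_j C_{j+1} - (Q_j + q) C_j + P_j C_{j-1} = 0,
    P_j = (j-1+alpha)(j-1+beta),
    Q_j = j[(j-1+gamma)(1+a) + a*delta + epsilon],
    R_j = a (j+1)(j+gamma),

so gamma must avoid the non-positive integers.  The accessory parameter q
enters every middle coefficient additively, and the closed form for C_i is
the orthogonal-polynomial expression evaluated at x = q.

The confluent equation is obtained by merging the singularities at a and
infinity: a -> oo with epsilon/a -> -eps', q/a -> q', alpha*beta/a -> alpha',
which (dropping primes) yields

    z(z-1) y'' + [eps z(z-1) + gamma (z-1) + delta z] y' - (alpha z - q) y = 0

with recurrence coefficients

    P_j = (1-j) eps + alpha,
    Q_j = j (j-1+gamma+delta-eps),
    R_j = (j+1)(j+gamma),

hence C_1 = q/gamma.  (Published coefficient lists for the confluent case
differ in signs between sources; the family above is fixed uniquely by the
requirement that the truncated series annihilates the ODE, which the
ode_residual oracle checks term by term, and by consistency with the a -> oo
limit of the general family.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .exceptions import ConvergenceDomainError
from .recurrence import ThreeTermRecurrence, closed_form_C, forward_substitution

__all__ = [
    "GeneralHeunParameters",
    "ConfluentHeunParameters",
    "HeunSeries",
    "general_heun_recurrence",
    "confluent_heun_recurrence",
    "heun_series",
    "heun_eval",
    "ode_residual",
    "convergence_radius",
]

_FUCHS_TOL = 1e-10


def _is_nonpositive_int(x, tol=1e-12) -> bool:
    xr = complex(x)
    return abs(xr.imag) < tol and xr.real <= tol and abs(xr.real - round(xr.real)) < tol


@dataclass
class GeneralHeunParameters:
    """Parameters (a, q; alpha, beta, gamma, delta, epsilon) of the general
    Heun equation.  ``epsilon`` may be omitted, in which case it is closed
    from the Fuchs relation epsilon = alpha + beta + 1 - gamma - delta."""

    a: object
    q: object
    alpha: object
    beta: object
    gamma: object
    delta: object
    epsilon: object = None

    def __post_init__(self):
        if self.epsilon is None:
            self.epsilon = self.alpha + self.beta + 1 - self.gamma - self.delta
        if self.a == 0:
            raise ValueError("a = 0 degenerates the singularity structure")
        fuchs = self.alpha + self.beta + 1 - self.gamma - self.delta - self.epsilon
        if abs(complex(fuchs)) > _FUCHS_TOL:
            raise ValueError(f"Fuchs relation violated by {complex(fuchs):.3e}")
        if _is_nonpositive_int(self.gamma):
            raise ValueError("gamma is a non-positive integer: the index-0 "
                             "Frobenius solution at z=0 does not exist")


@dataclass
class ConfluentHeunParameters:
    """Parameters (q; alpha, gamma, delta, epsilon) of the confluent Heun
    equation in the a->oo limit normalization of this package."""

    q: object
    alpha: object
    gamma: object
    delta: object
    epsilon: object

    def __post_init__(self):
        if _is_nonpositive_int(self.gamma):
            raise ValueError("gamma is a non-positive integer: the index-0 "
                             "Frobenius solution at z=0 does not exist")


@dataclass
class HeunSeries:
    """Truncated Frobenius series: coefficients [C_0..C_n] with C_0 = 1."""

    params: object
    coefficients: list
    n: int

    def __call__(self, z):
        return _horner(self.coefficients, z)


def _horner(coeffs, z):
    acc = 0 * z
    for c in reversed(coeffs):
        acc = acc * z + c
    return acc


def general_heun_recurrence(params: GeneralHeunParameters,
                            mode: str = "float64") -> ThreeTermRecurrence:
    """Recurrence family of the general Heun series, accessory = q."""
    a, al, be, ga, de, ep = (params.a, params.alpha, params.beta,
                             params.gamma, params.delta, params.epsilon)
    return ThreeTermRecurrence(
        P=lambda j: (j - 1 + al) * (j - 1 + be),
        Qt=lambda j: j * ((j - 1 + ga) * (1 + a) + a * de + ep),
        R=lambda j: a * (j + 1) * (j + ga),
        mode=mode,
        accessory=params.q,
    )


def confluent_heun_recurrence(params: ConfluentHeunParameters,
                              mode: str = "float64") -> ThreeTermRecurrence:
    """Recurrence family of the confluent Heun series, accessory = q."""
    al, ga, de, ep = params.alpha, params.gamma, params.delta, params.epsilon
    return ThreeTermRecurrence(
        P=lambda j: (1 - j) * ep + al,
        Qt=lambda j: j * (j - 1 + ga + de - ep),
        R=lambda j: (j + 1) * (j + ga),
        mode=mode,
        accessory=params.q,
    )


def _recurrence_for(params, mode):
    if isinstance(params, GeneralHeunParameters):
        return general_heun_recurrence(params, mode)
    if isinstance(params, ConfluentHeunParameters):
        return confluent_heun_recurrence(params, mode)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def heun_series(params, n: int, mode: str = "float64",
                method: str = "closed_form") -> HeunSeries:
    """First n+1 Frobenius coefficients of the Heun function at z = 0.

    ``method='closed_form'`` uses the orthogonal-polynomial expression for
    every C_i (each evaluated at the accessory parameter x = q);
    ``method='forward'`` iterates the recurrence instead.  The two agree
    exactly in exact-rational mode and to rounding otherwise.
    """
    if n < 0:
        raise ValueError(f"truncation order must be >= 0, got {n}")
    rec = _recurrence_for(params, mode)
    if method == "forward":
        coeffs = forward_substitution(rec, n)
    elif method == "closed_form":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            coeffs = [closed_form_C(rec, i) for i in range(n + 1)]
    else:
        raise ValueError(f"unknown method {method!r}")
    return HeunSeries(params=params, coefficients=coeffs, n=n)


def convergence_radius(params) -> float:
    """Radius of the disc about z = 0 where the Frobenius series converges:
    the distance to the nearest other finite singularity."""
    if isinstance(params, GeneralHeunParameters):
        return min(1.0, abs(complex(params.a)))
    return 1.0


def _is_polynomial(coeffs, tol=1e-13) -> bool:
    """Detect series truncation to a polynomial: a trailing run of (near-)zero
    coefficients relative to the largest one."""
    scale = max(abs(complex(c)) for c in coeffs) or 1.0
    tail = [abs(complex(c)) / scale for c in coeffs[-2:]]
    return len(coeffs) >= 3 and all(t < tol for t in tail)


def heun_eval(params, z, tol: float = 1e-12, n_max: int = 500):
    """Evaluate the Heun function by partial sums inside its disc.

    Returns ``(value, info)`` where info carries the number of terms used and
    an estimated truncation bound (the last neglected term magnitude).
    Outside the disc a non-polynomial series raises ConvergenceDomainError;
    if two consecutive tail terms never fall below ``tol`` a non-convergence
    warning is attached to the diagnostics and the partial value returned.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    r = convergence_radius(params)
    zc = complex(z)
    rec = _recurrence_for(params, "float64")
    if zc == 0:
        return 1.0, {"terms": 1, "bound": 0.0, "converged": True}
    coeffs = forward_substitution(rec, min(n_max, 40))
    inside = abs(zc) < r
    if not inside and not _is_polynomial(coeffs):
        raise ConvergenceDomainError(
            f"|z| = {abs(zc):.4g} >= radius {r:.4g} and the series does not truncate"
        )
    acc = 0.0 + 0.0j
    zpow = 1.0 + 0.0j
    prev_term = math.inf
    converged = False
    used = 0
    j = 0
    while j <= n_max:
        if j >= len(coeffs):
            coeffs = forward_substitution(rec, min(n_max, 2 * len(coeffs)))
        term = coeffs[j] * zpow
        acc += term
        used = j + 1
        if abs(term) < tol and prev_term < tol and j >= 2:
            converged = True
            break
        prev_term = abs(term)
        zpow *= zc
        j += 1
    bound = abs(term) / max(1e-300, 1 - abs(zc) / r) if inside else abs(term)
    info = {"terms": used, "bound": bound, "converged": converged}
    if not converged:
        import warnings

        warnings.warn(f"series did not converge to tol={tol} within {n_max} terms",
                      RuntimeWarning, stacklevel=2)
    if not isinstance(z, complex) and abs(acc.imag) < 1e-14 * max(1.0, abs(acc.real)):
        return acc.real, info
    return acc, info


def ode_residual(series: HeunSeries, z_points) -> float:
    """Maximum absolute ODE residual of the truncated series over z_points.

    Evaluates y, y', y'' term by term and substitutes into the defining
    equation (cleared of denominators).  For a convergent series the residual
    decays to zero with the truncation order, uniformly on compact subsets of
    the disc, so this is a parameter-free correctness oracle for the
    recurrence coefficients themselves.
    """
    p = series.params
    r = convergence_radius(p)
    c = [complex(v) for v in series.coefficients]
    d1 = [k * c[k] for k in range(1, len(c))]
    d2 = [k * (k - 1) * c[k] for k in range(2, len(c))]
    worst = 0.0
    for z in np.atleast_1d(np.asarray(z_points, dtype=complex)):
        z = complex(z)
        if abs(z) >= r and not _is_polynomial(c):
            raise ConvergenceDomainError(f"residual point |z|={abs(z):.4g} outside disc r={r:.4g}")
        y = _horner(c, z)
        yp = _horner(d1, z)
        ypp = _horner(d2, z)
        if isinstance(p, GeneralHeunParameters):
            a, al, be, ga, de, ep, q = (complex(p.a), complex(p.alpha), complex(p.beta),
                                        complex(p.gamma), complex(p.delta),
                                        complex(p.epsilon), complex(p.q))
            res = (z * (z - 1) * (z - a) * ypp
                   + (ga * (z - 1) * (z - a) + de * z * (z - a) + ep * z * (z - 1)) * yp
                   + (al * be * z - q) * y)
        else:
            al, ga, de, ep, q = (complex(p.alpha), complex(p.gamma), complex(p.delta),
                                 complex(p.epsilon), complex(p.q))
            res = (z * (z - 1) * ypp
                   + (ep * z * (z - 1) + ga * (z - 1) + de * z) * yp
                   - (al * z - q) * y)
        worst = max(worst, abs(res))
    return worst


def heun_params_to_json(params) -> str:
    import json

    def enc(v):
        if isinstance(v, Fraction):
            return str(v)
        if isinstance(v, complex):
            return [v.real, v.imag]
        return v

    if isinstance(params, GeneralHeunParameters):
        doc = {"kind": "general", "a": enc(params.a), "q": enc(params.q)}
    else:
        doc = {"kind": "confluent", "q": enc(params.q)}
    for name in ("alpha", "beta", "gamma", "delta", "epsilon"):
        if hasattr(params, name):
            doc[name] = enc(getattr(params, name))
    return json.dumps(doc, sort_keys=True)


def heun_params_from_json(text: str):
    import json

    doc = json.loads(text)

    def dec(v):
        if isinstance(v, list):
            return complex(v[0], v[1])
        if isinstance(v, str):
            return Fraction(v)
        return v

    kind = doc.pop("kind")
    vals = {k: dec(v) for k, v in doc.items()}
    if kind == "general":
        return GeneralHeunParameters(**vals)
    return ConfluentHeunParameters(**vals)


def series_to_tsv(series: HeunSeries) -> str:
    lines = ["j\tre_C\tim_C"]
    for j, cj in enumerate(series.coefficients):
        z = complex(cj)
        lines.append(f"{j}\t{z.real!r}\t{z.imag!r}")
    return "\n".join(lines) + "\n"
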