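"""Eigendecomposition of one-step CTMC generators via the quantization
polynomial of the spectral three-term recurrence.

For a model whose eigenvector series coefficients satisfy
R_j C_{j+1} - (Q_j + q) C_j + P_j C_{j-1} = 0 with q an affine function of
the relaxation rate lam, the physical (finite-chain) eigenvalues are exactly
the rates at which the series truncates, C_{N+1} = 0.  The closed form for
C_{N+1} turns this condition into a degree-(N+1) polynomial in q,

    (Q_0 + q) phi_N^N(q) - R_0 P_1 phi_{N-1}^N(q) = 0,

built symbolically in q through the monic orthogonal-polynomial recursion.
Roots are found with high-precision companion-free polynomial root finding
(mpmath) on exactly (rationally) assembled coefficients, then mapped back to
decay rates.  Everything is cross-checkable against dense linear algebra
(symmetrized tridiagonal eigensolver, matrix exponential), which this module
also provides as oracles.

Conventions: decay rates lam >= 0 with time dependence e^{-lam t};
lam_0 = 0 is the stationary mode and 1/lam_1 the dominant relaxation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import mpmath as mp
import numpy as np
import scipy.linalg as sla

from .exceptions import NotAnEigenvalueError
from .models import (
    BinaryChoiceModel,
    BirthDeathGenerator,
    VacillatingVoterModel,
    binary_choice_generator,
    binary_choice_heun_map,
    binary_choice_recurrence,
    stationary_distribution,
    vacillating_generator,
    vacillating_rate_of_q,
    vacillating_recurrence,
)
from .recurrence import ThreeTermRecurrence, phi_coefficients

__all__ = [
    "SpectralDecomposition",
    "quantization_polynomial",
    "eigen_spectrum",
    "dense_spectrum_oracle",
    "eigenvectors_from_series",
    "evolve",
    "matrix_exponential_oracle",
    "relaxation_report",
]

# zero-mode snap tolerance relative to the spectral radius: conservation is
# exact in the assembled generator, so the smallest root is a true zero.
ZERO_SNAP_REL = 1e-10


@dataclass
class SpectralDecomposition:
    """Decay rates (ascending, lam_0 = 0), eigenvectors as columns, optional
    projection weights for an initial condition, and relaxation times."""

    rates: np.ndarray
    eigenvectors: np.ndarray | None = None
    weights: np.ndarray | None = None

    @property
    def relaxation_times(self) -> np.ndarray:
        return 1.0 / self.rates[1:]

    @property
    def stationary(self) -> np.ndarray:
        if self.eigenvectors is None:
            raise ValueError("eigenvectors were not computed")
        v = self.eigenvectors[:, 0]
        return v / v.sum()


def quantization_polynomial(rec: ThreeTermRecurrence, N: int) -> list:
    """Ascending coefficients (in q) of the truncation polynomial
    (Q_0+q) phi_N^N(q) - R_0 P_1 phi_{N-1}^N(q); monic of degree N+1.

    ``rec`` holds the q-free middle coefficients Q_j; any accessory shift on
    the recurrence is ignored (q is the polynomial variable).  Arithmetic
    follows rec.mode — use exact mode for reliable roots at larger N.
    """
    if N < 1:
        raise ValueError(f"need N >= 1, got {N}")
    base = rec.with_accessory(0)
    polys = phi_coefficients(base, N)
    phiN, phiNm1 = polys[N], polys[N - 1]
    zero = base.convert(0)
    q0 = base.coeff_Qt(0)
    out = [zero] * (N + 2)
    for k, c in enumerate(phiN):  # (q + Q_0) * phi_N^N
        out[k + 1] += c
        out[k] += q0 * c
    corr = base.coeff_R(0) * base.coeff_P(1)
    for k, c in enumerate(phiNm1):
        out[k] -= corr * c
    return out


def _poly_roots_mp(coeffs, dps: int = 60):
    """High-precision roots of an ascending-coefficient polynomial."""
    with mp.workdps(dps):
        cs = []
        for c in coeffs:
            if isinstance(c, Fraction):
                cs.append(mp.mpf(c.numerator) / c.denominator)
            else:
                cs.append(mp.mpmathify(c))
        roots = mp.polyroots(cs, maxsteps=200, extraprec=4 * dps, asc=True)
        return [complex(r) for r in roots]


def eigen_spectrum(model, precision_dps: int = 60,
                   with_eigenvectors: bool = False) -> SpectralDecomposition:
    """Relaxation spectrum of a model via its quantization polynomial.

    The polynomial is assembled in exact rational arithmetic from the model's
    spectral recurrence, its roots found at ``precision_dps`` decimal digits,
    and mapped to decay rates through the model's q(lam) map.  The smallest
    rate is snapped to exactly zero (stationarity of the CTMC).  Rates are
    returned sorted ascending.
    """
    if isinstance(model, BinaryChoiceModel):
        N = model.N
        rec = binary_choice_recurrence(model, exact=True)
        hm = binary_choice_heun_map(model, exact=True)
        to_rate = lambda q: hm.rate_of_q(q)
    elif isinstance(model, VacillatingVoterModel):
        N = model.N
        rec = vacillating_recurrence(model, exact=True)
        to_rate = lambda q: vacillating_rate_of_q(model, q, exact=True)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")

    pol = quantization_polynomial(rec, N)
    roots = _poly_roots_mp(pol, dps=precision_dps)
    rates = np.array(sorted(float(complex(to_rate(Fraction(r.real))).real) for r in roots))
    imag_leak = max(abs(r.imag) for r in roots)
    if imag_leak > 1e-8 * max(1.0, max(abs(r) for r in roots)):
        warnings.warn(f"complex leakage {imag_leak:.2e} in quantization roots",
                      RuntimeWarning, stacklevel=2)
    gaps = np.diff(np.sort([r.real for r in roots]))
    if len(gaps) and gaps.min() < 1e-9 * max(1.0, abs(rates).max()):
        warnings.warn("near-degenerate quantization roots: projection should "
                      "fall back to the dense path", RuntimeWarning, stacklevel=2)
    if abs(rates[0]) < ZERO_SNAP_REL * max(1.0, abs(rates).max()):
        rates[0] = 0.0
    dec = SpectralDecomposition(rates=rates)
    if with_eigenvectors:
        vecs = np.column_stack([eigenvectors_from_series(model, lam) for lam in rates])
        dec.eigenvectors = vecs
    return dec


def dense_spectrum_oracle(g: BirthDeathGenerator) -> np.ndarray:
    """Decay rates of the dense generator via a symmetrizing similarity.

    Detailed balance makes D A D^-1 symmetric with off-diagonal
    -sqrt(b_n d_{n+1}); the symmetric tridiagonal eigensolver then returns
    the decay rates directly.  A vanishing interior rate breaks the
    symmetrization and triggers a general eigensolver fallback (warned).
    """
    inter = g.birth[:-1] * g.death[1:]
    if (inter <= 0).any():
        warnings.warn("zero interior rate: falling back to general eigensolver",
                      RuntimeWarning, stacklevel=2)
        return np.sort(-np.linalg.eigvals(g.matrix()).real)
    diag = g.birth + g.death
    off = -np.sqrt(inter)
    return np.sort(sla.eigh_tridiagonal(diag, off, eigvals_only=True))


def _series_coefficients_mp(model, lam, n_terms: int, dps: int = 50):
    """Forward-substituted series coefficients at rate lam, in mp arithmetic,
    already mapped to the probability basis."""
    with mp.workdps(dps):
        lam = mp.mpmathify(lam)
        if isinstance(model, BinaryChoiceModel):
            rec = binary_choice_recurrence(model).with_mode("mp")
            hm = binary_choice_heun_map(model)
            q = (lam - model.N * mp.mpf(model.eps1)) / mp.mpf(model.mu1)
            scale = lambda n: 1
        else:
            rec = vacillating_recurrence(model).with_mode("mp")
            q = (model.N - 1) * (mp.mpf(model.pd) * model.N - lam)
            scale = lambda n: mp.mpf(model.N - 1) ** n
        rec = rec.with_accessory(q)
        from .recurrence import forward_substitution

        C = forward_substitution(rec, n_terms)
        return [c * scale(n) for n, c in enumerate(C)]


def eigenvectors_from_series(model, lam, tol: float = 1e-8,
                             dps: int = 50) -> np.ndarray:
    """Eigenvector C(n), n = 0..N, from the model's eigen-series at rate lam.

    The first N+1 series coefficients of the eigen-generating-function are
    the eigenvector components in the probability basis (after the model's
    variable scaling).  The truncation residual C_{N+1} must vanish; if it
    does not (relative to the largest coefficient), lam is not an eigenvalue.
    The zero mode is normalized to total mass 1, decaying modes to unit
    maximum amplitude (their total mass is zero by conservation).
    """
    N = model.N
    C = _series_coefficients_mp(model, lam, N + 1, dps=dps)
    mags = [abs(c) for c in C[: N + 1]]
    tail = abs(C[N + 1]) / max(mags)
    if tail > tol:
        raise NotAnEigenvalueError(lam, float(tail))
    v = np.array([float(c) for c in C[: N + 1]])
    if abs(lam) <= ZERO_SNAP_REL:
        return v / v.sum()
    return v / np.abs(v).max()


def _symmetrized_decomposition(g: BirthDeathGenerator):
    """Stable eigen-decomposition A = Dinv (U Lam U^T) D of a reversible
    birth-death generator; returns decay rates ascending and the transforms."""
    pi = stationary_distribution(g)
    d = 1.0 / np.sqrt(pi)
    inter = g.birth[:-1] * g.death[1:]
    rates, U = sla.eigh_tridiagonal(g.birth + g.death, -np.sqrt(inter))
    return rates, U, d


def evolve(model_or_generator, P0, times, cond_max: float = 1e12) -> np.ndarray:
    """Solve dP/dt = A P by spectral decomposition: rows = states, columns =
    the requested times.  P0 must be a probability vector.

    Uses the symmetrized (orthogonal) eigenbasis, which is the numerically
    stable realization of P(n,t) = sum_i w_i C_i(n) e^{-lam_i t}.  If the
    stationary-measure conditioning exceeds ``cond_max`` (or the chain is
    reducible) it falls back to the dense matrix exponential with a warning.
    """
    g = _as_generator(model_or_generator)
    P0 = np.asarray(P0, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if P0.shape != (g.N + 1,):
        raise ValueError("P0 has wrong length")
    if (P0 < -1e-12).any() or abs(P0.sum() - 1.0) > 1e-10:
        raise ValueError("P0 must be a probability vector")
    try:
        rates, U, d = _symmetrized_decomposition(g)
        cond = d.max() / d.min()
    except Exception:
        cond = np.inf
    if not np.isfinite(cond) or cond**2 > cond_max:
        warnings.warn("ill-conditioned spectral basis: dense expm fallback",
                      RuntimeWarning, stacklevel=2)
        A = g.matrix()
        return np.column_stack([sla.expm(A * t) @ P0 for t in times])
    rates = np.where(np.abs(rates) < ZERO_SNAP_REL * max(1.0, np.abs(rates).max()),
                     0.0, rates)
    y0 = U.T @ (d * P0)
    out = (U @ (np.exp(-np.outer(rates, times)) * y0[:, None])) / d[:, None]
    return out


def matrix_exponential_oracle(g: BirthDeathGenerator, P0, t: float) -> np.ndarray:
    """Reference solution expm(A t) @ P0 with no spectral shortcuts."""
    P0 = np.asarray(P0, dtype=float)
    return sla.expm(g.matrix() * float(t)) @ P0


def _as_generator(model_or_generator) -> BirthDeathGenerator:
    if isinstance(model_or_generator, BirthDeathGenerator):
        return model_or_generator
    if isinstance(model_or_generator, BinaryChoiceModel):
        return binary_choice_generator(model_or_generator)
    if isinstance(model_or_generator, VacillatingVoterModel):
        return vacillating_generator(model_or_generator)
    raise TypeError(f"unsupported model type {type(model_or_generator).__name__}")


def relaxation_report(dec: SpectralDecomposition) -> list[dict]:
    """Table of decaying modes: index, rate, relaxation time; the slowest
    nonzero rate carries the dominant timescale flag."""
    rows = []
    for i, lam in enumerate(dec.rates):
        if i == 0:
            continue
        rows.append({
            "mode": i,
            "rate": float(lam),
            "relaxation_time": float(1.0 / lam) if lam > 0 else float("inf"),
            "dominant": i == 1,
        })
    return rows


def relaxation_report_tsv(dec: SpectralDecomposition) -> str:
    lines = ["mode\trate\trelaxation_time\tdominant"]
    for row in relaxation_report(dec):
        lines.append(f"{row['mode']}\t{row['rate']!r}\t{row['relaxation_time']!r}"
                     f"\t{int(row['dominant'])}")
    return "\n".join(lines) + "\n"
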