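"""Finite continued-fraction (Risken-style) solution of the spectral
three-term recurrence, and its equivalence to the rational form built from
the orthogonal-polynomial family.

With the separation ansatz C_j(t) = Ct_j e^{-lam t} the recurrence becomes

    R_j Ct_{j+1} - (Qt_j - lam) Ct_j + P_j Ct_{j-1} = 0,

and the ratios S_j = Ct_{j+1}/Ct_j satisfy the backward ladder

    S_j = -P_{j+1} / ( (lam - Qt_{j+1}) + R_{j+1} S_{j+1} ),

seeded by the truncation S_N = 0 (so S_{N-1} = -P_N / (lam - Qt_N)).  The
ladder unrolls into a finite continued fraction, and the coefficients are
recovered as products of the S_j.

The module also checks the identity between the finite continued fraction

    1 / (Q_1+q - R_1 P_2 / (Q_2+q - ... R_{N-1} P_N / (Q_N+q)))

and the rational function phi_{N-1}^N(q) / phi_N^N(q); both express the same
minor quotient of the truncated tridiagonal matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import PoleError
from .recurrence import ThreeTermRecurrence, phi_family

__all__ = [
    "ContinuedFractionLadder",
    "backward_ladder",
    "coefficients_from_ladder",
    "rational_identity_gap",
    "ladder_to_tsv",
]


@dataclass
class ContinuedFractionLadder:
    """Ratios S_j = Ct_{j+1}/Ct_j for j = 0..N at spectral parameter lam."""

    N: int
    lam: object
    S: list

    def __getitem__(self, j: int):
        return self.S[j]


def backward_ladder(rec: ThreeTermRecurrence, lam, N: int) -> ContinuedFractionLadder:
    """Compute the ladder S_N..S_0 by the backward recursion.

    A vanishing denominator means lam sits on a resonance of the truncated
    ladder; the error carries the offending index.  An intermediate S_j = 0
    for j < N-1 is legal here but will pole the *next* step down, which is
    reported rather than resolved (degenerate eigenvector structure).
    """
    if N < 1:
        raise ValueError(f"truncation index N must be >= 1, got {N}")
    lam = rec.convert(lam)
    S = [rec.convert(0)] * (N + 1)  # S_N = 0
    for j in range(N - 1, -1, -1):
        denom = lam - rec.coeff_Qt(j + 1)
        if S[j + 1] != 0:  # seed rung: R_N multiplies S_N = 0, never evaluated
            denom = denom + rec.coeff_R(j + 1) * S[j + 1]
        if denom == 0:
            raise PoleError(j)
        S[j] = -rec.coeff_P(j + 1) / denom
    return ContinuedFractionLadder(N=N, lam=lam, S=S)


def coefficients_from_ladder(ladder: ContinuedFractionLadder, C0=1) -> list:
    """Recover [Ct_0, ..., Ct_{N+1}] as running products of the S_j.

    Ct_j = C0 * prod_{i<j} S_i; the last entry is 0 by construction since
    S_N = 0 (the truncation condition Ct_{N+1} = 0).
    """
    out = [C0]
    for j in range(ladder.N + 1):
        out.append(out[-1] * ladder.S[j])
    return out


def rational_identity_gap(rec: ThreeTermRecurrence, q, N: int):
    """|continued fraction - phi_{N-1}^N(q)/phi_N^N(q)| for the Q-family.

    ``rec`` holds the q-free middle coefficients Q_j (its accessory shift is
    ignored here; q is supplied explicitly).  The gap is zero up to rounding
    wherever both sides are defined; a pole of either side raises.
    """
    if N < 2:
        raise ValueError(f"identity needs N >= 2, got {N}")
    base = rec.with_accessory(0)
    q = base.convert(q)
    # finite continued fraction, innermost rung first
    acc = base.coeff_Qt(N) + q
    for j in range(N - 1, 0, -1):
        if acc == 0:
            raise PoleError(j + 1, "continued-fraction rung")
        acc = (base.coeff_Qt(j) + q) - base.coeff_R(j) * base.coeff_P(j + 1) / acc
    if acc == 0:
        raise PoleError(0, "continued-fraction rung")
    lhs = 1 / acc
    fam = phi_family(base, N, q)
    if fam[N] == 0:
        raise PoleError(N, "phi_N^N(q)")
    rhs = fam[N - 1] / fam[N]
    return abs(lhs - rhs)


def ladder_to_tsv(ladder: ContinuedFractionLadder) -> str:
    lines = ["j\tS_j"]
    for j, s in enumerate(ladder.S):
        lines.append(f"{j}\t{s}")
    return "\n".join(lines) + "\n"
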