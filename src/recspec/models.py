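"""One-step (birth-death) continuous-time Markov models of binary choice.

Two concrete models are provided.

**Asymmetric binary choice (recruitment) model.**  N agents each hold one of
two opinions; with n agents deciding "right", transitions n -> n+1 fire at
rate b(n) = (N-n) eps1 + mu1 n (N-n) (spontaneous switching plus pairwise
recruitment) and n -> n-1 at d(n) = n eps2 + mu2 n (N-n).  The generating
function of the eigenvector at relaxation rate lam is a general Heun
function; the parameter map (derived from the generating-function PDE) is

    a = mu2/mu1, alpha = -N, beta = eps1/mu1,
    gamma = -(N-1) - eps2/mu2, delta = 0,
    epsilon = eps1/mu1 + eps2/mu2   (Fuchs),
    q(lam) = (lam - N eps1)/mu1.

Physical eigenfunctions are degree-N polynomials in z; demanding truncation
C_{N+1} = 0 quantizes q and hence lam.

**Vacillating voter model.**  Each agent wakes at unit rate; with
probability p_d it flips spontaneously; otherwise it consults peers and
flips at the per-agent rates (for the n-increasing direction)

    b(n)/(N-n) - p_d = (1-p_d) (n/(N-1)) (1 + (N-n)/(N-1)),

and symmetrically for d(n).  The eigenvector generating function (in the
scaled variable z with C_n = P(n)/(N-1)^n) satisfies a third-order ODE whose
series coefficients nevertheless obey a three-term recurrence,

    q(lam) = (N-1)(p_d N - lam),
    R_j = (j+1) [ (N-1)(N-p_d) - (1-p_d) j (j+1) ],
    Q_j = (1-p_d)(3N-2) j (N-j) / (N-1),
    P_j = (N+1-j) [ (j-1)(2N-j) + p_d ((N-j)^2 - j + 1) ] / (N-1)^2,

with Qt_j = Q_j + q(lam).  The j = 0 row reproduces the explicit boundary
condition (N-1)((N-1) p_d + N (1-p_d)) C_1 = q(lam) C_0 without any special
casing; the constructor nevertheless installs it as an explicit boundary
override so the boundary row is visible in the recurrence object.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable

import numpy as np

from .exceptions import ReducibleChainError
from .heun import GeneralHeunParameters
from .recurrence import ThreeTermRecurrence

__all__ = [
    "BinaryChoiceModel",
    "VacillatingVoterModel",
    "BirthDeathGenerator",
    "BinaryChoiceHeunMap",
    "binary_choice_generator",
    "binary_choice_heun_map",
    "binary_choice_recurrence",
    "vacillating_generator",
    "vacillating_recurrence",
    "vacillating_q_of_rate",
    "vacillating_rate_of_q",
    "chain_spectral_recurrence",
    "stationary_distribution",
    "gillespie_simulate",
    "vacillating_rule_simulate",
    "model_from_dict",
    "model_to_dict",
]


@dataclass(frozen=True)
class BinaryChoiceModel:
    """Fully asymmetric recruitment model: N agents, random switching rates
    eps1 (left->right) and eps2 (right->left), recruitment rates mu1, mu2."""

    N: int
    eps1: float
    eps2: float
    mu1: float
    mu2: float

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("need N >= 2 agents")
        if min(self.eps1, self.eps2, self.mu1, self.mu2) <= 0:
            raise ValueError("all rates must be positive (the Heun map divides by mu1, mu2)")


@dataclass(frozen=True)
class VacillatingVoterModel:
    """Vacillating voter model: N agents, spontaneous flip probability p_d."""

    N: int
    pd: float

    def __post_init__(self):
        if self.N < 3:
            raise ValueError("need N >= 3 agents")
        if not 0 < self.pd < 1:
            raise ValueError("p_d must lie strictly between 0 and 1")


@dataclass(frozen=True)
class BirthDeathGenerator:
    """Tridiagonal CTMC generator on states n = 0..N.

    ``birth[n]`` is the n -> n+1 rate (birth[N] = 0), ``death[n]`` the
    n -> n-1 rate (death[0] = 0).  The diagonal -(birth+death) is formed from
    the same floats as the off-diagonal entries, so column sums vanish to one
    ulp of the total outflow rate (probability conservation).
    """

    N: int
    birth: np.ndarray
    death: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.birth, dtype=float)
        d = np.asarray(self.death, dtype=float)
        object.__setattr__(self, "birth", b)
        object.__setattr__(self, "death", d)
        if b.shape != (self.N + 1,) or d.shape != (self.N + 1,):
            raise ValueError("birth and death must have length N+1")
        if b[self.N] != 0 or d[0] != 0:
            raise ValueError("boundary rates must vanish: birth[N] = death[0] = 0")
        if (b < 0).any() or (d < 0).any():
            raise ValueError("rates must be non-negative")

    def matrix(self) -> np.ndarray:
        A = np.zeros((self.N + 1, self.N + 1))
        idx = np.arange(self.N + 1)
        A[idx, idx] = -(self.birth + self.death)
        A[idx[1:], idx[:-1]] = self.birth[:-1]
        A[idx[:-1], idx[1:]] = self.death[1:]
        return A

    def to_tsv(self) -> str:
        lines = ["n\tbirth\tdeath"]
        for n in range(self.N + 1):
            lines.append(f"{n}\t{float(self.birth[n])!r}\t{float(self.death[n])!r}")
        return "\n".join(lines) + "\n"


def binary_choice_generator(m: BinaryChoiceModel) -> BirthDeathGenerator:
    n = np.arange(m.N + 1, dtype=float)
    b = (m.N - n) * m.eps1 + m.mu1 * n * (m.N - n)
    d = n * m.eps2 + m.mu2 * n * (m.N - n)
    return BirthDeathGenerator(N=m.N, birth=b, death=d)


@dataclass(frozen=True)
class BinaryChoiceHeunMap:
    """Heun parameters of the binary-choice eigenfunctions, with the
    accessory parameter as an affine function of the relaxation rate."""

    a: object
    alpha: object
    beta: object
    gamma: object
    delta: object
    epsilon: object
    q_of_rate: Callable[[object], object]
    rate_of_q: Callable[[object], object]

    def heun_parameters(self, lam) -> GeneralHeunParameters:
        return GeneralHeunParameters(a=self.a, q=self.q_of_rate(lam),
                                     alpha=self.alpha, beta=self.beta,
                                     gamma=self.gamma, delta=self.delta,
                                     epsilon=self.epsilon)


def binary_choice_heun_map(m: BinaryChoiceModel, exact: bool = False) -> BinaryChoiceHeunMap:
    """The general-Heun parameter map of the recruitment model.

    The eigenfunction at relaxation rate lam is H(a, q(lam); alpha, beta,
    gamma, 0; z) with q(lam) = (lam - N eps1)/mu1.  Note delta = 0 always;
    alpha = -N is a non-positive integer, which is what permits degree-N
    polynomial eigenfunctions at quantized q.
    """
    conv = (lambda x: Fraction(x)) if exact else (lambda x: float(x))
    N = m.N
    e1, e2, mu1, mu2 = map(conv, (m.eps1, m.eps2, m.mu1, m.mu2))
    a = mu2 / mu1
    alpha = conv(-N)
    beta = e1 / mu1
    gamma = -(N - 1) - e2 / mu2
    delta = conv(0)
    epsilon = alpha + beta + 1 - gamma - delta
    return BinaryChoiceHeunMap(
        a=a, alpha=alpha, beta=beta, gamma=gamma, delta=delta, epsilon=epsilon,
        q_of_rate=lambda lam: (conv(lam) - N * e1) / mu1,
        rate_of_q=lambda q: N * e1 + mu1 * q,
    )


def binary_choice_recurrence(m: BinaryChoiceModel, exact: bool = False) -> ThreeTermRecurrence:
    """Spectral recurrence of the binary-choice model: the general-Heun
    family with the model's parameter map, accessory left at 0 (set it to
    q(lam) with ``with_accessory`` to study a specific rate)."""
    hm = binary_choice_heun_map(m, exact=exact)
    a, al, be, ga, de, ep = hm.a, hm.alpha, hm.beta, hm.gamma, hm.delta, hm.epsilon
    return ThreeTermRecurrence(
        P=lambda j: (j - 1 + al) * (j - 1 + be),
        Qt=lambda j: j * ((j - 1 + ga) * (1 + a) + a * de + ep),
        R=lambda j: a * (j + 1) * (j + ga),
        mode="exact" if exact else "float64",
    )


def vacillating_generator(m: VacillatingVoterModel) -> BirthDeathGenerator:
    N, pd = m.N, m.pd
    n = np.arange(N + 1, dtype=float)
    b = pd * (N - n) + (1 - pd) * (N - n) * (n / (N - 1)) * (1 + (N - n) / (N - 1))
    d = pd * n + (1 - pd) * (N - n) * (n / (N - 1)) * (1 + n / (N - 1))
    b[N] = 0.0
    d[0] = 0.0
    return BirthDeathGenerator(N=N, birth=b, death=d)


def vacillating_recurrence(m: VacillatingVoterModel, exact: bool = False) -> ThreeTermRecurrence:
    """Spectral recurrence of the vacillating voter model (see module
    docstring).  The middle coefficients are the q-free Q_j; use
    ``with_accessory(q)`` with q = (N-1)(p_d N - lam) for a specific rate.

    Returns the family with the explicit j = 0 boundary row
    R_0 = (N-1)((N-1) p_d + N(1-p_d)) installed as an override (it agrees
    with the generic row; the override keeps the boundary condition visible).
    """
    N = m.N
    pd = Fraction(m.pd) if exact else m.pd
    one = Fraction(1) if exact else 1.0

    def R(j):
        return (j + 1) * ((N - 1) * (N - pd) - (one - pd) * j * (j + 1))

    def Q(j):
        return (one - pd) * (3 * N - 2) * j * (N - j) / (N - 1)

    def P(j):
        return (N + 1 - j) * ((j - 1) * (2 * N - j) + pd * ((N - j) ** 2 - j + 1)) / (N - 1) ** 2

    r0 = (N - 1) * ((N - 1) * pd + N * (one - pd))
    return ThreeTermRecurrence(
        P=P, Qt=Q, R=R,
        boundary_overrides={0: (None, 0, r0)},
        mode="exact" if exact else "float64",
    )


def vacillating_q_of_rate(m: VacillatingVoterModel, lam, exact: bool = False):
    pd = Fraction(m.pd) if exact else m.pd
    return (m.N - 1) * (pd * m.N - lam)


def vacillating_rate_of_q(m: VacillatingVoterModel, q, exact: bool = False):
    pd = Fraction(m.pd) if exact else m.pd
    return pd * m.N - q / (m.N - 1)


def chain_spectral_recurrence(g: BirthDeathGenerator, exact: bool = False) -> ThreeTermRecurrence:
    """Spectral recurrence of an arbitrary birth-death chain in the
    probability basis: R_j = d(j+1), Q_j = b(j)+d(j), P_j = b(j-1), with the
    accessory q = -lam (so Qt_j = b(j)+d(j) - lam).  Its truncation
    polynomial is the characteristic polynomial of the generator.

    The state space ends at N, so d(N+1) does not exist; row N only uses R_N
    as the (nonzero) divisor defining the truncation residual C_{N+1}, and we
    set R_N = 1 by convention — the condition C_{N+1} = 0 is unaffected."""
    conv = (lambda x: Fraction(x)) if exact else (lambda x: float(x))
    b = [conv(x) for x in g.birth]
    d = [conv(x) for x in g.death]
    one = conv(1)

    def guard(seq, j, name):
        if not 0 <= j <= g.N:
            from .exceptions import CoefficientRangeError

            raise CoefficientRangeError(name, j, g.N + 1)
        return seq[j]

    zero = conv(0)
    return ThreeTermRecurrence(
        P=lambda j: zero if j == 0 else guard(b, j - 1, "birth"),  # b(-1) = 0
        Qt=lambda j: guard(b, j, "birth") + guard(d, j, "death"),
        R=lambda j: one if j == g.N else guard(d, j + 1, "death"),
        mode="exact" if exact else "float64",
    )


def stationary_distribution(g: BirthDeathGenerator) -> np.ndarray:
    """Detailed-balance stationary law pi(n) ~ prod_{k<n} b(k)/d(k+1)."""
    for n in range(g.N):
        if g.birth[n] <= 0:
            raise ReducibleChainError(n)
        if g.death[n + 1] <= 0:
            raise ReducibleChainError(n + 1)
    logw = np.concatenate([[0.0], np.cumsum(np.log(g.birth[:-1]) - np.log(g.death[1:]))])
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def gillespie_simulate(g: BirthDeathGenerator, n0: int, t_end: float,
                       n_traj: int, seed: int) -> np.ndarray:
    """Exact stochastic simulation: states of n_traj trajectories at t_end.

    Vectorized over trajectories; each step draws an exponential waiting time
    with the current total propensity and moves up or down accordingly.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if not 0 <= n0 <= g.N:
        raise ValueError("initial state outside 0..N")
    rng = np.random.default_rng(seed)
    state = np.full(n_traj, n0, dtype=np.int64)
    t = np.zeros(n_traj)
    active = np.ones(n_traj, dtype=bool)
    while active.any():
        idx = np.nonzero(active)[0]
        s = state[idx]
        btot = g.birth[s]
        dtot = g.death[s]
        tot = btot + dtot
        frozen = tot <= 0
        if frozen.any():
            active[idx[frozen]] = False
            keep = ~frozen
            idx, s, btot, dtot, tot = idx[keep], s[keep], btot[keep], dtot[keep], tot[keep]
            if idx.size == 0:
                continue
        dt = rng.exponential(1.0 / tot)
        tnew = t[idx] + dt
        done = tnew >= t_end
        t[idx] = tnew
        active[idx[done]] = False
        move = ~done
        if move.any():
            up = rng.random(move.sum()) < (btot[move] / tot[move])
            state[idx[move]] += np.where(up, 1, -1)
    return state


def vacillating_rule_simulate(m: VacillatingVoterModel, n_samples: int, seed: int,
                              n_chains: int = 200, burn_in: int = 2000,
                              thin: int = 1, n0: int | None = None) -> np.ndarray:
    """Agent-rule stationary sampler for the vacillating voter model.

    Implements the microscopic consultation rules as events on the opinion
    count n (every agent is exchangeable, so the count is a sufficient
    state).  Each event picks a uniformly random agent i and one of three
    channels:

    * spontaneous (weight p_d): i flips;
    * direct consultation (weight 1-p_d): i consults a uniformly random
      other agent j and flips if j disagrees;
    * vacillation (weight 1-p_d): i consults j as above; if j disagrees, a
      further agent k is consulted uniformly among the N-1 agents other
      than j (so k may be i itself); i flips if k sides with i's current
      opinion — the mixed signal unsettles the agent.

    The two consultation channels together give the per-agent flip rate
    (1-p_d)(n'/(N-1))(1 + (N-n')/(N-1)) with n' the count of disagreeing
    peers, which is exactly the model's transition propensity; stationary
    statistics are therefore directly comparable with
    :func:`stationary_distribution` (time is rescaled by the constant event
    rate, which stationary quantities ignore).

    Returns ``n_samples`` post-burn-in opinion counts pooled across
    ``n_chains`` independent chains, recording every ``thin``-th event per
    chain (thinning reduces autocorrelation where mixing between consensus
    modes is slow, e.g. in the trimodal small-p_d regime).
    """
    N, pd = m.N, m.pd
    rng = np.random.default_rng(seed)
    if n0 is None:
        ns = rng.integers(0, N + 1, size=n_chains)
    else:
        ns = np.full(n_chains, n0, dtype=np.int64)
    if thin < 1:
        raise ValueError("thin must be >= 1")
    steps_keep = -(-n_samples // n_chains)  # ceil
    out = np.empty((steps_keep, n_chains), dtype=np.int64)
    w_spont = pd / (pd + 2 * (1 - pd))
    w_direct = (1 - pd) / (pd + 2 * (1 - pd))
    for step in range(burn_in + steps_keep * thin):
        agent_right = rng.random(n_chains) < ns / N
        n_disagree = np.where(agent_right, N - ns, ns)
        disagree1 = rng.random(n_chains) < n_disagree / (N - 1)
        n_same_pool = np.where(agent_right, ns, N - ns)  # includes agent i itself
        k_agrees = rng.random(n_chains) < n_same_pool / (N - 1)
        ch = rng.random(n_chains)
        flip = np.where(ch < w_spont, True,
                        np.where(ch < w_spont + w_direct, disagree1, disagree1 & k_agrees))
        ns = ns + np.where(flip, np.where(agent_right, -1, 1), 0)
        if step >= burn_in and (step - burn_in) % thin == 0:
            out[(step - burn_in) // thin] = ns
    return out.ravel()[:n_samples]


# --------------------------------------------------------------------------
# model (de)serialization for CLI / config files
# --------------------------------------------------------------------------


def model_to_dict(model) -> dict:
    if isinstance(model, BinaryChoiceModel):
        return {"model": "binary_choice", "N": model.N, "eps1": model.eps1,
                "eps2": model.eps2, "mu1": model.mu1, "mu2": model.mu2}
    if isinstance(model, VacillatingVoterModel):
        return {"model": "vacillating", "N": model.N, "pd": model.pd}
    raise TypeError(f"unknown model type {type(model).__name__}")


def model_from_dict(doc: dict):
    kind = doc.get("model")
    if kind == "binary_choice":
        return BinaryChoiceModel(N=int(doc["N"]), eps1=float(doc["eps1"]),
                                 eps2=float(doc["eps2"]), mu1=float(doc["mu1"]),
                                 mu2=float(doc["mu2"]))
    if kind == "vacillating":
        return VacillatingVoterModel(N=int(doc["N"]), pd=float(doc["pd"]))
    raise ValueError(f"unknown model kind {kind!r}")
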