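"""Seeded random fixtures: recurrence families, birth-death chains and Heun
parameter sets used by the property tests and the validation suite.

All randomness flows through a single seeded numpy generator, and generated
objects respect the invariants the rest of the package relies on: |R_j|
bounded away from zero, gamma bounded away from the non-positive integers,
strictly positive chain rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .heun import ConfluentHeunParameters, GeneralHeunParameters
from .models import BirthDeathGenerator
from .recurrence import ThreeTermRecurrence

__all__ = ["FixtureSpec", "generate_fixture", "random_recurrence",
           "random_birth_death", "random_heun_params"]

R_FLOOR = Fraction(1, 10)       # |R_j| >= 0.1
GAMMA_CLEARANCE = 0.1           # distance of gamma from {0, -1, -2, ...}


@dataclass
class FixtureSpec:
    """What to generate: kind in {random_recurrence, random_birth_death,
    heun_params}, size/magnitude bounds, and a mandatory seed."""

    kind: str
    seed: int
    size: int = 12
    magnitude: int = 8
    exact: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("random_recurrence", "random_birth_death", "heun_params"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.magnitude < 1 or self.size < 1:
            raise ValueError("bounds must be positive")


def _rand_fraction(rng, magnitude, nonzero_floor=None) -> Fraction:
    while True:
        num = int(rng.integers(-magnitude * 4, magnitude * 4 + 1))
        den = int(rng.integers(1, 5))
        f = Fraction(num, den)
        if nonzero_floor is None or abs(f) >= nonzero_floor:
            return f


def random_recurrence(spec: FixtureSpec) -> ThreeTermRecurrence:
    """Random tabulated coefficient family of length spec.size + 1 with
    |R_j| >= 0.1 (never zero: the closed form divides by prod R_j)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size + 1
    P = [_rand_fraction(rng, spec.magnitude) for _ in range(n)]
    Qt = [_rand_fraction(rng, spec.magnitude) for _ in range(n)]
    R = [_rand_fraction(rng, spec.magnitude, nonzero_floor=R_FLOOR) for _ in range(n)]
    if not spec.exact:
        P, Qt, R = ([float(v) for v in seq] for seq in (P, Qt, R))
    return ThreeTermRecurrence(P=P, Qt=Qt, R=R, mode="exact" if spec.exact else "float64")


def random_birth_death(spec: FixtureSpec) -> BirthDeathGenerator:
    """Random irreducible birth-death chain on 0..size with rates in
    (0.1, magnitude); boundary rates b(N) = d(0) = 0."""
    rng = np.random.default_rng(spec.seed)
    N = spec.size
    b = rng.uniform(0.1, spec.magnitude, size=N + 1)
    d = rng.uniform(0.1, spec.magnitude, size=N + 1)
    b[N] = 0.0
    d[0] = 0.0
    return BirthDeathGenerator(N=N, birth=b, death=d)


def random_heun_params(spec: FixtureSpec):
    """Random valid Heun parameters (general unless extra={'kind':'confluent'}).

    gamma is kept at distance >= 0.1 from the non-positive integers, |a| away
    from 0 and 1 is allowed, and epsilon closes the Fuchs relation for the
    general equation.  ``extra={'min_gamma': g0}`` restricts gamma >= g0; the
    initial-value ODE oracle needs gamma > 1 so that the second Frobenius
    solution z^(1-gamma) is unbounded at the origin and seed contamination is
    damped rather than amplified along the integration.
    """
    rng = np.random.default_rng(spec.seed)
    mag = float(spec.magnitude)
    min_gamma = spec.extra.get("min_gamma")

    def draw():
        return float(rng.uniform(-mag / 4, mag / 4))

    def draw_gamma():
        if min_gamma is not None:
            return float(rng.uniform(min_gamma, min_gamma + mag / 4))
        while True:
            g = draw()
            if g > 0.1 or min(abs(g - k) for k in range(int(-abs(g)) - 2, 1)) >= GAMMA_CLEARANCE:
                return g

    if spec.extra.get("kind") == "confluent":
        return ConfluentHeunParameters(q=draw(), alpha=draw(), gamma=draw_gamma(),
                                       delta=draw(), epsilon=draw())
    while True:
        a = float(rng.uniform(0.3, 3.0)) * (1 if rng.random() < 0.5 else -1)
        if abs(a) >= 0.3:
            break
    return GeneralHeunParameters(a=a, q=draw(), alpha=draw(), beta=draw(),
                                 gamma=draw_gamma(), delta=draw())


def generate_fixture(spec: FixtureSpec):
    """Dispatch on spec.kind; the same spec (same seed) always returns an
    identical object, and its JSON serialization is byte-identical."""
    if spec.kind == "random_recurrence":
        return random_recurrence(spec)
    if spec.kind == "random_birth_death":
        return random_birth_death(spec)
    return random_heun_params(spec)


def fixture_to_json(spec: FixtureSpec) -> str:
    """Generate and serialize a fixture deterministically."""
    obj = generate_fixture(spec)
    from .heun import heun_params_to_json
    from .recurrence import recurrence_to_json

    if isinstance(obj, ThreeTermRecurrence):
        return recurrence_to_json(obj)
    if isinstance(obj, BirthDeathGenerator):
        return json.dumps({"N": obj.N, "birth": [repr(x) for x in obj.birth.tolist()],
                           "death": [repr(x) for x in obj.death.tolist()]}, sort_keys=True)
    return heun_params_to_json(obj)
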