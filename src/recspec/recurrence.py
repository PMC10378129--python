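"""Closed-form solution of the general linear three-term recurrence

    R_j C_{j+1} - Qt_j C_j + P_j C_{j-1} = 0,      j = 0, 1, 2, ...

with boundary conditions C_0 = 1, C_{-1} = 0.

Writing the recurrence as a lower-triangular matrix equation and inverting it
with Cramer's rule expresses every C_i through a finite family of monic
orthogonal polynomials ``phi_j^i(x)`` defined by

    phi_0^i(x) = 1,   phi_1^i(x) = x + Qt_i,
    phi_j^i(x) = (Qt_{i-(j-1)} + x) phi_{j-1}^i(x)
                 - R_{i-(j-1)} P_{i-(j-2)} phi_{j-2}^i(x),

which encode the determinants and minors of the associated tridiagonal
matrix.  The closed form is

    C_i = ( Qt_0 phi_{i-1}^{i-1}(0) - R_0 P_1 phi_{i-2}^{i-1}(0) )
          / prod_{j=0}^{i-1} R_j,

with the convention phi_{-1} == 0, so that C_1 = Qt_0 / R_0.

Coefficient families may carry an additive *accessory shift* q (so the
effective middle coefficient is Qt_j = Q_j + q).  This is the natural form
for Heun-type series and for the spectral recurrences of birth-death chains,
where q is an affine function of the relaxation rate.

Three arithmetic modes are supported: ``float64`` (default), ``mp``
(arbitrary-precision mpmath floats) and ``exact`` (rational arithmetic with
:class:`fractions.Fraction`; results are exact whenever the coefficients are
rational).
"""

from __future__ import annotations

import ast
import json
import operator
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence, Union

import mpmath as mp

from .exceptions import CoefficientRangeError, SingularRecurrenceError

__all__ = [
    "ThreeTermRecurrence",
    "OrthogonalPolynomialFamily",
    "InverseColumnElements",
    "phi_family",
    "phi_coefficients",
    "closed_form_C",
    "forward_substitution",
    "inverse_column_elements",
    "recurrence_to_json",
    "recurrence_from_json",
    "coefficients_to_tsv",
]

MODES = ("float64", "mp", "exact")

CoefficientRule = Union[Callable[[int], object], Sequence, str]

# escalation threshold for the float64 stability contract: beyond this row
# index the phi coefficients can grow combinatorially and float64 results
# are no longer guaranteed to 1e-8 relative accuracy.
FLOAT64_SAFE_INDEX = 25


# --------------------------------------------------------------------------
# restricted arithmetic-expression grammar for serializable coefficient rules
# --------------------------------------------------------------------------

_BIN_OPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
}
_UNARY_OPS = {ast.UAdd: operator.pos, ast.USub: operator.neg}


def _compile_expr(expr: str, exact: bool) -> Callable[[int], object]:
    """Compile a restricted arithmetic expression in the variable ``j``.

    The grammar admits integer and decimal literals, the name ``j``, the
    binary operators ``+ - * / **`` and unary ``+ -``, and parentheses.
    Nothing else is evaluated; in particular no names, calls or attribute
    access, so rules loaded from files cannot execute code.
    """
    tree = ast.parse(expr, mode="eval")

    def ev(node, j):
        if isinstance(node, ast.Expression):
            return ev(node.body, j)
        if isinstance(node, ast.BinOp) and type(node.op) in _BIN_OPS:
            lhs, rhs = ev(node.left, j), ev(node.right, j)
            if exact and isinstance(node.op, ast.Div):
                return Fraction(lhs) / Fraction(rhs)
            return _BIN_OPS[type(node.op)](lhs, rhs)
        if isinstance(node, ast.UnaryOp) and type(node.op) in _UNARY_OPS:
            return _UNARY_OPS[type(node.op)](ev(node.operand, j))
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            if exact and isinstance(node.value, float):
                return Fraction(node.value)
            return node.value
        if isinstance(node, ast.Name) and node.id == "j":
            return j
        raise ValueError(f"disallowed syntax in coefficient expression: {expr!r}")

    ev(tree, 0)  # validate eagerly
    return lambda j: ev(tree, j)


def _as_rule(rule: CoefficientRule, name: str, exact: bool) -> Callable[[int], object]:
    if callable(rule):
        return rule
    if isinstance(rule, str):
        return _compile_expr(rule, exact)
    table = list(rule)

    def lookup(j: int, _table=table, _name=name):
        if not 0 <= j < len(_table):
            raise CoefficientRangeError(_name, j, len(_table))
        return _table[j]

    return lookup


# --------------------------------------------------------------------------
# the recurrence object
# --------------------------------------------------------------------------


@dataclass
class ThreeTermRecurrence:
    """Coefficient families (P_j, Qt_j, R_j) of a three-term recurrence.

    Parameters
    ----------
    P, Qt, R
        Coefficient rules: callables ``j -> value``, finite sequences
        (strict: an out-of-range index raises, tables are never padded), or
        restricted arithmetic expressions in ``j`` such as ``"(j+1)*(j+2)"``.
    boundary_overrides
        Optional map ``{j: (P_j, Qt_j, R_j)}`` replacing whole rows before
        any evaluation; entries may be ``None`` to keep the generic value.
    mode
        ``"float64"``, ``"mp"`` or ``"exact"``.
    accessory
        Additive shift q applied to every effective Qt_j (Heun convention
        ``Qt_j = Q_j + q``); overrides are shifted too.
    """

    P: CoefficientRule
    Qt: CoefficientRule
    R: CoefficientRule
    boundary_overrides: Mapping[int, tuple] | None = None
    mode: str = "float64"
    accessory: object = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        exact = self.mode == "exact"
        self._P = _as_rule(self.P, "P", exact)
        self._Qt = _as_rule(self.Qt, "Qt", exact)
        self._R = _as_rule(self.R, "R", exact)

    # -- scalar conversion per arithmetic mode ------------------------------
    def convert(self, x):
        if self.mode == "float64":
            return complex(x) if isinstance(x, complex) else float(x)
        if self.mode == "mp":
            return mp.mpmathify(x)
        if isinstance(x, (Fraction, int)):
            return Fraction(x)
        if isinstance(x, float):
            return Fraction(x)  # floats are exact binary rationals
        raise TypeError(f"value {x!r} is not rational; exact mode needs rational coefficients")

    def with_mode(self, mode: str) -> "ThreeTermRecurrence":
        return ThreeTermRecurrence(self.P, self.Qt, self.R, self.boundary_overrides,
                                   mode, self.accessory)

    def with_accessory(self, q) -> "ThreeTermRecurrence":
        return ThreeTermRecurrence(self.P, self.Qt, self.R, self.boundary_overrides,
                                   self.mode, q)

    # -- effective coefficients (override first, then accessory shift) ------
    def _row(self, j: int):
        p, qt, r = None, None, None
        if self.boundary_overrides and j in self.boundary_overrides:
            p, qt, r = self.boundary_overrides[j]
        p = self._P(j) if p is None else p
        qt = self._Qt(j) if qt is None else qt
        r = self._R(j) if r is None else r
        return p, qt, r

    def coeff_P(self, j: int):
        return self.convert(self._row(j)[0])

    def coeff_Qt(self, j: int):
        """Effective middle coefficient, including the accessory shift."""
        return self.convert(self._row(j)[1]) + self.convert(self.accessory)

    def coeff_Qt_base(self, j: int):
        """Middle coefficient without the accessory shift (the Q_j family)."""
        return self.convert(self._row(j)[1])

    def coeff_R(self, j: int):
        return self.convert(self._row(j)[2])


@dataclass
class OrthogonalPolynomialFamily:
    """The values [phi_0^i(x), ..., phi_i^i(x)] of the recursively defined
    monic polynomial family attached to a recurrence, evaluated at ``x``."""

    i: int
    x: object
    values: list

    def __getitem__(self, j: int):
        if j == -1:  # phi_{-1} == 0 convention (forced by C_{-1} = 0)
            return 0 * self.values[0]
        return self.values[j]


@dataclass
class InverseColumnElements:
    """First- and second-column inverse elements theta_{i,1}, theta_{i,2} of
    the lower-triangular recurrence matrix (the only two columns that enter
    C_i = Qt_0 theta_{i,1} - P_1 theta_{i,2})."""

    i: int
    theta1: object
    theta2: object


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def phi_family(rec: ThreeTermRecurrence, i: int, x) -> OrthogonalPolynomialFamily:
    """Evaluate phi_j^i(x) for j = 0..i by the three-term polynomial recursion.

    phi_j^i touches Qt and R at indices i-(j-1) down to 1 and P down to
    index 2; row 0 never enters the family itself.
    """
    if i < 0:
        raise ValueError(f"family index i must be >= 0, got {i}")
    x = rec.convert(x)
    one = rec.convert(1)
    values = [one]
    if i >= 1:
        values.append(x + rec.coeff_Qt(i))
    for j in range(2, i + 1):
        k = i - (j - 1)
        a = (rec.coeff_Qt(k) + x) * values[j - 1]
        b = rec.coeff_R(k) * rec.coeff_P(k + 1) * values[j - 2]
        values.append(a - b)
    return OrthogonalPolynomialFamily(i=i, x=x, values=values)


def phi_coefficients(rec: ThreeTermRecurrence, i: int) -> list:
    """Symbolic coefficient vectors (ascending powers of x) of phi_0^i..phi_i^i.

    Each phi_j^i is monic of degree exactly j.  Arithmetic follows the
    recurrence's mode, so in exact mode the vectors are exact rationals.
    """
    if i < 0:
        raise ValueError(f"family index i must be >= 0, got {i}")
    one = rec.convert(1)
    polys = [[one]]
    if i >= 1:
        polys.append([rec.coeff_Qt(i), one])
    for j in range(2, i + 1):
        k = i - (j - 1)
        c = rec.coeff_Qt(k)
        prev = polys[j - 1]
        # (x + c) * prev
        p = [prev[0] * c] + [prev[m - 1] + prev[m] * c for m in range(1, len(prev))] + [prev[-1]]
        sub = rec.coeff_R(k) * rec.coeff_P(k + 1)
        prev2 = polys[j - 2]
        for m, v in enumerate(prev2):
            p[m] = p[m] - sub * v
        polys.append(p)
    return polys


def forward_substitution(rec: ThreeTermRecurrence, i_max: int) -> list:
    """Brute-force solution [C_0, ..., C_i_max] by iterating the recurrence.

    C_{j+1} = (Qt_j C_j - P_j C_{j-1}) / R_j with C_0 = 1, C_{-1} = 0.
    This is the independent oracle for :func:`closed_form_C`.
    """
    if i_max < 0:
        raise ValueError(f"i_max must be >= 0, got {i_max}")
    one = rec.convert(1)
    C = [one]
    prev = rec.convert(0)
    for j in range(i_max):
        r = rec.coeff_R(j)
        if r == 0:
            raise SingularRecurrenceError(j)
        nxt = (rec.coeff_Qt(j) * C[j] - rec.coeff_P(j) * prev) / r
        prev = C[j]
        C.append(nxt)
    return C


def _closed_form_once(rec: ThreeTermRecurrence, i: int):
    fam = phi_family(rec, i - 1, rec.convert(0))
    denom = rec.convert(1)
    for j in range(i):
        r = rec.coeff_R(j)
        if r == 0:
            raise SingularRecurrenceError(j)
        denom = denom * r
    num = rec.coeff_Qt(0) * fam[i - 1] - rec.coeff_R(0) * rec.coeff_P(1) * fam[i - 2]
    return num / denom


def closed_form_C(rec: ThreeTermRecurrence, i: int):
    """C_i in closed form through the orthogonal-polynomial family.

    For i = 0 returns 1 (boundary).  For i = 1 the phi_{-1} == 0 convention
    gives C_1 = Qt_0 / R_0.  In float64 mode, indices beyond the stability
    contract or non-finite intermediate growth trigger automatic escalation
    to arbitrary precision (with a warning).
    """
    if i < 0:
        raise ValueError(f"index i must be >= 0, got {i}")
    if i == 0:
        return rec.convert(1)
    val = _closed_form_once(rec, i)
    if rec.mode == "float64":
        import math

        bad = not math.isfinite(abs(val))
        if bad or i > FLOAT64_SAFE_INDEX:
            if bad:
                warnings.warn(
                    f"float64 overflow at i={i}; escalating to arbitrary precision",
                    RuntimeWarning, stacklevel=2,
                )
                return float(_closed_form_once(rec.with_mode("mp"), i))
            warnings.warn(
                f"i={i} exceeds the float64 stability contract (i <= "
                f"{FLOAT64_SAFE_INDEX}); consider mode='mp' or 'exact'",
                RuntimeWarning, stacklevel=2,
            )
    return val


def inverse_column_elements(rec: ThreeTermRecurrence, i: int) -> InverseColumnElements:
    """theta_{i,1} and theta_{i,2}: the two inverse-matrix columns entering C_i.

    theta_{i,1} = phi_{i-1}^{i-1}(0) / prod_{j=0}^{i-1} R_j,
    theta_{i,2} = phi_{i-2}^{i-1}(0) / prod_{j=1}^{i-1} R_j,
    and consistently C_i = Qt_0 theta_{i,1} - P_1 theta_{i,2}.

    The infinite determinant behind Cramer's rule cancels against the minors
    row by row, so only these finite quotients are ever formed.
    """
    if i < 1:
        raise ValueError("inverse elements are defined for row indices i >= 1")
    fam = phi_family(rec, i - 1, rec.convert(0))
    prod0 = rec.convert(1)
    for j in range(i):
        r = rec.coeff_R(j)
        if r == 0:
            raise SingularRecurrenceError(j)
        prod0 = prod0 * r
    prod1 = prod0 / rec.coeff_R(0)
    return InverseColumnElements(i=i, theta1=fam[i - 1] / prod0, theta2=fam[i - 2] / prod1)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def _rule_to_jsonable(rule: CoefficientRule):
    if isinstance(rule, str):
        return rule
    if callable(rule):
        raise TypeError(
            "callable coefficient rules are not serializable; supply an "
            "expression string or a finite table instead"
        )
    return [_scalar_to_jsonable(v) for v in rule]


def _scalar_to_jsonable(v):
    if isinstance(v, Fraction):
        return f"{v.numerator}/{v.denominator}" if v.denominator != 1 else v.numerator
    return v


def _scalar_from_jsonable(v, exact: bool):
    if isinstance(v, str):
        return Fraction(v) if exact else float(Fraction(v))
    return v


def recurrence_to_json(rec: ThreeTermRecurrence) -> str:
    """Serialize to the package's JSON dialect (expression strings or tables)."""
    doc = {
        "P": _rule_to_jsonable(rec.P),
        "Qt": _rule_to_jsonable(rec.Qt),
        "R": _rule_to_jsonable(rec.R),
        "mode": rec.mode,
    }
    if rec.boundary_overrides:
        doc["overrides"] = {
            str(j): [_scalar_to_jsonable(v) if v is not None else None for v in row]
            for j, row in rec.boundary_overrides.items()
        }
    if rec.accessory != 0:
        doc["accessory"] = _scalar_to_jsonable(rec.accessory)
    return json.dumps(doc, sort_keys=True)


def recurrence_from_json(text: str) -> ThreeTermRecurrence:
    doc = json.loads(text)
    mode = doc.get("mode", "float64")
    exact = mode == "exact"

    def load_rule(key):
        raw = doc[key]
        if isinstance(raw, str):
            return raw
        return [_scalar_from_jsonable(v, exact) for v in raw]

    overrides = None
    if "overrides" in doc:
        overrides = {
            int(j): tuple(_scalar_from_jsonable(v, exact) if v is not None else None for v in row)
            for j, row in doc["overrides"].items()
        }
    accessory = _scalar_from_jsonable(doc.get("accessory", 0), exact)
    return ThreeTermRecurrence(load_rule("P"), load_rule("Qt"), load_rule("R"),
                               overrides, mode, accessory)


def coefficients_to_tsv(rec: ThreeTermRecurrence, i_max: int) -> str:
    """TSV table with columns j, P, Qt, R, C for j = 0..i_max."""
    C = forward_substitution(rec, i_max)
    lines = ["j\tP\tQt\tR\tC"]
    for j in range(i_max + 1):
        lines.append(
            f"{j}\t{rec.coeff_P(j)}\t{rec.coeff_Qt(j)}\t{rec.coeff_R(j)}\t{C[j]}"
        )
    return "\n".join(lines) + "\n"
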