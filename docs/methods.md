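# Methods

## The closed form and its oracle

The package solves the homogeneous linear three-term recurrence
`R_j C_{j+1} − Q̃_j C_j + P_j C_{j−1} = 0` with `C_0 = 1`, `C_{−1} = 0`.
Rewriting the rows as an infinite lower-triangular matrix equation and
applying Cramer's rule expresses `C_i` through two minors of the associated
tridiagonal matrix. Those minors obey the same three-term structure, which is
exactly the defining recursion of a finite family of monic orthogonal
polynomials `φ_j^i(x)`; the infinite determinant in Cramer's rule cancels row
by row against the minors, so only finite quotients are ever formed. The
result,

```
C_i = ( Q̃_0 φ_{i−1}^{i−1}(0) − R_0 P_1 φ_{i−2}^{i−1}(0) ) / ∏_{j=0}^{i−1} R_j ,
```

requires `R_j ≠ 0` on the evaluation range and the convention `φ_{−1} ≡ 0`
(forced by `C_{−1} = 0`, and giving `C_1 = Q̃_0/R_0`). Unlike the
continued-fraction solution it assumes nothing about convergence or
truncation of the sequence.

Every use of the closed form in this package is cross-checked against plain
forward substitution of the rows — a brute-force oracle that is correct by
construction. In exact rational arithmetic the two must agree digit for
digit, and the test suite asserts exactly that over hundreds of random
coefficient families.

### Arithmetic tiers

`φ_N^N` coefficients grow combinatorially with `N`, so three arithmetic modes
are provided: `float64` (default; the stability contract is relative error
below 1e-8 against the exact oracle through row 25 for coefficients of
moderate size, and a warning is emitted past that index, with automatic
escalation to arbitrary precision on overflow), `mp` (mpmath arbitrary
precision), and `exact` (stdlib `Fraction`; exact whenever the coefficients
are rational — note every float is a binary rational, so float inputs convert
losslessly). Spectral computations assemble the quantization polynomial in
exact arithmetic and only then move to 60-digit floating point for root
finding.

### Boundary-row overrides and the accessory shift

A recurrence may carry per-row replacement coefficients (applied before any φ
evaluation) and an additive accessory shift `q` on every middle coefficient
(`Q̃_j = Q_j + q`). The shift is how Heun-type series and spectral problems
enter the framework: shifting the middle coefficients by `q` is identical to
evaluating the φ family at `x = q` instead of `x = 0`, which is what makes
the truncation condition a *polynomial* in `q`.

## Continued fractions

The classic alternative solves the spectral recurrence with the backward
ladder `S_j = −P_{j+1}/((λ−Q̃_{j+1}) + R_{j+1}S_{j+1})`, seeded by the
truncation `S_N = 0`, and recovers coefficients as running products of the
`S_j`. The seed rung never evaluates `R_N` (it multiplies `S_N = 0`), which
matters for finite chains where row `N` has no physical `R`. A vanishing
denominator is reported as a pole error carrying the rung index; an exactly
zero intermediate `S_j` (degenerate eigenvector structure) is reported at the
next rung rather than resolved — no convention for it is imposed.

The finite continued fraction `1/(Q_1+q − R_1P_2/(Q_2+q − …))` equals the
rational function `φ_{N−1}^N(q)/φ_N^N(q)`; both are the same minor quotient
of the truncated tridiagonal matrix. The identity is checked exactly in
rational arithmetic and to 1e-10 relative in float64, away from poles of
either side; large-`q` behaviour (`∼ 1/q`, by the degree count of the monic
φ) is asserted separately.

## Heun functions

The general Heun equation (regular singularities 0, 1, a, ∞; Fuchs relation
`α+β+1 = γ+δ+ε`) has, for the index-0 Frobenius solution at the origin,
series coefficients with

```
P_j = (j−1+α)(j−1+β),  Q_j = j[(j−1+γ)(1+a) + aδ + ε],  R_j = a(j+1)(j+γ),
```

and `Q̃_j = Q_j + q`, so `γ` must avoid the non-positive integers and the
closed form applies verbatim with `x = q`. This grouping of `Q_j` is
confirmed by direct series substitution and — decisively — by the
ODE-residual oracle below. Published coefficient lists for the *confluent*
equation disagree between sources in the signs of `α` and of the whole `Q_j`;
the family used here,

```
P_j = (1−j)ε + α,   Q_j = j(j−1+γ+δ−ε),   R_j = (j+1)(j+γ),
```

is fixed uniquely by two independent requirements that the tests enforce:
(i) it is the a→∞ limit (with `ε/a → −ε'`, `q/a → q'`, `αβ/a → α'`) of the
general family, row by row after dividing by `a`; and (ii) the truncated
series annihilates the confluent equation
`z(z−1)y″ + [εz(z−1)+γ(z−1)+δz]y′ − (αz−q)y = 0` to rounding. The first
coefficient is `C_1 = q/γ` in both the limit and the recurrence, which pins
the sign of the `(αz−q)` term.

### Validity checks

Two oracles guard the series:

* **ODE residual.** The truncated series and its first two derivatives are
  evaluated term by term and substituted into the defining equation (cleared
  of denominators). For a correct coefficient family the residual decays
  geometrically with the truncation order on compact subsets of the
  convergence disc; an injected 1e-3 perturbation of a single coefficient
  inflates it by more than three orders of magnitude, so the oracle has real
  discriminating power. It needs no initial conditions and no integrator, so
  it covers the entire valid parameter range.
* **Initial-value integration.** An adaptive Runge–Kutta integration of the
  ODE from the origin (seeded with the hand-expanded two-term Taylor start)
  must match the summed series to 1e-8 at `|z| = 0.3 r`. This oracle is only
  well-conditioned for `γ > 1`: for `γ < 1` the second Frobenius solution
  `z^{1−γ}` *vanishes* at the origin, so any seed error acquires a component
  that grows like `(z/z_0)^{1−γ}` along the integration — an intrinsic
  ill-conditioning of the oracle, not of the series. The IVP comparison
  therefore draws `γ ≥ 1.1`; the residual oracle covers the rest.

Evaluation (`heun_eval`) sums partial sums until two consecutive terms fall
below the tolerance, with the radius guard `r = min(1, |a|)` (general) or
`r = 1` (confluent), relaxed only when the series is detected to have
truncated to a polynomial (a trailing run of vanishing coefficients). No
analytic continuation outside the disc is attempted.

## The binary-choice (recruitment) model

`N` agents hold one of two opinions; with `n` "right"-deciders the chain
moves `n → n+1` at `b(n) = (N−n)ε₁ + μ₁n(N−n)` and `n → n−1` at
`d(n) = nε₂ + μ₂n(N−n)`. All four rates are per unit time (`ε` per agent,
`μ` per agent pair); they must be positive, since the Heun map divides by
`μ₁` and `μ₂`. Substituting the eigenfunction ansatz into the generating
function PDE of the master equation gives a general Heun equation; carrying
the derivation through (it is reproduced symbolically in the package's
development history and validated by the tests) yields the parameter map

```
a = μ₂/μ₁,  α = −N,  β = ε₁/μ₁,  γ = −(N−1) − ε₂/μ₂,  δ = 0,
ε = ε₁/μ₁ + ε₂/μ₂ (Fuchs),   q(λ) = (λ − Nε₁)/μ₁ .
```

With this map the Heun recurrence row is precisely the `n`-basis master
equation row scaled by `−1/μ₁`, so the series coefficients of the
eigenfunction *are* the probability-basis eigenvector components — asserted
directly by the `A·C = −λC` residual test. Since `α = −N` is a non-positive
integer, `P_{N+1} = 0` and the quantized accessory values make the series a
degree-N polynomial: the truncation condition

```
q φ_N^N(q) − R_0 P_1 φ_{N−1}^N(q) = 0
```

is a monic polynomial of degree N+1 in `q` whose roots map affinely to the
decay rates `λ = Nε₁ + μ₁q`. (Some published statements of this map carry a
stray `(N−1)` in `β` and `q`; the version above is the one under which the
truncation condition reproduces the dense spectrum to working precision,
which the cross-oracle tests enforce at every run.)

Sign conventions: decay rates `λ ≥ 0` with time dependence `e^{−λt}`
throughout; the generator's eigenvalues are `−λ`.

## The vacillating voter model

Each agent wakes at unit rate; with probability `p_d` it flips spontaneously,
otherwise it consults peers. The package defines the model by its transition
propensities,

```
b(n) = p_d(N−n) + (1−p_d)(N−n)·(n/(N−1))·(1 + (N−n)/(N−1)),
d(n) = p_d·n    + (1−p_d)(N−n)·(n/(N−1))·(1 + n/(N−1)),
```

symmetric under `n ↔ N−n`. A natural-language "consult two peers and flip
only if both disagree" rule is *inconsistent* with these propensities — the
implied per-wake flip probability would exceed 1 near consensus, and the
corresponding generator has a different spectrum — so the propensities, which
are the quantities the spectral theory is built on, are taken as the model's
definition. The agent-rule simulation oracle realizes them exactly with two
independent consultation channels per waking agent `i` (each carrying weight
`1−p_d`): (A) consult `j ∈ others(i)` and flip on disagreement; (B) consult
`j ∈ others(i)`, and if `j` disagrees consult `k ∈ others(j)` (which may be
`i` itself) and flip if `k` sides with `i` — a mixed signal unsettles the
vacillating agent. Channel A contributes `n'/(N−1)` and channel B
`n'(N−n')/(N−1)²` per agent (with `n'` the disagreeing count), reproducing
the propensities identically; stationary statistics are invariant under the
constant event-rate rescaling.

For the spectrum, the eigenvector generating function in the scaled variable
(`C_n = P(n)/(N−1)ⁿ`) satisfies a third-order ODE whose series coefficients
nevertheless obey a three-term recurrence. Deriving it from the propensities
(symbolic computation, frozen into closed form) and normalizing rows so the
spectral parameter enters through `q(λ) = (N−1)(p_d N − λ)` gives

```
R_j = (j+1)[(N−1)(N−p_d) − (1−p_d)j(j+1)],
Q_j = (1−p_d)(3N−2) j(N−j) / (N−1),
P_j = (N+1−j)[(j−1)(2N−j) + p_d((N−j)² − j + 1)] / (N−1)²,
```

with `Q̃_j = Q_j + q(λ)`. The generic `j = 0` row equals the explicit
boundary condition `(N−1)((N−1)p_d + N(1−p_d))·C_1 = q(λ)·C_0` — note
`(N−1)(N−p_d)` is the same number — so no special-casing is mathematically
necessary; the constructor still installs the boundary row as an explicit
override to keep it visible. Rational (non-polynomial) coefficients in `j`
are harmless: the recurrence machinery only needs exact arithmetic, not
polynomial rows. The arbiter for this family is the same as for the Heun
map: the quantization roots must match the dense generator spectrum
(max |diff| < 1e-6 over the tested grid; observed at the 1e-13 level), and
the truncated series must reproduce the dense eigenvectors after the
`(N−1)ⁿ` rescaling.

One benign degeneracy: `R_N` vanishes at `p_d = 2N/(N²+1)` (e.g. ≈ 0.385 for
N = 5). The quantization polynomial never divides by `R_j`, so the spectrum
is unaffected; only forward substitution *through* row N would fail exactly
there.

For `N = 20` the stationary law is trimodal (local maxima at both consensus
states and the even split) for small `p_d`; the acceptance run uses
`p_d = 0.05`, inside that regime, and checks both the three-maxima property
of the detailed-balance law and the agent-rule sampler against it.

## Spectral solver

* **Quantization polynomial.** Assembled symbolically in `q` with the φ
  recursion (ascending coefficient lists; exact rational arithmetic for the
  models). Monic of degree N+1 by the degree bookkeeping of the monic φ.
* **Roots.** `mpmath.polyroots` at 60 decimal digits (configurable), on the
  exact coefficients. Complex leakage above 1e-8 relative and root gaps below
  1e-9 relative trigger warnings (near-degenerate spectra should use the
  dense path; the spectral form assumes diagonalizability).
* **Zero snapping.** The smallest rate is set to exactly 0 when below
  1e-10 × the spectral radius — conservation makes λ = 0 exact in the
  assembled generator, so this cannot mask a genuinely nonzero rate at the
  tested scales.
* **Dense oracle.** Detailed balance makes `DAD⁻¹` symmetric; decay rates
  come from `scipy.linalg.eigh_tridiagonal` on (b+d, −√(b_n d_{n+1})). A zero
  interior rate breaks symmetrization and falls back to a general
  eigensolver with a warning.
* **Eigenvectors.** Forward substitution of the model recurrence at `q(λ)` in
  50-digit arithmetic; the truncation residual `|C_{N+1}|/max|C|` above 1e-8
  raises a not-an-eigenvalue error. The zero mode is normalized to total mass
  1 (it must equal the detailed-balance law), decaying modes to unit maximum
  amplitude (their total mass is 0 by conservation, which is asserted, not
  imposed).
* **Time evolution.** `evolve` realizes `P(t) = Σ w_i C_i e^{−λ_i t}` in the
  symmetrized orthogonal eigenbasis (`D⁻¹U e^{−Λt} Uᵀ D P₀`), which is the
  numerically stable equivalent of solving `V·w = P₀` against the raw
  eigenvector matrix; when the stationary-measure conditioning exceeds 1e12
  (or the chain is reducible) it falls back to the dense matrix exponential
  with a warning. Output columns are checked to remain normalized to 1e-10.
* **Initial-condition projection.** The projection is this package's choice
  (nothing in the spectral formalism prescribes it); it is validated solely
  against the matrix-exponential oracle.

## Stochastic oracles and the fixture generator

`gillespie_simulate` is an exact SSA, vectorized across trajectories, with a
mandatory seed (all randomness in the package flows through
`numpy.random.default_rng`). The vacillating sampler runs many parallel
chains with uniform random initial opinions, a burn-in, and optional
thinning; in the trimodal regime mixing between consensus modes is slow
(the dominant relaxation time at N = 20, p_d = 0.05 is ≈ 125 events per
chain), so the acceptance configuration uses 500 chains, 4000 burn-in events
and thin = 50 to keep the autocorrelation of retained samples low.

The fixture generator draws recurrence families with `|R_j| ≥ 0.1` (the
closed form divides by `∏R_j`), birth–death chains with strictly positive
interior rates, and Heun parameters with `γ` at distance ≥ 0.1 from the
non-positive integers and `|a| ≥ 0.3`. These fixtures emulate the *structure*
of the target problems — they are not calibrated to any empirical data, so
passing tests certify the mathematics (exactness, cross-oracle agreement,
convergence), not the fit of either social-choice model to real populations.

## Known limitations

* Only the index-0 Frobenius solution at `z = 0` is implemented; solutions at
  the other singularities and the second local solution are parameter
  re-mappings left to the user. No analytic continuation beyond the disc.
* No biconfluent/doubly-/triconfluent Heun forms; no connection coefficients.
* Repeated eigenvalues: the spectral path warns and the caller should use the
  dense matrix-exponential route; the decomposition form assumes
  diagonalizability.
* Recurrences of order higher than three (vector continued fractions) are out
  of scope, as are absorbing/reflecting first-passage boundary problems and
  time-dependent rates.
* The float64 tier degrades past row ~25 by design; use `mp` or `exact` for
  deep recurrences.
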