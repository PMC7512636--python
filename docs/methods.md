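# Methods

This note records the model conventions, the numerical methods behind each
stage of the pipeline, the design choices that were genuinely open, and
the limits of what the validation shows.

## Parameter conventions

All configuration files and fixtures quote parameters in the scaled
notation used in figure captions for this model family: `eps`, `a`, `b`, `c`, `f`, the *scaled* quantities
`eps2_s` (= ε²s), `eps2_gamma` (= ε²γ), the pulse rates `lambda1/2`, and
either `eps2_EY2_1/2` (= ε²E[Yᵢ²]) or the channel intensities
`intensity_1/2` (= λᵢε²E[Yᵢ²]). Raw bookkeeping values (`s = eps2_s/ε²`
etc.) are derived once at load; everything downstream uses the raw values
with explicit ε powers. `ModelParams` accepts either route and also the
unscaled ecological rates (`from_rates`, with `a = a₁ − ε²s·c/f`).

The ε-scaling is formal bookkeeping for the averaging: the physically
meaningful combinations are ε²s (self-competition), ε²γ (mean delay) and
λᵢε²E[Yᵢ²] (noise intensity). ε ≤ 0.5 is enforced as a soft limit (warning)
because the averaging and the perturbation expansion both assume ε small.

A typographic note on the source model: the prey self-competition term in
the reduced drift is `−ε²(s/f)(f x₁ − c)`. Re-deriving the reduction from
the unreduced equations with `a = a₁ − ε²s·c/f` fixes the factor as `s/f`
(an `s·f` reading is inconsistent with the original model whenever
`f ≠ 1`), and the same `s/f` factor, at order ε², appears in the drift of
the first integral; the chain-rule identity is enforced by a test.

## Orbits and periods

The conservative system's first integral separates as
`r(x₁,x₂) = φ(x₁) + ψ(x₂)`; φ is monotone on either side of `c/f`, ψ on
either side of `a/b`. Orbits are parameterized *by time*, not arc length,
because the averaging weights are `dt`: the level curve `r = K` is traced
by integrating the conservative flow (DOP853, rtol = atol = 1e-10 by
default, exposed) from the root of `φ(x₁) = K`, `x₁ > c/f` on the ray
`x₂ = a/b`, detecting the falling and rising crossings of that ray as the
half- and full-period events. The dense solution is resampled at ≥ 512
(default 1024) uniform times; the stored polyline closes exactly by
construction and the first-return gap is checked against a tolerance
(default 1e-6).

The quasi-period is computed three ways and cross-checked to 1e-4
relative: the return time, and the two closed line integrals
`∮ dx₁/(x₁(a − bx₂))` and `∮ dx₂/(x₂(−c + fx₁)(1 + ε⁴sγx₁))`. The line
integrals split the contour into lower/upper branches; ψ is inverted with
Lambert-W (both real branches, with a series seed `u = 1 ± √(2v) + 2v/3`
plus Newton polish near the branch point, where `lambertw` alone loses
half its digits), φ by bracketed bisection, and the turning-point
square-root singularities are absorbed by the substitution
`x = x_min + (x_max − x_min)sin²θ` before Gauss–Legendre quadrature.

Small-K behavior: linearizing the conservative flow at the equilibrium
gives the harmonic period `2π/√(ac(1 + ε⁴sγc/f))`, used as the `T(r)`
extension below the computed r-grid and as the time-scale estimate for
orbit-closure caps (an orbit failing to close within 10 harmonic periods
is an error, not a retry).

## Derivate moments and their truncation

A channel-1 pulse maps `X₁ → X₁e^{εY}`, so the jump of the first integral
is exact: `Δr = (f − ε⁴csγ)X₁u + (ε⁴/2)fsγX₁²(2u + u²) − cεY` with
`u = e^{εY} − 1` (the logarithm collapses, `ln(1 + u) = εY`); likewise
for channel 2. Expanding in εY reproduces the printed jump-expansion
coefficients `A_{i1}..A_{i4}` term by term (the package hard-codes them
and a test re-derives them with sympy).

The n-th derivate moment of `R` is `Σᵢ λᵢE[(ΣₖεᵏA_{ik}Yᵢᵏ)ⁿ]` with
Gaussian amplitude moments, truncated at total order ε⁴. "Total order"
counts the ε factors *inside* the printed A's (they carry internal ε⁴
pieces): those contribute only at ε⁶ and beyond, so the moments use the
ε-homogeneous leading parts of the A's. This is the only reading under
which the hard-coded closed forms agree with a computer-algebra expansion
truncated at ε⁴ to machine precision, and it is what the averaged GFPK
equation keeps. The ε-order split of the averaged coefficients
(ε²Ā₁₁ + ε⁴Ā₁₂ etc.) is exact by construction — each term's ε power is
known symbolically, no numerical differencing is involved.

The averaged coefficients are tabulated on a log-spaced r-grid (default
60 nodes on [1e-3, r_max]); log spacing resolves the r → 0 region where
the diffusion Ā₂₁ vanishes linearly. r_max is enlarged (×1.6 steps) until
an exponential-tail estimate of the stationary mass beyond it falls below
1e-4, using a coarse 24-node leading-order solve per iteration.

## Stationary GFPK solution

All density work happens on a uniform fine grid (default 4001 nodes)
resampled from the coefficient tables with cubic splines, so 4th-order
central finite differences (one-sided at the ends) apply to the up-to-4th
derivatives required.

**p₀.** The zero-flux closed form is integrated in the well-conditioned
combination `ln p₀ = ∫ (2Ā₁₁ − Ā₂₁′)/Ā₂₁ dr`: near the origin both
`2Ā₁₁/Ā₂₁` and `(ln Ā₂₁)′` diverge like `1/r` but their difference stays
bounded. Because the remaining integrand still varies on scale ~r near
the lower boundary, cumulative integrals are evaluated as exact
antiderivatives of a cubic spline in `u = ln r` on a dense log grid. With
this construction the discretized leading-order operator applied to p₀
leaves an interior residual below 1e-6.

The origin is a degenerate boundary (Ā₂₁(0) = 0): the density behaves
like `r^{κ−1}` with `κ = 2Ā₁₁(0)/Ā₂₁′(0)`. κ ≤ 0 means non-integrable
stationary mass and raises a diagnostic error. The solved density is
extended from r_min = 1e-3 to r = 0 by quadratic extrapolation before
normalization.

**p₁ = 0.** The ε³ balance is the same homogeneous operator as the ε²
one, so p₁ ∝ p₀; the normalization conditions (`∫p = 1` with `∫p₀ = 1`)
force the multiple to zero — the only value consistent with the
boundary and normalization conditions.

**p₂.** Integrating the ε⁴ balance once (the integration constant vanishes
by zero flux at infinity) leaves the first-order linear equation
`−Ā₁₁p₂ + ½(Ā₂₁p₂)′ = S(r)`, solved with the integrating factor built
from p₀: `p₂ = p₀(J + α)`, `J = ∫ 2S/(Ā₂₁p₀) dr`, α fixed by `∫p₂ = 0`.
Two source modes exist:

- `printed` — only the third/fourth derivate-moment terms
  `(1/3!)(Ā₃p₀)″ − (1/4!)(Ā₄p₀)‴` (after one integration);
- `full_eps4` (default) — additionally the second-moment ε⁴ terms
  `Ā₁₂p₀ − ½(Ā₂₂p₀)′`, which belong to the same ε⁴ balance of the full
  stationary equation.

The default is `full_eps4`. The printed-only source is incomplete as an
ε⁴ balance of the stationary equation, and the discrepancy is not
academic: on the base fixture the printed source makes the correction
about three times too strong (marginal peaks 1.60/2.34 against 1.22/1.74
from the jump-SDE Monte Carlo; L1 distance ≈ 0.25), while the full source
lands on the simulation (L1 ≈ 0.03–0.04). Both modes are kept and
compared in tests.

**Residual accounting.** The stationary equation holds only up to its
O(ε⁶) remainder, so the residual of the assembled solution `p₀ + ε²p₂` is
evaluated order-consistently: the ε⁶-order contributions (ε⁴ coefficient
blocks acting on the ε²-weighted correction) are assigned to the
remainder. Under this measure the correction reduces the interior-max
residual by more than a factor ε⁻² on the base fixture. Interior means:
excluding 8 stencil nodes at each end and the lowest decade
`r < 10·r_min`, where the uniform grid under-resolves the weakly singular
boundary behavior.

**Assembly.** `p = p₀ + εp₁ + ε²p₂` may dip slightly negative in the far
tail; negative values are clipped with the removed mass recorded (warning
above 1e-3, hard error above 5% — at that point the expansion is invalid
for the parameters), then renormalized.

## Population densities

`p_{X₁X₂} = p(r)/(x₁x₂T(r))` on a default 400×400 grid over
[0.05, 4]² — covering the support of the stationary laws at the
reference parameter scale; `T(r)` is interpolated from the coefficient table and
replaced by the harmonic-limit period below the r-grid (removing the 0/0
at the equilibrium without affecting mass). The change-of-variables
identity `∬ p(r)/(x₁x₂T) dx₁dx₂ = ∫p(r)dr` is verified numerically to
~1e-2 (tightening under refinement) before marginals are renormalized,
with the renormalization factor logged. Moments come from trapezoid
quadrature; the relative fluctuation is Var(X)/E(X).

The Gaussian reference at intensities `Dᵢ = λᵢε²E[Yᵢ²]` uses the same
averaged ε²-coefficients with all fourth-moment (ε⁴) coefficients zeroed;
its stationary density is p₀ alone. Note Ā₁₁ and Ā₂₁ depend on the noise
only through the intensities, so the *entire* Poisson-vs-Gaussian
difference at equal intensity is the ε⁴ correction — which is why the
choice of p₂ source mode matters.

## Monte Carlo

Two jump schemes:

- `marcus_event` (default): exponential inter-arrival times per channel;
  noise-free drift advanced by fixed-step RK4 between arrivals; at a
  channel-i arrival, `Xᵢ ← Xᵢe^{εY}` exactly. This realizes the
  Stratonovich→Itô correction series with no pulse-shape discretization
  error, and preserves positivity by construction.
- `dipaola_triangular`: pre-drawn pulse trains spread as triangular
  impulses of base 2·dt with equal impulse, integrated by fixed-step RK4
  (the classical Runge–Kutta treatment of impulse-driven systems);
  requires dt ≪ 1/λ (warned), clamps at a positivity floor with an
  incident counter. The two schemes agree within sampling error on the
  base fixture (scheme-consistency test).

The Gaussian simulator integrates the log-populations, where Stratonovich
multiplicative noise is exactly additive, with a Heun predictor-corrector
drift step and per-step N(0, D·dt) increments.

Inner loops are numba-compiled; trajectories are thinned to ≤ 1e6 stored
points per sample, and ergodic histograms weight stored samples equally
(uniform sampling interval). Identical configuration + seed reproduces
trajectories bit-for-bit (per-sample seeds are `seed + i`).

Problem sizes: the package's desk-scale default is 5e4 time units per
sample at dt = 5e-3 with 8 samples and 1e3 burn-in, which resolves the
stationary marginals to L1 ≈ 0.03–0.05 against the analytic solution in
well under a minute. A `paper_scale` profile (4e8 units at dt = 1e-3,
triangular scheme) is provided for archival high-accuracy runs; it is
orders of magnitude slower and is not exercised by the test suite.
Burn-in and the equilibrium initial condition are this package's
choices.

The distributed-delay validator integrates the unreduced model with the
exponential kernel via the linear chain trick (`ż = (x₁ − z)/γ`), checked
against direct quadrature of the convolution and against the reduced
model: at ε²γ = 0.1 the reduced trajectories track the chain system to a
few percent over several cycles, consistent with an O(γ²) reduction
error.

## What the validation does and does not show

The Monte Carlo exercises the *reduced* stochastic model (delay already
collapsed to its first moment), so simulation-vs-analytic agreement validates the
averaging, truncation and perturbation steps — not the delay reduction
itself, which is only validated deterministically (chain-trick tests) and
for small γ. Synthetic pulse amplitudes are Gaussian; other amplitude
laws would change the fourth-moment coefficients (extension point, not
implemented). All quantitative agreement statements are at the reference
parameter scale (ε = 0.1, intensities ≈ 0.0075–0.02); for strong noise or
ε approaching 0.5 the perturbation solution degrades (watch the
clipped-mass diagnostic) and the far tail of p(r) is dominated by the
correction term — the derivate-moment expansion is asymptotic, not
convergent, in the tail.

## Known limitations

- Only the exponential delay kernel is implemented for the validator; the
  humped kernel `4t·e^{−2t/γ}/γ²` is documented but not simulated.
- No transient (time-dependent) GFPK solutions; stationary only.
- The upper admissible K is not bounded a priori; `find_orbit` exposes
  `max_K` but no default bound is imposed (positivity of the level-set
  domain for large ε⁴sγ is unexplored).
- No parameter inference, stochastic-stability/Lyapunov analysis, or
  variance-reduction techniques.
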