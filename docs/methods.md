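# Methods

## Model family

All three formulations describe the same physics: proliferating tumor mass
`u` grows by the Simeoni law and is damaged by the drug at rate
`k_out = η·C·u`; damaged mass `y` no longer proliferates and dies after a
random residence time with density `f`.  The master equation is

    u' = k_in(u, w) − k_out(C, u)
    y' = k_out(C, u) − (k_out * f)(t),          w = u + y,   y(0) = 0,

with `*` a convolution over the damage history.  Three residence densities
are implemented:

- **Point delay** `f = δ(· − T)`: the convolution collapses to
  `k_out(t − T)` and the system is a DDE.
- **Erlang(n, k1)**: by the linear chain trick the convolution system is
  exactly equivalent to the classical transit chain
  `y1' = k_out − k1 y1`, `yi' = k1(y_{i−1} − y_i)`, with `w = u + Σ yi`.
- **Mittag-Leffler(α, τ)** with survival `S(t) = E_α(−(t/τ)^α)`: the
  convolution term becomes `τ^(−α) D^(1−α) y` (a Caputo derivative), giving
  the fractional TCM.  At `α → 1` this degenerates to the exponential
  residence time, i.e. the Erlang chain with `n = 1`, `k1 = 1/τ`.

The convolution form is retained as a *validation oracle*: the chain and the
fractional system are independently integrated and must agree with it (the
package's equivalence tests enforce ≤1e−3 g and ≤1e−2 g sup-norm agreement
respectively at h = 2⁻⁸ over the 60-day study window).

### Semigroup rewrite

The fractional TCM mixes an ordinary and a fractional derivative in one
equation, which standard fractional steppers cannot consume.  Introducing
the latent state `z = D^(1−α) y` (with `z(0) = 0`, forced by `y(0) = 0`) and
using the semigroup property `y' = D^α(D^(1−α) y)` — valid here because both
derivatives are continuous — yields the multi-order system

    u' = k_in − ηCu                (order 1)
    D^α z = ηCu − τ^(−α) z         (order α)
    y' = ηCu − τ^(−α) z            (order 1)

Concretely we integrate `y` as an order-1 state driven by the same
right-hand side as `D^α z`; the observable total is `w = u + y` (the latent
`z` is bookkeeping, not mass — this is the one place the formulation is
ambiguous and we resolve it in favour of `w = u + y`).

## Parameters, units, defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| λ₀ | exponential-phase growth rate | day⁻¹ | 0.25 |
| λ₁ | linear-phase growth rate | g·day⁻¹ | 0.4603 |
| φ | growth-switch sharpness | – | 20 (warn below 10) |
| w₀ | implant mass | g | 0.0121 |
| η | drug potency | ml·(10⁴ ng)⁻¹·day⁻¹ | 0.37847 (Erlang) / 0.24657 (fractional) |
| k1, n | transit rate / chain length | day⁻¹, – | 0.54379, 4 |
| α, τ | ML order / time scale | –, days | 0.945, 3.6852 |
| k01,k21,k12,V | PK rates / volume | day⁻¹, ml | 1.6, 0.2353, 0.1699, 1028 |
| h | solver step | days | 2⁻⁸ ≈ 0.0039 |

### The concentration unit

The PK module reports plasma concentration literally as `C = q1/V` in ng/ml
(peak ≈ 4.4·10⁴ ng/ml for a 4.5·10⁷ ng/kg bolus).  Taken at face value with
potencies of order 0.25–0.38, the kill rate `ηC` would be ~10⁴ day⁻¹: the
proliferating pool would underflow within minutes of the first dose, no
regrowth after the dosing window would be possible, and any explicit scheme
at h = 2⁻⁸ is unstable.  The reference potencies are dynamically consistent
only if `C` enters the PD terms in units of 10⁴ ng/ml (10 µg/ml) — then
`ηC ≲ 1.7 day⁻¹`, the tumor regrows shortly after dosing stops, and η sits
naturally inside the fit bounds [0, 1] / [0, 10].  The package therefore
fixes `CONCENTRATION_UNIT = 1e4 ng/ml` and couples every model to
`C(t)/CONCENTRATION_UNIT`; η carries the reciprocal unit.

## Numerics

**Mittag-Leffler evaluation.**  `E_{α,β}(z)` on the real line uses the power
series for `z ∈ (−1, 1]` (cancellation < 1 digit there), the closed form
`e^z` at α = 1, and otherwise the spectral integral representation with the
substitution `u = r^{1/α}`, integrated adaptively with breakpoints across the
near-Lorentzian peak that forms as α → 1 (the kernel's complex poles pinch
the real axis).  Accuracy is ≥10 significant digits for α ≥ 0.25 on
z ∈ [−50, 1], verified against arbitrary-precision series summation and the
`E_{1/2}(−x) = e^{x²}erfc(x)` closed form; accuracy degrades gradually for
smaller orders, far below the delay model's working range.  The two-parameter
function (β = α) exists to evaluate the ML *density* stably; the density
diverges as `t^{α−1}` at `t → 0⁺` and is never evaluated at 0.

**Fractional solver.**  The multi-order Adams–Bashforth–Moulton PECE scheme
advances each state with the product-rectangle predictor and
product-trapezoid corrector of its own order while the right-hand side
couples all states.  One corrector pass by default (the cited solver's
convention; configurable — the reference does not state its iteration
count).  Order-1 states collapse exactly to classical trapezoidal PECE and
their history sums are maintained incrementally (O(N)); fractional states
keep full memory (O(N²)), the correct default at ~15k steps; no short-memory
truncation is applied.  Benchmarks: max error < 1e−3 against
`E_α(−t^α)` over [0, 5] at h = 2⁻⁸ for α ∈ {0.3, 0.5, 0.7, 0.9}; empirical
convergence order ≈ 2 for smooth order-1 problems and ≥ 1 for fractional
relaxation.  Time-dependent forcing (the PK concentration) is evaluated at
grid nodes only, so the simulate wrappers pre-tabulate `C` on the grid.

**PK closed form.**  Between boluses the two-compartment system is linear
autonomous and is propagated by eigendecomposition (scipy `expm` fallback for
a degenerate spectrum); boluses are right-limit jumps of `q1`, so `C` is
right-continuous and an observation at a dose time sees the post-dose value.
This gives the TCM solvers an interpolation-free `C(t)` at arbitrary nodes
and avoids nested-solver error coupling.  Validated against adaptive
integration to <1e−6 relative.

**Convolution quadrature.**  The oracle integrates `y' = k_out − (k_out*f)`
with Heun stepping; the convolution uses product-trapezoid weights with the
*exact* density mass per subinterval, `m_j = S(t_j) − S(t_{j+1})`, which
absorbs the `t^{α−1}` singularity of the ML density analytically (the first
subinterval's mass is computed from the survival difference, never from a
density sample).

**Growth switch.**  `k_in`'s switch factor `[1+(λ₀w/λ₁)^φ]^(−1/φ)` is
evaluated in the log domain (`logaddexp`), so φ = 20 (or 80) cannot
overflow at large masses.

**Estimation.**  Bounded nonlinear least squares (scipy trust-region
reflective) on residuals `w_model(t_n) − D_n`; the model is simulated on the
fixed grid and read at data times by nearest-grid-point lookup (h ≪
observation spacing), keeping the objective smooth and the fit deterministic.
The α upper bound 0.95 reproduces the reference estimation setup even though
the model admits α < 1.  `k` counts free parameters (2 Erlang, 3 fractional),
matching the AIC arithmetic.  Compartment-count selection breaks RMSE
near-ties (< 1e−6 relative + 1e−4 g absolute) toward smaller `n`; the
absolute floor matters when the delay is unidentifiable (no treatment
effect) and all RMSEs are numerically zero.  In the subset experiment the
refit model is scored against the *full* dataset (the natural reading of the
data-amount analysis; scoring against the subset alone is the alternative),
and subsets with no more points than free parameters are flagged unreliable.

## Synthetic data

The generator emulates the unpublished ten-point single-mouse design:
implant 0.0121 g at day 0, ten daily boluses of 4.5·10⁷ ng/kg from day 13,
ten observations at days {0, 7, 13, 16, 19, 22, 26, 33, 45, 60} (a package
convention — two pre-treatment, four around the dosing window, four in
regrowth; the real times are not published and are config-overridable), and
optional multiplicative lognormal noise `w·exp(σZ)` — multiplicative because
tumor masses span orders of magnitude and fits are judged on a log scale.
Ground truth, design and seed are stamped into the dataset metadata.

What passing round-trip tests show: the estimation machinery is consistent —
data generated by the model are recovered from the printed starts and
bounds to <1% (Erlang) / <5% (fractional).  What they do not show: anything
about real-data misspecification (inter-animal variability, measurement
schedules, model error); the generator produces exactly the model's own
dynamics.

## Sensitivity analysis

LHS is stratified per parameter (one draw per probability stratum of width
1/n, strata permuted independently across parameters).  PRCC uses average
ranks on ties and correlates rank-residuals after linearly regressing out
the other parameters; coefficients of constant columns are undefined (nan).
Sampling ranges: τ ~ lognormal(mean log 3.685, variance 0.5) as printed;
α ~ uniform(0.5, 0.95) and η ~ uniform(0.05, 0.5) are package assumptions
(the reference states only the distribution families) and are recorded in
result metadata.  Output times before day 13 are degenerate — no drug has
been given, the trajectory is identical for every sample — and are reported
as PRCC = 0 with a flag rather than as noise.  Failed simulations would be
excluded listwise with a count (none occur under the default ranges).
Desk-scale default is n = 200 samples; n = 3000 mirrors the reference run.

### Delay-robustness sweeps and the α regime

The robustness readout is the time of the post-treatment minimum of `w`
(nadir).  Increasing τ delays the nadir monotonically across the whole
working range.  For α the direction depends on the regime: in the
near-exponential regime α ∈ [0.85, 1) — the neighbourhood of the fitted
α = 0.945 — decreasing α monotonically delays the nadir, because the
heavier tail keeps damaged cells alive longer.  For α well below ~0.8 the
ML density's `t^{α−1}` mass near zero makes the *bulk* of damaged cells die
sooner, and the nadir-time readout is no longer monotone in α (it peaks
around α ≈ 0.8 at the fitted η and τ).  The robustness default therefore
sweeps α ~ uniform(0.85, 0.999), i.e. perturbations around the fitted value;
the non-monotone global structure is a genuine property of the model worth
knowing when interpreting "smaller α = longer delay".

## Problem sizes

Default runs use h = 2⁻⁸ over [0, 60] days (~15 400 steps; the full-memory
fractional state makes one simulation O(N²) ≈ 10⁸ multiply-adds, ~1 s).
Unit tests use coarser grids (2⁻³–2⁻⁶) where only self-consistency is at
stake; the acceptance tests run the benchmarks, equivalences, recovery and
a 200-sample PRCC at the full reference scale.

## Known limitations

- Orders α ≥ 1, adaptive stepping, and stiff/implicit fractional schemes are
  out of scope; the explicit scheme requires `ηC·h ≪ 1` (comfortably true in
  the working unit convention).
- The ML evaluator is real-argument only and validated for α ≥ 0.25.
- The exact published tumor measurements are not reproducible (raw data not
  public); all estimation claims are round-trip properties on synthetic data.
- Physical interpretation of α is heuristic (delay shape), and its
  identifiability from ten noisy points is weak — the noisy-fit example
  shows substantial scatter in recovered α at σ = 0.1.
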