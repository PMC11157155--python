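# Methods

## Model formulation

The system is a network of well-mixed compartments exchanging Zn by
first-order fluxes. Compartments have one of four roles: `internal`
(finite mass, dynamic δ), `source` (the diet, with a prescribed δ(t) and
infinite reservoir), `accumulator` (an excreta pool such as feces or urine
whose content passes straight through to a sink, so its δ tracks its
instantaneous input), and `sink` (infinite disposal).

Each flux carries a rate F (µg/day) and a fractionation factor α, stored
as a ratio and reported per mil as Δ = 1000·ln α. Working in delta
notation, the balance for an internal box i is

    M_i dδ_i/dt = Σ_in F (δ_src + Δ_in) − Σ_out F (δ_i + Δ_out),

which is the first-order expansion of exact ratio bookkeeping; the two
agree to O(Δ²/10⁶) (≲ 10⁻³ ‰ for |Δ| ≤ 1 ‰), and `steady_state`
exposes both (`method="delta"` and `method="ratio"`) as a cross-check.
Linearity makes the steady state a direct solve δ\* = −A⁻¹b and the
transient a matrix-exponential problem.

Validity requires the Zn masses themselves to be at steady state: the
package checks Σ influx = Σ efflux per finite box (tolerance 10⁻⁶ µg/day)
and `validate_mass_balance` reports any violation. The "printed" rat
variant deliberately fails this check (see below).

## Timescales

- **Residence time** of a box: mass / total efflux. This is the
  definition that reproduces the reference turnover column exactly
  (e.g. bone 3212 µg / 10.7 µg d⁻¹ = 300.2 d); no ln 2 factor is applied
  even where a half-life label is used upstream.
- **Relaxation times** of the coupled system: −1/eigenvalue of the rate
  matrix M⁻¹A over the finite boxes. These, not single-box residence
  times, govern equilibration: the slowest mode (696.8 d,
  integument-dominated) and the bone-dominated mode (314.4 d) control the
  long tail.

## Numerical integration

`simulate` uses an exponential integrator: with E = exp(A·dt) and
φ = A⁻¹(E − I), the update is x_{n+1} = E x_n + φ b(t_mid). This is exact
for piecewise-constant forcing and unconditionally stable, which matters
because the system is stiff (box timescales span 0.02 d for plasma to
~700 d for the integument). dt = 0.1 d resolves the fastest box;
convergence under dt refinement is covered by tests.

Equilibration progress after a step switch is the signed fractional
approach (δ(t) − δ(0))/(δ(∞) − δ(0)) in percent; non-monotone boxes may
transiently exceed 100%, and `time_to(p)` returns the first crossing.

Sinusoidal responses are measured on a simulated post-transient cycle
(transient = 5× the slowest relaxation time, rounded up to whole cycles),
not from the analytic transfer function: buffering is
100·(1 − peak-to-peak amplitude ratio), phase is the lag of the box's
local maximum behind the preceding diet maximum. A one-pole analytic
formula serves as a cross-check in the tests.

## The rat configuration

Three bundled variants of the 12-compartment, 19-flux rat Zn cycle
(diet source; intestine, plasma, liver, kidney, muscle, RBC, bone,
integument; feces and urine accumulators; waste sink):

- `rat_printed`: the flux table as originally printed. It is mass-
  imbalanced (plasma +673 / muscle −673 µg/day) because the
  muscle→plasma flux is given as 900 µg/day while muscle influx is
  227 µg/day.
- `rat_balanced`: the printed table with muscle→plasma corrected to
  227 µg/day (the unique value consistent with the muscle residence time
  of 8.6 d and mass 1960 µg). Baseline for the sweep.
- `rat_fitted_final`: `rat_balanced` with the calibrated parameters: bone
  exchange 3212/300.2 ≈ 10.70 µg/day each way (bone residence 300.2 d),
  plasma→integument 4 µg/day, intestinal-absorption fractionation split
  ±0.025 ‰ across the intestine⇄plasma pair, integument uptake −0.30 ‰,
  urinary α = 1.00044. Its steady state falls within every observed
  confidence interval.

Fractionation factors are stored in the YAML as α ratios with enough
digits that fixed spacings (liver = plasma − 0.84 ‰,
RBC = plasma + 0.10 ‰) hold exactly.

The observation table ships as CSV (`compartment, delta66Zn,
ci_halfwidth, n, excluded`): eight constrained compositions plus kidney,
which is recorded but excluded from fitting (its CI is a conservative
0.2 ‰ placeholder in the source data and the box is used as a free
check).

## Sweep and fit

The fit is a grid sweep plus confidence-interval membership — no
continuous optimisation, because the acceptance region (not a point
estimate) is the result. Default axes:

| axis | kind | range | points |
|---|---|---|---|
| intestinal absorption Δ (split ± across the pair) | fractionation | −0.30 … +0.30 ‰ | 25 |
| integument uptake Δ | fractionation | −0.50 … 0 ‰ | 11 |
| urinary Δ | fractionation | 0 … 1 ‰ | 11 |
| bone exchange flux | flux (log) | 1.1 … 231.1 µg/d | 15 |
| integument flux | flux (log) | 4 … 180 µg/d | 15 |

Grid step choice: the RBC observation (CI ± 0.03 ‰) combined with the
≈1.94 ‰/‰ leverage of the absorption amplitude on plasma confines the
accepted band of that axis to a width of ≈ 0.035 ‰. A 0.05 ‰ step can
therefore straddle the band without containing a node; the 0.025 ‰ step
used here guarantees at least one node inside any such band. Other axes
use coarser grids, keeping the full product at 680,625 nodes (< 1 s,
vectorised: flux axes rebuild the rate matrix, fractionation axes enter
the right-hand side linearly and are solved as a multi-RHS batch).

Flux axes preserve mass balance by compensation: e.g. raising the
integument loss g lowers plasma→intestine and the fecal through-flow by
the same amount, so every box stays balanced at every node.

A node is accepted iff |predicted − observed| ≤ CI half-width for every
constrained observation. An empty acceptance is a valid result and comes
with per-observation diagnostics (worst violation per node). The
representative set is the coordinate-wise median of accepted nodes,
snapped to the nearest accepted node. Because a balanced exchange flux
does not move the steady state, the bone exchange axis is unconstrained
by compositions alone; `calibrate_switch` filters it against a diet-
switch time series (χ² ranking + CI membership), which separates a
~300 d bone residence from the ~14 d literature alternative.

`renal_sensitivity` quantifies how little the urinary fractionation moves
the steady state (the urine flux is 4 µg/day against a 227 µg/day plasma
throughput, though renal recycling amplifies it ≈ 4×): ≈ 0.012 ‰ plasma
shift at the fitted amplitude 0.44 ‰, ≈ 0.028 ‰ at 1 ‰ — within all
observed CIs, which is why that axis is broad in the accepted region.

## Synthetic data generator

The generator reproduces the study conditions and is the test bed for
the fitting machinery (the per-diet tissue measurements underlying the
original fit are not distributable):

- noise: independent Gaussian per replicate per compartment, SD = half
  the reported CI half-width (CIs are 2·SE with the study's replicate
  counts); reported CI = 2·sd/√n. No covariance model exists to support
  anything richer.
- replicate counts mirror the small study groups (1–5).
- diet groups: supplier +0.42 ‰ (reference), lucerne −0.30 ‰, and five
  other feeds spanning the qualitative ordering of the source study
  (−0.09 … +0.50 ‰); exact non-reference values are conventional
  defaults, chosen once, since only the supplier feed value is published
  in the main text.
- switch series: steady state on the reference diet, step switch at day
  0, sampling at chosen days within the 54-day experiment.
- `random_model` builds small balanced networks by construction
  (through-flow chain + symmetric non-adjacent exchange pairs) for
  property tests against a brute-force stiff-ODE oracle.

An optional between-individual random effect is off by default: no
estimate of it exists separately from growth effects, which are out of
scope (growth dilution of body Zn is an acknowledged limitation of the
underlying model).

## Limitations

- Delta-notation linearisation: errors grow as Δ²; keep |Δ| ≲ a few ‰.
- Constant masses and fluxes: no growth, no homeostatic regulation of
  flux rates in response to Zn status.
- The accumulator treatment makes feces/urine δ track their inputs
  instantaneously; gut transit time is not modelled.
- Mode-to-box attribution of relaxation times is by dominant eigenvector
  component; for strongly mixed modes the label is indicative only.
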