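# Methods

## The model

The package implements a dimensionless mass-action model of the AppA/PpsR
redox switch that controls photosynthesis (PS) gene expression in
*Rhodobacter sphaeroides*. Five species are tracked: free reduced and
oxidized AppA (`a`, `b`, in units of total PpsR), free oxidized and reduced
PpsR (`p`, `r`, fractions of total PpsR) and the AppA–PpsR₂ complex (`c`,
one AppA and two PpsR units per copy). The reactions are

* AppA redox cycling: reduction `b → a` at unit rate (time is measured in
  AppA-reduction units), oxidation `a → b` at rate `O`, the oxygen
  concentration in units of K_O = k_Ar/k_Ao (μM);
* PpsR reoxidation `r → p` at rate `α·O`;
* electron transfer AppA_red + PpsR_ox → AppA_ox + PpsR_red at rate `β`,
  with reverse rate `β/K_eq` (`K_eq = ∞`, the default, zeroes the reverse
  term via a sentinel rather than a large float);
* complex formation `a + 2r → c` at rate `δ` (bimolecular in reduced PpsR,
  encoding the 2:1 stoichiometry) and blue-light-driven dissociation
  `c → a + 2r` at rate `δ·I`.

Two conservation laws hold exactly (`a+b+c = γ`, `p+r+2c = 1`); all steady
state and stability work is done on the reduced `(a, r, c)` system. Because
`δ` multiplies both complex fluxes, the steady-state complex condition
`c = a·r²/I` is δ-free: steady states are independent of `δ`, which the
test suite checks to 1e-8 across three decades.

Two structural consequences worth knowing:

* **Throughput bound.** At steady state every PpsR-reoxidation event is
  undone by one electron transfer that consumes one reduced AppA, so the
  oxidized-AppA balance forces `b = O·a + α·O·r` and hence
  `α·O·r ≤ γ`: the free reduced PpsR pool shrinks at least like 1/O. This
  bound caps how far into the oxygen axis the complexed (anaerobic-like)
  branch can survive.
* **Scaling quasi-degeneracy.** Scaling `(I, α, γ)` jointly by λ while
  scaling `(a, b, c)` by λ maps steady states onto steady states up to the
  `I·c` dissociation term; in the strong-sequestration regime the free
  PpsR pools — and therefore the predicted expression — are nearly
  unchanged. The λ=10 copy of the default parameter set reproduces the
  default expression curve to ~1e-3 a.u. Parameter-recovery experiments
  must avoid this direction (see below).

Default parameters (`I=0.001, α=6, β=500, γ=2.1, δ=1, K_eq=∞`,
`PpsR_total = 100 nM`) are the combination that best recapitulates the
combined microarray data; `I` is small because the underlying cultures grew
in the dark or under low white light.

## Promoter output

Free PpsR pools (nM, converted via `PpsR_total`) drive *pucB* transcription
through Hill functions with in-vitro constants: EC₅₀ 31 nM / Hill 4.1 for
the oxidized form, EC₅₀ 69 nM / Hill 3.4 for the reduced form, maximal
expression M_max = 5.1 a.u. Five binding cases are provided (ox-repressor;
red-repressor; red-activator; both repress; ox represses + red activates).
Mixed cases combine the two Hill terms multiplicatively — the
independent-site approximation; the true combination rule for the
two-site promoter is not experimentally constrained, and an additive rule
would change case-iv/v outputs at intermediate occupancy. Concentrations
feed the Hill terms in nM because the EC₅₀ values are printed in nM.

`hill_fit` estimates `A·xⁿ/(K_dⁿ + xⁿ)` by bounded trust-region least
squares multi-started over log-spaced K_d (spanning the data) and Hill
coefficients in [0.5, 8]; unweighted residuals.

## Normalization of expression tables

MAS 5.0 values are comparable within a series only. Each sample's relative
expression is mean(pucB probes 1194–1198) / rpoZ probe 2587; samples are
grouped by exact (oxygen %, light intensity, light colour) with the n−1
sample SD (singleton groups get SD 0 and are excluded from fitting, with a
logged warning). Probe aggregation is the arithmetic mean (the aggregation
used for the original five-probe set is not recorded anywhere; the mean is
the symmetric default). A reference-stability check reports per-condition
and across-condition coefficients of variation (population SD over mean;
the convention is fixed by the worked examples in the test suite) and flags
a reference gene whose across-condition CV exceeds 0.3 — the threshold is a
design choice sized so a mild 10% drift passes and a doubling fails.

## Oxygen calibration and fitting

Percent O₂ of the sparging gas maps linearly to dimensionless O with
30% ↔ O_max = 30. Combined with an aerobic dissolved-oxygen window of
200–380 μM this implies K_O between 6.7 and 12.7 μM (values reported to one
decimal). The fitting objective is the variance-normalized SSE,
`Σ_j Σ_i (y_i − Y_j)²/σ_j²`, with σ_j the per-level n−1 SD; predicting each
level's mean gives exactly `Σ_j (n_j − 1)`, which the tests use as an
algebraic anchor. Estimation is by exhaustive Cartesian grid search with
deterministic tie-breaking; failed grid points carry `nsse = ∞` and do not
abort the scan. Predictions follow the steady-state branch continued from
the anaerobic (O = 0) solution — the deterministic choice when the system
is bistable; past a fold the prediction jumps to the attractor reached from
the pre-fold state (the aerobic-continued branch can be explored by
sweeping downward instead).

The aerobic threshold operation reports the smallest grid O at which free
oxidized PpsR reaches 50% of total. With the default parameters this
crossing sits at O ≈ 3.3 (a direct consequence of the throughput bound
above), which is where the model's expression transition lives on the O
axis.

## Continuation and bistability

Steady-state branches in O are traced by pseudo-arclength continuation:
secant predictor, Newton corrector on the arclength-augmented system,
adaptive step in [1e-4, 0.5] with rejection of steps whose corrector lands
far from the predictor or bends the path sharply (such steps are the
classic branch-jumping failure near sharp folds — with `I ~ 1e-3` the folds
here are sharp). Folds are bracketed by ΔO sign reversals and refined by
Newton on the extended fold system `F = 0, J·v = 0, ‖v‖ = 1`; a refined
fold must carry a critical eigenvalue within 1e-6 of zero. Fold locations
move by < 1e-5 when the initial step is halved. Bistability is declared
when at least two folds bound an interval in which two distinct stable
states exist (verified by Newton from both branch segments and
cross-checked in the tests by direct integration from two initial
conditions). The engine is generic over one-parameter vector fields and is
exercised on the fold normal form `ẋ = μ − x²` where the fold location is
known exactly.

With the default α, γ, I, fold pairs appear for β ≳ 150: β = 100 is
monostable while β = 500 and β = 1000 carry fold pairs ([1.96, 3.10] and
[1.51, 3.08]); the alternative fit (α=3.8, β=800, γ=2.15) is bistable with
folds at [2.68, 4.45]. Root enumeration by seeded multistart confirms the
coexisting stable states independently of the continuation engine.

## Steady-state solving

Primary path: damped Newton on the reduced 3-variable ODE residual with the
analytic Jacobian (residual target 1e-10). At large β the raw residual
multiplies roundoff by β and Newton's basin collapses; the solver then
switches to Newton on the eliminated algebraic system in `(a, r)` (with
`c = a·r²/I`, `p = αOr/(βa)`), which is well-scaled, and finally to
integration toward the attractor (LSODA on the reduced system at moderate
tolerances) with Newton polishing. Stability is classified from the reduced
Jacobian's eigenvalues with a 1e-9 margin; marginal states raise an error
in strict mode rather than silently classifying. `ensure_stable` makes the
solver reject saddles and return the attractor reached from the initial
state — the semantics prediction code needs just past a fold.

## Synthetic data

The generator emulates the structure of the combined public microarray
dataset: six oxygen levels {0, 1, 3, 5, 10, 30}% (0, 3, 10, 30 mirror named
experimental conditions; 1 and 5 fill the semi-aerobic range), anaerobic
cultures under 10 and 100 W/m² white light, one 10%-oxygen blue-light arm,
a condition-independent reference probe, and heteroscedastic multiplicative
lognormal noise whose CV interpolates log-linearly in oxygen percent from
0.4 at 0% O₂ down to 0.05 at 30% (variance largest at low oxygen, as in
the real data). Reference values are lognormal around 500 (MAS5 scale,
CV 0.1). Blue-light conditions are evaluated at elevated irradiance
(I = 1 by default); white-light intensity effects are outside the redox
model and are deliberately not emulated — synthetic 10 and 100 W/m²
anaerobic arms share a mean. Everything is reproducible from a single seed.

What passing tests on synthetic data do not show: real cross-series batch
effects beyond a sample-level reference ratio, probe-specific biases,
non-lognormal outliers, and any light-intensity dose response. Conclusions
about those require the real tables.

## Problem sizes and numerical defaults

Tests run the recovery scan on a 162-point grid (4 replicates per level at
low noise), the Hill-fit calibration on 200 seeded replicates of 12-point
isotherms, and continuations with h₀ = 0.01 over O ∈ [0, 40]; the whole
suite completes in a few minutes on one core. Integrator defaults:
LSODA, rtol 1e-9 / atol 1e-11 for trajectories (conservation drift < 1e-7
enforced on every reported state), looser (1e-7/1e-10) inside the
relaxation fallback where Newton polishes the endpoint.

## Known limitations

* The reaction network is a reconstruction from the published scheme and
  parameter semantics; the throughput bound above places its expression
  transition and its 50%-oxidation point at O ≈ 3 rather than near the top
  of the experimental oxygen range, and bistability onsets near β ≈ 150.
  Quantities tied to the absolute O-scale of the transition should be read
  with that in mind.
* Only steady states are compared to data; no transient information is
  used, and the blue-light photocycle is reduced to a single irradiance
  parameter.
* The AppA–PpsR₂–DNA ternary complex and white-light inhibition are not
  modelled.
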