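# Methods

## Steady-state chain model

The core object is a two-enzyme pathway segment S1 →(E1)→ S2 →(E2)→ S3 in
which every pool is at steady state. The full flux balance (module
`invivokin.chain`) is

    E10·(k2·S1/K_M1 − k−1·S2/K_M2′) / (1 + S1/K_M1 + S2/K_M2′)
      = E20·(k4·S2/K_M2 − k−3·S3/K_M3) / (1 + S2/K_M2 + S3/K_M3)

with K_M2′ and K_M3 the affinities of each enzyme for its *product*. When
those are large (products rebind negligibly) the balance collapses to the
closed form S2 = A·S1/(B + C·S1) with A = k2·K_M2·E10, B = k4·K_M1·E20,
C = k4·E20 − k2·E10, and for Hill-like enzymes (exponents m, n) to
S2 = (A·S1^m/(B + C·S1^m))^(1/n).

Numerical and design choices:

* **Root finding (reversible balance).** The net-production residual is
  strictly decreasing in S2, so any sign-changing bracket contains exactly
  one root. We grow the bracket by doubling from max(K_M2, S1) and solve
  with Brent's method (relative tolerance 1e-14, capped at 200 iterations);
  on a monotone residual this has the same global-convergence guarantee as
  bisection and converges faster. S1 = 0 with no downstream product short-
  circuits to S2 = 0.
* **Exhausted capacity.** For C < 0 the closed form is physical only for
  S1 < −B/C (upstream flux below the downstream limiting rate); beyond that
  a `NoSteadyStateError` names the critical S1. No "clamped" value is ever
  returned.
* **Parameter convention.** `EnzymeParams.k_m` is always the
  half-saturation *concentration*; the constant appearing next to S^m in
  the denominators is k_m^m. At m = 1 the two coincide, so the MM and Hill
  forms nest exactly.
* **Units.** All chain computations are unit-agnostic (absolute µM or
  WT-normalised relative units); containers carry a `unit` tag and only
  ratios and shapes are interpreted across strains.
* **Apparent cooperativity.** Local log–log slopes d ln S2/d ln S1 use
  central differences (one-sided at the ends). The low-S1 slope of a Hill
  chain equals m/n analytically; the "fitted" apparent exponent instead
  refits the whole curve with the 3-parameter Hill law. For the (m, n)
  cooperativity grid the chain uses gently unbalanced capacities
  (downstream/upstream = 1.25) and the rising flank S1 ∈ [0.01, 1]·K_M:
  with strong downstream saturation in view, least squares in linear y
  inflates the fitted exponent of even non-cooperative (m = n) curves,
  because the tail of the chain curve saturates faster than any Hill
  function. On the flank the fitted exponent tracks m/n and the
  cooperativity criterion (fitted exponent > 1.05) agrees with m > n on
  the whole grid.

## Fractal kinetics

Under diffusion limitation the bimolecular rate constant decays as
k(t) = k0·t^(−h), 0 ≤ h < 1. For a dimerisation the decay integrates in
closed form (1/A = 1/A0 + k0·(t^{1−h} − t0^{1−h})/(1−h)); eliminating time
from the long-time asymptote A = (1−h)/(k0·t^{1−h}) gives rate = −k*·A^α
with α = 2 + h/(1−h). The effective-order estimator resamples the late-time
half of a trace log-uniformly (the asymptote neglects 1/A0, so early times
are excluded), differentiates by central differences and regresses
ln(−dA/dt) on ln A. Defaults: integration starts at t0 = 1e-6 time units
(the rate constant is singular at t = 0 for h > 0; t0 is configurable via
the time grid), late-time window = last 50% (configurable
`late_fraction`). Units of k0 depend on h and are treated as opaque but
consistent. Applied to substrate binding, the same argument yields
v = k2·E0·S^n/(K_M* + S^n): an apparent Hill law whose exponent reflects
the fractal dimension of the substrate's medium, not allostery.

## Fitting machinery

* **Models.** MM `v = vmax·x/(k_m + x)`; 3-parameter Hill
  `y = amp·x^n/(k_half^n + x^n)` with zero baseline and n bounded to
  [0.1, 10]; 4-parameter log-logistic
  `y = bottom + (top − bottom)/(1 + (x/ic50)^slope)` for inhibitor
  dose–response, whose fitted midpoint is reported as the apparent K_I
  (no Cheng–Prusoff correction — the operational constant is the sigmoid
  midpoint). The Hill K is recorded both as k_half and as
  k_m_apparent = k_half^n.
* **Optimisation.** Unweighted bounded trust-region least squares
  (no weighting scheme is assumed for the relative-abundance data), 8
  multi-starts for Hill (2 log-spaced k_half × exponents {0.5, 1, 2, 4}),
  6 for the 4PL, 4 for MM; ftol 1e-10 on the SSR. Starts that stall on the
  iteration cap are kept as flagged fallbacks; a fit error is raised only
  when every start fails. Degenerate inputs (all-zero response, flat
  dose–response) return flagged non-identifiable results instead of
  numbers that look meaningful.
* **Model comparison.** Extra sum-of-squares F-test,
  F = ((SSR_n − SSR_f)/Δp)/(SSR_f/(N − p_f)), preferring the fuller model
  at p < 0.05. Nesting is enforced: if the Hill SSR exceeds the MM SSR the
  Hill model is refitted from the MM solution with exponent 1.
* **Initial rates.** OLS slope over points with t ≤ window (default 20 s);
  consumption traces report the slope magnitude, with the OLS standard
  error.
* **Curve assembly.** One point per (strain, condition, dose, timepoint,
  replicate) key with both metabolites detected; replicates are never
  averaged; keys with a censored member are excluded (no imputation) and
  counted in a logged warning. Points partition by *dTMP* supplementation;
  thymidine-supplemented conditions count as unsupplemented because
  salvage-derived dTMP is still produced intracellularly and stays on the
  cooperative curve.

## Synthetic-data generator

The generator (`invivokin.synth`) emulates the targeted relative-
quantification time course the analysis consumes: strains WT, W133V and
I91L+W133V with expected dTMP fold-drops 1.0/0.5/0.1; timepoints 2, 4, 6,
8 h; 3 biological replicates; multiplicative lognormal noise with CV 0.25
(the study reports SEM of ≥3 replicates but no error model; 0.25 is a
realistic LC-MS between-replicate CV and is configurable); relative
detection limit 0.005. Expected product levels come from the steady-state
chain itself: upstream Hill exponent 2.5 without external dTMP, 1.0 with
it (the regime switch is a config-level rate-law choice; the diffusion
mechanism is not simulated), downstream exponent 1, equal half-saturation
constants at 0.6 of the WT substrate anchor, downstream/upstream capacity
ratio 2. Supplementation arms raise the expected substrate linearly with
dose (1.0 per mM for dTMP, 0.4 per mM for thymidine over doses 0.25–5 mM),
spanning both flanks of the curve as in the original design.

Calibration to the reported anchors: expected dTDP ratios are 0.0088 for
the double mutant (the reported "1% or less") and 0.37 for W133V (reported
0.20). No single Hill-2.5 curve passes through both printed dTDP anchors
exactly; the chosen half-saturation favours the double-mutant anchor,
which carries the disproportionate-drop claim, and leaves W133V within a
factor of two. dTTP tracks dTDP in expectation (the dTDP:dTTP ratio is
strain-independent) but has a higher *relative* detection limit (0.02):
the instrument limit is absolute, and dTTP's lower absolute abundance
means the double mutant's dTTP falls below it while its dTDP at ~1%
remains measurable — reproducing the censoring pattern of the original
data. Censoring is strict (`value < limit`), idempotent, and censored
records store the limit itself.

Randomness: one seed per run; each design cell draws from an independent
substream keyed by CRC32 hashes of its labels, so adding strains or
conditions never perturbs existing cells' draws, and tables are
bit-reproducible per seed.

What the generator does **not** emulate: growth-phase drift of metabolite
pools across timepoints (expectations are timepoint-stationary), raw LC-MS
artefacts (matrix effects, drift, missingness beyond the detection limit),
correlated noise between metabolites of one extract, and the salvage
branch's own kinetics. Passing recovery tests therefore demonstrate that
the *pipeline* is unbiased and calibrated under the assumed noise
structure, not that the original measurements satisfy those assumptions.

## Known behaviours and limitations

* Both axes of the in vivo curve are measured with noise; this
  errors-in-variables attenuation biases fitted exponents slightly
  downward (medians ≈ 2.35 and ≈ 0.9 for truths 2.5 and 1.0 at CV 0.25)
  and lifts the F-test's false-rejection rate on the supplemented regime
  mildly above nominal. On clean dose–response data (noise in y only) the
  F-test is calibrated (type-I ≈ 0.04–0.05 at α = 0.05).
* Problem sizes are chosen for tight feedback: recovery studies use 100
  seeds of the 36-point unsupplemented design, the type-I calibration
  1,000 replicates of a 36-point assay, and fractal traces 4,000 points
  over ten decades of time.
* Chains longer than two enzymes, time-course (non-steady-state)
  simulation, thermodynamic Haldane constraints, Bayesian or global
  multi-curve fitting are out of scope.
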