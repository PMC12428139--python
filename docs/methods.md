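# Methods

This note records the models behind `enzkin`, the defaults and why they were
chosen, and what the synthetic-data pipeline does and does not establish
about real measurements.

## Assay speciation

The model is deliberately minimal: one 1:1 metal–ADP binding equilibrium and
one PEP protonation step.

* The complex concentration is the root of c² − (M_t + D_t + K_d)c +
  M_t·D_t = 0 lying in [0, min(M_t, D_t)], evaluated as
  2·M_t·D_t / (S + √(S² − 4·M_t·D_t)) with S = M_t + D_t + K_d.  The
  textbook (S − √…)/2 form subtracts nearly equal numbers when K_d is much
  larger than the concentrations; the reciprocal form is exact in that limit.
  The test-suite checks the closed form against bisection on the mass-action
  residual to 10⁻⁹ mM over wide concentration grids.
* The ionized-PEP fraction is 1/(1 + 10^(pK − pH)) with pK = 6.3 by default.
  At the standard assay pH of 6.5 this is 0.613 — the dominant correction in
  these mixtures.
* Ignored on purpose: ADP protonation, metal–PEP complexation,
  temperature/ionic-strength dependence of K_d, and activity coefficients.
  These are the corrections a full chelator program applies; within the pH
  6.5 / 200 mM regime the 1:1 + Henderson–Hasselbalch model reproduces the
  species the rate laws need.
* Dissociation constants are configuration, never hard-coded physics.  The
  shipped example (`data/binding_constants.yaml`: K_d(MgADP) = 0.25 mM,
  K_d(MnADP) = 0.10 mM) carries representative literature-scale values for
  ~0.1–0.2 M ionic strength; every test supplies constants explicitly so no
  default is load-bearing.
* Ionic strength uses I = ½ Σ cᵢzᵢ² over the five modelled pools plus a
  single pre-computed buffer contribution; the balancing species is an inert
  1:1 salt, so the required addition is exactly target − I_current, and a
  mixture already above target is reported infeasible with the excess.

Concentrations are mM throughout the package; molar units appear only inside
the log-efficiency computation.

## Rate laws and derived constants

Velocities are specific activities (µmol·min⁻¹·mg⁻¹) end to end.  The
turnover number is a derived view:

    kcat [s⁻¹] = Vmax [µmol·min⁻¹·mg⁻¹] × M(catalytic unit) [g·mol⁻¹] / 60 000

The catalytic unit defaults to the homotetramer (`THA_PK_MASS`: 4 ×
(59 147.48 + 2 193.26) Da ≈ 245.36 kDa, the His6-tagged monomer that could
not be cleaved).  The tetramer basis is what reconciles the wild-type
specific activities with their published turnover column (77 → 315 s⁻¹; a
monomer basis would give 79 s⁻¹); the mass model is an explicit argument so
other bases can be explored.  Not every published kcat row is consistent
with a single conversion — the tests pin only the self-consistent rows.

Reporting-layer rounding (log efficiencies to 2 dp, kcat and fold changes to
integers) lives exclusively in `io.derived_constants_table`; no internal
computation rounds.

## Fitting

* Objective: unweighted least squares on untransformed velocities.
  Reciprocal-space fitting is intentionally absent — double-reciprocal plots
  are diagnostics, not objectives.
* Positivity by log-parameterization; Hill n bounded to [0.3, 6] and the
  mixed-inhibition α to [10⁻³, 10³] (an α fit pinned at the upper bound is
  operationally uncompetitive).
* Multistart: 8 deterministic starting points per fit, combining vmax guesses
  (1× and 2× the top observed velocity) with K guesses spread geometrically
  around the median concentration (and Ki around the median non-zero
  inhibitor level; Hill starts at n = 1 and 2).  The fit is therefore a pure
  function of the dataset.
* Convergence: scipy `least_squares` (trust-region reflective), ftol 10⁻¹⁰
  on the relative cost change, 500 iterations per start; failure on all
  starts raises a convergence error carrying the best attempt.
* Standard errors come from the Gauss–Newton approximation at the optimum
  (Jacobian mapped back from log space); no bootstrap.
* Bi-substrate and inhibition data are fitted globally — one parameter
  vector across all curves.  Whether the original analyses shared the
  uninhibited (Vmax, Km) with the inhibition fits is not documented; this
  implementation refits all parameters per dataset.
* Identifiability guards are structural, not numeric: single-substrate fits
  need ≥ 4 distinct levels (5 for Hill), bi-substrate grids ≥ 3 levels of
  each substrate (a single fixed co-substrate level leaves K_b
  unidentifiable), inhibition grids ≥ 3 inhibitor levels including zero.
* Model selection: AIC = n·ln(SSE/n) + 2k; candidates within ΔAIC < 2 of the
  minimum resolve to the fewest parameters, so nested alternatives must earn
  their extra parameter.

A property worth knowing: with proportional measurement noise, unweighted
least squares is mildly misspecified (high-velocity points carry more
variance), which fattens the tail of the C-vs-MT likelihood ratio on
competitive-generated data independently of the noise scale.  The
discrimination check in the acceptance suite therefore evaluates the
selection rule over the study's complete four-dataset dead-end suite rather
than a single dataset; the suite verifies the pooled success rate.

## Mechanism rules

`data/mechanism_rules.json` is the entire decision logic — ordered rules
over the four pattern cells plus the initial-velocity geometry, evaluated
first-match-wins, so the table can be audited against Cleland-style pattern
logic without reading code.  Encoded calls: an analog uncompetitive against
its co-substrate places its own substrate upstream (ordered call); both
analogs competitive against their own substrates with no uncompetitive
co-substrate cell, under an intersecting initial-velocity family, yields the
random sequential call; everything else is ambiguous with the violating
cells listed.  Two standing caveats ride along as annotations rather than
changing the call: a B-analog competitive against A suggests shared binding
sites, and dead-end patterns alone cannot distinguish rapid-equilibrium from
steady-state random binding.

An MT fit with |α − 1| < 0.05 is reported noncompetitive (the tolerance is
an argument of `classify_pattern`).  Pattern classification depends only on
K_m, K_i, α — rescaling V_max moves the intersection along 1/v but never
across regions.

## DSC

Two-state van't Hoff model: K(T) = exp[−(ΔH_vH/R)(1/T − 1/T_m)] on absolute
temperatures, Cp_ex = ΔH_cal·ΔH_vH·K/(R·T²(1+K)²).  ΔH_cal (the integral)
and ΔH_vH (the sharpness) are independent knobs: their ratio below one is
the signature of a partially aggregated sample in which only a fraction of
the loaded protein takes part in the cooperative transition.  That is
exactly how the truncated-enzyme endotherm is simulated — its calorimetric
enthalpy is ~20 % of the wild type's while the cooperative unit (ΔH_vH) is
kept at the wild-type value; simulating it with ΔH_vH = ΔH_cal would instead
produce a ~20 °C-wide transition that the 15–100 °C scan window truncates,
which no baseline procedure could integrate to 1 %.

The analyzer subtracts a linear baseline fitted initially through the first
and last 10 % of the grid and then refined by excluding the detected
transition region (provisional |excess| above 0.5 % of the provisional peak)
— without the refinement a transition near either end of the scan window
tilts the line.  T_m is the argmax of the residual excess, ΔH_cal its
trapezoidal integral over the positive part; both windows and thresholds are
arguments.  The suite verifies the simulate→analyze round trip to 0.1 °C and
1 % across T_m ∈ {60, 75, 90} °C and both reference enthalpies, and its
invariance to added linear baselines of slope ±5 cal·mol⁻¹·°C⁻².

Shape flags: `flat` when the peak is below 5× the baseline-window noise;
`inverted_aggregation` when a negative-going lobe preceding the endotherm
exceeds 25 % of the peak (the disaggregation-before-unfolding shape).  The
inverted trace is flagged, not modelled — no Lumry–Eyring kinetics, no
multi-transition deconvolution, and scan rate is metadata only.

The published ΔH unit string ("cal/mol °C") is treated as a typographical
artifact: ΔH here is always cal·mol⁻¹, the integral of Cp dT.  Whether those
published values are calorimetric or van't Hoff is not stated; the analyzer
reports the calorimetric integral only.

## Synthetic data

The generator reproduces the study's experiment designs
(`data/designs.yaml`).  Grids printed level-by-level are transcribed
verbatim; grids printed as ranges are filled with 8 geometrically spaced
levels across the stated range.  Editorial choices, made once:

* Two misprint-suspect levels ship in both readings (see the comments in
  `designs.yaml`): the bi-substrate grid's "0.40" MgADP level (read 0.040 in
  the default preset, matching the 0.0396 of the corresponding inhibition
  series) and the PEP saturation range's lower end "0.57" (read 0.057 —
  levels that all sit 9–24× above K_m cannot support the published
  K_m = 0.066 ± 0.003).
* The AMP inhibition series and the truncated-enzyme saturation grids are
  not printed; the presets bracket the relevant constants (K_i(AMP) =
  3.3 mM; K_0.5 = 3.15 and 0.17 mM) with 0-to-3×K spans, the design a
  kineticist would draw for those constants.

Noise: v = law(S)·(1 + cv·ε) + floor_sd·ε′, ε standard normal from one
seeded generator, replicates drawn independently, optional clipping at zero.
The 2 % proportional default is typical of coupled spectrophotometric
initial-rate assays; it is a stand-in, not a claim about any instrument.
The generating truth travels in dataset metadata under a namespaced key
(`enzkin:truth`) that fitting code never reads — a test verifies fits are
unchanged when it is stripped.

Problem sizes were chosen so the full suite and the acceptance script each
run in about a minute: 100-seed Monte-Carlo panels for recovery (3
replicates per design) and model discrimination, 1000-point speciation
grids, 0.05 °C DSC grids.

What passing does and does not show: the Monte-Carlo suites demonstrate that
the estimation machinery recovers known truths under the stated noise model
on the study's designs.  They do not validate the noise model itself against
real instruments, nor probe systematic errors the generator omits (coupled
LDH/NADH detection lags, enzyme inactivation during the assay, thermal
drift, buffer-dependent K_d shifts).  Real-data conclusions inherit those
caveats.

## Determinism

Every random draw flows from an explicit integer seed (`NoiseModel.seed`,
`RunConfig.seed`, `--seed`); fixed seeds reproduce datasets byte-for-byte,
and fits, pattern calls, and thermogram analyses are deterministic functions
of their inputs.
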