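# enzkin

Steady-state enzyme kinetics for metal-dependent phosphotransfer assays —
built around the characterization of a K⁺-independent archaeal pyruvate
kinase (PEP + MgADP → pyruvate + MgATP), but applicable to any two-substrate
enzyme analyzed with the same toolbox.

The package covers the full quantitative pipeline such a study needs:

* **Speciation** — what you weigh in is not what the enzyme sees.  The
  kinetically active species are the metal·ADP complex and the fully ionized
  PEP³⁻ pool.  `speciation` solves the 1:1 binding equilibrium
  (c² − (M+D+K_d)c + MD = 0, taken at its stable root), splits PEP by
  Henderson–Hasselbalch at pK 6.3, and computes the inert 1:1 salt addition
  (tetramethylammonium chloride) that holds ionic strength at a 200 mM
  target via I = ½ Σ cᵢzᵢ².
* **Rate laws** — Michaelis–Menten, Hill, the rapid-equilibrium random
  bi-bi law

  v = V_max·A·B / (K_a·K_b + K_a·B + K_b·A + A·B),

  and the linear competitive / mixed / uncompetitive dead-end inhibition
  laws, e.g. mixed: v = V_max·S / (K_m(1+I/K_i) + S(1+I/αK_i)).  Derived
  views: k_cat = V_max·M(oligomer)/60 000 s⁻¹, log₁₀(k_cat/K), Q10
  temperature scaling, fold changes.
* **Fitting** — unweighted nonlinear least squares on untransformed
  velocities (double-reciprocal plots are display-only), global across all
  curves of a bi-substrate or inhibition grid, log-parameterized with a
  deterministic 8-start lattice; model competition by AIC with a ΔAIC < 2
  parsimony tie-break.
* **Mechanism diagnostics** — exact double-reciprocal slopes/intercepts and
  their intersections (bi-bi families cross at (−1/K_a, 0); mixed at
  (−1/(αK_m), (1−1/α)/V_max)), plus a rule table (packaged, auditable JSON)
  turning a complete dead-end pattern table into a mechanism call
  (rapid-equilibrium random vs ordered vs ambiguous).
* **DSC** — two-state van't Hoff endotherm simulation and thermogram
  analysis (transition-aware linear baseline, Tm as peak of excess heat
  capacity, calorimetric ΔH as its integral, flags for flat and
  aggregation-inverted traces).
* **Synthetic data** — seeded generator reproducing the study's assay
  designs (concentration grids of the saturation, bi-substrate, and
  inhibition experiments) under a configurable noise model, so the whole
  pipeline is testable without laboratory data.

## Worked example

```python
from enzkin import (AssayComposition, BindingConstants, speciate,
                    NoiseModel, paper_design, generate_velocities,
                    fit_global_bisubstrate, THA_PK_MASS,
                    kcat_from_specific_activity, catalytic_efficiency)

# 1. speciate one reaction mixture (totals in mM, Kd(MgADP) = 0.25 mM)
bc = BindingConstants(kd_metal_adp=0.25)
mix = speciate(AssayComposition(metal_total=1.67, adp_total=0.30,
                                pep_total=1.127, pH=6.5), bc)
print(f"MgADP = {mix.metal_adp:.3f} mM, free Mg2+ = {mix.metal_free:.3f} mM, "
      f"PEP3- = {mix.pep_ionized:.3f} mM, added salt = {mix.balancing_salt:.1f} mM")

# 2. simulate a bi-substrate grid at 2 % noise and refit it globally
noise = NoiseModel(cv=0.02, seed=1)
data = generate_velocities(paper_design("fig4_bisubstrate"), "bibi",
                           {"vmax": 106, "ka": 0.031, "kb": 0.023}, noise)
fit = fit_global_bisubstrate(data)
vmax, ka, kb = (fit.parameters[k] for k in ("vmax", "ka", "kb"))
kcat = kcat_from_specific_activity(vmax, THA_PK_MASS)
print(f"Vmax = {vmax:.1f} umol/min/mg, Ka(PEP3-) = {ka:.4f} mM, "
      f"Kb(MgADP) = {kb:.4f} mM")
print(f"kcat = {kcat:.0f} s^-1, log kcat/Ka = {catalytic_efficiency(kcat, ka):.2f}")
```

prints

```
MgADP = 0.255 mM, free Mg2+ = 1.415 mM, PEP3- = 0.691 mM, added salt = 192.9 mM
Vmax = 105.8 umol/min/mg, Ka(PEP3-) = 0.0306 mM, Kb(MgADP) = 0.0232 mM
kcat = 433 s^-1, log kcat/Ka = 7.15
```

The speciated mixture shows why the correction matters: of 0.30 mM total ADP
only 0.255 mM is the MgADP substrate, and of 1.127 mM total PEP only
0.691 mM is ionized at pH 6.5.  The global fit recovers the generating
constants within the 2 % measurement noise; the turnover number is reported
per tetramer (245.36 kDa).

The same pipeline is scriptable from the shell:

```sh
enzkin simulate --figure fig5a_oxalate --model C \
    --truth '{"vmax": 77, "km": 0.066, "ki": 0.044}' --seed 3 -o oxa.csv
enzkin fit oxa.csv --model C -o oxa_fit.json
enzkin report oxa_fit.json --substrate "PEP3-" -o table
```

See `enzkin --help` for the full surface (`speciate`, `simulate`,
`simulate-dsc`, `fit`, `classify`, `dsc`, `report`).

## Layout

```
src/enzkin/
  speciation.py      equilibrium pools + ionic-strength balancing
  rate_laws.py       rate equations and derived constants
  fitting.py         global least squares, multistart, AIC selection
  mechanism.py       reciprocal geometry + rule-table mechanism calls
  thermal.py         DSC simulation and analysis
  synthetic_data.py  seeded designs + noise model
  io.py, cli.py      CSV/JSON formats, config, click CLI
  data/              design presets, rule table, example constants
docs/methods.md      modelling assumptions, defaults, limitations
```
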