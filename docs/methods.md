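# Methods

## Model

A single cell exchanges lactate with a fixed environment and metabolizes
glucose and lactate through five lumped fluxes. The dynamic variables are
intracellular lactate `L_i`, pyruvate `P` and cytosolic `NADH`; `NAD+` is
derived from the conserved pool `NAD+ = N_tot − NADH` and never integrated,
so pool conservation holds to machine precision by construction. Units are
mM and seconds throughout.

Flux laws (all defined in `lacflux.model`):

| flux | form | rationale |
| --- | --- | --- |
| `J_MCT` | `v_max,MCT·[s(L_e,H_e) − s(L_i,H_i)]`, `s(L,H) = L·H/((L+K_L)(H+K_H))` | symmetric reversible carrier co-transporting one proton per lactate; the proton gradient biases the direction, which is essential for realistic pH effects |
| `J_LDH` | `[LDH]_tot·(k_f·P·NADH − k_r·L_i·NAD+)` | near-equilibrium mass action, linear in the enzyme pool; at the reference state the unidirectional rates exceed the net rate ~30-fold, so the reaction direction is set by the redox state, not by LDH capacity |
| `J_glyco` | `v_max,glyco·Glc/(Glc+K_glc)·NAD+/(NAD++K_NAD)` | lumped glycolysis in pyruvate-equivalents (the 2 pyruvate/glucose stoichiometry is absorbed into `v_max,glyco`); the NAD+ factor stalls glycolysis when the cytosol is over-reduced |
| `J_PDH` | `v_max,PDH·P/(P+K_PDH)` | lumped PDH/TCA entry; proxies oxidative metabolism |
| `J_shuttle` | `k_shuttle·NADH` | first-order mitochondrial NADH re-oxidation (malate–aspartate shuttle); mitochondrial NADH itself is a separate compartment and not modelled |

Balance equations:
`dL_i/dt = J_MCT + J_LDH`, `dP/dt = J_glyco − J_LDH − J_PDH`,
`dNADH/dt = J_glyco − J_LDH − J_shuttle`. Glucose and extracellular
lactate/protons are fixed boundary conditions (no extracellular mass
balance): this is a single-cell model and deliberately excludes glycogen,
ATP/ADP energetics, oxygen transport, two-cell coupling and diffusion.

Steady state implies `J_LDH = −J_MCT`, `J_PDH = J_MCT + J_glyco`,
`J_shuttle = J_PDH`, hence `J_MCT = J_shuttle − J_glyco`: the cell imports
lactate exactly when NADH shuttling outruns glycolytic NADH production.
The oxidative/glycolytic phenotype is therefore controlled by `k_shuttle`
and `v_max,PDH`, and classification (`lacflux.scans.classify_phenotype`)
uses the sign of steady-state `J_MCT` with a dead band of 1e-6 mM/s.

With glycolysis fixed, flux balance alone gives the closed-form
contribution formula `α = γ·r/(1+r)` (fractional oxidative increase α per
fractional transport increase γ at basal supply ratio
`r = J_MCT,0/J_glyco,0`). The regenerated reference grid
(`lacflux.contribution.generate_table1`) rounds each α the way the
published table prints it — two significant figures below 0.10, two
decimals at and above — and assigns the band (below 10% / 10–29% / ≥30%)
from the rounded value. One printed cell (r = 0.1, γ = 0.5: 0.046) is
inconsistent with the formula itself (0.04545 rounds to 0.045); the
package reproduces the formula value and the test suite pins that cell as
the only discrepancy.

An alternative transporter form (`mct_form: simpson_alternative`) drops the
proton coupling (`s(L) = L/(L+K_L)`), for checking that conclusions do not
hinge on the carrier equation as long as the proton gradient is otherwise
respected.

## Reference parameter set and calibration

The bundled `oxidative_reference` config is the basal condition for every
scenario and scan. Fixed anchors: basal oxidative flux
`J_PDH,0 = 0.01 mM/s` (the percent responses are invariant to this scale),
basal supply split 43% lactate / 57% glycolysis (`r = 0.75`), `L_e = 1 mM`,
`Glc = 1 mM` with `K_glc = 0.05 mM` (glucose-saturated), `pH_e 7.4`,
`[LDH]_tot = 3.2 mM` with `k_f = 100 (mM·s)⁻¹` (near-equilibrium),
`N_tot = 0.5 mM` (cytosolic NAD pool).

The remaining constants are identified by `analysis/01_calibrate_reference.py`:
candidate basal targets (L_i, L/P ratio, redox state) and kinetic constants
(K_PDH, K_NAD, K_MCT,L, K_MCT,H, pH_i) parameterize a family in which all
maximal rates and the LDH reverse constant are solved analytically so the
basal steady state is exact; the candidate vector is then fitted by least
squares to the published steady-state responses of the stimulation panels
(oxidative, glycolytic and in-vivo-calibrated cells), with the
physiological windows as bounds. The calibrated cell sits at
`L_i = 0.396 mM`, `L/P = 19.9`, `NADH/NAD+ = 0.068`, `pH_i 7.15` — inside
the constraint windows — and reproduces the worked-example responses to
within ~1 percentage point. Two legend values are not matched to within
2 points by any parameter vector we found (the glycolytic cell's
extracellular-lactate panel, −6.8 points, and the in-vivo
extracellular-lactate panel, −2.1 points); the basal in-vivo supply ratio
comes out 2.34 against the quoted 2.2 (+6.5%). These sit outside the
worked-example set and are reported in `results/calibration_report.csv`.
The cultured-cell glycolytic factor (0.401) is solved separately so the
reference cell at 1.1 mM extracellular lactate settles at r = 3.2; the
5.5 mM and reduced-glycolysis variants then emerge (r = 4.2 and 11.9
against quoted 4.1 and 11.5) rather than being fitted.

Physiological constraint windows (data in the config, not code):
`L_i ∈ [0.3, 1.5] mM`, `L_i/P ∈ [8, 25]`, `NADH/NAD+ ∈ [0.005, 0.07]`.

## Numerics

* **Steady states** (`lacflux.steady_state.solve_steady_state`): Powell
  hybrid root-finding on the 3-dimensional reduced system in transformed
  variables (log concentrations, logit NADH fraction) that keep iterates in
  the physical box; non-convergence falls back to stiff integration
  (LSODA) to t = 1e5 s and re-polishing. Convergence means
  `max |rhs| < 1e-10 mM/s`; results carry the residual. Multi-start from
  five spread guesses (`find_steady_states`) detects multistability and
  flags it; none was observed anywhere in the scanned regions.
* **Scans** (`lacflux.scans.scan_2d`): row-wise sweeps warm-started from
  grid neighbours; a scan fails loudly if >10% of nodes do not converge.
  Iso-curves use scikit-image marching squares with linear interpolation to
  axis coordinates.
* **Integration oracle** (`lacflux.synthetic.integration_oracle`): LSODA at
  rtol 1e-12/atol 1e-14 — an independent brute-force route to the same
  steady states, used to validate the root-finder (agreement < 1e-6 mM on
  100 constraint-respecting sampled parameter sets).
* **Percent changes** are computed on steady-state fluxes (the published
  bars are steady states, not transients) and reported on the release
  magnitude `|J_MCT|` when the basal cell is an exporter. Scenario
  multipliers commute and invert exactly; "glycolysis reduced by 49%/60%"
  is implemented as `v_max,glyco` × 0.51/0.40 (flux-proportional at fixed
  saturation — an approximation, since the NAD+ saturation shifts
  slightly).
* **Frozen glycolysis** clamps `J_glyco` of the stimulated state to the
  basal flux, which makes the contribution formula an exact flux-balance
  consequence; the suite asserts agreement to < 0.1 percentage point over
  random transport-side stimulations.

## Synthetic data and parameter recovery

`simulate_observations` emulates steady-state measurements of
(J_MCT, J_PDH, L_i, P) under stimulation scenarios with multiplicative
Gaussian noise (`observed = truth·(1 + N(0, cv))`, redrawn when a positive
truth would flip sign — measurements of positive quantities carry
scale-proportional error). `sample_parameters` rejection-samples uniform
draws inside stated ranges, keeping sets whose steady state passes the
constraint windows. `recover_parameters` fits free parameters by bounded
least squares with inverse-variance weights (`σ = cv·|observed|`), flags
rank-deficient designs, and reports per-parameter relative errors against
the known truth. The default free pair is (`k_shuttle`, `v_max,PDH`) — the
two phenotype-determining knobs. With 20 random transport/glycolysis
stimulation conditions at 1% noise, 25 replicate fits recover both to a
median relative error of ~0.2% and ~0.05%; zero-noise recovery is exact to
machine precision. All randomness flows through explicit seeds; equal
seeds give bit-identical tables.

What the generator does *not* emulate: correlated measurement error,
systematic calibration bias between flux and concentration measurements,
cell-to-cell heterogeneity within a preparation, and transients. Passing
recovery tests therefore show identifiability of the two knobs under the
stated noise model, not robustness to structured experimental error.

## Problem sizes

The test suite uses a 20×20 grid (400 steady states) for the full
phenotype plane, 6×6 and 5×5 grids in unit tests, 100 sampled parameter
sets for the solver-vs-oracle check, 50 random stimulations for the
flux-balance property, and 25 replicate recovery fits of 20 conditions —
sizes chosen to match the published sweeps where a size is stated (the
400-simulation plane) and to keep each property statistically meaningful.

## Known limitations

* The original supplementary equations and parameter table were not
  available to this implementation; the flux laws above are the package's
  own forms with the published structural features (proton-coupled
  reversible carrier, mass-action LDH, NAD+-limited glycolysis, linear
  shuttle), and the reference parameters are calibrated to the printed
  results rather than transcribed. Quantities far from the calibration
  anchors (e.g. absolute fluxes under extreme pH) inherit this uncertainty.
* PDH carries no explicit mitochondrial NAD+ dependence; whatever
  dependence exists is absorbed into `v_max,PDH`.
* The environment is static: scenarios that would deplete or acidify the
  extracellular space (dense tissue, strong export) are outside scope.
* Band assignment in the contribution table follows the printed rounding,
  so cells at band edges (0.29 vs 0.30) depend on the display convention,
  which is intentional.
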