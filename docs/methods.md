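# Methods

## Model

One protocell is described by the molecule counts of six species:
fatty acids (`fa`, the membrane), FeS-chelating amino acids (`aa1`),
nucleotide-precursor amino acids (`aa2`), sugars (`s`), an energy
currency (`e`) and nucleotide cofactors (`n`).  Between divisions the
counts obey a deterministic ODE; at the division threshold the cell
halves.  Three assumptions frame everything else:

1. **Carbon enters only through CO₂ fixation.**  FeS clusters chelated
   by AA₁ and associated with the membrane reduce CO₂ to an activated
   C₂ unit.  Fe³⁺ and S²⁻ are not rate-limiting, so the cluster pool is
   proportional to the AA₁ count — but clusters act at the membrane,
   and a membrane of `fa` fatty acids offers a finite number of sites.
   The fixation flux is therefore mass-action in AA₁ with a saturable
   membrane-occupancy factor:

       Φ = k_fix · co2 · fa · (ρ/(k_m+ρ)) · (1 + K_CN_eff·[N]),   ρ = aa1/fa.

   For ρ ≪ k_m this is simply proportional to the number of AA₁ (the
   null model operates at ρ* = λ_AA1/λ_FA = 0.75 against k_m = 3, i.e.
   at 20% occupancy).  The saturation matters only when catalysis
   piles amino acids onto a membrane that is not growing — exactly the
   situation in which a protocell should *not* be able to fix carbon
   ever faster, since a fixed membrane cannot host unboundedly many
   clusters.  Without this factor, the division rate reduces to
   `f_AA1 · (growth boost)` identically and no allocation imbalance can
   ever slow growth, contradicting the collapse phenomenology the
   model exists to capture.

2. **Finite carbon is divided among competing branches.**  Each branch
   carries a baseline weight λᵢ (thermodynamic assignments: 0.376 FA,
   0.282 + 0.282 AA, 0.05 S, 0.01 E; they sum to 1).  Nucleotide
   catalysis of branch *i* removes the fraction K_iN of that branch's
   residual kinetic barrier at nucleotide saturation, scaling its
   weight hyperbolically:

       wᵢ = λᵢ / (1 − K_iN·σ),   σ = [N]/(k_sat+[N]),   fᵢ = wᵢ/Σwⱼ.

   This is why catalysis strengths live in [0, 1): K_iN = 1 would mean
   a barrier fully removed.  The form makes "weak" catalysis (0.33) a
   mild ~1.5× weight boost but "strong" catalysis (0.99) an up-to-100×
   boost — the qualitative asymmetry between gentle reallocation and
   pathological flux diversion.  Renormalization enforces the carbon
   budget: more of one species always means less of the others.

3. **Nucleotide synthesis is substrate-limited, not kinetics-limited.**
   Nucleotides condense from AA₂ + S + E (1:1:1 per nucleotide) with
   trimolecular kinetics and a linear autocatalytic boost
   `(1 + K_NN·[N])`.  The default concentration scale (`vol_per_fa`)
   makes the cell concentrated enough that the energy currency — only
   1% of the carbon — is the binding constraint on nucleotide output.
   This is the regime in which catalysing energy production pays while
   catalysing sugar production (5% of carbon, in excess) does not.

**Cost coupling.**  When one cofactor type performs both pathway and
fixation catalysis (α = 1), engagement with pathway substrates competes
with fixation: `K_CN_eff = K_CN·max(0, 1 − α·maxᵢK_iN)`.  The strongest
single engagement sets the cost; with distinct cofactor types (α = 0)
there is none.  The floor at zero is the model's only sanctioned clip.

**Division and inheritance.**  The cell divides when `fa` reaches
`fa_div` (surface area at the critical size; the event is located by
the integrator's root-finder, |fa − fa_div|/fa_div < 1e−6).  The
tracked daughter inherits half of every count; in the stochastic
variant each species is partitioned binomial(count, ½) independently
(counts rounded half-to-even first), and a `noise` knob in [0, 1]
scales the segregation standard deviation linearly between exact
halving and the full binomial draw.  One daughter is followed per
division; under binomial partitioning the two daughters are
exchangeable, so a single lineage carries the same statistics.

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| λ_FA, λ_AA1, λ_AA2, λ_S, λ_E | baseline branch fractions | 0.376, 0.282, 0.282, 0.05, 0.01 | — |
| K_CN (`k_cn`) | nucleotide catalysis of fixation | 10³ | conc⁻¹ |
| K_NE (`k_ne`) | nucleotide synthesis base rate | 2 | conc⁻³·day⁻¹ |
| K_NN (`k_nn`) | nucleotide autocatalysis | 2 | conc⁻¹ |
| K_iN (`k_in`) | pathway catalysis strengths | 0 | — (fraction of barrier) |
| α (`alpha`) | catalysis cost coupling | 0 | — |
| `co2` | ambient CO₂ multiplier | 1 | — |
| `n_c2` | C₂ units per molecule | 1 per branch | — |
| `k_fix` | base fixation rate | 9.21738… | day⁻¹ (calibrated) |
| `k_m` | membrane-site half-saturation | 3 | AA₁:FA ratio |
| `k_sat` | pathway-catalysis half-saturation | 0.03 | conc |
| `vol_per_fa` | volume per fatty acid | 0.05 | vol |
| `fa_div` | division threshold | 1000 | count |

The first three blocks are the published constants; the last block is
this package's calibration, chosen once as follows and not revisited:

* `fa_div = 10×` the default initial fatty-acid count (100), so a cell
  completes a few near-doublings before first division.
* `k_fix = ln2·(k_m+ρ*)/λ_AA1`: in the null model the AA₁:FA ratio is a
  closed-form attractor (ρ* = λ_AA1/λ_FA), growth is exactly
  exponential at rate `λ_FA·k_fix·ρ*/(k_m+ρ*)`, and this choice pins
  the null steady division rate to exactly 1.0/day.  All reported
  rates are therefore multiples of the null model's.
* `vol_per_fa = 0.05` sets the concentration scale so that nucleotide
  synthesis is energy-supply-limited (not kinetics-limited) across the
  slow-to-moderate fixation-catalysis regime, and steady [N] is of
  order 0.1–1 where the published catalytic constants are effective.
* `k_m = 3` keeps the null model in the proportional (20%-occupancy)
  regime while letting extreme amino-acid loading saturate the
  membrane.
* `k_sat = 0.03` places pathway catalysis near saturation (σ ≈ 0.95)
  at the slow-preset operating point, so the weak/moderate/strong
  strengths of the sweeps express their full contrast.

The `slow`/`fast` fixation-catalysis presets used by the pathway
sweeps are K_CN = 10^0.9 and 10^4.

## Simulation and steady state

The ODE is integrated with LSODA (SciPy), rtol 1e−8 / atol 1e−10
(config-exposed; collapse-regime dynamics are stiff), with a terminal
event on `fa = fa_div`.  Substrate concentrations are floored at zero
inside the rate laws, so small negative integrator excursions are
harmless; a count below −1e−9 (relative to cell size) raises a
numerical-state error carrying the offending state.  Cells whose
fatty-acid count never reaches the threshold within a 100-day cycle
window are flagged *collapsed* and report rate zero; a cell with
`aa1 = 0` or `e = 0` is a legal, merely non-growing state, not an
error.

Lineages run up to 200 divisions / 500 days by default (experiments
use 60–80 divisions, which is 3–10× past convergence at the presets
studied).  A deterministic lineage is converged when the last five
inter-division intervals have relative spread < 1e−4; the division
rate is the reciprocal of their mean, and equilibrium concentrations
are the time-average (trapezoid) over the final growth cycle.
Stochastic lineages never settle to a fixed interval, so the first
half of the intervals is discarded as burn-in and convergence is
judged by the two halves of the remainder agreeing within two standard
errors; the rate is the reciprocal of the post-burn-in mean.

An independent cross-check used in the test suite: in balanced
exponential growth every steady quantity follows from a scalar fixed
point (the utilized fraction of energy-currency production), giving an
algebraic route to the division rate that is exact for the null model
and first-order accurate under catalysis.  The simulated rates agree
with it to a few percent.

## What the experiments emulate — and what they do not

The experiment layer reproduces the study's parameterizations at desk
scale: the K_CN response, pathway-catalysis sweeps at K_iN ∈
{0, 0.33, 0.66, 0.99} under slow/fast fixation catalysis with and
without cost, autocatalysis×fixation heat maps (13×13 log grids by
default; 5×5 in the acceptance script), initial-condition scans,
segregation-noise scans, the sugar carbon-cost variant (run under the
slow preset, where supply limitation is cleanly expressed; the default
cost grid spans 1–32 C₂ per sugar, with the catalysis benefit flipping
sign near 10) and the CO₂ scan.

All comparisons are *relative orderings against the in-run baseline*
(the K_iN = 0 rate under the same preset).  Absolute divisions-per-day
depend on the calibration constants and are not meaningful beyond the
null model's pinned 1.0/day.  Passing sweeps therefore demonstrate the
network topology's qualitative behaviour — which feedbacks help, which
unbalance, which collapse — not quantitative rates of any real
prebiotic system.  Other deliberate idealizations: no spatial
structure, osmotic or membrane biophysics beyond the fatty-acid count;
no explicit Fe/S ion pools or CO₂/H₂ depletion; no population-level
competition between lineages; cell volume strictly proportional to
fatty-acid count (no surface-to-volume geometry).

## Known limitations

* **Convex nucleotide response to energy-pathway catalysis.**  The
  barrier-reduction weight law is hyperbolic in K_iN; the equilibrium
  nucleotide concentration under the KEN sweep is therefore strictly
  increasing but convex (R² ≈ 0.91 against a straight line on the
  default grid, computed by `scripts/acceptance.py`), steepening near
  K_EN = 0.99.  Any weight law gentle enough to make that response
  exactly linear is too gentle to reproduce the amino-acid collapse;
  with one law for all branches the two behaviours trade off, and the
  collapse — the model's central phenomenon — was kept.
* With the default threshold (1000 fatty acids, volume scale 0.05) the
  minor species are present in tens of copies at division, so the
  stochastic variant probes genuinely small-number noise; the reported
  robustness (means over ≥ 20 seeds within two standard errors of the
  deterministic values) is an ensemble statement, not a per-lineage
  one.
* The steady state is a point attractor at every parameter combination
  examined; the convergence criteria above are not designed to detect
  oscillatory or multistable regimes.
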