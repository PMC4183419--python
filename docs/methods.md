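# Methods

## The model

`isoflux` represents whole-body nitrogen metabolism as a multi-compartmental
system in which every pool *i* carries two state variables: its nitrogen
amount N_i (mmol N·100 g BW⁻¹) and its isotopic abundance δ¹⁵N_i (‰ vs
atmospheric N₂, R_standard = 0.0036765). Every directed flux *j → i* carries
a first-order rate constant k_ij (d⁻¹, fraction of the source pool
transferred per day) and a fractionation factor ε_ij (‰). The elemental
system is linear mass action,

    dN_i/dt = Σ_j k_ij N_j − Σ_j k_ji N_i + I_i,

with I the constant dietary input. The isotopic abundance of the
instantaneous flux leaving pool *j* is δ_j + ε (so a negative ε marks a
pathway with higher affinity for ¹⁴N), which yields the delta-balance form

    dδ_i/dt = [ Σ_in f (δ_src + ε_in − δ_i) − Σ_out f ε_out ] / N_i.

This is the first-order linearization of exact two-isotope bookkeeping; at
natural abundance (|δ| of a few ‰, |ε| ≤ ~10 ‰) its error is far below the
0.1 ‰ instrument precision. An exact mode that tracks ¹⁵N amounts and
converts through the delta definition is provided purely as a verification
oracle (`find_steady_state_exact`); the property suite checks agreement to
< 0.05 ‰ on random graphs of up to six pools.

Two consequences of the formalism are used repeatedly. First, at fixed
pool sizes the isotopic steady state is *linear in δ and in ε*, so steady
states and fractionation estimation are exact linear solves, not iterative
fits. Second, for a protein pool fed by synthesis (ε_s) and drained by
unfractionated degradation, the steady state obeys δ_P = δ_AA + ε_s, and a
tissue protein pool obeys the branch-point closed form

    Δ¹⁵N_P = Δ¹⁵N_PlAA − p·ε_ox + ε_s,   p = f_ox / (f_out + f_ox + f_s − f_d),

where p is the share of the tissue's free amino-acid (AA) disposal going to
oxidation rather than net protein export. Note the sign of ε_s: synthesis
with ε_s > 0 enriches the protein fraction above the free pool, which is
what the enriched protein fractions require. The oxidative term lowers the
free-AA pool below plasma when ε_ox > 0 and raises it when ε_ox < 0.

Elimination pools (urinary urea and ammonia, feces, hair and desquamation
losses) are reported as flow-through observables: the measured δ of an
excretum is the abundance of its instantaneous flux, δ_source + ε_flux.
An accumulating excreta reservoir never reaches isotopic steady state, so
this convention is what makes steady-state excreta measurements meaningful.

## The rat topology

The shipped rat model has 21 compartments and 49 fluxes: three luminal
pools (stomach, small intestine, caeco-colon); protein and free-AA pools of
SI mucosa, liver, plasma, muscle, kidney, heart, red blood cells and skin;
hair; and body urea. Dietary N enters the stomach; absorbed mucosal AA
reach the liver via the portal vein; each tissue exchanges AA with plasma,
turns protein over and oxidizes AA; every oxidation flux routes to body
urea (it aggregates inter-organ transfer plus hepatic deamination); urea is
either excreted or recycled to the colon where part is salvaged back into
the hepatic AA pool. Choices that the counts and per-compartment balance
require but that could be drawn differently: plasma protein is synthesized
from the *hepatic* AA pool (plasma proteins are liver-made) and returns AA
to plasma on degradation; urinary ammonia is drawn from hepatic AA; hair
keratin is laid down from skin AA; heart and RBC do carry (small) oxidation
fluxes; hair has no free-AA pool.

## Calibration

Calibration is two-phase and deterministic.

**Phase 1 — rates from pool sizes.** Measured pool sizes are imposed as
the exact elemental steady state. The under-determined balance is closed
by literature rules: f_sT = f_dT = FSR_T·T_P per tissue (FSR spanning
3 %/d in RBC to 150 %/d in SI mucosa; muscle 11 %/d); f_inT = TI_T·f_sT
with TI = 1.5 everywhere except skin (0.8); a single %ox across tissues
sized so total urea production equals intake (giving %ox =
intake/(intake + Σf_s) ≈ 29 % at the shipped baseline); gastric emptying =
intake; endogenous secretion, fecal, ammonia, hair and desquamation losses
as fixed intake fractions; proximal absorption from an ileal digestibility
of 0.9; hepatic delivery to plasma pinned at 250 % of intake. The
remaining fluxes close one balance each, in a declared order (urinary urea
from whole-body balance, recycling from the urea balance, colonic
absorption from the colon balance, portal flux from the mucosal balance,
hepatic AA inflow from the liver balance); the plasma AA balance is the
redundant consistency check. Rate constants follow as k = f/N_source.
Because liver synthesis counts hepatic + plasma protein output, the
splanchnic %ox (f_oxSpl/(f_oxSpl + f_sL + f_sPl + f_sSI)) equals the
uniform tissue value exactly.

**Phase 2 — fractionation factors from Δ¹⁵N.** Parsimony is encoded
structurally: degradation, plasma/tissue AA transport, gut transit and
simple losses are pinned at ε = 0; the free set is ε_s per tissue (8,
including plasma protein), ε_ox per tissue (7), and ε_secSI, ε_absCC,
ε_UE, ε_NH4 — 19 parameters. Each measured compartment contributes its
steady-state balance row (normalized by its inflow so residuals are in ‰)
and each measured excretum one observation row (δ_obs = δ_src + ε); the
free ε solve a single linear least-squares problem. With the shipped
fixture the system is exactly determined (19 unknowns, 24 rows, 5 of which
are ε-free consistency rows), so residuals vanish at machine precision; a
rank check reports any unidentifiable subset (e.g. freeing a degradation ε
alongside its synthesis ε creates an exact null direction). All fitting is
done in diet-referenced Δ¹⁵N space so the dietary baseline cancels.

## The baseline fixture (synthetic)

No measurement data are redistributable, so the shipped baseline
(`data/rat_measurements.csv`) is a synthetic stand-in constructed once by
`scripts/make_baseline_fixture.py`. Pool sizes are plausible for a ~400 g
rat per 100 g body weight (muscle protein 95, skin 52, liver 12.4 mmol N
·100 g⁻¹, free-AA pools 1–6 % of their protein pools). The Δ¹⁵N pattern
was designed to the qualitative structure reported for rats under standard
conditions — every N fraction enriched over the diet except muscle free AA
and body urea; urinary urea at the dietary value; protein-minus-AA
differences of 4.8, 4.1 and 0.6 ‰ in muscle, heart and kidney; values
spanning about −1.5 to +5 ‰ — with splanchnic free-AA values kept close to
their supply so the implied oxidation ε stay within the few-‰ range
plausible for enzymatic amino-group transfer. Five pattern values are not
free (stomach content, plasma free AA, hair, caeco-colonic content, feces):
they are computed from the model's own balance equations, which makes the
designed pattern exactly attainable and the 19 free ε exactly identifiable.
The calibrated ground truth then has ε_ox negative in every tissue except
muscle, and ε_UE = +0.6 ‰ so urinary urea matches the diet.

What passing tests do and do not show: exact noiseless recovery and
unbiased noisy recovery prove the generator and calibrator are inverses and
the pipeline is numerically correct; reproduction of the headline indices
(29 % oxidation share, 18 % recycling, 250 % delivery, the compensation
percentages) shows the closure rules interlock as intended. They do not
certify the biological accuracy of the stand-in pool sizes or ε values, and
emergent magnitudes that depend on them (grid enrichments, regression
slopes, starvation amplitudes) should be read as model-family behaviour,
not as measurements.

## The measurement generator

`synthetic.simulate_dataset` perturbs the ground-truth steady state with
independent Gaussian noise: additive on δ (default SD 0.1 ‰, the replicate
precision of natural-abundance isotope-ratio mass spectrometry) and on log
pool size (default 5 % relative, a generic gravimetric/assay scale), for a
default cohort of 10 animals; replicates are pooled by mean with SD columns.
It emulates steady-state snapshot data only — no growth-phase ¹⁵N
bioaccumulation, no within-day fed/fasted cycling, no inter-animal
covariance between fractions. All randomness flows from a single seed.

## Scenarios

Scenarios alter rate constants only; ε are intrinsic pathway properties and
never move. Gradual perturbations follow k(t) = k_target + (k₀ −
k_target)e^(−t/τ) with τ = 1 d by default (final steady states are
τ-independent; the transient amplitude check is reported for τ ∈ {0.5, 1,
2} d). Homeostatic compensation is exact linear algebra: at the baseline
pool sizes dN/dt = B·k is linear in k, so the free rates that re-zero it
solve a small linear system, and because compensating rates follow the same
ramp as the perturbation, the elemental balance holds exactly at every
instant. Infeasible compensations (negative rates, unbalanceable rows) are
reported with the violated compartments.

Muscle-turnover scenarios need no free-AA resupply rule: at steady state
the synthesis drain is returned by degradation, so the tissue AA pool is
set by k_in·Pla/(k_ox + k_out) independently of k_s, and a 20 % change in
k_sM yields the full 20 % protein-mass change with plasma untouched at the
final state.

The dietary-quality grid drives splanchnic %ox through a common factor on
k_oxSI and k_oxL. The full-compensation ("blue") family frees the
recycling loop (k_UH, k_absCC) plus the portal rebalance k_PV, leaving
peripheral delivery fixed; recycling efficiency then rises 18 → ~45 % as
%ox rises 29 → 50 %. The partial-compensation ("red") family pins
recycling 60 % above baseline and peripheral delivery on a declining
schedule, and lets a single uniform scale on all peripheral tissue rates
(plus k_PV, k_inL, k_UH, k_UE, k_absCC) close the balance — peripheral
turnover falls by up to ~46 % at the endpoint. Intermediate mixes
interpolate the recycling and delivery targets between the two families;
the union of points feeds the fecal/urinary Δ¹⁵N-vs-recycling regressions.
Per grid point the new isotopic steady state is a linear solve at unchanged
pool sizes; infeasible points are recorded, not fatal.

Starvation scenarios set intake to zero (no elemental or isotopic steady
state exists; results are reported as δ¹⁵N at the 7-day horizon, flagged
`no_final_steady_state`). The mechanism family interpolates between a pure
breakdown rise (k_dM 0.11 → 0.24 d⁻¹) and a pure oxidative shift (+80 %
k_oxM with −75 % k_sM, moving muscle %ox from 29 to ~75 %); for each mix a
bisection on the oxidative amplitude matches the muscle protein loss of the
pure-breakdown scenario, so the family isolates the isotopic signature of
the mechanism at fixed mass loss.

Isotopic incorporation kinetics are summarized by t50/t95 of the relative
change curve (Δ¹⁵N(t) − Δ¹⁵N_initial)/(Δ¹⁵N_final − Δ¹⁵N_initial), by
linear interpolation with first-crossing semantics for non-monotone
transitions; a zero net change is reported as undefined rather than forced.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with LSODA (the rate constants
  span gastric emptying at ~17 d⁻¹ down to RBC turnover at 0.03 d⁻¹, so the
  system is stiff), rtol 1e-8, atol 1e-10; trajectories sampled on an even
  grid, dense enough for the kinetics interpolation at its default 1501
  points.
* Steady states: elemental by direct linear solve (singularity reported as
  a structural diagnostic listing suspect compartments); isotopic by linear
  solve at fixed N; residual tolerances 1e-8·intake and 1e-6 ‰·d⁻¹.
* Degenerate pools: a compartment below 1e-12 mmol with nonzero throughput
  raises a singularity error naming it; pools that are merely draining
  (starvation) stay positive under mass action and keep a frozen δ once
  empty of throughput. Integrated N is clipped at −1e-9 (beyond that the
  run errors with a timestamp).
* Zero denominators in derived indices (e.g. recycling efficiency under
  zero urea production) yield NaN, flagged, never an exception.

## Known limitations

Lumped amino-acid nitrogen (no per-AA speciation or compound-specific
δ¹⁵N); constant continuous intake (no meal patterning); no body-weight
change, so the trophic-accumulation dynamics of growing animals are out of
scope; point estimates only (recovery SDs quantify noise propagation, not
posterior uncertainty); the exact flux roster beyond the structural
constraints is a reconstruction, and all emergent magnitudes inherit the
synthetic baseline's assumptions.
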