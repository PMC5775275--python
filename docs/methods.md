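# Methods

## Model and assumptions

The asparagine synthetase reaction is represented as a continuous Petri net:
eleven places (species with continuous concentrations) and five transitions
(reactions) under mass-action kinetics, so every reaction's flux is its rate
constant times the product of its substrate concentrations. The induced ODE
system is dx/dt = S·v(x) with S the stoichiometry matrix over the dynamic
species. Two assumptions shape the network:

* **Clamping.** ATP and Mg²⁺ are boundary species: they enter the r3 flux
  product but their derivatives are identically zero, modeling the large
  buffer excess (10 mM each against 1.6 mM aspartate). Mg²⁺ additionally
  appears on both sides of r3 (catalytic), so it would be conserved even
  unclamped.
* **Sequential mechanism with dissociation.** Glutamine hydrolysis (r1, r2)
  and asparagine formation (r3, r4) are distinct sequential stages coupled
  only through the enzyme–ammonia complex, and that complex can dissociate
  unproductively (step D). This is what allows glutamate synthesis to
  continue after aspartate is exhausted, and it makes the late-time Glu:Asn
  ratio a direct readout of kD relative to k3·[Asp][ATP][Mg²⁺].

Water and pyrophosphate are ubiquitous and omitted.

## Units

The sources for the assay mix concentrations in mM, enzyme loadings in
mg/mL and nmol/mL, and quote all five rate constants with a single unit
label even though mass-action constants of different reaction orders cannot
share units. The package therefore works in one abstract concentration unit
(c.u.): assay species are loaded at their mM values (Asp 1.6, Gln 10, ATP 10,
Mg²⁺ 10), the enzyme at the loading the constants were fitted against (0.1
for TaASN1, 0.09 for TaASN2; the nmol/mL figures are stored as metadata
only), and the rate constants are taken at face value as magnitudes in this
system. Every quantity the package reports is either invariant to this
choice or generated self-consistently within it.

## Numerical choices

* **Integrator.** `scipy.integrate.solve_ivp` with LSODA at rtol 1e-8 /
  atol 1e-10. The system is stiff — kD = 700 s⁻¹ against k1·[Gln][ASNe] ≈
  0.016 s⁻¹ spans five orders of magnitude — and LSODA's automatic
  stiffness switching handles both the millisecond complex transient and the
  half-hour substrate depletion. The default output grid is 2001 points over
  2100 s (2000 steps of 1.05 s). Halving the tolerances moves final
  concentrations by far less than 1e-6 relative (tested).
* **Nonnegativity.** Mass-action systems started nonnegative stay
  nonnegative; output values in [-100·atol, 0) are clipped to zero as solver
  noise, anything more negative raises an integration error rather than
  being silently repaired.
* **Conserved moieties.** The left null space of S is computed exactly with
  sympy and scaled to smallest-integer vectors. The network has four laws
  (aspartate pool, glutamine pool, total enzyme, AMP−Asn), used as
  trajectory-level oracles in the tests.
* **Exact-time sampling.** The integrator accepts an explicit output grid;
  the data generator and the fit objective both evaluate the model at the
  exact observation times (the objective's dense grid is augmented with
  them), so residuals carry no interpolation error and a noiseless self-fit
  has SSE at the solver-noise floor (~1e-14).

## Parameter estimation

The objective is the unweighted sum of squared concentration residuals over
asparagine and glutamate, all replicates and time points. No weighting is
applied because both observed species live on comparable scales (0–10 c.u.);
a per-species weighting hook exists for datasets where that fails.

The optimizer is a from-scratch Hooke–Jeeves pattern search: per-coordinate
exploratory moves (±step, first improvement, fixed coordinate order
k1,k2,k3,k4,kD restricted to the free set), pattern extrapolation moves while
they keep improving, geometric step contraction (factor 0.5) otherwise, with
projection onto box bounds and non-finite objective values treated as +∞.
The search runs in log10 space because the default bounds span twelve
decades (1e-6 to 1e6), over which additive steps are meaningless. Defaults:
initial step 0.2 decades, stop step 1e-5 decades, at most 20,000
evaluations. Pattern-loop continuation requires improvement beyond a 1e-12
relative threshold; strictly-positive but rounding-level gains (which arise
when extrapolation repeatedly projects against an infeasible region) would
otherwise stall the step schedule. A Nelder–Mead simplex fallback is exposed
behind the same interface, and a multi-start wrapper scales the start values
by configurable multipliers.

For recovery experiments the default free set is {k1, kD} with {k2, k3, k4}
fixed: the two enzymes share k2–k4, and the fast interior steps are weakly
identifiable from 7-point Asn/Glu data, whereas k1 and kD control the
observable glutamate rate and Glu:Asn ratio directly.

## Synthetic assay generator

The generator emulates an o-phthalaldehyde/fluorescence HPLC activity assay
and defines the study conditions:

* initial mixture Asp 1.6, Gln 10, ATP 10, Mg²⁺ 10, enzyme 0.1 (TaASN1) or
  0.09 (TaASN2);
* sampling at 1.5, 2.5, 3.5, 5, 15, 25, 35 min (90–2100 s), two replicates;
* calibration standards at 0, 5, 10, 15, 20 nmol, fitted by ordinary least
  squares, inverted to concentrations with negative back-calculations
  clipped to zero and flagged;
* multiplicative Gaussian noise on peak areas, default CV 5% — a typical
  fluorescence-HPLC repeatability figure; no error model is prescribed by
  the assay itself, so this is configurable;
* the measured standards carry the same noise as the samples, so calibration
  uncertainty propagates into the back-calculated concentrations exactly as
  in a real run (this is why low concentrations are noticeably biased at 5%
  CV: the fitted intercept error is amplified at the bottom of the curve).

What it does not emulate: chromatographic peak shapes and retention,
derivatization-efficiency kinetics, quenching delay (the acid stop is
treated as instantaneous), carry-over, and drift between runs. Passing
recovery tests therefore show identifiability under ideal measurement-chain
behavior, not robustness to chromatography artifacts.

## Problem sizes

Recovery experiments use 100 evenly spaced sampling times over (0, 2100] s
with two replicates (400 observations of two species); this densification of
the 7-point design gives the pattern search a smooth objective while keeping
a single fit to a few seconds and ~100–200 objective evaluations. The
noise-degradation check uses 20 time points and 10 seeds.

## Known limitations

* The fast constants k2, k3, k4 are effectively non-identifiable from
  Asn/Glu time courses alone at this design; the package fixes them for
  recovery and documents joint fits as an option, not a default.
* Enzyme loadings in mass and molar units disagree by ~30% in the sources;
  the package does not attempt to reconcile them and stores the molar
  figures as metadata.
* The calibration maps a single linear curve to both amino acids; real
  assays fit per-analyte standards (the generator's curve is shared because
  its slope/intercept are arbitrary in model units).
* No sensitivity analysis, confidence intervals, or stochastic (discrete
  Petri-net) semantics.
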