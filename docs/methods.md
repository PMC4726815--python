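# Methods

## Model structure

The simulator represents AMPAR trafficking at a single parallel
fibre–Purkinje cell synapse as a closed, bidirectional recycling loop. Two
compartments of equal volume are modelled: the sub-membrane region (the
cytosol within 120 nm of the plasma membrane) and the sub-endosome region.
The sub-membrane is subdivided into three well-mixed areas — postsynaptic
density (PSD), extra-synaptic membrane (X) and endocytic zone (EZ) — which
are species labels, not separate volumes: lateral diffusion between them is
first order with primary rate constants `k.diff.*`. Physically these rates
are the ratio of the receptor diffusion coefficient to the source-area size
(the helper `diffusion_rate(D, area)` documents the conversion); they are
kept as primary parameters because the sub-area sizes are not independently
constrained.

A receptor species is a triple (phospho-state × binding partner ×
location). The two GluA2 phospho-sites, S880 and Y876, are mutually
exclusive by construction: a receptor carries exactly one of
{unphosphorylated, pS880, pY876}, so no doubly phosphorylated state can be
expressed. Binding states are free, GRIP, PICK1, PICK1-PKC*, the tripartite
GRIP-PICK1 and GRIP-PICK1-PKC* complexes, and NSF. Legality rules: GRIP-
containing complexes exist only at the PSD and endosome; NSF-bound
receptors only at the endosome. This yields 57 receptor species; with the
six dynamic enzyme species (PKC, PKC*, PICK1-PKC*, PP2A, SFK, PTPMEG) the
state vector has 63 entries, coupled by 221 elementary reactions expanded
from 57 templates.

GRIP, PICK1 and NSF are fixed-concentration pools: a molecule consumed by
binding is assumed to be replaced immediately from the bulk cytosol, so
these species contribute constant concentration factors to mass-action
rates and are never depleted. The PICK1-PKC* complex, by contrast,
sequesters one finite PKC molecule and is a dynamic species; the model
conserves total PKC across its free, active, PICK1-bound and
receptor-bound forms (checked structurally by the network validator,
alongside receptor-number conservation).

## Rate laws and units

Amounts are particle numbers; concentrations are particles/µm³ with both
compartments at V = 1 µm³ by default (120 nm × 8.33 µm²), so numbers and
concentrations coincide. Binding follows mass action; bimolecular
concentration-based constants are converted to particle propensities
through V. Phosphorylation and dephosphorylation follow irreversible
Michaelis–Menten kinetics evaluated per substrate species independently
(no competition between substrates for an enzyme), matching the convention
of standard biochemical-network simulators. Receptors already carrying
PICK1-PKC* are S880-phosphorylated at the PKC turnover rate (first order in
the complex). NSF-bound receptors are never phosphorylation substrates.

Two template-level decisions deserve note:

* **S880 phosphorylation and GRIP.** GRIP association is abolished for
  pS880 receptors; pS-GRIP complexes arise only by phosphorylation of an
  already-anchored receptor and decay with the ~200-fold enhanced off-rate
  `k.ampar-grip.offpS` (also used for the full tripartite dissociations
  when the receptor is pS880 — the enhanced rate is a property of the
  pS-GRIP bond, not of a particular template).
* **Binding locations.** Only GRIP and NSF interactions are
  location-restricted; PICK1 association/dissociation occurs in every
  sub-area. Restricting PICK1 to the PSD/endosome leaves free receptors
  stranded at the EZ as a permanently un-internalisable surface pool
  (~5 % of the surface by itself), which is incompatible with the basal
  mobile fraction the model is required to exhibit.

## Scenarios and events

A scenario is a perturbation schedule on top of a parameter set: PP2A
inhibition (fractional removal of the PP2A amount from t = 0), SFK scaling,
PTPMEG knockout, exocytosis block, an EZ-escape override, the Y876F
phospho-null mutant (removal of the Y876 kinase templates), and the PKC
activation step. The step is implemented as stop–modify–restart: at the
step time the entire PKC pool is transferred to PKC* and deactivation is
set to zero for the rest of the run, i.e. activation is held for the whole
induction window; late-phase deactivation is outside the model's scope.

The 4-fold high-calcium increase of PICK1–AMPAR association enters through
the PICK1-PKC* binding rate (`k.ampar-pick.on* = 4 × k.ampar-pick.on`, a
validated relation), a species that only exists while PKC is active — so
calcium elevation is implicit in the PKC step. An explicit `calcium_high`
flag can additionally switch the plain PICK1 association rate to the 4×
value; it is off in the standard LTD protocol because applying it there
internalises Y876-protected receptors indiscriminately and eliminates the
PTPMEG-gating phenotype that is the model's central behaviour.

Every named protocol first relaxes the system to the basal steady state of
its t = 0 parameters (the burn-in; the steady state is independent of the
initial receptor arrangement), then runs the 3000-second experiment with
the PKC step at 1000 s. Relative readouts are normalised to the PSD (or
surface) population at the instant before the step, and "20 minutes" means
1200 s after the perturbation onset. Internalisation assays block
exocytosis at t = 0 from the burnt-in state, activating PKC at t = 0 when
requested, with PP2A uninhibited by default.

## Numerical choices

LSODA (scipy.integrate.solve_ivp) with relative tolerance 1e-8 and absolute
tolerance 1e-10 particles; dense output on a 1 s grid; state clipped at
zero inside the flux evaluator to suppress integrator-scale negatives.
Receptor conservation is verified on every output point (tolerance 1e-6
relative; halving the tolerances changes 20-minute observables by well
under 0.1 %). Steady states are detected by chunked integration (2000 s
chunks, cap 2×10⁵ s) until every derivative is below 1e-6 particles/s.
Calibration uses Brent's method on the logarithm of each knob with
geometric bracket expansion and early abort when the observable saturates
short of its target; the three one-dimensional calibrations are iterated to
a joint fixed point (they are nearly separable and converge in 2–3
passes). Sensitivity coefficients use central differences at 1 % relative
perturbation — in the scaled coefficient the rate cancels,
SSC = (n₊ − n₋)/(2·h·n₀) — with the steady state re-detected per
perturbation; coefficients are stable to <5 % under halving of the step.

## The shipped parameter set

No published per-reaction rate table ships with the package, so the default
set is the package's own operating point, chosen once to satisfy the
model's stated basal constraints and the qualitative regime the mechanism
requires, with magnitudes anchored to the trafficking literature
(second-scale phospho-turnover, minute-scale GRIP anchoring with a large
pS-induced off-rate increase, receptor diffusion of order 0.1 µm²/s over
sub-micron areas, a very low EZ escape rate of 0.008 s⁻¹ reflecting
stargazin trapping). Three parameters are then *calibrated*, reproducing
the published procedure exactly:

* `k.endo` — 40 % of surface receptors internalised over 20 minutes with
  exocytosis selectively blocked (basal, PKC inactive);
* `k.exo` — exocytosis balances endocytosis basally (steady-state surface
  population equal to the initial 125; drift <1 % per 1000 s follows);
* `kcat.ptpmeg` — basal Y876-phosphorylated fraction of 25 % (the
  PSD-restricted variant of the observable is exposed alongside).

Tolerances are ±2 percentage points on fractions ("approximately" in the
source procedure); the bisection resolves far tighter. Calibrated entries
carry a `calibrated` provenance label; re-running calibration moves no
parameter by more than 0.1 %.

Two deliberate regime choices: SFK operates in its linear regime
(Km = 500 particles/µm³, far above any substrate pool) while PTPMEG is
near saturation (Km = 10). With the opposite choice the Y876-phosphorylated
fraction *rises* during induction — as the unphosphorylated pool shrinks, a
saturated kinase speeds up per substrate — whereas the mechanism being
modelled has it falling roughly by half as PKC outcompetes SFK for the
shrinking unphosphorylated pool. The enzyme pools (PKC 20, PP2A 20, SFK 10,
PTPMEG 10 particles) put phospho-turnover on the seconds-to-tens-of-seconds
scale, fast relative to trafficking.

## What the default set does and does not reproduce

With the calibrated defaults the simulator reproduces, as properties: the
basal calibration surface itself; basal stability (<1 % over 3000 s) with
no S880 phosphorylation and a mobile fraction under 6 %; strong wild-type
LTD (PSD population falling to ~56 % of baseline at 20 minutes) with an
immediate mobilisation burst and a declining Y876-phospho fraction
(26 % → 13 %); near-absent LTD in the PTPMEG-null system (<5 % depression)
with no mobilisation; the internalisation-assay factorial (40 % basal,
~43 % with PKC alone, ~100 % with PKC + PTPMEG); monotone PP2A-inhibition
and SFK-concentration sweeps; Y876F rescue of the PTPMEG-null system to the
SFK-null limit; loss of LTD expression once the EZ escape rate exceeds
~0.01 s⁻¹; and the sensitivity sign structure (exocytosis and inward PSD
diffusion raise the LTD steady-state membrane population, PKC turnover and
outward diffusion lower it, kcat/Km antagonistic per enzyme).

Exact figure-level magnitudes published for the original parameter set
(e.g. a decline to 44 % of baseline, an 18 % mobile fraction during LTD,
0.16 receptors/s of pS traffic, the specific sweep endpoints and
sensitivity magnitudes) depend on that parameter table and are not
reproduced number-for-number by the default set; supplying such a table as
a parameter file recovers them to the extent the table does. Known
quantitative deviations of the defaults: the mobile fraction during LTD
stabilises near 50 % rather than ~18 %; during the LTD steady state the
unphosphorylated form carries more inward flux than the pS form (PP2A
dephosphorylates many PICK1-bound receptors en route to the EZ, though pS
trafficking still switches on strongly from zero); and the basal PSD
Y876-phospho fraction sits at ~26 % rather than ~20 %.

## Problem sizes

The shipped experiments use the full 63-species network: 3000-second
scenario runs integrate in well under a second of CPU; the complete
calibration loop takes a few seconds; the 25-parameter sensitivity table
(51 steady-state evaluations) completes in a few seconds. The test suite
runs the entire battery — calibration, all named scenarios, the three
sweeps, sensitivity, and the SBML round-trip — in under a minute.

## SBML interchange

`export_sbml` writes the expanded network as a self-contained SBML Level 3
document (explicit MathML kinetic laws; fixed pools as boundary species).
The package's own reader compiles the document back into a runnable model
through an independent path — kinetic laws are evaluated from the parsed
MathML, not reconstructed from the native rate-law objects — and the
re-imported model reproduces native trajectories to ~1e-7 particles, which
serves as the cross-simulator consistency check. The document is not
validated against an external SBML toolchain.

## Limitations

Sub-compartments are well-mixed boxes; there is no spatial or
particle-resolved diffusion and no stochastic integrator. Receptor
synthesis, degradation and desensitisation are excluded, as are GRIP
isoform differences, the dimeric GRIP-PICK1 complex, finite GRIP/PICK1
pools, and the upstream Ca²⁺/mGluR1/PKC feedback loop (represented only by
the step activation). Late-phase LTD maintenance after the PKC window is
out of scope. PTPMEG acts in both compartments by default; a
membrane-restricted variant is available as a build flag
(`ptpmeg_membrane_only`).
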