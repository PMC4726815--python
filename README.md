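# amparcycle

A deterministic kinetic simulator of AMPA-receptor (AMPAR) recycling at the
cerebellar parallel fibre–Purkinje cell synapse, and of the phosphorylation
"master switch" that converts that recycling loop into long-term depression
(LTD).

## The model

Synaptic strength at this synapse is set by the number of AMPARs in the
postsynaptic density (PSD). The model tracks 250 receptors cycling between
four well-mixed regions — PSD, extra-synaptic membrane (X), endocytic zone
(EZ) and endosome — through an elementary reaction network expanded from 57
reaction templates:

* **Scaffold binding.** GRIP anchors receptors at the PSD and the endosome
  (association `k.ampar-grip.on`, dissociation `k.ampar-grip.off`); PICK1
  competes for the same GluA2 PDZ ligand and licenses endocytosis; NSF binds
  free endosomal receptors and is required for exocytosis. GRIP, PICK1 and
  NSF are fixed-concentration cytosolic pools.
* **Trafficking.** Receptors not bound to GRIP hop laterally
  (PSD ⇌ X ⇌ EZ at `k.diff.*`); only PICK1-bound receptors at the EZ are
  internalised (`k.endo`); NSF-bound endosomal receptors are reinserted into
  the extra-synaptic membrane (`k.exo`).
* **The switch.** The GluA2 C-terminus carries two mutually exclusive
  phospho-sites. PKC phosphorylates S880 (dephosphorylated by PP2A), which
  abolishes GRIP binding and hands the receptor to PICK1; Src-family kinases
  (SFK) phosphorylate Y876 (dephosphorylated by PTPMEG), which blocks S880
  phosphorylation and thereby protects the GRIP anchor. All
  (de)phosphorylation follows Michaelis–Menten kinetics,
  `v = kcat·[E]·[S]/(Km + [S])`, per substrate species.

LTD induction is a step activation of the whole PKC pool after 1000 s of
basal conditions, together with 60 % PP2A inhibition, and LTD expression is
measured purely as the reduction of the PSD receptor population. The
interplay produces the model's core predictions: PTPMEG gates LTD (without
it, SFK locks receptors in the Y876-phosphorylated, GRIP-anchored state),
PP2A inhibition tunes LTD magnitude, SFK activity restrains it, and a
Y876-phospho-null receptor (Y876F) rescues LTD in a PTPMEG-null system.

The network is integrated as a stiff ODE system (LSODA) in particle-number
units; receptor number is conserved to 1e-6 relative in every scenario.

## Worked example

```python
from amparcycle import ParameterSet, calibrate_all, calibration_report, run_scenario
from amparcycle.protocols import relative_psd_at

params = calibrate_all(ParameterSet.default())
print(calibration_report(params))
traj, obs = run_scenario("ltd", params)
print(round(relative_psd_at(traj), 1))
```

prints

```
{'internalised_20min_pct': 40.0, 'basal_surface': 125.0,
 'basal_pY876_pct': 25.0, 'basal_pY876_pct_psd': 26.07}
55.9
```

Calibration pins the three free parameters to the basal operating point
(`k.endo = 0.0955`, `k.exo = 0.0137`, `kcat.ptpmeg = 0.319` with the shipped
defaults): 40 % of surface receptors are internalised in 20 minutes when
exocytosis is blocked, exocytosis balances endocytosis (125 surface
receptors at steady state), and 25 % of receptors are Y876-phosphorylated.
The LTD run then shows the PSD population falling to 55.9 % of baseline 20
minutes after PKC activation, the mobile (non-GRIP-bound) surface fraction
jumping from 5 % to ~49 %, an S880-phosphorylated PSD pool of ~15 %, and the
Y876-phosphorylated fraction declining from 26 % to 13 %. In the PTPMEG-null
scenario the same PKC step depresses the PSD population by less than 5 % —
the gating phenotype.

The same experiments are scriptable from the shell:

```bash
amparcycle calibrate --out calibrated.yaml --report report.json
amparcycle run --scenario ltd --params calibrated.yaml --out traj.csv --observables obs.csv
amparcycle sweep --what pp2a --params calibrated.yaml --out pp2a.csv
amparcycle sensitivity --params calibrated.yaml --out ssc.csv
amparcycle export-sbml --params calibrated.yaml --out model.xml
```

The sensitivity command reports scaled sensitivity coefficients
(∂n/∂r)(r/n) of the LTD steady-state membrane population n for every rate
parameter; with the shipped set the strongest levers are the PSD diffusion
rates (+0.57/−0.53), exocytosis (+0.52) and the PKC/PP2A kinetics, while
most binding constants are weak (|SSC| < 0.1).

## Layout

```
src/amparcycle/
  states.py       legal receptor state space (phospho x binding x location)
  network.py      template -> elementary-reaction expansion + validation
  parameters.py   named rates, pools, geometry, provenance, defaults
  dynamics.py     compiled RHS, scenarios, events, LSODA integration
  calibration.py  basal operating-point calibration (bisection fixed point)
  protocols.py    named in-silico experiments, observables, sweeps
  sensitivity.py  scaled sensitivity coefficients
  sbml.py         SBML L3 export and independent re-import simulator
  io.py, cli.py   parameter/CSV I/O and the command-line interface
docs/methods.md   modelling assumptions, parameter choices, limitations
```
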