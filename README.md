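# allosense

Quantitative analysis of a cyclic-nucleotide-controlled c-di-GMP
phosphodiesterase: two-site binding thermodynamics, allosteric activation
kinetics, the occupancy→activity linkage test, and rigid-body metrics for
the sensor domain's swing-out motion.

## The scientific problem

A bacterial EAL-domain phosphodiesterase carries an N-terminal CRP-family
cNMP sensor dimer that binds cAMP or cGMP and gates hydrolysis of the
second messenger c-di-GMP. The sensor binds its two ligands with opposite
cooperativity — cAMP negatively, cGMP positively — and the enzyme only
switches on when **both** sensor sites are occupied. This package
reimplements, as a tested library, the quantitative chain behind that
conclusion:

1. **Binding thermodynamics** (`allosense.binding`). Isothermal titration
   calorimetry (ITC) data are described by the independent
   two-sets-of-sites model with per-class stoichiometries n₁, n₂,
   association constants K₁, K₂ and enthalpies ΔH₁, ΔH₂. Derived
   bookkeeping follows ΔG = −RT ln K, ΔS = (ΔH − ΔG)/T, K_d = 1/K
   (R = 1.987 cal mol⁻¹ K⁻¹, T = 298.15 K). The macroscopic sequential
   reformulation uses the binding polynomial Q(L) = 1 + β₁L + β₂L², giving
   dimer species fractions f₀, f₁, f₂ and mean occupancy ν = f₁ + 2f₂.
   Cooperativity is classified by c = 4K₂ₐ/K₁ₐ (c = 1 for identical
   independent sites).
2. **Titration simulation and fitting** (`allosense.itc`). A perfusion-cell
   forward model — δq(i) = Q(i) − Q(i−1)(1 − dVᵢ/V₀) with
   Q(i) = V₀·P(i)·[n₁θ₁ΔH₁ + n₂θ₂ΔH₂] and free ligand from exact mass
   balance — plus multi-start nonlinear least squares to recover the six
   parameters from a thermogram.
3. **Activation kinetics** (`allosense.kinetics`). Phosphodiesterase rates
   against the chromogenic substrate PNPP (product quantified via
   ε₄₀₅ = 18,000 M⁻¹ cm⁻¹) fitted to the allosteric sigmoidal model
   v = V_max·Aʰ/(K_halfʰ + Aʰ), with an extra-sum-of-squares F test against
   the h = 1 hyperbola.
4. **Linkage inference** (`allosense.linkage`). Predicted activity curves
   under competing activation hypotheses (activity ∝ f₂, ∝ f₁+f₂, or ∝ ν/2)
   and a three-criterion consistency report that asks whether the kinetic
   data require double occupancy.
5. **Structural metrics** (`allosense.structure`). Kabsch superposition,
   stator-aligned swing angle for the sensor body (C-helix interface
   residues 97–110 as stator, cNMP body 6–83), the Asp95–Ile62 Cα P-loop
   probe, and the residue 111→117 domain-swap topology distances.
6. **Synthetic data** (`allosense.synth`) generates every input with known
   ground truth under the study conditions, so the whole chain is testable
   offline.

## Worked example

A fixtures-only end-to-end run (synthetic data generated from one seed,
then fitted and interpreted):

```sh
allosense run --seed 1 --out report.json
```

prints, among other things:

```
ITC cAMP: Kd = 0.914 / 26.3 uM, cooperativity negative (c = 0.139)
ITC cGMP: Kd = 11.7 / 0.874 uM, cooperativity positive (c = 53.4)
kinetics cAMP: Vmax = 1, K_half = 56.85 uM, h = 1.73
kinetics cGMP: Vmax = 1.21, K_half = 25.79 uM, h = 1.91
...
verdict: double_required
```

Reading this: the noisy synthetic cAMP titration refits to dissociation
constants of ~0.9 and ~26 μM (truth 0.775/22.4 μM; the 0.2 μcal heat noise
moves them slightly), classified as negative cooperativity since the
second binding is ~30-fold weaker than the statistical expectation;
cGMP refits to positive cooperativity. The Hill fits recover K_half and
h near their generating values (54.22 μM/1.85 and 26.17 μM/1.94), and the
three-criterion linkage report concludes that activation requires both
sensor sites to be occupied — K_half sits about twofold above the
low-affinity K_d for both ligands, the activation ordering contradicts the
single-site prediction, and h > 1 despite negative binding cooperativity.

The same steps are available piecewise (`allosense make-fixtures`,
`simulate-itc`, `fit-itc`, `fit-kinetics`, `link`, `structure-metrics`,
`report`) and as library calls; see the module docstrings.

Swing metrics against deposited coordinates work directly on mmCIF/PDB
files, e.g.

```sh
allosense structure-metrics --ref 6hq2.cif --mov 6hq4.cif \
    --stator A:97-110,B:97-110 --body A:6-83 --out metrics.json
```

## Layout

```
src/allosense/
  binding.py    occupancy models, mass balance, ΔG/ΔH/ΔS bookkeeping
  itc.py        titration forward model, two-sets-of-sites fitting, CSV I/O
  kinetics.py   PNPP rate computation, Hill fitting, F test
  linkage.py    activation-hypothesis predictions, three-criterion report
  structure.py  mmCIF/PDB parsing, Kabsch superposition, swing metrics
  synth.py      seeded generators with ground truth (study-condition defaults)
  pipeline.py   orchestration and the consolidated analysis report
  cli.py        `allosense` command-line interface
docs/methods.md detailed model, parameter and design notes
```
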