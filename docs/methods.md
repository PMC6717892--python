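# Methods

This note records the models, conventions and numerical choices behind
`allosense`, and what the synthetic-data tests do and do not demonstrate.

## Binding models and their identification

**Two sets of sites.** Calorimetric titrations are described by two
independent site classes per monomer: fractional saturations
θᵢ = KᵢL/(1 + KᵢL), bound ligand per monomer n₁θ₁ + n₂θ₂. The fitted
parameters are (n₁, n₂, K₁, K₂, ΔH₁, ΔH₂). With n₁ ≈ n₂ ≈ 0.5 per monomer
this is one site of each class per dimer. Protein concentrations are
always per **monomer**; the sequential model below works per **dimer**.
Conversions are explicit, never implicit.

**Sequential (binding polynomial).** The dimer's macroscopic description
is Q(L) = 1 + β₁L + β₂L², f₀ = 1/Q, f₁ = β₁L/Q, f₂ = β₂L²/Q,
ν = f₁ + 2f₂. Mapping fitted class constants onto stepwise constants —
β₁ = 1/K_d(first event), β₂ = β₁/K_d(second event) — treats the fitted
classes as ordered binding events. The titration data cannot distinguish
microscopic site-specific constants from this macroscopic reading; the
identification is an interpretive assumption and every report that uses it
says so. Both parameterizations are first-class citizens of the API.

**Cooperativity index.** c = 4·K₂ₐ/K₁ₐ compares the second association
constant to the first after removing the 4× statistical factor of two
identical independent sites. The non-cooperative band is c ∈ [0.9, 1.1]
(±10%), reflecting the relative uncertainty of fitted constants of this
kind; outside it, c < 1 is negative and c > 1 positive cooperativity.

**Units.** Energies in calories (R = 1.987 cal mol⁻¹ K⁻¹), T fixed at
298.15 K (the titrations equilibrate at 25 °C), concentrations molar,
association constants M⁻¹. No unit auto-detection anywhere: interfaces
declare their units in their signatures and file schemas.

## ITC forward model

Each injection of dVᵢ into the constant-volume cell (V₀ = 1.4 ml)
multiplies existing concentrations by (1 − dVᵢ/V₀) and adds injectant at
c_syr·dVᵢ/V₀ (the "perfusion" convention). The cumulative heat content is
Q(i) = V₀·P(i)·[n₁θ₁ΔH₁ + n₂θ₂ΔH₂] at the free-ligand concentration
solving the mass balance, and the measured heat is
δq(i) = Q(i) − Q(i−1)(1 − dVᵢ/V₀), the correction accounting for complex
displaced from the active volume. Commercial instruments implement
variants of this volume correction that are not publicly specified;
because the simulator and fitter share this single forward model, all
round-trip results are independent of the convention, which is isolated in
one function pair (`TitrationProtocol.concentration_schedule`,
`_model_heats_ucal`).

Free ligand comes from bracketed bisection on [0, L_tot] (the residual is
strictly monotone, so the root is unique), 200 iteration cap, residual
tolerance 10⁻¹⁰·L_tot; the solver is vectorized across injections.

**Fitting.** Normalized heats (cal per mol of injectant) are fitted by
`least_squares` (via lmfit) over (n₁, n₂, log₁₀K₁, log₁₀K₂, ΔH₁, ΔH₂),
K bounds 10²–10¹⁰ M⁻¹, from five starts (the caller's initial guess plus
four seeded perturbations), keeping the lowest residual sum of squares.
The first (small) injection is excluded by default — the standard reason
the pre-injection exists. Standard errors come from the Jacobian-based
covariance, delta-rule-transformed from log K to K.

**Label ambiguity.** The two site classes enter the model symmetrically,
so a fit can return them in either order. When an initial guess is
supplied (the normal case) the returned labels are anchored to it: the
permutation nearest the guess in (log K, ΔH) space wins. Only when no
anchor exists does a fixed convention apply (class 1 = larger |ΔH|·K).
Anchoring was chosen over the fixed convention as the default because the
conventional ordering would silently swap the class labels of a ligand
whose *second* binding event is the tighter one (exactly the positive-
cooperativity case), making fitted tables hard to compare with their
initializing values.

**Curve-shape caveat.** For a single tight site class the steepest descent
of the normalized-heat curve sits at molar ratio ≈ n, the classic
equivalence-point result, and the tests assert it. For two classes with
strong negative cooperativity the weak site saturates gradually and the
curve is smeared: under the default cAMP conditions the half-of-initial-
plateau crossing falls at molar ratio ≈ 0.57 — after n₁ but well before
n₁ + n₂ ≈ 0.89. Tests assert the bracketing property, not a spurious
sharp-equivalence value.

## Activation kinetics

Rates are unit-agnostic: V_max carries the dataset's units, because
published activation plots cannot be reduced to a common specific-activity
unit from text alone. The generator therefore uses normalized V_max = 1
for cAMP and 1.22 for cGMP (the cGMP-saturated maximum is 22% higher).
Least squares is unweighted (no weighting scheme is stated for the source
data). K_half is fitted in log space (bounds 10⁻⁶–10⁹ μM) to keep it
positive without rescaling; h is bounded to [0.05, 10].

Model comparison against the h = 1 hyperbola uses the extra-sum-of-squares
F test, F = (RSS₁ − RSS)/(RSS/(n − 3)) with 1 and n − 3 degrees of
freedom. On exactly noiseless sigmoidal data RSS → 0 and F is reported as
infinity with p = 0.

## Linkage inference

The three criteria are operationalized as:

1. **Ordering.** The observed K_half ordering across the two ligands is
   compared with the orderings predicted by the single-site hypothesis
   (half-point of f₁ + f₂, dominated by the first-event affinity) and the
   double-occupancy hypothesis (half-point of f₂). The criterion favors
   whichever hypothesis uniquely reproduces the observed ordering.
2. **Twofold band.** K_half/K_d(low-affinity) must fall in [1.5, 3.0] for
   both ligands. The band brackets "approximately twofold": the published
   values give 2.42 and 2.30, and the band edges keep a genuine
   equal-to-K_d case (ratio 1) and a strongly decoupled case (ratio ≫ 3)
   out.
3. **Hill versus cooperativity.** h > 1.1 for a ligand whose ITC
   classification is negative cooperativity is treated as incompatible
   with single-site activation (which would give h < 1); the 0.1 margin
   over 1 absorbs fit uncertainty.

The verdict is `double_required` only when all three criteria favor it;
anything else is `undetermined` — the report never forces a conclusion.

Predictions assume free ligand ≈ total ligand. At assay-like enzyme loads
(1 mg/ml ≈ 23 μM monomer) this is wrong below ~1 μM activator, so every
prediction carries a warning and a depletion-corrected mode
(`enzyme_dimer_uM=...`) is provided; the free≈total default mirrors how
activation constants are conventionally compared with binding constants.

**Known discrepancy, left as such.** With the cAMP macroscopic constants,
occupancy-proportional activation through f₂ predicts an apparent Hill
coefficient near 1.1 — materially below the observed 1.85. The report
shows predicted and observed values side by side and does not attempt to
reconcile them; reproducing the observed steepness would require an
additional conformational equilibrium that the binding data alone cannot
constrain. The binding-polynomial bound h_app ≤ 2 holds for all
hypotheses and is property-tested.

## Structure metrics

Superposition is Kabsch SVD on paired Cα atoms (proper rotation enforced
via the determinant sign). The swing angle is defined operationally: align
the two states on the C-helix stator (residues 97–110, both chains), then
superpose the cNMP body (residues 6–83, one chain) of the aligned state
onto the reference body; the rotation angle of that second transform is
the swing. No hinge-axis decomposition is performed — the hinge (residues
84–95, fulcrum 81–86) is reported descriptively, and the β-hairpin shift
is operationalized as the maximum body Cα displacement after stator
alignment, since the hairpin's exact residue range is not specified in the
source analyses.

Rotation angles use atan2(|sin θ|, cos θ) with |sin θ| from the skew part
of R — full machine precision at small angles, where arccos((tr−1)/2)
loses half its digits. Author residue numbering is used throughout;
alternate conformers collapse to the highest-occupancy atom (ties keep the
first); no symmetry expansion.

Probe-distance tolerances: ±0.3 Å for specific Cα-pair distances
(Asp95–Ile62: 20.1 Å apo, 16.7 Å half-occupied, 14.6 Å doubly bound),
±1 Å for the 111→117 swap/non-swap distances (printed rounded to
integers), ±5° for swing angles (method-dependent). Tests against
deposited coordinates (6HQ2/6HQ3/6HQ4/6HQ7) run only when those files are
placed under `data/structures/`; they are not bundled. The synthetic
fixtures exercise the identical code path with exact ground truth.

## Synthetic data: what it shows and what it does not

Generator defaults are the study conditions: the published two-sets
best-fit parameters per ligand; the 1.4 ml cell with a 2 μl pre-injection
and 24 × 6 μl injections at 100 μM cell / 1.0 mM syringe (inside the
stated 50–150 μM and 0.5–1.6 mM ranges); 12 log-spaced activator
concentrations spanning 0.2–1000 μM in triplicate; heat noise 0.2 μcal
(the order of a VP-type instrument's baseline); relative rate noise 3%.
All draws flow from a single integer seed and are bit-reproducible.

The generators emulate the *fitted models plus measurement noise*. They do
not emulate baseline drift, injection-volume error, active-site titration
error, protein aggregation, substrate depletion during rate measurement,
or crystallographic coordinate error. Passing round-trip tests therefore
demonstrates that the estimation machinery is correct and well
conditioned under the study design — not that the models are the right
description of the real enzyme, which is exactly the question the original
experiments address. Wet-lab magnitudes that cannot be recomputed at desk
scale (the ~8-fold c-di-GMP turnover increase, the 22% V_max difference,
cellular c-di-GMP levels) enter only as generator defaults or fixture
constants.

Problem sizes used by the test suite and acceptance script — 25-injection
titrations, 12-point kinetic grids, 20- and 50-seed stochastic recovery
sweeps, 120-residue two-chain Cα scaffolds — were chosen as the smallest
designs that are faithful to the study conditions and statistically
informative for the properties under test.

## Error handling and determinism

Domain violations (negative concentrations, non-positive constants) raise
typed exceptions at the boundary. Iterative solves are deterministic:
bisection for mass balance, seeded multi-start for fits. Fit
non-convergence and non-identifiability (e.g. an all-zero thermogram, for
which ΔH → 0 and K is meaningless) are reported as flags on the result
object, never exceptions, so batch analyses degrade gracefully. Pipeline
reports serialize to sorted-key JSON and regenerate byte-identically from
identical inputs; provenance records the config hash, seed and package
version.
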