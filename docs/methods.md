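# Methods

## The model

The package implements a rule-based mass-action model of how two stress
MAPKs, JNK and p38, co-regulate the ATF2 transactivation-domain (TAD)
phosphoswitch (T69/T71) in a well-mixed cellular compartment.  Three
molecules are tracked:

* **ATF2 TAD** with three phosphosites — T69 and T71 (the switch) and
  the vertebrate-specific S90 — and a single MAPK-binding slot (the
  Zn-finger + D-motif module), so JNK and p38 binding are mutually
  exclusive.
* **JNK** and **p38**, each reduced to a two-state activity cycle:
  inactive (np) and active (pp).  Upstream kinase action (rate k7 for
  JNK, k6 for p38) and phosphatase deactivation (dp1, dp2) are first
  order and act only on free MAPKs, because the activating kinases and
  deactivating phosphatases engage the same docking surface as the
  substrate.

Binding modes:

* JNK binds the Zn-finger + D-motif module independently of any
  phosphorylation state (kon1/koff1, K_D ≈ 5 µM).
* Active p38 binds bipartitely through the D-motif/DRS plus the
  SPFENEF/F-motif–FRS interaction (kon2/koff2), but only when S90 is
  unphosphorylated — pS90 sterically blocks the FRS interface.
* p38 can also bind through the D-motif alone (kon3/koff3, K_D ≈ 1 mM),
  available to inactive p38 in any ATF2 state and to active p38 when
  S90 is phosphorylated.

Catalysis, always from the bound active complex: JNK phosphorylates T69
and T71 at equal rate k1 (independent of the other site) and S90 at k2;
p38 phosphorylates T69 at k3 and T71 at k3 while T69 is unmodified but
at the slower k4 once T69 carries phosphate.  Site phosphatases act
independently of binding state: dp3 removes pT69/pT71, dp4 removes pS90.

Expanding these rules over all site/bond/activity combinations yields 44
species and 144 mass-action reactions for the wild type (40 species for
the MUT4 variant, which lacks the bipartite mode).  Three design points
were genuinely open and were resolved as follows:

* **dp3/dp4 act on bound ATF2.**  Phosphatases are not modeled as
  binding species, so site dephosphorylation is applied wherever the
  site is phosphorylated.  One exception is structural: removing pS90 on
  the D-motif-only complex of *active* p38 would create a state
  excluded by the binding-eligibility rules (that complex exists only
  because pS90 blocks the bipartite mode), so that single reaction is
  omitted.  The flux through it is negligible in all regimes examined.
* **DRS-only eligibility is variant-independent.**  Active p38 with
  unmodified S90 is always routed to the bipartite mode; under MUT4 it
  therefore cannot bind at all.  This keeps the species set a strict
  subset of the wild type's.
* **Active p38 catalyzes from either complex.**  The 500-fold affinity
  difference between the modes already encodes the occupancy
  difference.

## Variants

`S90N` (the invertebrate-like switch): k2 = 0 and kon2 ← 4.5 × the
wild-type value, reproducing the ~5-fold stronger binding of the
asparagine motif.  `MUT4` (FENEF → AENEA): bipartite binding removed.
`JNK_IN_8` (covalent JNK inhibitor): k1 = k2 = 0 with binding intact.

## Parameters and calibration

Units are µM, seconds and µM⁻¹s⁻¹.  Measured anchors fix the binding
constants: kon1 = 1, koff1 = 5 (K_D 5 µM); kon3 = 0.1, koff3 = 100
(K_D 1 mM).  The bipartite K_D is set to 2 µM, a plausible avidity
value between the FRS-peptide affinity (~34 µM) and tight docking
complexes.  Catalytic rates k1 = k3 = 0.1 s⁻¹, k2 = 0.2 s⁻¹ and
k4 = 0.01 s⁻¹ (T71 on a pT69 substrate is markedly slower) are
order-of-magnitude choices for MAPK–substrate turnover in the bound
state.

The unmeasured in-cell rates are pinned by the anchoring fractions used
throughout the calibration workflow: 40 min after stimulation, 10% of
JNK and 5% of p38 are active and 80% of ATF2 is doubly phosphorylated in
the control.  With dp1 = 4.5 × 10⁻³ and dp2 = 4.75 × 10⁻³ s⁻¹ (free-MAPK
deactivation on the few-minute timescale), one-dimensional root solves
give k_stim7 = 5.0002 × 10⁻⁴, k_stim6 = 2.2488 × 10⁻⁴ and
dp3 = 1.6894 × 10⁻⁴ s⁻¹; these are frozen as package defaults.  Basal
activity is k_eq6 = k_eq7 = 10⁻⁶ s⁻¹ (the lower edge of the scan grid),
and dp4 = 10⁻³ s⁻¹ places pS90 at ~73% in the stimulated control.
Totals are 1 µM for each protein; the NanoBit system adds 1.65 µM
exogenous p38 to a single merged pool.

### Staged fitting

`calibration` mirrors the staged workflow: `jnk_stage` fits (k_stim7,
dp1) to pp-JNK time courses with a soft 10%-at-40-min anchor;
`p38_stage` fits (k_stim6, dp2, dp4) to the control and JNK-inhibited
NanoBit complex signals together with the control pp-p38 blot series;
`atf2_stage` fits dp3 with the 80% anchor.  Anchors enter as weighted
equality penalties (weight 100) so the objective stays smooth.  Rates
are searched in log10 space; the general default box is [10⁻⁶, 10²] s⁻¹,
and the in-cell stage fits use [10⁻⁵, 10⁻¹] s⁻¹, the minute-to-hour
band of first-order cellular signaling rates.

The pp-p38 blot series is part of the p38 stage for an identifiability
reason worth recording: the NanoBit signal is normalized to its
pre-stimulation value, which leaves (k_stim6, dp2) free to slide along a
compensation valley (nearly all p38 active, with rescaled complex
kinetics) that multiplicative noise can turn into the global optimum.
The absolute pp-p38 fraction breaks the degeneracy.

Optimization is differential evolution (rand1bin, dithered mutation
0.5–1.0, crossover 0.7, Sobol initialization, seeded) followed by
bounded Gauss–Newton refinement started from the DE winner and from a
few seeded Sobol points across the box; the best refined point is
returned.  The multistart refinement is what makes small DE budgets
reliable against the valley described above.  Fits run the solver at
rtol 10⁻⁵ / atol 10⁻⁹; reported simulations use rtol 10⁻⁸ / atol 10⁻¹².

## Simulation

The protocol is pre-equilibration under basal rates followed by a step
increase of k6/k7 at t = 0 (no ramp — the stimulus is modeled as
instantaneous) for 40 min.  Integration uses LSODA with the analytic
Jacobian assembled from the reaction network.  Pre-equilibration
integrates to 10⁵ s and refines with Newton iterations in which three
rows of the (singular) steady-state system are replaced by the ATF2,
JNK and p38 conservation constraints; the result has residuals at
machine precision and makes pre-equilibration exactly idempotent.  The
integration horizon doubles automatically if the refinement fails.

Observables: pp-MAPK fractions count every species containing the MAPK
in its active state; the pp-ATF2 fraction counts species with **both**
T69 and T71 phosphorylated, matching the anti-pT69/pT71 readout (singly
phosphorylated species are not counted; the antibody's cross-reactivity
is not modeled); the NanoBit-like signal is total p38:ATF2 complex
normalized to its pre-stimulation value.

## Response-surface analysis

`scan_analysis` stimulates the pre-equilibrated model at every point of
a log-spaced (k_stim6, k_stim7) grid — default 25 × 25 over
[10⁻⁶, 10⁻²] s⁻¹ — and records terminal pp-JNK/pp-p38 (µM, the surface
axes) and the pp-ATF2 fraction.  Pre-equilibration is shared across the
grid since it depends only on basal rates.

* **Inflection**: maximum of d(pp-ATF2)/d log(activated-MAPK fraction)
  along a path (diagonal or single-MAPK axis), parabolic-interpolated,
  reported as a percentage of the maximal activated fraction reached on
  the path (a percentage of total MAPK is also reported).  The
  half-maximum crossing is computed separately
  (`half_activation_crossing`) because the two metrics disagree
  precisely in the interesting regimes: an affinity-raised variant
  elevates the low-flux floor, which flattens the normalized sigmoid
  and moves the max-derivative point *up* while the half-activation
  flux moves *down*.  Scenario comparisons therefore use the
  half-activation flux.
* **Equal-sensitivity line**: zero contour (marching squares) of
  ∂f/∂log pp-JNK − ∂f/∂log pp-p38 from central differences on the log
  grid; points above it are more JNK-sensitive.
* **Local minima**: interior strict minima along the JNK axis with a
  configurable depth floor (default 10⁻³ fraction) against solver
  noise.
* **Scenarios** multiply on-rates only: kon1 × 100, kon2 × 100, and the
  combined 10-fold JNK-weaker / p38-stronger case (kon1 ÷ 10,
  kon2 × 10, kon3 × 10).

With the calibrated defaults the wild-type surface shows the headline
qualitative structure: S90N responses are monotone (additive) along
both axes; the wild type develops interior local minima along the JNK
axis at high p38 flux (JNK first vetoes p38 via pS90 before its own
catalysis compensates); raising JNK docking affinity 100-fold
desensitizes the switch to p38 (half-activation flux up ~3.3-fold)
while raising the p38 FRS affinity oversensitizes it (down ~3.2-fold).

A quantitative caveat is documented rather than hidden: the anchoring
fractions place 80% of the response at ~7.5% mean MAPK activation, so
the maximum log-derivative along the diagonal of any calibration
satisfying the anchors falls at ~1–4% of maximal activation.  Reported
inflection positions from this calibration are therefore lower than
would be obtained from independently measured catalytic rates, and the
acceptance script reports the measured values as computed.

## In vitro kinetics

`invitro_kinetics` provides the assay formulas used to parameterize the
model: nonlinear least-squares Michaelis–Menten fits (v = Vmax·S/(KM+S),
with a non-saturation flag when KM exceeds 10× the largest substrate
concentration), a four-parameter logistic dose–response with free Hill
slope (floor/ceiling constrained to [0, 1.2]; a response range below
0.1 raises a no-inhibition error), and the competitive-inhibition
conversion Ki = IC50/(1 + S/KM).  The reference configuration is the
pp-p38 → ATF2 reaction with KM = 17.3 µM and S = 2 µM, under which a Ki
of 33.6 µM corresponds to IC50 ≈ 37.5 µM.

## Synthetic data

The generator emulates the three measurement families the pipeline
consumes: anisomycin time courses of pp-JNK/pp-p38/pp-ATF2 fractions on
the 0/5/10/20/40-min blot grid; NanoBit-like complex signals (merged
2.65 µM p38 pool, normalized to untreated); and the in vitro tables
(substrate series 100…0.5 µM; 3-fold peptide dilutions from 1 mM).
Noise is multiplicative lognormal, mean-preserving, with stated CV —
blot densitometry and luminescence errors scale with signal.  Identical
seeds reproduce tables bit for bit.

What passing tests show — and do not show — about real data: the
generator draws from the same model family the calibrator fits, so
recovery tests demonstrate correctness of the fitting machinery and
identifiability of the design, not robustness to model misspecification.
Replicate-correlated errors, blot saturation, loading-control artifacts
and antibody cross-reactivity are not emulated.

## Numerical choices

LSODA with analytic Jacobian; rtol 10⁻⁸ / atol 10⁻¹² µM by default
(10⁻⁵/10⁻⁹ inside fits); pre-equilibration residual < 10⁻¹² µM/s
(machine-zero in practice); simulation failures inside an objective
return a 10⁶ penalty; inflection detection requires ≥ 15 path samples
and a response range ≥ 1% of span; local-minimum depth floor 10⁻³.
Problem sizes: 25 × 25 grids (625 ODE solves per surface, a few tens of
milliseconds each), 10 seeded replicates in recovery studies with
compact DE budgets (popsize multiplier 4–5, 8–10 generations, 4–5
refinement starts), chosen as the smallest designs that give stable
statistics.

## Limitations

Well-mixed, single-compartment; MAPKs have two states (no dual-site
activation-loop kinetics); phosphatases are implicit first-order sinks;
transcriptional output is out of scope — the model's endpoint is
phosphoswitch occupancy.  Default catalytic rates are plausible choices
consistent with the stated affinities and anchors, not measurements;
conclusions that depend on absolute inflection positions inherit that
uncertainty (see the caveat above).
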