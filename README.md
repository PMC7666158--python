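# phosphoswitch

Rule-based kinetic modeling of how two stress MAPKs — JNK and p38 —
co-regulate the ATF2 transactivation-domain phosphoswitch.

The ATF2 TAD carries a tandem phosphoswitch (T69/T71) whose
phosphorylation turns on transcription.  Both JNK and p38 phosphorylate
it, but through structurally different binding modes: JNK docks on a
Zn-finger + D-motif module regardless of its own activation state,
while active pp-p38 engages the TAD bipartitely through the D-motif
(DRS) and an SPFENEF/F-motif (FRS) interaction that exists only on the
activated kinase.  JNK additionally phosphorylates S90, which blocks
the p38 FRS interaction — one kinase vetoing the other's access.  This
package turns that rule set into an explicit mass-action network and
asks the quantitative question: how does phosphoswitch output depend on
the relative flux through the two upstream pathways?

It is intended for systems-biology practitioners who want a tested,
scriptable re-implementation of this model family: combinatorial
network expansion, stiff-ODE protocol simulation, staged parameter
calibration by differential evolution, and stimulation-rate
response-surface analysis.

## Model sketch

Species are ATF2 TAD states (T69, T71, S90 ∈ {U, P} × binding mode) and
two-state MAPKs (np/pp).  Mass-action rules:

* binding: JNK ↔ ATF2 (kon1/koff1, K_D ≈ 5 µM); pp-p38 ↔ ATF2
  bipartite (kon2/koff2, requires S90 = U); p38 ↔ ATF2 D-motif-only
  (kon3/koff3, K_D ≈ 1 mM),
* catalysis from the bound active complex: JNK → T69, T71 (k1) and
  S90 (k2); p38 → T69 (k3), T71 (k3, or k4 once T69 is phosphorylated),
* first-order MAPK activation (k6, k7: basal `k_eq`, stimulated
  `k_stim`) and deactivation (dp1, dp2) on free MAPKs only,
* site phosphatases dp3 (pT69/pT71) and dp4 (pS90).

The wild-type network has 44 species and 144 reactions.  Variants:
`S90N` (non-phosphorylatable S90, 4.5× stronger FRS binding), `MUT4`
(no bipartite mode), `JNK_IN_8` (JNK catalysis inhibited).  Default
rates are calibrated so that 40 min of stimulation activates ~10% of
JNK and ~5% of p38 and doubly phosphorylates ~80% of ATF2 — the
anchoring fractions of the calibration workflow (see
`docs/methods.md`).

## Worked example

Simulate the stimulated wild type from its pre-equilibrated basal
state:

```bash
phosphoswitch simulate --out run/
```

prints the 40-min endpoint observables:

```json
{
  "pp_jnk_fraction": 0.10000010215442426,
  "pp_p38_fraction": 0.05000074200712956,
  "pp_atf2_fraction": 0.7999989665033945,
  "ps90_fraction": 0.7334410205077678,
  "p38_atf2_complex_total": 0.00585265590597464
}
```

i.e. with 10% of JNK and 5% of p38 active, 80% of ATF2 carries the
double phosphorylation and ~73% carries pS90, which is why the
p38:ATF2 complex (the NanoBit-like observable) sits low at ~0.006 µM.
The same run from Python:

```python
import phosphoswitch as ps

params = ps.ModelParameters().with_variant("WT")
net = ps.ReactionNetwork.build(params)
traj = ps.run_protocol(net, params, ps.Protocol(sampling_times=(0.0, 2400.0)))
print(traj.observables["pp_atf2_fraction"][-1])   # 0.7999989665033945
```

Response surfaces and their metrics:

```python
surface = ps.run_flux_scan(net, params, ps.FluxGrid.default(25))
metrics = ps.SurfaceMetrics.from_surface(surface)
print(sorted(metrics.local_minima))   # rows (high p38 flux) with an
                                      # interior minimum along the JNK axis
```

On the wild-type surface the JNK-axis slices at high p38 flux are
non-monotone — increasing JNK flux first *lowers* pp-ATF2 (pS90 evicts
p38 before JNK catalysis compensates) — while the S90N surface is
additive and monotone along both axes.  The affinity scenarios
(`ps.run_affinity_scenarios`) reproduce the specificity logic: a
100-fold stronger JNK dock makes the switch less responsive to p38
(half-activation flux up ~3.3×), a 100-fold stronger p38 FRS makes it
oversensitive (~3.2× down).

Other entry points: `phosphoswitch fit --stage p38_stage --data
nanobit.csv --seed 1` (staged DE calibration), `scan`, `scenarios`,
`synth` (seeded synthetic datasets), `kinetics` (Michaelis–Menten /
IC50 / Ki fits), `build-network --format BNGL|SBML` (model export with
round-trip count checks).

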