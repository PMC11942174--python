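# Methods

This note records the models and procedures the package implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish
about real data.

## Virtual-screen triage funnel

The funnel operates on scored binary fingerprints (ECFP4-like bit-index
sets) and is deliberately agnostic about where the scores come from: any
predicted-affinity column works, so the pipeline composes with docking or
neural scorers without containing one.

Stage order is novelty → rank → cluster → filter → select:

* **Novelty filter.** A compound is excluded iff its maximum Tanimoto
  similarity to any known binder is *strictly greater* than the cutoff
  (default 0.5); a compound at exactly the cutoff is retained. The
  similarity of two empty fingerprints is defined as 0 with a warning —
  the conservative choice, since featureless records should neither be
  excluded as known-binder look-alikes nor merged into clusters.
* **Ranking.** Descending score, ties broken by ascending compound id;
  truncation to `top_n` (default 30,000). Every tie anywhere in the funnel
  is id-broken, which makes the whole funnel invariant to input order — a
  property the tests assert directly.
* **Butina clustering** at similarity ≥ cutoff (default 0.35). The
  unassigned compound with the most unassigned neighbors — recounted each
  round — becomes the next centroid and absorbs its unassigned neighbors.
  Recounting each round (rather than sorting neighbor counts once) changes
  assignments only in edge cases but makes the reference semantics exact;
  a brute-force similarity-matrix implementation in the test suite agrees
  on every random library of ≤ 12 compounds across 100 seeds.
* **Property filters.** The proprietary medicinal-chemistry rule set used
  in industrial screens is not reproducible; the defaults here are
  documented stand-ins: Lipinski-style bounds (MW ≤ 500, logP ≤ 5,
  HBD ≤ 5, HBA ≤ 10) plus rejection of any record with a positive
  `toxicophore_alerts` count. Predicates are an ordered named list and a
  record's rejection is attributed to the first predicate it fails.
* **Selection.** How "top 96" interacts with diversity clusters is
  underdetermined; the rule adopted is: visit clusters by their best
  member's score, take that best member, at most one per cluster, up to
  `n_select` (default 96). With all-singleton clusters this provably
  reduces to plain rank-truncation, which the tests use as a cross-check.

## Rb⁺ efflux quantification and Hill fitting

Fractional efflux is `efflux / (efflux + lysate)` per well. Preprocessing
follows the assay convention: average technical duplicates within each
biological replicate, subtract the mean untransfected (endogenous
background) fraction, divide by the mean vehicle (dose 0) fraction of the
reference condition. Negative post-subtraction values are clipped to 0 and
flagged, never silently. A processed table refuses a second pass — the
normalization is not idempotent, so double application is treated as an
error rather than a no-op.

The dose-response model is the "log(inhibitor) vs response — variable
slope" four-parameter logistic, written directly in dose:

    y(x) = bottom + (top − bottom) / (1 + (x/IC50)^h),  h > 0.

The assay literature rarely prints the equation; this parameterization is
fixed here and decreasing in dose for h > 0, with y(0) = top, so vehicle
points anchor the top plateau naturally without entering any log-dose
axis. Fitting is trust-region least squares on (top, bottom, log₁₀ IC50,
h) with bounds top ∈ [0, 1.5], bottom ∈ [0, 1.5] (a fit with bottom > top
is flagged non-convergent), h ∈ (0, 10], and multi-start from 5 log-spaced
IC50 seeds spanning the dose range — cheap insurance against spurious
minima on noisy 5–8-point curves. Standard errors come from the fit
covariance; the IC50 SE is delta-method-propagated from the log scale.
Degenerate inputs (flat responses, IC50 outside [min dose/100, max
dose·100]) are reported with `converged=False` rather than raised.
Requiring ≥ 4 distinct nonzero doses is the minimum for a 4-parameter fit.

Because potency is conventionally reported as mean ± SEM over independent
transfections, `ic50_with_sem` fits each biological replicate separately
and summarizes across replicates; the covariance-based per-fit SE remains
available as a secondary output. Fitting on a log-IC50 scale makes the
estimator exactly scale-equivariant: scaling all doses by c scales the
IC50 by c, which the tests assert to 1e-6 relative.

Group comparisons (`compare_to_control`) are a thin wrapper over standard
machinery: one-way ANOVA (scipy `f_oneway`) with Dunnett-vs-control or
Tukey all-pairs adjusted p-values (scipy `dunnett` / `tukey_hsd`). Groups
of identical constants yield an undefined F, flagged, with all adjusted
p-values set to 1 by convention. Under a simulated global null the
family-wise rate of any significant Dunnett comparison sits inside the
binomial 95% interval around the nominal α = 0.05.

## Binding-pocket dynamics

Frames are superposed onto frame 0 of their own run by the Kabsch SVD
solution restricted to a pocket Cα selection, with the proper-rotation
determinant correction; the fitted rigid transform is applied to all atoms
so the ligand rides along. Degenerate (collinear) selections are rejected.
A quaternion (Horn) solver in the test suite provides the independent
oracle, agreeing to 1e-9 in RMSD.

**Mobility.** Per fragment, the center of mass (mass-weighted over heavy
atoms by default; geometric-center and all-atom options exist for
sensitivity checks) is traced through the aligned frames, and mobility is
the root-mean-square scalar displacement from the frame-0 COM, per run;
the pooled value is the root-mean over runs. For isotropic per-axis jitter
of SD σ the expectation is √3·σ, which the generators are validated
against within 15% at 5 × 300 frames. Frame 0 after alignment is the
"initial position" reference by construction.

**Contacts.** A residue is in contact in a frame iff its minimum
heavy-atom pair distance to any ligand heavy atom is ≤ the cutoff
(default 3.5 Å, inclusive). Hydrogens are excluded: MD analyses of this
kind conventionally use heavy-atom contacts, and the criterion stays
meaningful on structures without resolved hydrogens. Per-frame neighbor
searches use a k-d tree; an exhaustive all-pairs scan in the test suite
anchors its correctness on every fixture ≤ 50 atoms. The binding-residue
set retains residues with contact fraction ≥ 0.30 in ≥ 3 of 5 runs (both
comparisons inclusive, "at least"); the quorum generalizes to
⌈3n/5⌉ for n ≠ 5 runs. Inclusion is driven by whole-ligand contact;
per-fragment fractions are reported in the frequency table but do not
drive inclusion. The display table (`frequency_report`) keeps residues
whose run-averaged whole-ligand fraction is *strictly* above the display
threshold (default 0.40).

## Pore-radius profiling

At each plane z along a straight, user-supplied pore axis the profiler
reports the largest sphere centered in that plane touching no atom:
max over centers of min over atoms of (distance − vdW radius). Search is a
deterministic lateral grid (0.1 Å) hill-climb seeded from the previous
plane's optimal center (the axis for the first plane), refined by
Nelder–Mead. The climb is local on purpose: the global in-plane maximum
can sit outside the channel wall near the open ends of a finite structure,
whereas the seeded climb stays in the pore's own basin and follows the
channel, which is also what annealing-based profilers compute. Radii are
capped at `max_probe` with a flag (including planes with no atoms in
reach). Default vdW radii are the Bondi set, overridable per element;
shrinking all radii by δ provably shifts a cylindrically symmetric profile
up by exactly δ, which serves as an analytic regression test. No automatic
axis detection is attempted — channel structures are conventionally
deposited pre-oriented with the symmetry axis along z.

`min_radius_near` localizes the profile minimum within ± a window of a
residue set's mean axial coordinate (e.g. a bundle-crossing gate ring),
warning when the window's minimum is an endpoint.

## Synthetic fixtures: what they do and do not show

Generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs, and every truth record carries its seed.

* **Trajectories.** A ring of 3-heavy-atom residues (radius 12 Å) around a
  5-fragment, 11-atom ligand. Fragment jitter is a rigid Gaussian
  displacement per fragment per frame (frame 0 stays at rest, making √3·σ
  the exact mobility expectation); global drift is a per-frame rigid
  rotation+translation of everything, exactly removable by alignment.
  Contact occupancies are planted by moving the target residue's outermost
  side-chain atom to 2.8 Å from the nearest ligand heavy atom of that
  frame (resting ≥ 6 Å away) in exactly round(q·n_frames) seeded frames —
  the same min-heavy-atom-pair distance definition the analyzer uses, so
  planted truths are exact, not approximate, even under fragment jitter.
  Residue-side planting also keeps fragment COMs clean for mobility truths
  and makes conflicting placements impossible; plans naming unknown
  residues, out-of-range runs or occupancies outside [0, 1] are rejected
  as infeasible. The fixtures contain no force-field physics, water, or
  realistic protein geometry: passing tests establish the correctness of
  the analysis operators, not the realism of any simulation.
* **Plates.** Defaults mirror the assay conditions: doses 0–200 µM
  spanning the 1–200 µM range, technical duplicates, three biological
  replicates, 5% noise CV, a 0.1 untransfected background fraction, and a
  planted curve (top 0.7, bottom 0.05, IC50 9.23 µM, slope 1). Noise is
  multiplicative log-normal (unit mean) on the raw efflux and lysate
  signals, not on fractions — instrument readings are positive counts, and
  fractions then inherit realistic heteroscedasticity. Validation requires
  background + top ≤ 1 so noiseless fractions stay in [0, 1].
* **Libraries.** Clusters grow from random seed fingerprints (256 bits, 32
  on) by independent per-bit flips; known-binder look-alikes are exact
  copies of generated binder fingerprints, so the strict >0.5 novelty
  boundary removes exactly them. Properties are drawn inside the Lipinski
  box so the default filters do not confound funnel tests.
* **Pores.** Rings of atoms with centers on the stated wall radius (so the
  analytic on-axis probe radius is wall − atom radius), tiled at 0.5 Å;
  a coarse-tiling flag is raised when angular gaps exceed the atom radius.
  The 2.25 Å-wall / 1.5 Å-atom constricted fixture plants a 0.75 Å
  constriction, the closed-gate dimension of an inward-rectifier pore.

## Verification studies and problem sizes

`scripts/acceptance.py` (shared harness with `tests/test_acceptance.py`)
runs: 500 simulated triplicate dose-response experiments (IC50 log-uniform
2–50 µM) — median |relative error| of the IC50 estimate and its bias; 100
random contact fixtures against the all-pairs oracle plus 10 planted
occupancy/retained-set fixtures; drift realignment, rigid-motion
invariance and σ-ordering on 5-run ensembles; 100 random Butina libraries
against the brute-force reference plus 20 planted-cluster/novelty
libraries; analytic cylinder and constriction pore fixtures; and a
1000-rep Dunnett global-null calibration. These sizes keep the full run
under two minutes on one CPU while leaving Monte-Carlo margins well inside
the asserted tolerances.

## Known limitations

* Binary trajectory formats (XTC/DCD) are not read natively; ensembles
  enter as multi-frame XYZ plus a PDB topology, or programmatically.
* The pore tracer assumes a straight axis; curved channels would need a
  bent-axis extension.
* The toxicophore/oral-availability filters are explicit stand-ins, not
  the proprietary rule sets used in industrial screens.
* The Hill machinery covers inhibition curves only (no EC50/stimulation
  parameterization), matching the assay it quantifies.
* Printed experimental potencies from the original assays depend on raw
  data that is not redistributable; the package's claims are therefore
  recovery of planted truths and oracle agreement, not re-derivation of
  published numbers.
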