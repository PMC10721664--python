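# Methods

## The data model

An epicardial surface is a triangulated closed shell; every triangle
carries a chamber label (LV or RV). Electrical state is a per-vertex
activation time in milliseconds from QRS onset; each map is re-referenced
so its earliest vertex activates at t = 0 (the loader offers a strict mode
that errors instead of shifting). A triangle's activation time is the
arithmetic mean of its three vertex times. This convention matches how
mapping systems and the simulator emit data (values at points), while
giving every surface element a well-defined area weight; its cost is that
element times cannot be prescribed independently of their neighbours, which
matters for the linear-map construction below.

Units are fixed — mm and ms — with no inference. On-disk formats are plain
text: a CSV pair (`vertices.csv`: id,x,y,z; `triangles.csv`:
id,v1,v2,v3,label), a narrow ASCII-PLY dialect with a per-face integer
`chamber` property (0 = LV, 1 = RV), and activation maps as
`vertex_id,time_ms` CSV. Coordinates are written with 17 significant
digits and parsed with round-trip float precision, so ASCII round-trips
are bit-exact.

## Activation curves and the LVx/RVx/BIVx statistics

The activation curve of a scope is the cumulative area fraction of its
triangles, sorted by activation time, with tied times merged into single
step events; it is a right-continuous step function ending at 1. The
time-to-fraction statistic is the step-function infimum — the smallest
event time whose cumulative fraction reaches f — with no interpolation
between surface elements (an element is either activated or not). Area
weighting is the default; vertex-count weighting (every element equal) is
available behind a flag since electrogram-point semantics are also
plausible, and the two coincide exactly on uniform-area meshes.

QRS duration defaults to the map-derived biventricular completion time
(BIV time at fraction 1). A measured 12-lead QRSd can be supplied instead
and is not required to bound the map's completion time — surface-ECG QRS
and epicardial completion genuinely differ. Ratios are carried at full
precision; two-decimal rounding is applied only for display.

|LVRVDIFF| = |LV80 − RV80| is the interventricular synchrony score;
fractional changes (post − pre)/pre are used both for the LVESVI response
measure and for RV80-FC under biventricular pacing (undefined, and an
error, at pre = 0).

## The wavefront simulator

Activation is modeled as multi-source shortest-path travel time on the
mesh edge graph: vertex time = min over breakthrough sites of (onset delay
+ geodesic travel time), edge weight = length / local conduction velocity.
Local velocity is a base speed (default 1.0 mm/ms, the order of working-
myocardium epicardial spread) times a per-chamber scale, times a trans-seam
multiplier (default 0.45) on edges whose incident triangles span both
chambers, times a scar multiplier when the edge midpoint lies within a
patch radius (Euclidean membership, chosen over geodesic for determinism
and simplicity). A graph model was chosen over fast marching or monodomain
deliberately: it is exactly checkable against an independent shortest-path
solver (the suite asserts bitwise equality against a networkx reference),
and the statistics under test depend on the ordering and spacing of element
activation times, not sub-element geometric fidelity. Graph distances
overestimate true surface geodesics by a mesh-dependent factor; none of the
tested properties depend on that factor.

Presets encode phenomenology, not conduction physiology, since only the
phenomenology is specified for the clinical patterns: LBBB places a single
breakthrough on the RV free wall, so the LV is reached late through the
slow seam — producing LV80 > RV80 and the characteristic late-LV tail;
RBBB is the mirror image. Paced presets place sites at the RV apex and/or
LV lateral wall; biventricular pacing with LV-first offset delays the RV
site by 30 ms. Jitter (log-normal velocity perturbations with σ = 0.06–0.10
and site relocation within an 8 mm neighbourhood) emulates patient-to-
patient variability; the ordering guarantees hold across all tested seeds
because they follow from breakthrough-site topology, not from the jittered
magnitudes.

## Linear activation maps

The analytic reference state — cumulative area fraction linear in time from
onset to completion, hence every time-to-fraction ratio equal to the
fraction itself — is constructed by a probability-integral transform: sweep
vertices base-to-apex, set each vertex's time to duration × (area fraction
swept), then sharpen with three fixed-point passes that re-map vertex times
through the realized area-weighted triangle-time distribution (each pass
removes the curvature introduced by triangle times being vertex means).
Because the LV/RV seam is a plane containing the sweep axis of the
symmetric shell, LV, RV and BIV curves are linear simultaneously.

Residual deviation is a boundary effect of the first and last elements:
the 80% crossing lands within about one triangle's area granularity
(max single-triangle area / total area), the completion time within a
vertex ring's worth (~3 triangles). Tests therefore use 2× (times) and 4×
(ratios) the single-triangle granularity as the bound; at refinement
level 3 (1280 triangles) the measured deviations are ~0.5× and ~2.3×.

## Synthetic cohorts

`simulate_cohort` draws, per patient: a bundle-branch-block type
(P(LBBB) = 2/3, matching the 30-patient design the generator emulates),
jittered conduction velocities and sites from a per-patient substream
(numpy SeedSequence spawning from one integer seed, so cohorts are bitwise
reproducible), and activation maps for the five settings. Tissue velocity
is treated as a patient property — pacing changes breakthrough sites and
delays, not myocardial conduction — which also lets one multi-source
shortest-path solve serve all settings. Q-LV is measured mechanistically
as the intrinsic-map activation time at the patient's LV pacing site.

Outcomes are `intercept + Σ slope × predictor + Normal(0, σ)`, with the
predictors exactly those of the response models: |LVRVDIFF| under LVP and
RVP for the two LVESVI fractional changes, LV80 under BIVP for post-CRT
log BNP, the RV80 fractional change under BIVP for Δ peak VO₂, and
intrinsic RV80 for RVEF. Default intercepts, slopes and noise scales are
chosen once so simulated outcomes span the clinically observed ranges
(LVESVI-FC around −0.3…+0.2, log BNP 4–6, Δ peak VO₂ within ±2 mL/kg/min,
RVEF 20–45%): e.g. LVESVI-FC = −0.30 + 0.005·|LVRVDIFF|_LVP + N(0, 0.10).

What the generator does **not** emulate: septal activation (epicardial
surfaces only), inverse-reconstruction error of real body-surface mapping,
visit-to-visit variability (each setting's map is a fresh draw), missing
outcomes, and any nonlinearity or confounding in the outcome couplings.
Passing tests therefore demonstrate that the pipeline computes its
statistics correctly and recovers generative structure — not that the
clinical effect sizes themselves are reproduced.

## Statistics

- One-sample t-tests of ratio parameters against the constant-rate
  reference 0.8 (scipy); the all-identical degenerate sample is defined as
  t = 0, p = 1 at the reference.
- Within-group OLS slopes of LV80/RV80/BIV80 on QRSd; the LBBB-vs-RBBB
  difference is the group×QRS interaction of the pooled model, whose
  coefficient equals the difference of within-group slopes.
- Ratio models: ratio ~ LBBB (coded 1) with per-moderator interaction
  terms for scar, ischemic etiology, Q-LV and QRSd.
- Robust regression: Huber M-estimation by IRLS, tuning constant 1.345,
  scale re-estimated each iteration by MAD, convergence when coefficients
  change < 1e-8 (max 200 iterations, non-convergence is an error carrying
  the last iterate). Standard errors and p-values from the robust fit
  (statsmodels RLM); R² and the model p-value are defined on the weighted
  least-squares fit at the final Huber weights, since no robust R² is
  otherwise pinned down.
- Missing outcomes: listwise deletion per model with n_used reported.
- Group comparisons: Kruskal–Wallis (continuous), Fisher exact
  (categorical; scipy for 2×2, exact conditional enumeration for 2×k),
  Shapiro–Wilk as a diagnostic. Raw p-values are reported throughout;
  Benjamini–Hochberg adjustment is available but off by default.

## Pacing recommendation

The recommended setting is the paced configuration minimizing |LVRVDIFF|
at 80%, because interventricular electrical synchrony is the quantity tied
to LV functional response; ties break by smaller BIV80, then by the fixed
order BIVP, BIVP_LV30, LVP, RVP so the answer is unique.
BIVP_LV30 is kept distinct from BIVP in reporting. Responder thresholds
are inclusive ("at least"): LVESVI-FC ≤ −0.05 and Δ peak VO₂ ≥ 1.0
mL/kg/min; a missing outcome yields a missing flag, never False.

## Problem sizes and numerical choices

Unit and property tests run on shells at refinement 2–3 (320–1280
triangles); granularity-sensitive checks use level 3. The simulator–oracle
equivalence suite uses twenty 500-vertex random convex triangulations. The
parameter-recovery experiment uses cohorts of n = 200 on the level-2 shell
across 500 replicates; the t-test calibration uses 10,000 replicates at
n = 20. Tie-breaks everywhere are deterministic (stable sorts, fixed
setting order); all randomness flows from explicit integer seeds.

## Known limitations

- The ellipsoidal shell is one connected surface partitioned by a septal
  plane; there is no septum, no valve plane, and LV/RV areas are equal by
  symmetry — real RV free walls are smaller.
- Graph geodesics, not surface geodesics: travel times are exact on the
  graph but overestimate continuum distances anisotropically.
- The 2×k Fisher test enumerates the full conditional table space; it is
  exact but exponential in k, intended for the small contingency tables of
  cohort description.
- Huber ±2·SE intervals at n = 200 have finite-sample coverage ≈ 95.0–95.3%
  (t-theory: P(|T₁₉₈| ≤ 2) ≈ 0.953), not the asymptotic 95.45%.
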