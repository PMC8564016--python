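# Methods

## Scope and model

`ffram` computes a non-invasive estimate of fractional flow reserve
from (i) a coronary-tree geometry given as per-branch arc-length /
lumen-area profiles with parent–child topology, and (ii) scalar
physiology: left-ventricular mass (LVM), systolic/diastolic cuff
pressure, optionally hematocrit.  The estimate is

FFR(s) = 1 − ΔP_cum(s) / Pa,

where ΔP_cum accumulates, from the ostium outward, the viscous
Hagen–Poiseuille density 8πμq/A(s)² outside lesions and an analytical
three-segment loss model inside lesions.  The model is steady-state and
rigid-walled; pulsatility, vessel compliance, autoregulation and
microvascular resistance are all outside its scope, as is any image
processing — geometry arrives already segmented.

## Perfusion pressure

Pa = DBP + (SBP − DBP)/3 − 6.8 mmHg.  The first two terms are the
standard cuff estimate of mean arterial pressure; the fixed offset
accounts for the fall of aortic pressure under pharmacologic hyperemia.
The offset is configurable (`pa_offset_mmhg`); setting it to 0 gives
resting MAP.

## Flow model

* **Total resting flow.**  Q_total = q0 · LVM, with q0 = 0.8
  mL·min⁻¹·g⁻¹ — a standard resting myocardial perfusion per gram.  The
  linear LVM relation is the model's only patient-flow input; q0 is
  exposed in the configuration because literature values span roughly
  0.6–1.0.
* **Allocation at bifurcations.**  Daughter flows are proportional to
  (reference healthy diameter)^γ with γ = 7/3, the flow–diameter
  scaling exponent for coronary bifurcations; Murray's γ = 3 is a
  configuration change.  The reference diameter of a daughter is the
  75th percentile of equivalent diameters over its proximal 5 mm, so a
  stenosis sitting at a daughter's ostium does not starve its own
  subtree — the analytical model must not create a flow–lesion feedback
  it cannot resolve.  Conservation is exact by construction (shares sum
  to the incoming flow), and is re-checked to 1e-12 relative in tests.
* **Hyperemia.**  Terminal flows are multiplied by k(DS*), where DS* is
  the maximum diameter stenosis on the supply path (with serial
  lesions, the tightest governs the reserve — a conservative choice).
  k is piecewise linear: k_max = 4.0 up to DS 0.3, falling to
  k_floor = 1.0 at DS 0.9.  The plateau reflects the ~4-fold flow
  increase of adenosine hyperemia in healthy vessels; the linear decay
  encodes exhaustion of vasodilatory reserve with severity.  The
  functional form is a modelling choice of this package, chosen for
  monotonicity, boundedness and two-parameter interpretability; all
  four numbers are configurable.  Internal branch flows are rebuilt by
  summation from the leaves so conservation again holds to round-off.

## Lesion anatomy

Lesions are measured on a median-smoothed (default 1 mm window),
monotone-cubic-resampled (default 0.25 mm grid) area profile:

1. a disease-free reference A_ref(s) interpolates linearly between
   "healthy anchors" (local area maxima above the 60th percentile, plus
   the branch endpoints);
2. lesion cores are runs where DS(s) = 1 − √(A/A_ref) ≥ 0.25 (the
   lower bound of an angiographically "mild" stenosis);
3. each core is extended outward past the DS < ds_min/2 shoulder and on
   to the reference-recovery point where DS effectively vanishes
   (< 1e-4).  The shoulder positions are refined on the *unsmoothed*
   profile: a moving median blurs the taper-to-healthy corner by up to
   half a window, and stopping at the half-threshold crossing alone
   systematically truncates smooth tapers (for a half-cosine taper at
   DS 0.5 the crossing sits a third of the taper length inside the true
   edge).  With the recovery-point rule, length recovery on synthetic
   sweeps is grid-exact;
4. the throat is the contiguous region with A ≤ 1.05·A_s around the
   minimum — a pointwise minimum would give the maximally stenosed
   segment zero length on any smooth profile;
5. entrance and exit angles use equivalent circular radii:
   α = atan((r_p − r_s)/L_ps), β = atan((r_d − r_s)/L_sd), 90° for an
   abrupt step.  For anatomy on the scale of real lesion tables
   (throat ≈ 3.8 mm², lengths ≈ 10.8/3.7/3.5 mm) these give angles of a
   few to ~15 degrees, the range reported for coronary lesions.

A_p and A_d are read at the detected shoulders.  Multi-lesion vessels
report the hemodynamically dominant lesion (largest drop, ties to the
proximal one).

## Pressure-drop closures

The taper viscous drop integrates the Poiseuille density over a
linear-radius taper in closed form,
I = L/(3(r1−r2)) (1/r2³ − 1/r1³), continuous in the straight-tube
limit.  The entrance coefficient ζ_c = 0.5(1 − A_s/A_p)^{3/4} sin α is
a gradual-contraction correlation; the exit coefficient
ζ_e = min(1, 2.6 sin β) is a diffuser rule capped at the Borda–Carnot
sudden-expansion value.  Both reduce correctly in the abrupt and axial
limits and carry the stated dependence on the entrance/exit angles.
All three lesion components are irreversible losses and therefore
non-negative; the reversible Bernoulli difference between the lesion
ends is excluded by default (component tables of real cohorts report
all three segment drops as positive, which a decomposition carrying
full Bernoulli recovery cannot produce).  A flag
(`include_bernoulli_net`) adds the net term for study.  These closures
are isolated behind `lesion_pressure_drop` so alternatives can be
swapped without touching callers.

## Numerical choices

* SI units internally (m, m², Pa, m³/s); clinical units (mm, mm², mmHg,
  mL/s) at every file and CLI boundary.  1 mmHg = 133.322387415 Pa.
* Resampling uses shape-preserving monotone-cubic (PCHIP)
  interpolation: resampled areas never overshoot the bracketing input
  samples, so resampling cannot create phantom stenoses.
* Path integrals use trapezoid quadrature on the working grid, with
  interval endpoints added explicitly (a lesion's proximal end need not
  be a grid point) and lesion interiors excluded — their drop is
  charged analytically.  An independent verification oracle
  (`oracle_pressure_drop`) re-integrates the same closure by Simpson
  quadrature on a ≥10× finer grid; analytic and oracle drops agree to
  ≤1e-4 relative on linear-taper lesions (the taper closed form is
  exact for that geometry).
* If cumulative losses reach Pa the FFR is clamped at a configurable
  floor (default 0.01) with a warning: near-occlusive lesions are
  outside the model's validity, and a clamped profile is flagged on the
  result.
* Fully occluded branches (area 0, flagged) are rejected by flow and
  pressure routines with a dedicated error rather than dividing by
  zero.

## Synthetic geometry and the virtual cohort

The generator realizes the three-segment lesion anatomy exactly:
half-cosine radius tapers (C¹ smooth, so detection is exercised on
non-trivial profiles) or linear tapers (for which the viscous closed
form is exact — used by the oracle tests), with the lesion breakpoints
inserted into the sampling grid so the specified throat area is realized
exactly.  Virtual cohorts draw anatomy from truncated normals matched
to a typical invasively studied coronary-disease cohort (A_p
6.80 ± 3.66 mm², A_s-equivalent severities, L 10.77 ± 6.74 mm, tapers
≈ 3.5–3.7 ± 3 mm, LVM 115 ± 31 g, cuff 134 ± 17 / 77 ± 11 mmHg,
hematocrit 0.42 ± 0.03), with a configurable prevalence (default 0.43)
of DS ≥ 0.5.  Severities for the two prevalence arms are truncated
normals on [0.5, 0.9] and [0.02, 0.5).  Each cohort vessel is a single
branch standing in for one coronary artery; its myocardial territory is
therefore a fraction of the LVM, set by caliber–flow adaptation
(Murray's cube law against a nominal 4.5 mm root caliber).  Without
this, a small-caliber vessel would implausibly carry the whole LV's
flow and show ischemic FFR with no stenosis.  Per-vessel RNG
substreams are keyed by (seed, index), so enlarging a cohort never
reshuffles earlier vessels.

What the cohort does **not** emulate: real tortuosity, diffuse disease,
eccentric lumina, segmentation noise, multi-vessel trees per patient,
or CFD-grade "true" FFR labels.  Passing tests on this cohort
demonstrate internal consistency and calibrated statistics, not
clinical accuracy.

## Evaluation statistics

ROC AUC is the tie-corrected Mann–Whitney statistic; orientation
(whether low scores flag disease, as for FFR, or high scores, as for
diameter stenosis) is an explicit argument everywhere and never
inferred.  Paired AUCs are compared with the DeLong
structural-components estimator (normal-approximation CIs and two-sided
p); its type-I error is verified by Monte-Carlo at n = 30.  Per-patient
aggregation uses the worst vessel: minimum for FFR-like indexes,
maximum for stenosis-like, and a patient is ischemic if any vessel's
invasive FFR ≤ 0.80 (threshold inclusive).  Diameter-stenosis calls are
reported at both the ≥50% and ≥70% thresholds.

## Problem sizes

Default verification sizes — 1000 quadrature draws, 200 oracle lesions,
200-vessel recovery sweep, 100-tree monotonicity suite, 2000 DeLong
null replicates, 100-vessel cohort summaries — run in a few seconds on
one CPU and give stable results across seeds.

## Known limitations

* The loss coefficients are engineering correlations; absolute drops
  for a specific lesion geometry carry the usual factor-level
  uncertainty of such closures, even though trends (in A_s, q, L, α, β)
  are robust.
* k(DS) is a stylized hyperemia model; patient-specific microvascular
  disease is not represented.
* Serial lesions add their drops with no interaction correction, and
  the tightest lesion governs the hyperemic multiplier of the whole
  path.
* The per-branch flow is piecewise constant between junctions; flow
  loss to unresolved side branches is ignored.
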