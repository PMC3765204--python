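# Methods

## The problem and the model

Conventional reporting of glioma surgery results — extent of resection (EOR)
percentages, "gross total resection" rates, residual volumes — is biased by
where in the brain the tumors happen to sit: a cohort with more insular or
peri-rolandic tumors will report worse numbers for reasons that have nothing
to do with surgical quality. Resection probability maps (RPMs) remove this
bias by asking, voxel by voxel, how often tissue at a given anatomical
location was resected.

Inputs are per-patient pairs of binary masks on a common 1 mm template grid
(nominally MNI152): the postoperative *tumor* mask (resection cavity plus
residual glioma — the compound is the reference tumor volume) and the
*residual* mask, which must be a subset of it. For a cohort, at every voxel
v,

- T(v) = number of patients with glioma at v (tumor localization map),
- R(v) = number of patients with residual glioma at v,
- P(v) = (T(v) − R(v)) / T(v), the resection probability, defined where
  T(v) ≥ 1 and stored as NaN elsewhere so that no-data can never be
  confused with never-resected.

Maps are built per hemisphere, using the clinical lateralization label of
each patient (not the mask centroid), so that contralateral tumor extension
stays attached to the patient's side. Pooling cohorts sums T and R before
recomputing P; the pooled voxels with T ≥ 1 and P = 0 form the "minimal
common brain" — tissue never resected in any patient.

## Voxel-wise comparison of two cohorts

At each voxel informative in both cohorts (the *testable* domain), the
resected/residual counts form a 2×2 table (a, b; c, d) with a + b = T_A(v),
c + d = T_B(v). Voxels informative in only one cohort receive no test
(NaN): a 2×2 test with an empty margin is undefined.

**Fisher exact test (two-sided).** p is the sum of hypergeometric point
masses, over the margin-constrained support, that do not exceed the observed
table's mass — the convention of standard exact-test implementations, not
the doubled one-sided p. Point masses are compared with a relative tie
tolerance of 1e-7 to absorb floating-point noise; the p-value is clipped to
(0, 1]. Degenerate cases: an all-zero table is NaN; margins admitting a
single table give p = 1 exactly.

**Effect size.** The conditional maximum-likelihood odds ratio: the value ψ
for which the expectation of the first cell under Fisher's noncentral
hypergeometric distribution (given all four margins) equals the observed
cell. It is found by bracketed root-finding on log ψ (expanding bracket +
Brent, xtol 1e-12). When the observed cell sits at the upper/lower end of
the attainable support the estimate is +∞/0; single-point support yields
NaN. Maps display log ψ (a symmetric scale whose sign says which cohort
resected more); worked examples report ψ itself. For the reference table
(10 of 12 resected vs 3 of 10) this gives ψ = 10.13 — deliberately the
conditional MLE, not the sample cross-product ratio 35/3 ≈ 11.67.

**Permutation-adjusted p-values.** Voxel measurements are spatially
dependent, so per-voxel significance is calibrated against an empirical
null: patients are relabeled to the two cohorts with cohort sizes preserved,
m distinct non-identity assignments drawn without replacement (rejection
sampling with a seeded generator; default m = 2000, reduced for desk-scale
experiments). The pooled case list is canonicalized by sorting on patient
id before drawing, so results do not depend on input order. For each
relabeling the per-voxel Fisher p is recomputed (a lazily-filled lookup
table over margin pairs makes this cheap — tables recur massively), and

    p_adj(v) = (1 + #{j : p_j(v) ≤ p_obs(v)}) / (m + 1),

the add-one rank guaranteeing p_adj ≥ 1/(m+1) and finite-sample validity
(p_adj is super-uniform under exchangeability). Relabeled tables can have an
empty cohort margin at a voxel; these get p = 1 (single attainable table),
keeping the null matrix finite.

**Empirical FDR (q-values).** For candidate thresholds t (the distinct
observed p_adj values), S(t) counts observed voxels with p_adj ≤ t and F̂(t)
estimates the expected number of null discoveries as the average, over the m
relabelings, of the number of voxels whose *null adjusted p* is ≤ t. The
null adjusted p of relabeling j is its leave-self-out rank — relabeling j is
treated exactly as the observed data is treated against the ensemble. This
is a deliberate choice: ranking null p-values self-inclusively would make
the smallest attainable null adjusted p equal 2/(m+1) > 1/(m+1), so
F̂(1/(m+1)) would vanish identically and every voxel whose observed p
undercuts its entire null would receive q = 0 by construction — an expected
false-discovery fraction of ~1/(m+1) under the global null. With
leave-self-out ranks the null calibration is clean (see below). Then

    q(v) = min over t ≥ p_adj(v) of F̂(t) / max(S(t), 1),   clipped to [0, 1],

monotone non-decreasing in p_adj by the min step. Voxels with q below the
declaration threshold (default 0.2, deliberately liberal for exploratory
mapping) form the differential mask; the thresholded log-OR map shows the
effect size only there.

## Synthetic data generator

No public cohort of co-registered mask pairs exists, so validation uses
simulation with known ground truth: a per-voxel resection-probability field
p*(v) on a small grid (default 48³ at 1 mm — desk-scale minutes rather than
cloud-scale hours) and a stochastic tumor model. Per patient, a tumor blob
is a rough-surfaced ellipsoid: centre jittered (SD 3 voxels) around a
hemisphere-specific mean, radius ~ Normal(10, 2) voxels (≈4 mL — a
miniature of clinical volumes, proportionate to the miniature grid), mild
axis anisotropy (±20%), and a smooth Gaussian random field (SD 4 voxels)
perturbing the surface by ±30% of the radius; the largest connected
component is kept, so blobs are connected and non-empty by construction.

Residues follow the marginal rule "tumor voxel retained as residue with
probability 1 − p*(v)" in two flavours:

- `bernoulli`: independent draws per voxel; the empirical RPM converges to
  p* at the binomial rate (used for parameter-recovery checks).
- `coherent`: one smooth uniform field per patient (Gaussian copula:
  smoothed white noise, SD 4 voxels, mapped through the normal CDF)
  thresholds the same rule, so residues are spatially contiguous and
  concentrate where p* is low while the per-voxel marginal stays exactly
  1 − p*(v). This is the model used for calibration/recovery experiments,
  since spatial dependence is precisely what the permutation machinery
  exists for.

What the generator does *not* emulate: registration error, segmentation
disagreement between observers, anatomically realistic glioma geometry and
infiltration along white-matter tracts, inter-patient correlation of tumor
location with resectability. Passing tests therefore demonstrate the
statistical machinery's calibration and power under a known truth, not
clinical validity on real MRI data.

## Experiments and their fixed conditions

- **Null calibration**: two cohorts of 25 from identical truth (smooth
  axial gradient p* from 0.2 to 0.9, coherent residues), m = 200, ten
  seeds. Measured: differential voxels at FDR 0.2 — zero in 10/10 seeds.
- **Recovery**: base p* = 0.7, a 10³-voxel cube lowered to 0.3 in cohort B,
  n = 30 + 30, m = 200, ten seeds. Sensitivity on planted testable voxels
  exceeds 0.5 in 10/10 seeds (typically ≈0.95–1.0). Specificity outside a
  2-voxel dilation of the cube is ≈0.983–0.997: with ~10³ strongly
  differential voxels an FDR-0.2 rule *licenses* up to ~20% false
  discoveries, and the realized false-discovery proportion tracks the
  nominal level, so specificity beyond ~0.99 is not an achievable target at
  this effect size and m — raising m (the full-scale default is 2000)
  shrinks the minimum attainable adjusted p and with it the absolute number
  of false positives.
- **Minimal detectable difference**: single-voxel two-sample design,
  proportions symmetric about 0.5 (the maximal-variance baseline), n = 30
  per cohort, two-sided Fisher test at α = 0.10, target power 0.8, ≥5000
  Monte-Carlo replicates per point on a 0.01 grid of differences. The MDD
  is the smallest difference whose estimated power reaches the target; the
  exact power is 0.798 at d = 0.35 and 0.821 at d = 0.36, so the estimate
  concentrates on 0.35–0.36. The exact test is conservative relative to
  normal-approximation power calculations (which give ≈0.32 here); we keep
  the exact test because it is the voxel-level test actually used.

## Numerical choices and degenerate inputs

- Grid equality uses an absolute tolerance of 1e-4 on affine entries
  (NIfTI stores float32 headers); masks are binarized at 0.5 after any
  interpolating resampling (majority rule); non-finite or out-of-[0,1]
  mask values are rejected, never coerced.
- Memoized statistics are bit-identical to direct per-table computation:
  both paths share the same enumeration rule and tie tolerance.
- Isotonic regression (pool-adjacent-violators) is applied to the
  Monte-Carlo power curve for reporting; the MDD itself uses the raw curve.
- Seeds: every stochastic component (cohort simulation, relabeling draws,
  Monte-Carlo power) takes an explicit seed; identical seeds reproduce all
  arrays bit for bit.

## Known limitations

- Inference is voxel-marginal: no cluster-level statistics, no spatial
  smoothing of evidence, no covariate adjustment.
- The empirical-FDR estimator assumes exchangeability of patients across
  cohorts under the null; systematic cohort differences in tumor *location*
  (as opposed to resection behaviour) violate it and are only partially
  absorbed by the per-hemisphere design.
- Segmentation and registration are upstream of this package and taken as
  given; their errors propagate unmodeled.
- With small m, the discreteness of p_adj (multiples of 1/(m+1)) makes
  q-values coarse; m = 2000 is recommended for real analyses.
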