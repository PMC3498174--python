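# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `tractprof`, in the order the pipeline runs.

## Tensor model and fitting

The single-tensor (Gaussian-diffusion) model treats the per-voxel signal as
`S_i = S0 exp(-b_i g_iᵀ D g_i)` with `D` a symmetric 3×3 tensor in mm²/s.
`S0` is the mean of all b=0 volumes. Fitting is ordinary least squares on
`log(S_i/S0)` against the six unique tensor elements; because every voxel
shares the same design matrix, the whole volume is solved with one
pseudoinverse. Requirements: at least one b=0 volume and six distinct
gradient axes (axes, not signed directions — g and −g are equivalent).
Voxels with any nonpositive signal are excluded from the mask with a
warning rather than patched.

**Robust mode** guards against single corrupted measurements (e.g. a
motion-spiked direction): log-residuals are sigma-clipped at 3× the
MAD-based sigma and the voxel refit, at most 5 iterations. This is a
deliberately simple, deterministic robust estimator; it is not an
implementation of any particular published robust tensor fit, and it will
not fix systematic artifacts that affect many directions at once.

Negative eigenvalues (possible in noise) are kept, not clamped; the scalar
formulas are applied as-is, except that FA of an exactly-zero tensor is
defined as 0. Transparency is preferred over silent repair; the count of
affected voxels is logged.

## Interpolation

Two interpolators serve different purposes:

- **Tensors** (for tracking) are interpolated trilinearly, element by
  element; the result is symmetric by construction. Integer voxel indices
  are voxel centers, world coordinates come from the NIfTI affine, indices
  are 0-based. This convention is used everywhere in the package.
- **Scalar maps** (for profiling) use a tensor-product B-spline, default
  cubic, with **not-a-knot boundary conditions** per axis
  (`make_interp_spline` + `NdBSpline`). Not-a-knot was chosen over the more
  common mirror-boundary prefilter because it interpolates the grid data
  exactly *and* reproduces polynomial fields (in particular linear ramps)
  all the way to the grid edge, so no separate boundary fallback is needed.
  Axes shorter than order+1 voxels degrade to linear. Samples outside the
  grid return NaN, which the profiling stage treats as a missing value.

## Tractography

Deterministic streamline tracking integrates the principal-eigenvector
field with classical RK4 at a fixed step. Parameters, defaults, and why:

| parameter | default | meaning |
|---|---|---|
| `step_mm` | 1.0 | RK4 step length (all emitted inter-point distances equal it; no terminal partial step) |
| `seed_fa` | 0.3 | seed mask: voxels with FA strictly greater |
| `fa_stop` | 0.2 | halt when interpolated FA at the candidate point falls below |
| `angle_stop_deg` | 30 | halt when the turn between the last chord and the next RK4 direction exceeds |
| `max_length_mm` | 250 | safety cap per direction |
| `min_length_mm` | 10 | discard seed-noise stubs (configurable; the threshold is a pragmatic floor, not anatomically motivated) |

Eigenvectors are axial, so sign continuity matters: at every RK4 stage the
local principal direction is flipped to have nonnegative dot product with
the incoming direction; the first step from a seed uses the raw eigenvector
and its negation for the two tracking directions. A point that would
violate a stopping criterion is never emitted. Seeds sit at voxel centers
(one per mask voxel); optional extra seeds are jittered uniformly within
the voxel under an explicit rng seed, and jittered seeds that land outside
the field are skipped.

All streamlines advance in lockstep so tensor interpolation and the 3×3
eigendecompositions run batched across the active front; results are
bitwise identical to tracking seeds one at a time.

## Segmentation

A fiber is assigned to a tract when at least one point falls in each of the
two waypoint ROIs (point-in-mask via rounding the point's continuous voxel
coordinate), order-agnostic; orientation is imposed later. An optional
NOT-ROI excludes fibers that touch it. Probability-map refinement scores
each candidate by the **mean probability over the unique voxels it visits**
— deduplication removes the step-size dependence a per-point mean would
have — and discards fibers below a threshold (default 0.3; the choice of
mean-over-voxels and the default threshold are this package's decisions,
exposed as parameters). Template-space ROIs and maps are brought into
subject space by applying a *precomputed* dense displacement field
(nearest-neighbor for masks, linear for maps); estimating such deformations
is out of scope. An 18-tract manifest can be supplied as JSON; atlas
volumes are user-provided.

## Cleaning

After resampling each fiber to `n_nodes = 100` equidistant nodes (exact
arc-length spacing, endpoints preserved) and orienting all fibers
start-ROI → end-ROI, node k's fiber coordinates are modeled as a trivariate
Gaussian with sample covariance (divisor N−1). A fiber's distance from the
core is the **maximum over its nodes** of the Mahalanobis distance — the
conservative reading of "deviates from the core"; a mean-over-nodes variant
would under-flag focal detours. Covariances are regularized with +1e-6 mm²
on the diagonal before inversion to survive degenerate (coplanar) node
clouds.

Per iteration, fibers are flagged if their length exceeds the current mean
by more than 4 SD (one-sided: only too-long fibers are suspect) or their
distance exceeds 5 SD. Flagged fibers are removed **only if their count
exceeds the chance expectation** under the Gaussian bundle model — N times
the normal tail beyond 4 SD for length, N times the chi(3 dof) tail beyond
5 SD for distance — so a homogeneous bundle converges in one iteration
without nibbling at its own tails. Length statistics are recomputed over
the current set each iteration. Termination is guaranteed (the count
strictly decreases whenever anything is removed); removing every fiber is
an error, not a silent empty result. Surviving fibers are returned
unaltered — cleaning removes fibers, it never resamples or edits them.

## Tract Profiles

Fibers are clipped to the span between the point nearest the start ROI and
the point nearest the end ROI (fibers whose nearest points come out
inverted are dropped with a warning), then re-resampled to 100 nodes. The
scalar map is sampled at each fiber's own node coordinates — not at the
core — so each fiber contributes its local tissue measurement. Node values
are averaged with weights `w[i,k] ∝ exp(-D_m(x[i,k])²/2)`, normalized per
node: the Gaussian density kernel is the natural membership probability
under the Gaussian core model already used for cleaning (the exact kernel
is a package choice and is configurable in spirit: any decreasing function
of D_m preserves the convex-combination and monotone-influence properties
the tests assert). Fibers sampling outside the map are excluded at that
node with renormalization; a node with no valid sample is NaN and flagged.

The default analysis region is the inter-ROI span, where waypoint planes
make node indices anatomically comparable across subjects. A full-length
profile is available (`--full-length`), with the caveat that distal
portions are not guaranteed to be in register across subjects.

## Profile statistics

Normative profiles store per-node mean, sample SD, and empirical
percentiles {5, 10, 25, 75, 90, 95} (linear interpolation between order
statistics); the cohort matrix is retained so individual percentile
positions are empirical rather than Gaussian-approximated. An individual is
flagged abnormal when at least `min_run = 10` consecutive nodes (10% of the
tract) fall outside the chosen band (10/90 or 5/95); the run length is a
required, documented parameter with no canonical value — single-node
excursions are expected by construction of the bands.

Point-wise inference uses pooled-variance two-sample t (Welch optional) or
Pearson r (optionally partialling out a covariate such as age from both
sides). Family-wise error across the 100 correlated nodes is controlled by
the max-statistic permutation method: for each relabeling, take the maximum
|statistic| over nodes; corrected p at node k is
`(1 + #{perm max ≥ |observed_k|}) / (nperm + 1)`. The add-one estimator
keeps p-values strictly positive and finite-sample valid; uncorrected
p-values come from the same permutation set, which makes
corrected ≥ uncorrected an exact identity rather than an approximation.
Label arrangements are enumerated exhaustively when their count does not
exceed `nperm`; otherwise sampled. Everything is deterministic under the
rng seed.

## The phantom module

The generators emulate exactly the structures the pipeline measures:

- **Tensor fields**: tubes around parametric centerlines (straight, arc);
  inside a tube the principal axis is the centerline tangent and the
  cylindrically symmetric eigenvalues (λ₁, λ₂, λ₂) are solved from the
  planted FA target and mean diffusivity via `d = FA/√(3−2FA²)`,
  λ₁ = MD(1+2d), λ₂ = MD(1−d). Defaults: MD 0.7×10⁻³ mm²/s (typical white
  matter), bundle FA 0.8, background FA 0.15 — an axially symmetric tensor
  about +z, below both the 0.3 seed and 0.2 stop thresholds (a strictly
  isotropic background would have FA 0; the small background anisotropy is
  a deliberate stand-in for gray-matter-like tissue). Where bundles
  overlap, tensors are averaged and the trace renormalized to the target
  MD: a documented simplification of multi-fiber physics that reproduces
  the FA-lowering effect of crossings without modeling them.
- **DWI signals**: Stejskal–Tanner forward model on a 30-direction
  Fibonacci-sphere scheme at b = 900 s/mm² with one b=0 volume, plus Rician
  noise (independent Gaussian noise on the real and imaginary channels,
  magnitude taken). The default noisy condition used in the end-to-end
  checks is noise_sd = S0/40 (SNR 40 at b=0).
- **Profile cohorts**: multivariate-normal subject profiles around a mean
  with a squared-exponential node covariance (SD 0.05, length scale 10
  nodes — smooth, strongly correlated neighboring nodes, as real Tract
  Profiles are); optional per-node group offsets on half the subjects; a
  behavioral score generated as slope × standardized node-50 value + noise.

What the phantoms do **not** emulate — and hence what passing tests do not
establish about real data: susceptibility and eddy-current distortion,
motion, partial voluming against CSF, non-Gaussian diffusion, branching or
kissing fiber configurations, inter-subject anatomical variability, or
registration error in atlas ROIs. The phantoms validate the machinery, not
the anatomy.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each property is cleanly measurable:
phantom grids 40×16×16 at 2 mm (≈600 seed voxels, ≈600 streamlines);
end-to-end recovery at SNR 40 with two independent noise realizations;
family-wise error from 1000 null cohorts of 48 subjects at nperm = 500;
normative bands from 2000 subjects with 500 held-out draws; effect
localization and behavior-peak recovery over 10 cohort realizations each
(a +1 SD focal effect at n = 24/group sits near the corrected detection
threshold, so single realizations are noisy by design).

## Known limitations

- Single-tensor model only: no multi-shell, no orientation-distribution
  models; crossing regions lower FA and deflect tracking, as they do for
  any tensor-based STT.
- The robust fit is a generic sigma-clipper, not a published estimator.
- The probability-score rule (mean over unique voxels) and threshold have
  no canonical published values; both are parameters.
- Whole-fiber outlier aggregation (max-node) and the Gaussian weight kernel
  are declared package choices among reasonable alternatives.
- Full-length profiles are not landmark-aligned across subjects.
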