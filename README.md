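# tractprof

Automated fiber-tract quantification for diffusion-tensor MRI: from a
diffusion-weighted volume to identified white-matter fascicles and
**Tract Profiles** — 100-node vectors of FA/MD/RD/AD sampled along each
tract's core — plus normative-profile construction, individual-versus-norm
comparison, and point-wise group/behavioral statistics with
permutation-based multiple-comparison correction.

Mean diffusion measures per tract hide where along a fascicle tissue
differs: crossing fibers, partial voluming, development and disease all act
at specific positions. `tractprof` is for researchers and methodologists
who need along-tract measurements that are anatomically comparable across
subjects, and a fully synthetic phantom suite so every stage is testable
without scan data.

## The method

1. **Tensor model.** Per voxel, the DWI signal follows
   `S = S0 exp(-b gᵀ D g)`; `D` is fit by linearized least squares on
   log-signals (optional robust sigma-clipping of residual outliers). From
   sorted eigenvalues λ₁ ≥ λ₂ ≥ λ₃:
   `FA = √(3/2)·√Σ(λᵢ-λ̄)² / √Σλᵢ²`, `MD = λ̄`, `RD = (λ₂+λ₃)/2`, `AD = λ₁`.
2. **Tractography.** Deterministic streamline tracking (STT): fourth-order
   Runge–Kutta integration of the principal-eigenvector field at a 1 mm
   fixed step, seeded at every voxel with FA > 0.3, halted when interpolated
   FA < 0.2 or the turn between the last segment and the next step exceeds 30°.
3. **Segmentation.** A streamline joins a named tract if it passes through
   the tract's two waypoint ROIs; candidates are then scored against a tract
   probability map (mean probability over visited voxels) and aberrant
   low-scoring fibers are discarded.
4. **Cleaning.** Each fiber is resampled to 100 equidistant nodes; the
   node-wise spread of fiber coordinates is modeled as a trivariate Gaussian
   (mean μ, covariance S). Fibers longer than 4 SD above the mean length or
   farther than 5 SD Mahalanobis distance
   `D_m(x) = √((x-μ)ᵀ S⁻¹ (x-μ))` from the core are removed iteratively
   until none remain.
5. **Tract Profile.** Fibers are clipped to the inter-ROI span, the scalar
   map is spline-sampled at each fiber's nodes, and node values are averaged
   with Gaussian weights `w ∝ exp(-D_m²/2)` so near-core fibers dominate.
6. **Statistics.** Cohorts of profiles yield normative means, SDs and
   percentile bands; individuals are compared as per-node z-scores and
   flagged when a long run of nodes leaves the band. Point-wise t-tests and
   behavior correlations are corrected for the 100 correlated comparisons
   with the max-statistic permutation procedure (far less conservative than
   Bonferroni under strong node-to-node correlation).

## Worked example

A synthetic phantom with a known mid-tract FA dip (0.75 → 0.50), imaged at
SNR 40 with 30 directions at b = 900 s/mm², then pushed through the whole
pipeline:

```python
import numpy as np
import tractprof as tp

dip = lambda t: 0.75 - 0.25 * np.exp(-0.5 * ((t - 0.5) / 0.12) ** 2)
bundle = tp.BundleSpec(
    centerline=tp.straight_centerline([4, 15, 15], [74, 15, 15]),
    radius=5.0, fa_profile=dip,
)
field, fa_true, _ = tp.build_tensor_field([bundle], (40, 16, 16), voxel_size=2.0)

gtab = tp.default_gradient_table(30, bvalue=900.0)
dwi = tp.synthesize_dwi(field, gtab, s0=100.0, noise_sd=2.5, seed=0)
fit = tp.fit_tensor_volume(dwi)
fa = tp.scalar_map(fit, "FA")

wb = tp.whole_brain_tractography(fit, fa, tp.TrackingParams(), seed=0)
def roi(i):
    mask = np.zeros((40, 16, 16), bool); mask[i] = True
    return tp.WaypointROI(mask=mask, affine=field.affine, name=f"x{i}")
tract = tp.TractDefinition("demo", roi_start=roi(5), roi_end=roi(34))
g = tp.segment_by_waypoints(wb, tract)
g = tp.orient_fiber_group(g, tract)
g, report = tp.remove_outliers(g)
g = tp.clip_to_rois(g, tract, n_nodes=100)
core = tp.compute_tract_core(g)
profile = tp.tract_profile(g, fa, core)

print(f"streamlines: {len(wb)}  after segmentation+cleaning: {len(g)}")
print(f"profile FA at nodes 0/50/99: "
      f"{profile.values[0]:.3f} / {profile.values[50]:.3f} / {profile.values[99]:.3f}")
truth = dip((np.linspace(core.mu[0, 0], core.mu[-1, 0], 100) - 4) / 70)
print(f"planted-profile RMSE: {np.sqrt(np.mean((profile.values - truth) ** 2)):.4f}")
```

Output:

```
streamlines: 616  after segmentation+cleaning: 616
profile FA at nodes 0/50/99: 0.742 / 0.506 / 0.742
planted-profile RMSE: 0.0067
```

The 100-node profile recovers the planted dip (0.506 at node 50 against a
true minimum of 0.50) with an overall node-wise RMSE under 0.01 at this
noise level. The same pipeline runs from the shell: `tractprof fit`,
`track`, `segment`, `clean`, `profile`, `stats`, `phantom` and `run`
(a JSON-config end-to-end runner); see `tractprof --help`.

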