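# Methods

`pvsquant` implements a semi-automated pipeline for quantifying white-matter
perivascular spaces (WM-PVS) on paired T1/T2 brain MRI, together with a
synthetic phantom generator and a cohort simulator that stand in for
clinical data. This note records the models, the parameters that matter,
and the design choices made where more than one reasonable option existed.

## The measurement model

PVS are fluid-filled channels around penetrating vessels: T2-hyperintense,
T1-hypointense, normally under 3 mm in calibre. On an anisotropic axial
acquisition (0.4–0.8 mm in-plane, 4.4 mm slices) they appear as punctate or
linear hyperintensities inside white matter, thinner than the slice. Because
the structure is thinner than the voxel in at least one direction, the
pipeline measures **voxel counts**, not mm³, and normalizes each subject's
PVS load by their white-matter voxel count.

Per subject the stages are:

1. **Rigid registration** of the T2 onto the T1 grid — 6-DOF, Mattes mutual
   information (cross-contrast robust), multi-resolution with shrink factors
   4/2/1 and smoothing 2/1/0 mm, dense metric evaluation (deterministic),
   regular-step gradient descent. Intensities are resampled trilinearly;
   masks nearest-neighbour. A user-supplied transform bypasses optimization.
   Reported transforms map fixed-space mm points to moving-space mm points
   (the resampling convention).
2. **Adaptive denoising** — non-local means, run 2D per axial slice because
   4.4 mm slice gaps make through-plane patches dissimilar. The noise level
   is self-estimated per slice (median absolute deviation of wavelet detail
   coefficients) and combined across slices by the median, so a clean volume
   estimates ~0 and passes through unchanged. Defaults: patch radius 1
   (3×3), search radius 6, filter strength h = 0.8σ. The small patch is
   deliberate: with larger patches, voxels within a patch-radius of a
   point-like bright structure never find matching patches and retain nearly
   raw noise, producing spurious single-voxel detections at a fixed
   threshold. With 3×3 patches that "rare patch halo" collapses onto the
   structure's immediate 8-neighbourhood, which clusters with the structure
   and cannot inflate counts.
3. **White-matter mask** — externally produced masks are accepted (the
   intended path for real data, where a whole-brain segmentation tool
   produces them). For phantoms a fallback segments WM by Otsu brain
   extraction plus 3-class k-means intensity clustering of the smoothed T1,
   taking the brightest class and filling in-plane holes (PVS are
   T1-hypointense holes *inside* WM and belong in a WM mask). The fallback
   is phantom-grade; clinical-grade accuracy is out of contract.
4. **Erosion** of the WM mask by 1 voxel (6-connected 3D structuring
   element) to discard boundary partial-volume voxels. Because a 3D erosion
   at 4.4 mm slices is aggressive — it annihilates any single-slice
   structure — a 2D in-plane (4-connected) mode is exposed; the mode used is
   logged in the provenance record.
5. **Intensity uniformization** — a degree-2 3D polynomial is fitted to the
   log-intensities of WM voxels with iterative MAD trimming (robust to the
   hyperintense PVS minority), the exponentiated field divided out, and the
   result rescaled so the WM median equals 1000. Fitting in the log domain
   matches the multiplicative bias model and makes the operation idempotent.
   The 1000 anchor is the convention that gives the detection threshold its
   meaning: 60 on this scale is a 6% local hyperintensity.
6. **Local difference map** — for each voxel inside the eroded WM mask,
   `value = I(v) − mean(I over the surrounding ring)`. The default ring is
   the in-plane 3×3 ring (8 neighbours): at this anisotropy, through-plane
   neighbours do not sample comparable tissue. Neighbours outside the image
   are excluded from the mean; neighbours outside the WM mask are included
   by default (they are the tissue a PVS contrasts against) — both choices
   are flags and are logged. A radius parameter and a 3D 26-neighbour mode
   exist; note the ring radius bounds the width of detectable structures
   (a ring of radius 1 suppresses blobs much wider than ~3 voxels).
7. **Detection** — a voxel is PVS iff its difference value is *strictly
   greater than* 60 (on the WM-median-1000 scale). The threshold is exposed.
8. **Per-slice clustering** — 8-connected components ("edges or corners
   touch") independently within each axial slice; identical in-plane
   positions on adjacent slices are different clusters. The slice axis is
   identified as the dominant-spacing axis and can be overridden; an
   ambiguous geometry is an error, not a guess.
9. **Summary** — PVS voxel count, WM voxel count, their ratio, per-slice
   cluster counts, the maximum per-slice count, and an ordinal grade:
   0 → 0 PVS; 1 → 1–10; 2 → 11–20; 3 → 21–40; 4 → >40 in the busiest slice.
   The **enlargement flag** is true when at least 3 clusters (volume-wide)
   have a minor-axis extent above 3 mm, measured as the shorter side of the
   minimum-area rotated rectangle over the cluster's voxel corners in mm —
   the diameter perpendicular to the cluster's main axis.

Degenerate inputs fail loudly: non-finite voxels inside a mask, empty WM
masks, ambiguous slice axes, zero-margin contingency tables and constant
vectors all raise named errors rather than being silently patched.

A T1/T2 ratio map (hypointense along PVS) is available for QC; detection
itself runs on the uniformized T2 only.

## The phantom

The generic phantom paints concentric ellipsoids (CSF rim / GM rim / WM
core; no gyrification — the pipeline only needs a WM interior) on the T1
grid at 0.8×0.8×4.4 mm and on a T2 grid at 0.4×0.4×4.4 mm, plants straight
cylindrical tubes wholly inside WM (isotropic-random, in-plane, or
axis-aligned orientations; bounded retries, with an error reporting the
placed count on failure), then applies a smooth multiplicative bias field
and additive Gaussian (optionally Rician) noise, both parameterized as
fractions of the WM level. Tissue levels default to WM 1000 / GM 1250 /
CSF 2000 / PVS 1800 in T2 and WM 1000 / GM 750 / CSF 250 / PVS 350 in T1.
Partial volume is rendered by evaluating the cylinder indicator on a
deterministic 4×4×2 sub-voxel grid — a numerical evaluation of the exact
voxel-in-cylinder fraction, accurate to ~3% of a voxel at these radii. The
T2 can be rendered through a rigid misalignment; the stored true transform
is exactly what registration should recover. Ground truth is the set of
voxels at least half inside a tube, and per-slice true counts come from the
same per-slice clustering oracle used downstream.

The **counting phantom** is the configuration used for count-recovery
experiments. At 4.4 mm slices only through-plane tubes occupy a substantial
fraction of any voxel, so it plants punctate (slice-perpendicular) tubes
snapped to in-plane voxel centres, spanning whole slabs, radius 0.82–0.88 mm.
Each tube then paints a plus-shaped 5-voxel cross per slab (centre fraction
1, edge neighbours ≈0.75, corners below one half), and a short analysis
shows the threshold-60 detector selects exactly the half-volume ground
truth on a clean image, with contrast margins several times the simulated
noise. This makes noise-free recovery exact by construction *given the
pipeline is correct*, which is precisely what the recovery tests are meant
to establish. What these phantoms do **not** emulate: gyral geometry,
oblique and in-plane PVS (present in the generic phantom but without a
voxel-exact truth), texture, motion, and multi-tissue partial volume at the
WM boundary; conclusions about real-data accuracy beyond the modelled
effects should not be drawn from them. Tube calibres are a design choice —
no calibre distribution is available to fit — placed to straddle visibility
at this resolution, not fitted to data.

## The cohort simulator

One row per subject: group (64 ASD / 72 non-ASD neuropsychiatric controls
by default), sex (male fraction 0.672 / 0.556), age uniform on 1–9 years,
ASD severity level 1/2/3 with probabilities 10/64, 18/64, 36/64, complex-ASD
fraction 0.844, and comorbidity flags (ADHD 15.6%/4.2%, epilepsy
14.1%/11.1%, insomnia 37.5%/0%, intellectual disability 40%/19%). PVS
volume (voxels) is log-normal: baseline median 420 with log-sd 0.61
(matching the printed female-control median and IQR width), multiplied by
1.4 if male, 1.9 for ASD children under 4 years, 1.15 per ASD severity
level above 1, and 1.2 for insomnia — the effect directions and rough
magnitudes the analysis is designed to probe, anchored to the printed
stratified medians. The visual grade derives from a latent count
`volume / 25 × LogNormal(0, 0.2)`, rounded and binned by the grade scale;
the 0.2 log-sd yields roughly 15% adjacent-grade confusion, so grade and
volume are positively but imperfectly correlated (Spearman ρ ≈ 0.9).
These defaults were fixed once from the printed cohort structure and are
not calibration knobs.

## Statistics

Descriptives are medians with IQRs (linear interpolation between order
statistics) and n (%) with per-variable non-missing denominators printed.
Group comparisons: Mann–Whitney (2 groups; scipy's exact/asymptotic policy,
tie-corrected) or Kruskal–Wallis (>2); categorical variables: Fisher's
exact when any expected cell count is below 5, else Pearson chi-square
without continuity correction — the rule is configurable and the test used
is recorded in every result, because printed p-values in retrospective
tables cannot always be attributed to one test. Spearman correlation with
tie-corrected ranks; Shapiro–Wilk for normality narration. α = 0.05. No
multiple-testing correction is applied, deliberately mirroring the analysis
design; report consumers should treat borderline rows accordingly.
Display rounding: percentages to 1 decimal (half-up), p-values to 2
significant figures, `<0.0001` below 1e-4.

## Numerical choices and known limitations

- The difference map of an in-mask voxel with no admissible neighbours is
  defined as 0 (no surround to contrast against).
- Threshold comparisons are strict (`> 60`), so a value of exactly 60 is
  not PVS.
- Cluster counts are *not* monotone in the threshold (splitting); voxel
  counts are, and the property tests assert the voxel-level statement.
- Registration accuracy on phantoms is ~0.1 mm in-plane; recovery
  experiments render T2 on the T1 grid and skip optimization so that
  counting accuracy is not confounded with resampling blur.
- Problem sizes in tests and the acceptance script (20 phantoms of
  128×128×24 per condition, 1000 null simulations at n = 50/group, 200
  power simulations at n = 200/group) were chosen to make Monte-Carlo
  variability small relative to the asserted margins.
- The NLM denoiser preserves linear structures well (patches repeat along
  the line) but single-voxel punctate structures survive on raw contrast
  alone; at 5% noise the busiest-slice count is stable to ±1, which is why
  noisy recovery is asserted within 10% rather than exactly.
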