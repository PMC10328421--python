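# pvsquant

Semi-automated quantification of **white-matter perivascular spaces
(WM-PVS)** on paired T1/T2 brain MRI — segmentation by local contrast,
per-slice counting, ordinal grading, and nonparametric case–control
statistics — with a synthetic phantom and cohort generator so the whole
pipeline is testable without any clinical data.

Perivascular (Virchow–Robin) spaces are fluid-filled channels around
penetrating vessels. They are T2-hyperintense and T1-hypointense, normally
under 3 mm, and become conspicuous when glymphatic fluid exchange is
impaired; their burden is studied as an imaging marker in paediatric
neurodevelopmental cohorts. On anisotropic axial acquisitions (0.4–0.8 mm
in-plane, 4.4 mm slices) PVS are thinner than the slice, so volume is
measured in voxels and normalized by each subject's white-matter volume.

## Method

For each subject, with T2 rigidly registered to T1 (mutual information),
denoised (slice-wise non-local means with self-estimated noise), and
white-matter intensity uniformized to a median of 1000:

* inside the WM mask eroded by 1 voxel, compute the voxel-wise local
  contrast `d(v) = I(v) − mean(I over the in-plane 8-neighbour ring)`;
* a voxel is a PVS voxel iff `d(v) > 60` (6% of the WM level);
* cluster PVS voxels per axial slice with 8-connectivity (edges or corners
  touch), record per-slice cluster counts and the maximum `N_max` over
  slices;
* grade: 0 (`N_max`=0), 1 (1–10), 2 (11–20), 3 (21–40), 4 (>40);
* report the raw PVS voxel count and the WM-normalized ratio, and flag
  radiological *enlargement* when ≥3 clusters exceed 3 mm across their
  minor axis.

Cohort statistics mirror a standard retrospective case–control analysis:
median (IQR) and n (%) summaries, Mann–Whitney / Kruskal–Wallis for
quantitative comparisons, chi-square or Fisher's exact for categorical
ones, Spearman correlations, Shapiro–Wilk normality checks, α = 0.05.

See `docs/methods.md` for models, parameter rationale, and limitations.

## Worked example

```python
import pvsquant as pq

# a synthetic subject: 9 through-plane PVS-like tubes, 5% noise
cfg = pq.counting_phantom_config(n_tubes=9, seed=4, noise_sigma=0.05)
case = pq.generate_phantom(cfg)

out = pq.run_subject(
    case.t1, case.t2,
    wm_mask=case.wm_mask_true,
    config=pq.PipelineConfig(registration="identity"),
)
r = out.report
print("true per-slice counts:", case.per_slice_true_counts)
print("detected per-slice   :", r["per_slice_counts"])
print(r["pvs_voxel_count"], "PVS voxels of", r["wm_voxel_count"],
      "WM; max/slice", r["max_slice_count"], "grade", r["grade"])
```

```
true per-slice counts: [0, 0, 0, 0, 0, 0, 0, 0, 1, 4, 3, 2, 2, 3, 3, 3, 0, 0, 0, 0, 0, 0, 0, 0]
detected per-slice   : [0, 0, 0, 0, 0, 0, 0, 0, 1, 4, 4, 2, 2, 3, 3, 3, 0, 0, 0, 0, 0, 0, 0, 0]
99 PVS voxels of 52751 WM; max/slice 4 grade 1
```

At 5% noise every planted tube is recovered in its correct slices, with
one spurious extra cluster in slice 10; the maximum per-slice count (4)
and hence the grade (1, i.e. 1–10 PVS in the busiest slice) match the
ground truth. The same pipeline is exposed on the command line:

```bash
pvs simulate-phantom --seed 1 --n-tubes 9 --out phantom/
pvs quantify --t1 phantom/t1.nii.gz --t2 phantom/t2.nii.gz \
    --wm-mask phantom/wm_mask_true.nii.gz --out subject.json
pvs simulate-cohort --seed 2 --out cohort.csv
pvs cohort-stats --table cohort.csv --out report/
```

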