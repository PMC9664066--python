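# fibrofat

Spatial colocalization analysis of **epicardial adipose tissue (EAT)** and
**left-atrial (LA) wall fibrosis** from labeled 3D image volumes.

Epicardial fat is implicated in atrial fibrillation, either by direct
adipocyte infiltration of the adjacent myocardium or by paracrine signalling.
These two mechanisms make different spatial predictions: infiltration implies
that fibrotic wall regions sit *closer* to fat depots than non-fibrotic
regions; a paracrine/systemic mechanism requires no such overlap. `fibrofat`
implements the image-analysis chain that tests this on a per-surface-point
basis:

1. **Wall construction** — the LA wall is built by dilating the endocardial
   (blood-pool) segmentation by a metric distance (default 2 mm) and
   subtracting the endocardium.
2. **Fibrosis quantification** — wall voxels with LGE-type intensity above
   μ + k·σ are labeled fibrotic (default k = 3), where μ, σ are robust
   (sigma-clipped median / 1.4826·MAD) estimates of the non-enhanced wall
   signal; burden is reported as % of wall volume.
3. **Reconstruction** — the LA surface is extracted by marching cubes
   (world-mm vertices, Taubin-relaxed), and the fat mask is converted to
   volume-weighted sample points at ≤ 1 mm spacing.
4. **Registration** — the fat frame is aligned to the fibrosis frame by a
   closed-form rigid landmark fit (Kabsch SVD) on pulmonary-vein / mitral
   annulus / appendage analogs.
5. **Colocalization metrics** — for every surface vertex *x*:
   * d_EAT(x) = min over fat samples *p* of ‖x − p‖ (mm),
   * V_EAT(x) = Σ volumes of fat samples with ‖x − p‖ ≤ r (default r = 5 mm),
   * coverage(x) = 1 if any fat lies within r.
6. **Statistics** — vertex samples are stratified by fibrosis label, pooled
   across cases, and compared with the two-sided Mann–Whitney U test (exact
   enumeration for small tie-free samples, tie-corrected normal approximation
   otherwise); medians and IQRs are reported per group.

Because patient MRI is not distributable, the package ships a **synthetic
phantom generator**: an ellipsoidal LA with a thin wall, a pericardial shell,
spherical fat depots confined to the wall–pericardium layer, a
ventricular-fat slab (total-vs-LA fat distinction), angular-cap fibrotic
patches with elevated synthetic LGE signal, and a known rigid misalignment
between the two acquisition frames. The ground-truth colocalization mode
(`near` / `far` / `random`) controls whether depots are planted inside,
away from, or independently of the fibrotic caps.

## Worked example

```python
from fibrofat import PhantomConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    n_cases=6, coloc_mode="far", seed=1,
    phantom=PhantomConfig(grid_shape=(72, 72, 72), voxel_size_mm=(1.25, 1.25, 1.25)),
)
summary, results = run_pipeline(config)
```

prints (via the report fields of `summary` and `results`):

```
cases analysed:            6
mean fibrosis burden:      17.2 % of wall volume
mean LA EAT volume:        5.5 mL
d_EAT fibrotic median:     15.98 mm (IQR 12.25, 19.97), n=5301
d_EAT non-fibrotic median: 6.63 mm (IQR 3.33, 11.79), n=25311
Mann-Whitney U p-value:    2.23e-308
coverage within 5 mm:      fibrotic 0.9 % vs non-fibrotic 38.7 %
```

With fat planted **away** from the fibrotic caps (`coloc_mode="far"`),
fibrotic surface points are markedly farther from fat (median 16.0 mm vs
6.6 mm) and almost never have fat within 5 mm (0.9 % vs 38.7 % coverage);
the pooled rank test is overwhelming because tens of thousands of vertices
contribute. `coloc_mode="near"` reverses both inequalities. On phantoms the
direction is known by construction, which is what makes the pipeline
testable end to end.

A CLI wraps the same stages:

```bash
fibrofat phantom --out-dir cases/ --n-cases 3 --coloc-mode random --seed 7
fibrofat quantify cases/case000.labels.nii.gz cases/case000.lge.nii.gz
fibrofat run --out-dir out/ --n-cases 6 --coloc-mode far --seed 1
fibrofat report out/cohort_summary.json
```

Artifacts: NIfTI volumes, landmark CSVs, VTK polydata surfaces with
per-vertex `fibrotic` / `d_eat_mm` / `v_eat_mm3` arrays (ParaView-ready),
per-vertex sample CSVs, and a cohort summary JSON stamped with a config hash.

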