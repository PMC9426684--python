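# cinescar

Predicting post-contrast scar information from **contrast-free** cine
cardiac MR.

After myocardial infarction, scar tissue is confirmed clinically with late
gadolinium enhancement (LGE) imaging, which needs a contrast injection.
Cine short-axis (SAX) sequences — acquired in every cardiac MR exam, no
contrast — already encode indirect evidence of scar: reduced regional
contraction and subtle signal/texture changes.  `cinescar` implements, as a
reusable and fully tested pipeline, the experimental chain needed to study
this prediction problem:

1. **Ground-truth preparation** — match each LGE image to the cine frame
   with the closest trigger time (TT), register it into cine coordinates by
   maximising Mattes-style mutual information over an affine transform
   (translation, rotation, scale, shear) with a (1+1) evolutionary
   optimiser, zero-pad cine stacks to 32 frames, and score alignment with an
   automated QC statistic.
2. **Engineered features** from the cine frames alone:
   dense Lucas–Kanade optical flow (8×8 window, 5×5/σ=3 Gaussian weights)
   giving pixel-wise displacement r = |v|·kΔt over frame pairs at skip
   interval k = 3 (11 maps for 32 frames), compressed by PCA;
   the rate of myocardial area change aᵢ = ΔA/(kΔt) over the same pairs;
   and 2D radiomics (shape, first-order, GLRLM run-length texture) of the
   myocardium at end-diastole, end-systole and the middle frame, after
   1.9 mm area-interpolation resampling and 1–99 percentile / 256-level
   intensity normalisation.  Features are filtered by Pearson redundancy
   (|r| > 0.9) and point-biserial significance (p < 0.001).
3. **Classifiers** — an RBF-kernel SVM and a decision tree on the
   standardised feature table, evaluated with confusion-matrix metrics,
   10-fold cross-validated ROC/AUC and permutation feature importance; plus
   NumPy implementations of the deep models: a scaled UNet trained with the
   channel-weighted Dice loss L = Σᵢ βᵢ(1 − DSCᵢ), β = (0.15, 0.25, 0.25,
   0.35), and a ResNet-50 classifier description with the class-weighted
   cross-entropy (λᵢ = (1/kᵢ)·(N/C)).

Because clinical data cannot ship with code, the package includes a
**synthetic phantom generator**: a contracting annular myocardium around an
LV blood pool with an optional scar sector of reduced contraction, realistic
shared tissue texture, asymmetric extra-cardiac structure, acquisition
noise, and an LGE image with hyperintense scar and a known affine
misalignment.  Every stage of the pipeline is validated against this known
ground truth.  See `docs/methods.md` for models, conventions and
limitations — in particular, benchmark numbers on phantoms validate the
pipeline machinery, not clinical feasibility.

## Worked example

Run the full pipeline on the default synthetic cohort (80 scar / 80
healthy; a couple of minutes on one CPU):

```python
from cinescar.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
print("qc pass fraction:", result.qc_pass.mean())
for name, m in result.models.items():
    print(f"{name}: accuracy={m.report['accuracy']:.3f} "
          f"f1={m.report['f1']:.3f} auc={m.auc:.3f}")
    top = sorted(m.importance["features"], key=lambda d: -d["mean"])[:3]
    print("  top features:", [f["name"] for f in top])
```

prints

```
qc pass fraction: 1.0
svm: accuracy=1.000 f1=1.000 auc=1.000
  top features: ['es_shape_major_axis_length', 'es_glrlm_run_length_nonuniformity', 'area_rate_2']
dt: accuracy=0.938 f1=0.938 auc=0.938
  top features: ['es_shape_major_axis_length', 'area_rate_7', 'area_rate_1']
```

Every LGE image was registered back onto its cine frame well enough to pass
QC (`qc pass fraction: 1.0` — the cohort applies random affine
misalignments of up to ±8 px / ±12°), and both classifiers recover the scar
label on the 20% held-out studies (32 of 160).  Permutation importance
ranks the end-systolic myocardium shape and the area-change-rate features
highest — the phantom's scar reduces regional contraction, so at
end-systole a scarred annulus stays wider and its area shrinks more slowly,
and the pipeline finds exactly that designed signal.  (These accuracies are
a property of the deliberately separable phantom cohort, not a clinical
claim; see `docs/methods.md`.)

The same experiment from the shell:

```bash
cinescar run-all --out runs/demo --n-scar 80 --n-healthy 80 --seed 1
```

which writes `features.csv`, `report.json` (confusion matrices, ROC/AUC,
importances) and `manifest.json` (config hash, seeds, QC summary) under
`runs/demo/`.  Individual stages are exposed as `cinescar simulate`,
`prep`, `features`, `classify`, `train-dl` and `evaluate`.

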