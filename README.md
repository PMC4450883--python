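# mahinge

Automatic detection of the two **mitral-annulus hinge points** (the septal
and lateral attachment points of the mitral valve leaflets) in 2D
four-chamber echocardiographic frames.

Echocardiograms are noisy and low-resolution, so corner/edge detectors and
global texture features fail at this task.  `mahinge` instead combines:

1. **A sparse local-context feature.**  Each pixel is described by
   mean-filtered (3×3) gray values sampled along eight directions at
   45° intervals, at radii {1, 3, 5, 9, 13, 17, 23, 29}, plus the pixel
   itself — a 65-dimensional nonnegative vector encoding the fixed
   spatial arrangement of cardiac tissue around the annulus.
2. **A histogram-intersection-kernel SVM with exact fast evaluation.**
   The kernel K(x, z) = Σᵢ min(xᵢ, zᵢ) is *additive*, so the decision
   function h(z) = Σₗ αₗ yₗ K(z, xₗ) + b splits into 1-D pieces
   h(z) = Σᵢ hᵢ(zᵢ) + b.  Sorting each dimension's support values once
   gives hᵢ(t) = Aᵢ(r) + t·Bᵢ(r), with r found by binary search —
   O(n log m) per pixel instead of O(n·m), with identical results.
3. **Density-field refinement.**  Each SVM-positive candidate stamps a
   diamond weight template (weight R − D_block, R = 10) onto a density
   field F; a threshold H is searched between min(F) and max(F) until the
   pixels with F > H form *exactly two* connected components; their
   centroids seed a 2-means pass over the nearby candidates, and the final
   cluster means are the hinge points.

A synthetic **four-chamber phantom generator** (dark chambers, bright
walls, an annulus line interrupted by a valve gap, multiplicative Gamma
speckle, known ground truth) makes the whole pipeline trainable and
testable without clinical data.

## Worked example

```bash
mahinge demo --seed 0 --out demo_run
```

trains on 10 generated phantoms, detects on 5 held-out phantoms, and
prints (abridged):

```
Hinge-point localization error vs. manual annotation (mm)
frames: 5   failures: 0   mean Euclidean: 0.40000000000000002
landmark  axis  mean_mm                   variance_mm2
septal    x     0.5                       0
septal    y     0                         0
lateral   x     0.29999999999999999       0.060000000000000012
lateral   y     0                         0
```

Each row is the mean absolute error and population variance of one
landmark along one image axis (x = column, y = row), converted to mm with
the phantom's 0.5 mm/pixel spacing; `failures` counts frames where no
candidate cluster survived refinement.  Here both hinge points are
recovered within ≈1 pixel on every frame.  `demo_run/` also receives the
report in JSON/CSV, the trained model, and the fully resolved
configuration; rerunning with the same seed reproduces every file
byte-for-byte.

The same stages are available individually (`mahinge simulate / extract /
train / detect / evaluate`) and as a library:

```python
import mahinge as mh

frames = mh.generate_dataset(20, mh.PhantomParams(), seed=100)
det = mh.HingePointDetector().fit(frames)           # sklearn-style
results = det.predict(mh.generate_dataset(5, mh.PhantomParams(), seed=7))
print(results[0].septal, results[0].lateral)
```

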