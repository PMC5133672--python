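# defcyto

A desk-scale workbench for multiparameter deformability cytometry: simulate
viscoelastic cells passing an extensional-flow stretching junction, extract
fifteen biophysical parameters from the resulting image stacks, and analyze
populations with clustering, feature ranking, classification, gating and
mixture deconvolution.

## The science

Deformability cytometry stretches single cells hydrodynamically in a
microfluidic cross-junction while imaging them at microsecond frame
intervals. How far and how fast a cell deforms reports on its cytoskeleton
and nuclear mechanics — label-free markers that separate, for example,
pluripotent from differentiated cells or malignant from benign cells in a
fluid sample. Because no instrument data ships with this package, a
physics-based simulator provides ground-truth events: each synthetic cell is
an area-conserving ellipse following Kelvin–Voigt creep,

```
strain(t) = eps_max * (1 - exp(-t / tau))
```

inside the junction and partial exponential recovery after exit, optionally
decorated with low-amplitude cosine boundary modes to control morphology.
Frames are rasterized with a Gaussian point-spread function and additive
noise, so the extraction pipeline faces realistic segmentation conditions
while every event carries its analytic ground truth.

The extractor segments each frame, refines the boundary to a sub-pixel
iso-contour, and reduces the event to fifteen parameters: initial diameter
(A), circularity (C1), deformability at four stages (D1–D4, major/minor axis
of the moment-equivalent ellipse), creep timing (T1, T2), strain measures
(S1, S2), boundary morphology (M1–M4: roughness and trace-crossing counts
before and at maximal deformation), and area ratio (AR1).

The analysis layer provides expectation-maximization Gaussian-mixture
clustering, a clustering-error metric, greedy backward feature elimination
(unsupervised or SVM-cross-validation mode), linear/Gaussian SVM
classification with seeded stratified cross-validation, ROC/AUC, quantile
and threshold gating, spiked-mixture fraction prediction with
limit-of-detection analysis, PCA/LDA projections, pairwise similarity
matrices, and a bead-based deformability-to-stiffness calibration curve.

## Worked example

Simulate two mechanical phenotypes, extract features, and train a
classifier:

```python
import numpy as np
from defcyto import (RenderSpec, ViscoelasticCellSpec, simulate_event,
                     batch_extract, train_svm, predict_fractions)

render = RenderSpec(noise_sd=0.02)
rng = np.random.default_rng(0)
events = []
for label, d_mean, strain in [("soft", 14.0, 0.55), ("stiff", 17.0, 0.20)]:
    for i in range(40):
        spec = ViscoelasticCellSpec(
            initial_diameter=float(rng.normal(d_mean, 0.8)),
            max_strain=float(rng.normal(strain, 0.03)),
            rng_seed=int(rng.integers(2**31)))
        events.append(simulate_event(spec, render,
                                     event_id=f"{label}-{i}", label=label))

table, rejected = batch_extract(events)
labels = [ev.label for ev in events if ev.event_id in table.index]
print(f"extracted {len(table)} events, rejected {len(rejected)}")
print(table[["A", "D3", "S1", "T1"]].groupby(labels).median().round(3))

bundle = train_svm(table, labels, kernel="linear", seed=0)
print(f"5-fold CV accuracy: {bundle.cv_accuracy:.3f}")
print("class fractions:", {k: round(v, 3) for k, v in
                           predict_fractions(bundle, table).items()})
```

Output:

```
extracted 80 events, rejected 0
            A     D3     S1   T1
soft   13.915  2.363  0.541  8.0
stiff  16.850  1.434  0.199  8.0
5-fold CV accuracy: 1.000
class fractions: {'soft': 0.5, 'stiff': 0.5}
```

The soft population (median diameter 13.9 µm) reaches a deformability of
2.36 and a strain of 0.54, while the stiff population barely deforms
(D3 = 1.43); a linear SVM separates them perfectly and recovers the 50/50
composition of the pooled sample.

The same workflow runs end-to-end from the command line:

```bash
defcyto run --config config.yaml --out results/ --seed 1
```

which writes the rendered event stacks (multi-page TIFF + JSON sidecar), the
feature table CSV, classification results and a manifest with per-file
checksums and the derived per-stage seeds.

## Documentation

A methods note covering the cell model, its assumptions, all default
parameters and the numerical choices in the analysis layer is in
[docs/methods.md](docs/methods.md).
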