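# octseg

Cascaded compressed encoder–decoder segmentation of intraretinal layers in
macular OCT B-scans, plus everything needed to train and evaluate the
pipeline without clinical data:

- **phantom** — synthetic macular OCT generator: smooth ordered boundary
  surfaces with a foveal pit, per-layer reflectivity bands, multiplicative
  gamma speckle, thin-RNFL cases and INL microcysts, with exact ground-truth
  class maps and surfaces.
- **io_formats** — volume/surface readers and writers (PNG/TIFF directory
  layouts, HDF5 containers, long-format surface CSV).
- **preprocess** — fovea localization by parabola fitting of the inner
  surface, 6×6 mm crop, bilinear resize to the network input size.
- **networks** — one parametrized compressed U-Net template (4 stages,
  channel depth doubling, dropout after stages 3–4) covering both cascade
  stages, a classic 5-level reference U-Net, and exact parameter counting
  (framework count cross-checked against a closed-form layer-by-layer
  formula). Networks run on a small numpy/BLAS conv-net engine included in
  the package (`octseg.nn`) — no deep-learning framework required.
- **losses** — focal loss and the class-weighted focal loss with weights
  `w = 1 − n_foreground / n_total` pooled over the training labels.
- **cascade** — two-stage training (Adam, early stopping on validation
  accuracy, teacher forcing for the second stage) and cascade inference:
  the 3-class retina map joins the image as the second input channel of the
  9-class stage.
- **postprocess** — adaptive hole filling, column-wise boundary extraction,
  Laplacian-of-thickness outlier rejection, PCHIP infill, 3×3 box
  smoothing, ordering enforcement.
- **metrics** — per-class Dice, per-boundary MAE (μm), regional
  thickness/volume parameters, one-way-ANOVA ICC with confidence interval.
- **app / cli** — parameter-count report and a reproducible end-to-end
  phantom benchmark.

## CLI

```bash
octseg params                        # architecture parameter-count report
octseg phantom --out data --n-volumes 2 --size 128 --seed 0
octseg preprocess --in <vol> --out <vol> --extent-mm 6.0 --size 512
octseg train --stage rs --data data --out rs.npz
octseg train --stage is --data data --out is.npz
octseg predict --rs rs.npz --is is.npz --in <vol> --out preds/
octseg postprocess --in preds/ --out surfaces.csv --tau-um 20
octseg evaluate --pred surfaces.csv --gold gold.csv --out report.json
octseg benchmark --seed 0 --out report.json   # end-to-end phantom benchmark
```

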