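# momentkit

Orthogonal image-moment descriptors, rotation-invariant texture baselines,
and a cross-validated feature benchmark for 2-D grayscale images.

## What it does

`momentkit` implements a unified family of moment-based global image
descriptors together with the evaluation protocol needed to compare them:

* **Cartesian moments** — continuous Legendre (`LM`) and discrete Chebyshev
  moments of the first (`CHM`) and second (`CH2M`) kind.
* **Circular moments on the unit disk** — Zernike (`ZM`), pseudo-Zernike
  (`PZM`), orthogonal Fourier–Mellin (`OFMM`), Chebyshev–Fourier (`CHFM`),
  pseudo-Jacobi–Fourier (`PJFM`), Jacobi–Fourier (`JFM`), Bessel–Fourier
  (`BFM`), radial harmonic Fourier (`RHFM`), exponent Fourier (`EFM`), and
  the polar harmonic transforms (`PCET`, `PCT`, `PST`).
* **Fractional-order variants** — `FrJFM`, `FrRHFM`, `FrPCET`, `FrPCT`,
  `FrPST` via the substitution `r -> r**alpha` with the orthogonality-
  preserving Jacobian weight (`alpha = 1` reduces exactly to the integer
  families).
* **Texture baselines** — 13 Haralick statistics on four symmetric `d = 1`
  GLCMs (`HARri`, 52 values) and the 36-bin rotation-invariant LBP histogram
  (`LBPri`).
* **Benchmark pipeline** — stratified 10-fold cross-validation with
  train-fold z-scoring and grid-search model selection (inner 3-fold CV)
  over five classifier categories (SVM, k-NN, decision tree, naive Bayes,
  bagged trees), scored by support-weighted per-class one-vs-rest accuracy,
  with category-level aggregation.
* **Synthetic data** — deterministic labeled texture generators (oriented
  gratings, Gaussian random fields, blob mixtures) and analytic basis-image
  fixtures, so the whole package is testable without external datasets.

All circular bases are normalized to be orthonormal on the disk, magnitude
features are rotation invariant (exactly under 90° grid rotation), and every
moment family supports reconstruction.

## CLI

```sh
# generate a 3-class synthetic dataset of 64x64 texture patches
momentkit synth --out data/ --classes 3 --per-class 20 --size 64 --seed 1

# extract per-descriptor feature CSVs (order 5)
momentkit extract --data data/ --out features/ --descriptors CHM,ZM,RHFM --order 5

# cross-validated benchmark; writes a descriptor x classifier results table
momentkit evaluate --features features/ --out results.csv --classifiers kNN --k 10 --seed 42

# reconstruct an image from its moments
momentkit reconstruct --image data/class0/img_0000.png --family ZM --order 10 --out rec.png
```

`momentkit --config run.yaml ...` accepts a YAML file with per-descriptor
`MomentSpec` overrides (e.g. `jacobi_p`, `alpha`) and classifier grid
overrides. Datasets are directories of class-named subfolders holding
PNG/TIFF/BMP images (RGB is reduced to luminance).

## Library use

```python
import numpy as np
import momentkit as mk

img = np.random.default_rng(0).random((64, 64))
fv = mk.extract_features(img, "ZM")            # 21 rotation-invariant values
ms = mk.compute_circular_moments(img, mk.MomentSpec(family="RHFM", n_max=8))
rec = mk.reconstruct(ms, 64, 64)
```

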