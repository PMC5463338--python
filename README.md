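# octdme

Automatic classification of spectral-domain optical coherence tomography
(SD-OCT) volumes as **diabetic macular edema (DME) vs normal**.

DME presents on OCT B-scans as retinal thickening, intraretinal cystoid
spaces and subretinal fluid. `octdme` implements a classical
texture-classification pipeline for whole volumes:

1. **Pre-processing** — speckle denoising (mean, median, Lee, wavelet
   hard/soft thresholding, non-local means, or any plug-in denoiser),
   localization of the retinal pigment epithelium (RPE) as a
   second-order polynomial fitted with RANSAC, column-wise flattening so
   the RPE becomes a horizontal line, and a fixed anatomical crop of
   325 px above / 30 px below the RPE and a centered 340 px lateral
   strip — i.e. 356 × 340 B-scans.
2. **Features** — a 4-level Gaussian pyramid feeding either
   rotation-invariant uniform local binary patterns (LBP-riu2, with
   (P, R) ∈ {(8,1), (16,2), (24,3)}, histogrammed over non-overlapping
   patches) or histograms of oriented gradients (HoG, 4 × 4 px cells,
   2 × 2-cell blocks at 1-cell stride, 9 unsigned bins).
3. **Representation** — concatenated histograms, optionally reduced by
   PCA (40 components for HoG, 20 for LBP), optionally encoded per
   volume as a bag of visual words over a k-means codebook.
4. **Classification** — linear SVM, RBF SVM or random forest at the
   B-scan level with a majority vote per volume (ties count as DME), or
   directly at the volume level for the bag-of-words representation.
5. **Evaluation** — leave-two-patients-out cross-validation (each fold
   holds out one DME and one normal patient) with volume-level
   sensitivity SE = TP/(TP+FN) and specificity SP = TN/(TN+FP).

Clinical SD-OCT volumes of this kind are generally not redistributable,
so the package ships a **synthetic phantom generator**: layered retina
with a curved bright RPE band, multiplicative gamma speckle (L-look
model) and DME-type lesions. Every stage is tested end to end on these
phantoms.

Descriptor geometry on the standard 356 × 340 crop (pyramid levels
356×340 → 178×170 → 89×85 → 44×42):

| descriptor | per-B-scan length |
|---|---|
| LBP8-riu2 | 180 |
| LBP16-riu2 | 324 |
| LBP24-riu2 | 468 |
| HoG (4 levels) | 347,940 (266,112 / 63,468 / 15,120 / 3,240 per level) |

## Worked example

Simulate a small balanced phantom dataset and evaluate the default
pipeline (NLM denoising → flatten/crop → LBP16-riu2 → Histogram+PCA →
linear SVM):

```bash
$ octdme simulate --n-dme 4 --n-normal 4 --rows 256 --cols 512 \
      --n-scans 16 --seed 0 --out demo
wrote 8 volumes to demo ({'DME': 4, 'NORMAL': 4})

$ octdme evaluate --manifest demo/manifest.csv --out demo_report --seed 0
SE=1.000 SP=0.750 -> demo_report/report.csv
```

`report.csv` holds one row per configuration:

```
descriptor,representation,classifier,n_words,SE,SP,TP,FN,TN,FP
lbp-ri,hist_pca,linear_svm,,1.0,0.75,4,0,3,1
```

Here all 4 DME volumes were recognized (SE = 1.0) and 3 of 4 normal
volumes (SP = 0.75); per-fold JSON logs record each held-out pair and
its diseased-B-scan counts. The denoiser benchmark harness compares
mean PSNR against the speckled baseline:

```bash
$ octdme bench-denoise --looks 4 --seeds 0,1,2 --rows 128 --cols 128
    denoiser  mean_psnr_db
       noisy     17.643559
        mean     24.041386
      median     22.999675
         lee     21.007223
wavelet_hard     17.813526
wavelet_soft     20.669704
         nlm     19.342264
```

The same functionality is available as a library; the descriptor
extractors (`LBPDescriptor`, `HOGDescriptor`), PCA (`HistogramPCA`) and
bag-of-words encoder (`BagOfWords`) are scikit-learn compatible
estimators:

```python
from octdme import LBPDescriptor, HistogramPCA
X = LBPDescriptor(points=16, radius=2).fit_transform(preprocessed_scans)
Z = HistogramPCA(n_components=20).fit(X).transform(X)
```

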