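# nodulescan

A lung-nodule detection pipeline for CT slices, with a built-in synthetic
thorax phantom so every stage runs and validates without any external data.

Stages:

1. **Enhancement** (`nodulescan.enhancement`) — each slice is tiled into 8×8
   blocks, transformed with an orthonormal 2D DCT, and split into low/high
   frequency components by zig-zag coefficient rank. CLAHE (clipped per-tile
   histogram equalization with bilinear blending) is applied to the
   low-frequency reconstruction only; the high-frequency residual is added
   back unchanged, so detail is preserved and noise is not amplified.
2. **Segmentation** (`nodulescan.segmentation`) — corner-scan background
   removal, an iterative mean-split threshold initialised at −950 HU,
   differential-evolution optimal thresholding (DE/rand/1/bin minimising the
   total Gaussian misclassification error of the histogram partition),
   corner-seeded removal of outside air, and hole filling.
3. **Candidates** (`nodulescan.candidates`) — bright connected components
   inside the lung mask, thresholded with the DE optimum of the median
   slice; pruned by area-equivalent diameter (3–30 mm) and elongation
   (tubular vessels).
4. **Features** (`nodulescan.wld`) — Weber Local Descriptor: differential
   excitation and gradient orientation maps, per-block normalized
   histograms, fused into one vector (FS-k = k bins per histogram).
5. **Classification** (`nodulescan.classify`) — RBF SVM with train-only
   feature standardization, plus the evaluation protocol: stratified
   splits, confusion matrices, accuracy/sensitivity/specificity,
   stratified k-fold CV, ROC curves.
6. **Phantom** (`nodulescan.phantom`) — seeded thorax-like HU slices with
   ground-truth lung masks, implanted smooth-profile nodules (3–30 mm),
   random-walk vessels and vessel cross-section blobs; plus an end-to-end
   labeled-dataset generator.

## CLI

```sh
nodulescan phantom --n-slices 20 --size 256 --spacing 0.7 --nodules 2 \
    --diam 5:20 --noise 12 --seed 17 --out-dir phantoms/
nodulescan enhance --input slice.tif --block-size 8 --lf-cutoff 16 \
    --clip-limit 0.01 --tiles 8x8 --window -1000:400 --output enhanced.png
nodulescan segment --input slice.tif --k 2 --de-pop 20 --de-gens 100 \
    --seed 17 --output-mask mask.png
nodulescan detect --input phantoms/ --mask-dir masks/ --spacing 0.7 \
    --dmin 3 --dmax 30 --elong-max 3.0 --out candidates.csv
nodulescan features --candidates candidates.csv --images phantoms/ \
    --fs 14 --blocks 2x2 --alpha 3.0 --out features.csv
nodulescan train --features features.csv --kernel rbf --c 1.0 --seed 17 \
    --model model.pkl
nodulescan eval --model model.pkl --features test.csv \
    --report metrics.json --roc roc.csv
nodulescan run --input phantoms/ --report report.json   # full pipeline
```

HU images persist as 16-bit TIFF with a +1024 offset; 8-bit PNG inputs are
treated as windowed gray levels. DICOM input needs the optional `pydicom`
dependency (`pip install nodulescan[dicom]`).

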