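# saliency3d

Volumetric visual-saliency detection of brain tumours from multi-sequence MRI.

Glioblastoma stands out on MR imaging because it looks *different* from the
surrounding brain in a way that varies across acquisition sequences: bright on
FLAIR and T2, with distinct contrast enhancement on T1C. `saliency3d` turns
that chromatic rarity into a voxel-level tumour-likelihood map. It is aimed at
computer-aided detection (CADe): given three co-registered, skull-stripped
sequences of one subject, it produces a full-resolution saliency volume on a
0–255 scale in which the whole-tumour region is highlighted, plus the
threshold-sweep machinery (precision/recall, ROC, AUC) to score that map
against a ground-truth segmentation.

## Method

1. **Pseudo-colouring.** Each sequence is normalized by its maximum intensity
   and scaled to 8 bits, then the three are stacked as RGB channels
   (FLAIR → R, T1C → G, T2 → B) and converted to CIE L\*a\*b\*, where colour
   differences are perceptually meaningful Euclidean norms.
2. **Cube decomposition.** For each scale k ∈ {4, 8, 16} the conformed volume
   (dimensions zero-padded to multiples of 16) is partitioned into
   non-overlapping k×k×k cubes, each represented by its mean
   (L̄\*, ā\*, b̄\*).
3. **Axis-restricted colour saliency.** The saliency of cube V(i,j,l) is

       Sc(V_ijl) = Σ ‖ ΔLab(V_ijl, V_xyz) ‖

   summed over every cube sharing at least one index coordinate
   (x=i ∨ y=j ∨ z=l, self excluded) — its three axis planes. This replaces
   the O(n²) all-pairs comparison with roughly n·3·(plane area) operations
   (10–20× fewer at BRATS volume sizes) while still drawing evidence from
   all three major axes.
4. **Spatial weighting.** Salient regions congregate, so each pairwise term
   is damped by 1/(1 + d), with d the Euclidean distance between cube index
   triples (a `factored` variant multiplies the summed colour saliency by the
   summed weights instead).
5. **Multi-scale fusion.** Per-scale maps are upscaled to full resolution by
   centre-anchored trilinear interpolation, min–max normalized, averaged with
   weights r_k = 1/3, rescaled to [0, 255], and median-smoothed (3×3×3).

A deterministic synthetic phantom (brain ellipsoid + tumour ball + Gaussian
noise, with exact ground truth) makes the whole pipeline testable without any
external dataset.

## Worked example

```sh
python examples/01_phantom_to_saliency.py
```

```
phantom: shape (96, 96, 96), tumour voxels 4224
saliency range: [0.0, 254.7] (0-255 scale)
mean saliency inside tumour:   225.5
mean saliency in healthy brain: 162.4
```

The tumour ball (4,224 of 884,736 voxels) receives markedly higher saliency
than healthy brain tissue. Sweeping all 256 thresholds
(`examples/02_threshold_evaluation.py`) quantifies this:

```
threshold  precision  recall   FPR
        0     0.0048  1.0000  1.0000
       64     0.0063  1.0000  0.7608
      128     0.0135  1.0000  0.3494
      192     0.9284  0.9787  0.0004
      255     1.0000  0.0000  0.0000

AUC (ROC): 1.0000   AUC (PR): 0.9967
```

At threshold 192 the binary mask recovers 97.9 % of tumour voxels with a
false-positive rate of 4×10⁻⁴; the ROC area rounds to 1.0000 (0.99998).

The same pipeline is available from the shell:

```sh
saliency3d phantom --size 96 --seed 42 --out-dir data/
saliency3d detect --flair data/flair.nii.gz --t1c data/t1c.nii.gz \
                  --t2 data/t2.nii.gz --out saliency.nii.gz
saliency3d eval --map saliency.nii.gz --gt data/gt.nii.gz --out-prefix results/subj
saliency3d counts --dims 240,240,240 --k 4
```

`detect` accepts real BRATS-style NIfTI inputs the same way; volumes of any
shape are conformed internally and the output map is cropped back to the
input geometry.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, what the phantom does and does not emulate, and known
limitations.
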