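# Methods

## Model

`saliency3d` implements a bottom-up, fully computational saliency model for
3D multi-sequence MRI. Its premise: in a pseudo-colour composite of FLAIR,
T1C and T2, glioma tissue is *chromatically rare* — its combination of
channel intensities occurs in a small fraction of the volume — and rarity in
colour space, aggregated over space, is a usable tumour-likelihood score.
No training data, atlas or shape prior is involved; the only inputs are the
three co-registered, skull-stripped volumes.

The pipeline stages and their assumptions:

**Pseudo-colouring.** Each channel is normalized by its own maximum and
scaled to 8 bits with round-half-up (`floor(255·v/max + 0.5)`), so 8- and
16-bit sources share one code path and outputs are bit-reproducible. The
maximum is taken over the whole volume, background included; an all-zero
channel is passed through as zeros with a warning. Channel order is fixed:
FLAIR → R, T1C → G, T2 → B. This stage assumes intensity is meaningful only
relative to the per-volume maximum — there is no inter-subject intensity
calibration.

**Colour space.** RGB is converted via the sRGB transfer function to XYZ and
then to CIE L\*a\*b\* (L\* ∈ [0, 100]). The D65 white point is taken as the
row sums of the sRGB→XYZ matrix itself rather than a separately tabulated
white; the two differ in the fourth decimal, and using the matrix's own white
makes achromatic inputs (R=G=B) map to exactly a\* = b\* = 0, which the
zero-input property of the pipeline relies on.

**Conforming.** Cube decomposition needs dimensions divisible by every scale,
so volumes are zero-padded to the next multiple of 16 (the lcm of 4, 8, 16)
at the high-index end of each axis only. Trailing padding keeps voxel
(0,0,0) aligned between spaces and is exactly invertible by cropping; the
pad value 0 is background in skull-stripped data. In-plane dimensions are
not required to be equal; each axis is conformed independently.

**Cube decomposition.** At scale k the volume is partitioned into
non-overlapping k×k×k cubes, each summarized by its arithmetic mean Lab
value. The per-channel mean of all cube means equals the global voxel mean
(a conservation identity used in the tests).

**Axis-restricted saliency.** The colour saliency of cube (i,j,l) is the sum
of Euclidean Lab distances to every cube sharing at least one index
coordinate with it — the union of its three axis planes, self excluded, with
set semantics (a cube on a shared line is counted once). The spatially
weighted form damps each pairwise term by 1/(1+d), where d is the Euclidean
distance between cube index triples. Index space is the natural unit here:
it is scale-free, and the damping expresses that colour contrast with nearby
cubes is stronger evidence of a compact salient object than contrast with
distant ones. Distances are never below 1 for distinct cubes, so the
weighted saliency is at most half the unweighted one — an invariant the test
suite checks.

Two groupings of the distance weight are provided. `per_pair` (default)
applies the weight inside the sum, pairing each colour difference with its
own distance; `factored` computes the colour saliency first and multiplies
it by the summed weights. The per-pair form is the one consistent with the
motivating idea (each neighbour's colour evidence is discounted by *its*
distance); the factored form is retained behind a flag because it is an
equally literal reading of the formula and is useful for fidelity
experiments. Both are validated against a brute-force oracle that loops over
all cube pairs and tests the shares-a-coordinate predicate literally.

*Computation.* The axis-plane neighbour set is the union of three planes;
by inclusion–exclusion, a sum over it equals the three plane sums minus the
three line sums (pairwise plane intersections), the triple intersection being
the cube itself (zero contribution, and for weight-only sums the +1 self
weights cancel between planes and lines). Plane sums reduce to dense
pairwise-distance computations within each 2D slice, chunked to bound
memory, so the cost is O(n · plane) with small NumPy constants instead of a
per-cube scatter.

**Upscaling and fusion.** Per-scale cube maps are brought to full resolution
by separable (trilinear) linear interpolation with cube values anchored at
cube centres; voxels beyond the outermost centres take the edge value.
Because the three scales sum very different numbers of terms, each
full-resolution map is min–max normalized to [0, 1] before fusion (a
constant map collapses to zeros, avoiding 0/0); the maps are then combined
with weights r_k = 1/3 and the result min–max rescaled to [0, 255].
Normalization before fusion is a deliberate design choice — without it the
coarsest scale, whose sums have the fewest but largest terms, would dominate
arbitrarily — and it can be disabled (`normalize_scales=False`) to study
that effect. Finally a 3×3×3 median filter (reflection boundaries) removes
isolated speckle; kernel size 3 is the smallest non-trivial cube and the
default because larger kernels visibly erode the tumour boundary at k=4
resolution.

**Consequence: the zero-input property.** A spatially uniform nonzero input
becomes a constant Lab volume, every cube mean is equal, all pairwise
differences vanish, and the final map is identically zero. This holds
end-to-end and is tested through the full pipeline.

## Evaluation protocol

Saliency maps are binarized at every integer threshold t ∈ [0, 255] with the
inclusive rule `mask = map ≥ t`, which guarantees the all-positive anchor at
t = 0. The positive class is the whole tumour (any nonzero ground-truth
label). Precision is defined as 1 when no voxel is predicted positive, the
standard convention that keeps PR curves well formed. ROC AUC is trapezoidal
over points sorted by FPR with (0,0) and (1,1) anchors; PR AUC traverses
thresholds in descending order (recall non-decreasing) from the conventional
(recall 0, precision 1) anchor, so ties at equal recall enter at their
highest-precision point and a perfectly separating map scores exactly 1.
Evaluation covers all voxels of the cropped-back volume, background
included; an optional brain mask restricts the domain to nonzero-FLAIR
voxels for sensitivity analyses. Anchor identities — perfect map AUC 1,
constant map AUC 0.5, inverted perfect map AUC 0 — hold exactly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `scales` | (4, 8, 16) | cube sides in voxels; coarse scales localize, fine scales keep detail |
| `weights` | 1/3 each | fusion weights; must sum to 1 |
| `eq3_mode` | `per_pair` | placement of the 1/(1+d) distance weight |
| `median_kernel` | 3 | side of the cubic median filter (odd; 1 disables) |
| `normalize_scales` | true | per-scale min–max normalization before fusion |
| conform divisor | 16 | lcm of the scales; trailing zero-padding |

## Synthetic phantom

The phantom emulates the geometry and contrast regime of skull-stripped,
co-registered glioma MRI: zero background, a brain ellipsoid (semi-axes
0.42/0.45/0.40 of the volume side) with channel-specific tissue means
(FLAIR/T1C/T2 = 90/100/80), an embedded tumour ball (default radius 10 in a
96³ volume, ≈0.5 % of voxels — a realistic whole-tumour fraction) with means
200/140/190 — hyperintense in FLAIR and T2, moderate T1C contrast, so the
tumour is chromatically distinct in all three channels — and additive
Gaussian noise (σ = 10, ≈10 % of tissue intensity) clipped at zero because
MR magnitude images are non-negative. Generation is fully determined by the
seed. An `end-slice` preset places a small tumour near the top of the brain,
the configuration where slice-wise 2D saliency tends to highlight the entire
small cross-section.

What the phantom does **not** emulate: tissue classes (WM/GM/CSF) and their
texture, intra-tumoral heterogeneity (edema vs necrotic vs enhancing core),
bias fields, Rician noise statistics, partial-volume effects, multi-focal
lesions, and inter-subject intensity variation. Passing the phantom tests
therefore demonstrates that the algorithm recovers a chromatically rare,
compact object under noise — the mechanism the method relies on — but not
clinical-grade performance; on real cohort data the detection quality must
be re-established against expert segmentations.

## Numerical choices

- Round-half-up (`floor(x+0.5)`) in 8-bit scaling: fixed rule, reproducible
  outputs.
- Inclusion–exclusion cancellation can leave tiny negative saliency values
  (order 1e-13); they are clamped to 0.
- Brute-force oracle refuses grids larger than 8 per axis (it is O(n²) with
  Python loops, for testing only).
- Constant per-scale maps normalize to zeros rather than dividing by zero.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical phantoms and, the pipeline being deterministic,
  bit-identical saliency files.
- Problem sizes in the tests and acceptance script (96³ default phantom,
  48³ for per-module pipeline tests, oracle grids ≤ 6³ per axis) were chosen
  as the smallest volumes that exercise every scale and keep the cube grids
  non-trivial at k = 16.

## Known limitations

- Max-normalization ties the intensity scale to a single voxel; a hot
  artefact (e.g. residual skull) would compress the useful dynamic range.
- The saliency map flags *rarity*, not pathology: any chromatically rare
  structure (large vessels, artefacts) can score high; the method is a
  detection aid, not a segmenter.
- Whole-volume evaluation counts the easy background voxels; AUC values are
  correspondingly optimistic compared to brain-masked evaluation.
- The cube decomposition is axis-aligned and non-overlapping; tumour
  boundaries that straddle cube faces are recovered only via the multi-scale
  fusion and interpolation, at limited precision.
- Memory scales with the largest 2D slice squared during plane sums
  (chunked, but still the dominant cost for 240³ inputs at k = 4).
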