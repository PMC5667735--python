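"""Generate a synthetic phantom and run the full saliency pipeline.

The phantom is a 96-voxel brain ellipsoid with an embedded tumour ball that
is hyperintense in FLAIR/T2 and shows distinct T1C contrast.  The pipeline
fuses the three sequences to pseudo-colour, converts to CIE L*a*b*, computes
cube-level colour saliency at scales 4/8/16, and fuses the upscaled maps.
"""

import numpy as np

from saliency3d import PhantomSpec, compute_saliency, generate_phantom

seqs, gt = generate_phantom(PhantomSpec(seed=42))
print(f"phantom: shape {seqs.shape}, tumour voxels {int(gt.whole_tumour.sum())}")

saliency, record = compute_saliency(seqs)
cropped = record.crop(saliency.data)

tumour = gt.whole_tumour
brain = (seqs.flair.data > 0) & ~tumour
print(f"saliency range: [{cropped.min():.1f}, {cropped.max():.1f}] (0-255 scale)")
print(f"mean saliency inside tumour:   {cropped[tumour].mean():.1f}")
print(f"mean saliency in healthy brain: {cropped[brain].mean():.1f}")
# A higher tumour mean means the map highlights the lesion against the brain:
# the tumour's rare colour signature dominates the axis-plane comparisons.
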