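"""Deterministic synthetic multi-sequence brain phantom.

The phantom emulates skull-stripped, co-registered BRATS-style inputs: a
zero background, a bright "brain" ellipsoid with channel-specific tissue
intensities plus additive Gaussian noise (clipped at zero, since MR
magnitudes are non-negative), and an embedded spherical tumour that is
hyperintense in FLAIR and T2 with distinct T1C contrast — i.e. chromatically
rare once the three channels are fused to pseudo-colour.  A binary
ground-truth mask marks the tumour ball exactly.

Two presets are provided: ``standard`` (centred tumour) and ``end-slice``
(a small off-centre tumour near the top of the brain, the configuration
where slice-wise 2D saliency tends to highlight the whole small foreground).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .volume_io import LabelVolume, ScalarVolume, SequenceSet, write_volume

#: (FLAIR, T1C, T2) channel means inside healthy brain tissue.
DEFAULT_TISSUE_MEANS = (90.0, 100.0, 80.0)
#: (FLAIR, T1C, T2) channel means inside the tumour ball.
DEFAULT_TUMOUR_MEANS = (200.0, 140.0, 190.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of the synthetic phantom."""

    size: int = 96
    brain_semiaxes: tuple[float, float, float] = (0.42, 0.45, 0.40)  # fractions of size
    tumour_center: tuple[float, float, float] | None = None  # default: volume centre
    tumour_radius: float = 10.0
    tissue_means: tuple[float, float, float] = DEFAULT_TISSUE_MEANS
    tumour_means: tuple[float, float, float] = DEFAULT_TUMOUR_MEANS
    noise_sd: float = 10.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValidationError(f"phantom size must be >= 8, got {self.size}")
        if self.tumour_radius < 1:
            raise ValidationError(f"tumour radius must be >= 1, got {self.tumour_radius}")
        if any(m < 0 for m in self.tissue_means + self.tumour_means):
            raise ValidationError("channel means must be non-negative")
        if self.tumour_center is None:
            c = (self.size - 1) / 2.0
            object.__setattr__(self, "tumour_center", (c, c, c))


def end_slice_spec(size: int = 96, seed: int = 42) -> PhantomSpec:
    """Stress preset: small tumour near the top of the brain ellipsoid.

    Exercises the end-slice failure mode of 2D slice-wise saliency, where the
    brain cross-section is small and a whole-slice comparison misfires.
    """
    c = (size - 1) / 2.0
    semi = (0.42, 0.45, 0.40)
    # centre the ball ~80% of the way up the z semi-axis, radius small enough
    # to stay inside the ellipsoid
    radius = max(3.0, size / 24.0)
    z = c + 0.80 * semi[2] * size - radius
    return PhantomSpec(
        size=size,
        brain_semiaxes=semi,
        tumour_center=(c, c, z),
        tumour_radius=radius,
        seed=seed,
    )


def _ellipsoid_mask(size: int, semiaxes_frac: tuple[float, float, float]) -> np.ndarray:
    c = (size - 1) / 2.0
    ax = np.array(semiaxes_frac) * size
    grid = np.indices((size, size, size), dtype=float)
    r2 = sum(((grid[i] - c) / ax[i]) ** 2 for i in range(3))
    return r2 <= 1.0


def _ball_mask(size: int, center: tuple[float, float, float], radius: float) -> np.ndarray:
    grid = np.indices((size, size, size), dtype=float)
    r2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return r2 <= radius**2


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[SequenceSet, LabelVolume]:
    """Generate the three-sequence phantom and its ground-truth mask.

    Identical spec and seed give bit-identical output.  Raises if the tumour
    ball is not fully inside the brain ellipsoid (the tumour must sit in
    tissue, not background).
    """
    spec = spec or PhantomSpec()
    brain = _ellipsoid_mask(spec.size, spec.brain_semiaxes)
    tumour = _ball_mask(spec.size, spec.tumour_center, spec.tumour_radius)
    if not np.all(brain[tumour]):
        raise ValidationError("tumour ball extends outside the brain ellipsoid")

    rng = np.random.default_rng(spec.seed)
    affine = np.eye(4)
    volumes = []
    for tissue_mean, tumour_mean in zip(spec.tissue_means, spec.tumour_means):
        data = np.zeros((spec.size,) * 3)
        data[brain] = tissue_mean
        data[tumour] = tumour_mean
        if spec.noise_sd > 0:
            data[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        np.clip(data, 0.0, None, out=data)
        volumes.append(ScalarVolume(data=data, affine=affine))

    labels = LabelVolume(data=tumour.astype(np.int16), affine=affine)
    seqs = SequenceSet(*volumes, subject_id=f"phantom-{spec.size}-{spec.seed}")
    return seqs, labels


def write_phantom(
    seqs: SequenceSet, labels: LabelVolume, out_dir: str | Path
) -> dict[str, Path]:
    """Write FLAIR/T1C/T2/GT as four NIfTI files sharing one affine."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in (("flair", seqs.flair), ("t1c", seqs.t1c), ("t2", seqs.t2)):
        p = out_dir / f"{name}.nii.gz"
        write_volume(vol.data.astype(np.float32), vol.affine, p)
        paths[name] = p
    p = out_dir / "gt.nii.gz"
    write_volume(labels.data, seqs.affine, p)
    paths["gt"] = p
    return paths
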