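"""Pseudo-colour composition and CIE L*a*b* conversion.

The three MR sequences are stacked as RGB channels (FLAIR -> R, T1C -> G,
T2 -> B) after per-channel max-normalization to 8 bits, then converted to
CIE L*a*b* so that colour differences can be taken as Euclidean norms.  The
sRGB transfer function with the D65 white point is used throughout, giving
L* in [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .errors import ValidationError
from .volume_io import ScalarVolume, SequenceSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PseudoColorVolume:
    """8-bit pseudo-colour volume; channel order (R, G, B) = (FLAIR, T1C, T2)."""

    data: np.ndarray  # (X, Y, Z, 3) uint8

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 4 or data.shape[3] != 3:
            raise ValidationError(f"expected (X, Y, Z, 3) channel stack, got {data.shape}")
        if data.dtype != np.uint8:
            if np.any(data < 0) or np.any(data > 255) or np.any(data != np.rint(data)):
                raise ValidationError("channel values must be integers in [0, 255]")
            data = data.astype(np.uint8)
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class LabVolume:
    """Per-voxel CIE L*a*b* values with L* in [0, 100]."""

    data: np.ndarray  # (X, Y, Z, 3) float, channels (L, a, b)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4 or data.shape[3] != 3:
            raise ValidationError(f"expected (X, Y, Z, 3) Lab stack, got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValidationError("Lab values must be finite")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def L(self) -> np.ndarray:
        return self.data[..., 0]

    @property
    def a(self) -> np.ndarray:
        return self.data[..., 1]

    @property
    def b(self) -> np.ndarray:
        return self.data[..., 2]


def normalize_to_8bit(channel: ScalarVolume | np.ndarray) -> np.ndarray:
    """Scale a channel by its maximum intensity onto the 8-bit range.

    The output is ``floor(255 * v / max(v) + 0.5)`` (round-half-up), so the
    brightest voxel maps to 255 regardless of source bit depth.  An all-zero
    channel stays all-zero (with a warning) rather than dividing by zero.
    """
    data = np.asarray(getattr(channel, "data", channel), dtype=float)
    vmax = data.max()
    if vmax <= 0:
        log.warning("normalize_to_8bit: channel is all-zero; output left all-zero")
        return np.zeros(data.shape, dtype=np.uint8)
    scaled = np.floor(255.0 * data / vmax + 0.5)
    return scaled.astype(np.uint8)


def compose_pseudo_rgb(seqs: SequenceSet) -> PseudoColorVolume:
    """Stack the normalized sequences as RGB = (FLAIR, T1C, T2)."""
    r = normalize_to_8bit(seqs.flair)
    g = normalize_to_8bit(seqs.t1c)
    b = normalize_to_8bit(seqs.t2)
    return PseudoColorVolume(data=np.stack([r, g, b], axis=-1))


# D65 white point as implied by the sRGB primaries themselves (row sums of the
# RGB->XYZ matrix).  Normalizing by this, rather than a separately tabulated
# white, makes achromatic inputs (R=G=B) map to exactly a* = b* = 0.
_XYZ_WHITE = skcolor.rgb2xyz(np.ones((1, 1, 3)))[0, 0]


def rgb_to_lab(rgb: PseudoColorVolume) -> LabVolume:
    """Convert the 8-bit pseudo-colour volume to CIE L*a*b* (sRGB, D65)."""
    srgb = rgb.data.astype(np.float64) / 255.0
    xyz = skcolor.rgb2xyz(srgb)
    t = xyz / _XYZ_WHITE
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3.0 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return LabVolume(data=np.stack([L, a, b], axis=-1))
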