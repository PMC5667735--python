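"""NIfTI volume I/O, multi-sequence validation, and conforming.

The saliency algorithm decomposes volumes into non-overlapping k-cubes, so
every spatial dimension must be divisible by the largest cube side.  Input
volumes of arbitrary shape (e.g. BRATS 240x240x155) are therefore *conformed*
by zero-padding the trailing end of each axis up to the next multiple of the
divisor; a :class:`ConformRecord` permits exact inverse cropping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Least common multiple of the default cube scales (4, 8, 16); one conforming
#: pass at this divisor serves all three scales.
DEFAULT_DIVISOR = 16

_AFFINE_ATOL = 1e-5


@dataclass(frozen=True)
class ScalarVolume:
    """One MR sequence: a 3D grid of non-negative intensities plus its affine.

    Parameters
    ----------
    data
        3D array of intensities.  Arbitrary dynamic range (8- or 16-bit
        sources are both common); must be non-negative.
    affine
        4x4 voxel-to-world affine, carried through the pipeline unmodified.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValidationError(f"expected a non-empty 3D volume, got shape {data.shape}")
        if np.any(data < 0):
            raise ValidationError("intensities must be non-negative")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {affine.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass(frozen=True)
class SequenceSet:
    """The three co-registered sequences of one subject (FLAIR, T1C, T2)."""

    flair: ScalarVolume
    t1c: ScalarVolume
    t2: ScalarVolume
    subject_id: str = ""

    def __post_init__(self) -> None:
        ref = self.flair
        for name, vol in (("t1c", self.t1c), ("t2", self.t2)):
            if vol.shape != ref.shape:
                raise ValidationError(
                    f"shape mismatch between flair {ref.shape} and {name} {vol.shape}"
                )
            if not np.allclose(vol.affine, ref.affine, atol=_AFFINE_ATOL):
                raise ValidationError(f"affine mismatch between flair and {name}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flair.shape

    @property
    def affine(self) -> np.ndarray:
        return self.flair.affine


@dataclass(frozen=True)
class ConformRecord:
    """Bookkeeping for the zero-padding applied by :func:`conform`."""

    original_shape: tuple[int, int, int]
    conformed_shape: tuple[int, int, int]
    pad_amounts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for o, c, p in zip(self.original_shape, self.conformed_shape, self.pad_amounts):
            if p < 0 or o + p != c:
                raise ValidationError("inconsistent conform record")

    def crop(self, data: np.ndarray) -> np.ndarray:
        """Invert the padding: crop ``data`` back to the original shape."""
        if tuple(data.shape[:3]) != self.conformed_shape:
            raise ValidationError(
                f"expected conformed shape {self.conformed_shape}, got {data.shape[:3]}"
            )
        ox, oy, oz = self.original_shape
        return data[:ox, :oy, :oz]


@dataclass(frozen=True)
class LabelVolume:
    """Integer ground-truth labels; the whole-tumour mask is ``data > 0``.

    BRATS-style annotations use labels {1: necrosis, 2: edema, 3: non-enhancing
    core, 4: enhancing core}; the whole tumour is their union.
    """

    data: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValidationError(f"expected a 3D label volume, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.array_equal(rounded, data):
                raise ValidationError("label volume must be integer-valued")
            data = rounded.astype(np.int16)
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def whole_tumour(self) -> np.ndarray:
        return self.data > 0


def _load_volume(path: str | Path) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ScalarVolume(data=data, affine=img.affine)


def read_sequence_set(
    flair_path: str | Path,
    t1c_path: str | Path,
    t2_path: str | Path,
    subject_id: str = "",
) -> SequenceSet:
    """Read and cross-validate the FLAIR/T1C/T2 trio of one subject.

    Raises
    ------
    FileNotFoundError
        If any path does not exist.
    ValidationError
        If the three volumes disagree in shape or affine.
    """
    for p in (flair_path, t1c_path, t2_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"no such NIfTI file: {p}")
    return SequenceSet(
        flair=_load_volume(flair_path),
        t1c=_load_volume(t1c_path),
        t2=_load_volume(t2_path),
        subject_id=subject_id or Path(flair_path).stem.split(".")[0],
    )


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a ground-truth label volume."""
    img = nib.load(str(path))
    return LabelVolume(data=np.asarray(img.dataobj), affine=img.affine)


def conform(
    volume: ScalarVolume, divisor: int = DEFAULT_DIVISOR
) -> tuple[ScalarVolume, ConformRecord]:
    """Zero-pad each axis up to the next multiple of ``divisor``.

    Padding is appended at the high-index end only so voxel (0,0,0) stays
    aligned between original and conformed space.  Already-divisible axes are
    untouched; conforming is idempotent.
    """
    if divisor < 1:
        raise ValidationError(f"divisor must be >= 1, got {divisor}")
    shape = volume.shape
    pad = tuple((-s) % divisor for s in shape)
    conformed_shape = tuple(s + p for s, p in zip(shape, pad))
    if pad == (0, 0, 0):
        record = ConformRecord(shape, conformed_shape, pad)
        return volume, record
    padded = np.pad(volume.data, [(0, p) for p in pad], mode="constant", constant_values=0)
    record = ConformRecord(shape, conformed_shape, pad)
    return ScalarVolume(data=padded, affine=volume.affine), record


def conform_set(
    seqs: SequenceSet, divisor: int = DEFAULT_DIVISOR
) -> tuple[SequenceSet, ConformRecord]:
    """Conform all three sequences of a set with one shared record."""
    flair, record = conform(seqs.flair, divisor)
    t1c, _ = conform(seqs.t1c, divisor)
    t2, _ = conform(seqs.t2, divisor)
    return SequenceSet(flair, t1c, t2, seqs.subject_id), record


def write_map(
    saliency: "np.ndarray | object",
    record: ConformRecord,
    path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Crop a conformed-space saliency map back to the original shape and write it.

    The map is written as float32 NIfTI with the supplied affine (identity if
    none is given).  ``saliency`` may be a raw array or any object with a
    ``data`` attribute (e.g. :class:`~saliency3d.saliency_core.SaliencyMap`).
    """
    data = np.asarray(getattr(saliency, "data", saliency), dtype=np.float32)
    cropped = record.crop(data)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(cropped, affine)
    nib.save(img, str(path))


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a raw array as NIfTI, preserving its dtype."""
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
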