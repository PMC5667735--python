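"""Cube decomposition, axis-restricted colour saliency, and multi-scale fusion.

The conformed L*a*b* volume is partitioned into non-overlapping k x k x k
cubes, each summarized by its mean (L*, a*, b*).  The colour saliency of a
cube is the sum of Euclidean Lab distances to every cube sharing at least one
index coordinate with it (its three axis planes, self excluded); the
spatially weighted variant additionally damps each term by 1/(1 + d), with d
the Euclidean distance between cube index triples.  Per-scale maps are
upscaled to full resolution by centre-anchored trilinear interpolation, fused
as a weighted sum across scales, rescaled to [0, 255] and median-smoothed.

The axis-plane summation set is the union of three planes through the cube;
by inclusion-exclusion the sum over it equals the three plane sums minus the
three line sums (the pairwise plane intersections), with the triple
intersection -- the cube itself -- contributing zero.  This turns an
O(n * plane) scatter into dense per-slice pairwise computations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .color_pipeline import LabVolume
from .errors import ValidationError

log = logging.getLogger(__name__)

EQ3_MODES = ("per_pair", "factored")

_PAIR_CHUNK = 1024  # row block size for pairwise-norm computations


@dataclass(frozen=True)
class CubeGrid:
    """Per-scale grid of cube-mean L*a*b* values.

    ``means`` has shape (I, J, K, 3) where (I, J, K) are the cube counts per
    axis and the last axis holds (mean L*, mean a*, mean b*).
    """

    k: int
    means: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        if means.ndim != 4 or means.shape[3] != 3:
            raise ValidationError(f"expected (I, J, K, 3) cube means, got {means.shape}")
        if not np.all(np.isfinite(means)):
            raise ValidationError("cube means must be finite")
        object.__setattr__(self, "means", means)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.means.shape[:3]

    @property
    def mean_L(self) -> np.ndarray:
        return self.means[..., 0]

    @property
    def mean_a(self) -> np.ndarray:
        return self.means[..., 1]

    @property
    def mean_b(self) -> np.ndarray:
        return self.means[..., 2]


@dataclass(frozen=True)
class SaliencyGrid:
    """Per-cube colour saliency Sc and distance-weighted saliency S at one scale."""

    k: int
    Sc: np.ndarray
    S: np.ndarray


@dataclass(frozen=True)
class MultiScaleConfig:
    """Tunables of the multi-scale saliency computation.

    scales
        Cube sides; each must divide the conformed volume dimensions.
    weights
        Fusion weight per scale; must sum to 1.  Default: equal thirds.
    eq3_mode
        ``per_pair``: the 1/(1+d) weight multiplies each pairwise colour
        difference.  ``factored``: the colour saliency is computed first and
        multiplied by the summed distance weights.
    distance weighting is always Euclidean in cube-index units.
    """

    scales: tuple[int, ...] = (4, 8, 16)
    weights: tuple[float, ...] | None = None
    eq3_mode: str = "per_pair"
    median_kernel: int = 3
    normalize_scales: bool = True

    def __post_init__(self) -> None:
        if not self.scales or any(s < 1 for s in self.scales):
            raise ValidationError(f"scales must be positive, got {self.scales}")
        weights = self.weights
        if weights is None:
            weights = tuple(1.0 / len(self.scales) for _ in self.scales)
            object.__setattr__(self, "weights", weights)
        if len(weights) != len(self.scales):
            raise ValidationError("need one weight per scale")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1, got {sum(weights)}")
        if self.eq3_mode not in EQ3_MODES:
            raise ValidationError(f"eq3_mode must be one of {EQ3_MODES}, got {self.eq3_mode!r}")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValidationError(f"median kernel must be odd >= 1, got {self.median_kernel}")

    @property
    def divisor(self) -> int:
        return math.lcm(*self.scales)


@dataclass(frozen=True)
class SaliencyMap:
    """Full-resolution non-negative saliency volume on the 0-255 scale."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValidationError(f"expected a 3D saliency map, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValidationError("saliency values must be finite")
        if data.size and (data.min() < -1e-9 or data.max() > 255 + 1e-9):
            raise ValidationError("saliency values must lie in [0, 255]")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# cube decomposition


def cube_decompose(lab: LabVolume, k: int) -> CubeGrid:
    """Partition the Lab volume into k-cubes and take per-cube channel means.

    Every spatial dimension must be divisible by k (conform the volume first).
    """
    X, Y, Z = lab.shape
    if any(d % k for d in (X, Y, Z)):
        raise ValidationError(f"volume shape {(X, Y, Z)} not divisible by k={k}; conform first")
    blocks = lab.data.reshape(X // k, k, Y // k, k, Z // k, k, 3)
    means = blocks.mean(axis=(1, 3, 5))
    return CubeGrid(k=k, means=means)


def axis_plane_indices(
    idx: tuple[int, int, int], dims: tuple[int, int, int]
) -> set[tuple[int, int, int]]:
    """All cubes sharing at least one index coordinate with ``idx``, excluding it.

    This is the summation set of the colour-saliency sum: the union of the
    three axis-aligned planes through the cube, with set semantics (cubes on
    shared lines counted once).
    """
    i, j, l = idx
    I, J, K = dims
    if not (0 <= i < I and 0 <= j < J and 0 <= l < K):
        raise ValidationError(f"index {idx} out of range for dims {dims}")
    out: set[tuple[int, int, int]] = set()
    for y in range(J):
        for z in range(K):
            out.add((i, y, z))
    for x in range(I):
        for z in range(K):
            out.add((x, j, z))
    for x in range(I):
        for y in range(J):
            out.add((x, y, l))
    out.discard((i, j, l))
    return out


# ---------------------------------------------------------------------------
# axis-restricted saliency sums (inclusion-exclusion over planes and lines)


def _pair_norm_rowsums(vals: np.ndarray, W: np.ndarray | None) -> np.ndarray:
    """Row sums of the pairwise Lab-distance matrix of ``vals`` (P, 3),
    optionally weighted elementwise by W (P, P).  Chunked to bound memory."""
    P = vals.shape[0]
    out = np.empty(P)
    for start in range(0, P, _PAIR_CHUNK):
        stop = min(start + _PAIR_CHUNK, P)
        diff = vals[start:stop, None, :] - vals[None, :, :]
        norms = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        if W is not None:
            norms *= W[start:stop]
        out[start:stop] = norms.sum(axis=1)
    return out


def _plane_weight_matrix(U: int, V: int) -> np.ndarray:
    uu, vv = np.meshgrid(np.arange(U, dtype=float), np.arange(V, dtype=float), indexing="ij")
    coords = np.stack([uu.ravel(), vv.ravel()], axis=1)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1))
    return 1.0 / (1.0 + d)


def _line_weight_matrix(K: int) -> np.ndarray:
    idx = np.arange(K, dtype=float)
    return 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))


def _plane_sums(means: np.ndarray, axis: int, weighted: bool) -> np.ndarray:
    """For each cube, the (optionally distance-weighted) sum of Lab distances
    to every cube in its plane perpendicular to ``axis`` (self included, =0)."""
    c = np.moveaxis(means, axis, 0)
    S, U, V, _ = c.shape
    W = _plane_weight_matrix(U, V) if weighted else None
    out = np.empty((S, U, V))
    for s in range(S):
        out[s] = _pair_norm_rowsums(c[s].reshape(U * V, 3), W).reshape(U, V)
    return np.moveaxis(out, 0, axis)


def _line_sums(means: np.ndarray, axis: int, weighted: bool) -> np.ndarray:
    """For each cube, the sum of Lab distances to every cube on its line along
    ``axis`` (the intersection of the two planes containing that line)."""
    c = np.moveaxis(means, axis, 2)
    U, V, K, _ = c.shape
    W = _line_weight_matrix(K) if weighted else None
    out = np.empty((U, V, K))
    for u in range(U):
        diff = c[u][:, :, None, :] - c[u][:, None, :, :]  # (V, K, K, 3)
        norms = np.sqrt(np.einsum("vpqk,vpqk->vpq", diff, diff))
        if W is not None:
            norms = norms * W
        out[u] = norms.sum(axis=-1)
    return np.moveaxis(out, 2, axis)


def _axis_restricted_sum(means: np.ndarray, weighted: bool) -> np.ndarray:
    total = np.zeros(means.shape[:3])
    for axis in range(3):
        total += _plane_sums(means, axis, weighted)
        total -= _line_sums(means, axis, weighted)
    # tiny negatives can arise from cancellation; clamp
    return np.maximum(total, 0.0)


def color_saliency(grid: CubeGrid) -> np.ndarray:
    """Per-cube colour saliency: sum of Euclidean Lab distances over the
    axis-plane neighbour set.  Zero everywhere for a uniform grid."""
    return _axis_restricted_sum(grid.means, weighted=False)


def _weight_field(dims: tuple[int, int, int]) -> np.ndarray:
    """Per-cube sum of 1/(1+d) over the axis-plane neighbour set (self excluded).

    Depends only on the grid geometry, not the colours.  The self term carries
    weight 1 in each plane and each line; the plane-minus-line combination
    cancels it exactly."""
    I, J, K = dims
    total = np.zeros(dims)
    for axis in range(3):
        rest = [d for a, d in enumerate(dims) if a != axis]
        U, V = rest
        plane_row = _plane_weight_matrix(U, V).sum(axis=1).reshape(U, V)
        shape = [1, 1, 1]
        other_axes = [a for a in range(3) if a != axis]
        shape[other_axes[0]] = U
        shape[other_axes[1]] = V
        total += plane_row.reshape(shape)
        line_row = _line_weight_matrix(dims[axis]).sum(axis=1)
        shape = [1, 1, 1]
        shape[axis] = dims[axis]
        total -= line_row.reshape(shape)
    return total


def spatial_weighted_saliency(grid: CubeGrid, mode: str = "per_pair") -> np.ndarray:
    """Distance-weighted saliency over the axis-plane neighbour set.

    ``per_pair`` (default): each pairwise colour difference is damped by
    1/(1 + d) before summation, so nearby colour contrast dominates.
    ``factored``: the plain colour saliency is multiplied by the summed
    distance weights of the neighbour set.
    """
    if mode not in EQ3_MODES:
        raise ValidationError(f"unknown eq3 mode {mode!r}; expected one of {EQ3_MODES}")
    if mode == "per_pair":
        return _axis_restricted_sum(grid.means, weighted=True)
    return color_saliency(grid) * _weight_field(grid.dims)


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_saliency(grid: CubeGrid, mode: str = "per_pair") -> tuple[np.ndarray, np.ndarray]:
    """Reference implementation of Sc and S by explicit loops over all cube
    pairs, testing the shares-a-coordinate predicate literally.

    Guarded to grids of side <= 8 per axis; intended for testing only.
    """
    if mode not in EQ3_MODES:
        raise ValidationError(f"unknown eq3 mode {mode!r}")
    dims = grid.dims
    if max(dims) > 8:
        raise ValidationError(f"brute force guard: dims {dims} exceed 8 per axis")
    means = grid.means
    Sc = np.zeros(dims)
    S = np.zeros(dims)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for l in range(dims[2]):
                wsum = 0.0
                for x in range(dims[0]):
                    for y in range(dims[1]):
                        for z in range(dims[2]):
                            same = i == x and j == y and l == z
                            if same or not (i == x or j == y or l == z):
                                continue
                            dcol = float(np.linalg.norm(means[i, j, l] - means[x, y, z]))
                            d = math.sqrt((i - x) ** 2 + (j - y) ** 2 + (l - z) ** 2)
                            Sc[i, j, l] += dcol
                            if mode == "per_pair":
                                S[i, j, l] += dcol / (1.0 + d)
                            else:
                                wsum += 1.0 / (1.0 + d)
                if mode == "factored":
                    S[i, j, l] = Sc[i, j, l] * wsum
    return Sc, S


# ---------------------------------------------------------------------------
# upscaling, fusion, smoothing


def upscale_map(
    grid_values: np.ndarray, k: int, target_shape: tuple[int, int, int]
) -> np.ndarray:
    """Trilinear upscaling of a per-cube map to full resolution.

    Cube values are anchored at cube centres; voxels beyond the outermost
    centres take the edge cube's value (constant extension).  Linear
    interpolation is separable, so the result is bounded by the grid's
    min and max.
    """
    grid_values = np.asarray(grid_values, dtype=float)
    if tuple(d * k for d in grid_values.shape) != tuple(target_shape):
        raise ValidationError(
            f"grid dims {grid_values.shape} at k={k} do not match target {target_shape}"
        )
    axes = []
    for g, t in zip(grid_values.shape, target_shape):
        p = np.arange(t, dtype=float)
        c = (p - (k - 1) / 2.0) / k  # voxel position in cube-centre coordinates
        axes.append(np.clip(c, 0.0, g - 1.0))
    mesh = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(grid_values, np.stack(mesh), order=1, mode="nearest")


def _minmax01(data: np.ndarray) -> np.ndarray:
    lo, hi = data.min(), data.max()
    if hi - lo <= 0:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def fuse_scales(
    maps: dict[int, np.ndarray], config: MultiScaleConfig | None = None
) -> SaliencyMap:
    """Weighted superposition of full-resolution per-scale maps.

    Each map is min-max normalized to [0, 1] first (constant maps collapse to
    zero) unless ``normalize_scales`` is off, then combined with the config
    weights and min-max rescaled to [0, 255].
    """
    config = config or MultiScaleConfig(scales=tuple(sorted(maps)))
    if set(maps) != set(config.scales):
        raise ValidationError(f"maps for scales {sorted(maps)} do not match config {config.scales}")
    shapes = {np.asarray(m).shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValidationError(f"per-scale maps disagree in shape: {shapes}")
    fused = np.zeros(shapes.pop())
    for k, w in zip(config.scales, config.weights):
        m = np.asarray(maps[k], dtype=float)
        if config.normalize_scales:
            m = _minmax01(m)
        fused += w * m
    return SaliencyMap(data=255.0 * _minmax01(fused))


def median_smooth(saliency: SaliencyMap, kernel: int = 3) -> SaliencyMap:
    """3D median filter with a cubic kernel (reflection at borders)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValidationError(f"median kernel must be odd >= 1, got {kernel}")
    if kernel == 1:
        return saliency
    smoothed = ndimage.median_filter(saliency.data, size=kernel, mode="reflect")
    return SaliencyMap(data=smoothed)


# ---------------------------------------------------------------------------
# complexity accounting


def nominal_comparison_counts(M: int, N: int, k: int) -> tuple[int, int, int]:
    """Exact operation counts for an M x M x N volume decomposed at scale k.

    Returns ``(n_cubes, all_pairs, axis_plane_total)`` where ``all_pairs`` is
    the cost of comparing every cube with every other, and
    ``axis_plane_total`` is the per-cube three-plane tally (planes counted
    with multiplicity, self included) that the axis-restricted sum replaces
    it with.
    """
    if M % k or N % k:
        raise ValidationError(f"dims ({M}, {M}, {N}) not divisible by k={k}")
    m, n = M // k, N // k
    n_cubes = m * m * n
    all_pairs = n_cubes * (n_cubes - 1)
    axis_plane_total = n_cubes * (m * m + 2 * m * n)
    return n_cubes, all_pairs, axis_plane_total
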