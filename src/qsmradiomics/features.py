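"""Radiomic feature extraction from a susceptibility volume and VOI mask.

Computes the canonical 105-feature set — 18 first-order, 13 shape and 74
texture features — from a 3D quantitative-susceptibility volume (ppm) and a
co-registered binary volume-of-interest mask. Texture features are built on
five gray-level matrices: co-occurrence (GLCM), run length (GLRLM),
size zone (GLSZM), dependence (GLDM) and neighbouring gray-tone difference
(NGTDM). GLCM and GLRLM are evaluated per lattice direction over the 13
unique axes of the 26-neighbourhood and averaged; GLSZM, GLDM and NGTDM are
direction-free, using full 26-connectivity.

Distances for voxel pairs, runs and neighbourhoods are measured in voxel
steps on the lattice, ignoring the anisotropic spacing; physical spacing
enters only the shape features and TotalEnergy.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist
from skimage import measure

from .config import DegenerateVoiError, StudyConfig

logger = logging.getLogger(__name__)

_EPS = np.spacing(1.0)

# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class VoxelGrid:
    """3D scalar susceptibility field with anisotropic voxel spacing (mm)."""

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid requires a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")


@dataclasses.dataclass
class VoiMask:
    """Binary 3D mask selecting the volume of interest."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("VoiMask requires a 3D array")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass
class DiscretizedVoi:
    """Integer gray levels 1..Ng inside the VOI; 0 outside (sentinel)."""

    levels: np.ndarray  # int array, full grid shape
    mask: np.ndarray  # bool, same shape
    n_levels: int  # Ng


@dataclasses.dataclass
class GrayLevelMatrix:
    """A texture counting matrix plus the sizes its features need.

    For GLCM/GLRLM/GLSZM/GLDM ``counts`` is the raw P(i, j) matrix with rows
    indexed by gray level 1..Ng. For NGTDM the per-level vectors are stored
    in ``s_i``, ``n_i`` and ``p_i`` instead.
    """

    family: str
    counts: Optional[np.ndarray] = None
    offset: Optional[Tuple[int, int, int]] = None
    n_levels: int = 0
    n_voxels: int = 0  # VOI voxels relevant to the family (Np / Nvp)
    s_i: Optional[np.ndarray] = None
    n_i: Optional[np.ndarray] = None
    p_i: Optional[np.ndarray] = None

    @property
    def n_observations(self) -> float:
        """Nz — total count mass (pairs, runs, zones or voxels)."""
        return float(self.counts.sum()) if self.counts is not None else 0.0

    @property
    def normalized(self) -> np.ndarray:
        nz = self.n_observations
        return self.counts / nz if nz > 0 else self.counts


# ---------------------------------------------------------------------------
# canonical feature roster
# ---------------------------------------------------------------------------

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]

SHAPE_NAMES = [
    "Volume", "SurfaceArea", "SurfaceVolumeRatio", "Sphericity",
    "Maximum3DDiameter", "Maximum2DDiameterSlice", "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow", "MajorAxisLength", "MinorAxisLength",
    "LeastAxisLength", "Elongation", "Flatness",
]

GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]

GLDM_NAMES = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

GLRLM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

GLSZM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]

NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

FEATURE_NAMES: List[str] = (
    [f"firstorder_{n}" for n in FIRSTORDER_NAMES]
    + [f"shape_{n}" for n in SHAPE_NAMES]
    + [f"glcm_{n}" for n in GLCM_NAMES]
    + [f"gldm_{n}" for n in GLDM_NAMES]
    + [f"glrlm_{n}" for n in GLRLM_NAMES]
    + [f"glszm_{n}" for n in GLSZM_NAMES]
    + [f"ngtdm_{n}" for n in NGTDM_NAMES]
)

assert len(FEATURE_NAMES) == 105

#: the five features highlighted by the group-level analysis
REPRESENTATIVE_FEATURES = [
    "firstorder_10Percentile",
    "firstorder_Median",
    "shape_Volume",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glszm_GrayLevelNonUniformity",
]


def direction_set() -> List[Tuple[int, int, int]]:
    """The 13 unique lattice axes of the 3D 26-neighbourhood at distance 1.

    One representative offset per axis; no offset in the list is the
    negation of another, and the union of the list with its negations is
    the full 26-neighbourhood. Pair/run counting is insensitive to the sign
    of the offset, so each axis is traversed once.
    """
    return [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, 0, 1), (0, 1, 1),
        (1, -1, 0), (1, 0, -1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
    ]


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def discretize(
    grid: VoxelGrid,
    mask: VoiMask,
    bin_count: Optional[int] = 16,
    bin_width: Optional[float] = None,
) -> DiscretizedVoi:
    """Map VOI intensities to integer gray levels 1..Ng.

    Fixed bin count: ``level = 1 + floor((x - min) / (max - min) * n)``,
    clamped so the maximum maps to ``n``. Fixed bin width ``w`` (ppm):
    ``level = 1 + floor((x - min) / w)``. A constant VOI yields the single
    level 1 (Ng = 1) under either policy.
    """
    if (bin_count is None) == (bin_width is None):
        raise ValueError("exactly one of bin_count / bin_width must be given")
    m = mask.data
    if not m.any():
        raise DegenerateVoiError("empty VOI mask")
    x = np.asarray(grid.values, dtype=np.float64)
    vals = x[m]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities inside the VOI")
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(x.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
        ng = 1
    elif bin_count is not None:
        lv = 1 + np.floor((vals - lo) / (hi - lo) * bin_count).astype(np.int64)
        lv = np.minimum(lv, bin_count)
        levels[m] = lv
        ng = int(bin_count)
    else:
        lv = 1 + np.floor((vals - lo) / bin_width).astype(np.int64)
        levels[m] = lv
        ng = int(lv.max())
    return DiscretizedVoi(levels=levels, mask=m, n_levels=ng)


def _bbox(mask: np.ndarray, pad: int = 1) -> Tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _crop(disc: DiscretizedVoi) -> Tuple[np.ndarray, np.ndarray]:
    sl = _bbox(disc.mask)
    return disc.levels[sl], disc.mask[sl]


def _offset_slices(shape, off):
    """Slices (src, dst) so that arr[dst] = arr shifted by ``off`` at arr[src]."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# gray-level matrices
# ---------------------------------------------------------------------------


def glcm(disc: DiscretizedVoi, offset: Tuple[int, int, int]) -> GrayLevelMatrix:
    """Gray-level co-occurrence matrix for one lattice offset.

    Counts every ordered in-VOI voxel pair separated by ``offset``, then
    symmetrizes by adding the transpose, so P(i, j) = P(j, i).
    """
    lv, m = _crop(disc)
    ng = disc.n_levels
    src, dst = _offset_slices(lv.shape, offset)
    valid = m[src] & m[dst]
    a = lv[src][valid] - 1
    b = lv[dst][valid] - 1
    counts = np.zeros((ng, ng), dtype=np.float64)
    if a.size:
        np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    if counts.sum() == 0:
        logger.debug("glcm: no valid pair for offset %s", offset)
    return GrayLevelMatrix(
        family="GLCM", counts=counts, offset=offset, n_levels=ng,
        n_voxels=int(m.sum()),
    )


def glrlm(disc: DiscretizedVoi, offset: Tuple[int, int, int]) -> GrayLevelMatrix:
    """Gray-level run-length matrix along one lattice direction.

    P(i, j) counts maximal runs of gray level i and length j; runs break at
    the VOI boundary. Every VOI voxel belongs to exactly one run, so
    sum_ij j * P(i, j) equals the VOI voxel count.
    """
    lv, m = _crop(disc)
    ng = disc.n_levels
    nvox = int(m.sum())
    max_len = max(int(np.ceil(np.sqrt(3) * max(lv.shape))), 1)
    counts = np.zeros((ng, max_len), dtype=np.float64)

    src, dst = _offset_slices(lv.shape, offset)
    # cont[v] True when v continues the run arriving from v - offset
    cont = np.zeros(lv.shape, dtype=bool)
    cont[dst] = m[dst] & m[src] & (lv[dst] == lv[src])
    frontier = m & ~cont  # run starts
    length = 1
    while frontier.any():
        # does the run extend one more step?
        nxt = np.zeros(lv.shape, dtype=bool)
        nxt[src] = frontier[src] & cont[dst]
        ends = frontier.copy()
        ends[src] &= ~cont[dst]  # interior voxels whose continuation exists
        lv_end = lv[ends]
        if lv_end.size:
            np.add.at(counts[:, length - 1], lv_end - 1, 1.0)
        # advance surviving runs
        frontier = np.zeros(lv.shape, dtype=bool)
        frontier[dst] = nxt[src]
        length += 1
        if length > max_len:  # pragma: no cover - guarded by geometry
            raise RuntimeError("run length exceeded bounding-box diagonal")
    # trim trailing all-zero columns beyond the longest observed run
    last = int(np.max(np.nonzero(counts.sum(axis=0))[0])) + 1 if counts.any() else 1
    return GrayLevelMatrix(
        family="GLRLM", counts=counts[:, :last], offset=offset, n_levels=ng,
        n_voxels=nvox,
    )


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm(disc: DiscretizedVoi) -> GrayLevelMatrix:
    """Gray-level size-zone matrix (26-connected zones, direction-free)."""
    lv, m = _crop(disc)
    ng = disc.n_levels
    nvox = int(m.sum())
    zones: List[Tuple[int, int]] = []  # (level-1, size)
    for level in range(1, ng + 1):
        sel = m & (lv == level)
        if not sel.any():
            continue
        lab, nlab = ndimage.label(sel, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((level - 1, int(s)) for s in sizes)
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((ng, max_size), dtype=np.float64)
    for i, s in zones:
        counts[i, s - 1] += 1.0
    return GrayLevelMatrix(
        family="GLSZM", counts=counts, n_levels=ng, n_voxels=nvox,
    )


def _neighbor_stats(lv: np.ndarray, m: np.ndarray):
    """Per-voxel count / level-sum / equal-level count over in-VOI 26-neighbours."""
    nbr_count = np.zeros(lv.shape, dtype=np.int32)
    nbr_sum = np.zeros(lv.shape, dtype=np.float64)
    nbr_equal = np.zeros(lv.shape, dtype=np.int32)
    offsets = direction_set()
    for off in offsets + [tuple(-o for o in off) for off in offsets]:
        src, dst = _offset_slices(lv.shape, off)
        both = m[src] & m[dst]
        # neighbour of the voxel at dst is the voxel at src
        nbr_count[dst] += both
        nbr_sum[dst] += np.where(both, lv[src], 0)
        nbr_equal[dst] += both & (lv[dst] == lv[src])
    return nbr_count, nbr_sum, nbr_equal


def gldm(disc: DiscretizedVoi) -> GrayLevelMatrix:
    """Gray-level dependence matrix over the full 26-neighbourhood.

    A neighbour is dependent when its level equals the centre's (tolerance
    alpha = 0). P(i, j+1) counts VOI voxels of level i with j dependent
    neighbours; feature formulas index columns 1-based, i.e. dependence
    size = dependent-neighbour count + 1 (the centre itself).
    """
    lv, m = _crop(disc)
    ng = disc.n_levels
    _, _, nbr_equal = _neighbor_stats(lv, m)
    dep = nbr_equal[m]  # dependent-neighbour count per VOI voxel
    levels = lv[m] - 1
    counts = np.zeros((ng, int(dep.max()) + 1), dtype=np.float64)
    np.add.at(counts, (levels, dep), 1.0)
    return GrayLevelMatrix(
        family="GLDM", counts=counts, n_levels=ng, n_voxels=int(m.sum()),
    )


def ngtdm(disc: DiscretizedVoi) -> GrayLevelMatrix:
    """Neighbouring gray-tone difference matrix.

    For each level i, over VOI voxels of level i that have at least one
    in-VOI 26-neighbour: n_i is their count, p_i = n_i / Nvp, and s_i sums
    |i - mean level of the voxel's in-VOI neighbours|.
    """
    lv, m = _crop(disc)
    ng = disc.n_levels
    nbr_count, nbr_sum, _ = _neighbor_stats(lv, m)
    has = m & (nbr_count > 0)
    levels = lv[has]
    diff = np.abs(levels - nbr_sum[has] / nbr_count[has])
    s_i = np.zeros(ng, dtype=np.float64)
    n_i = np.zeros(ng, dtype=np.float64)
    np.add.at(s_i, levels - 1, diff)
    np.add.at(n_i, levels - 1, 1.0)
    nvp = float(n_i.sum())
    p_i = n_i / nvp if nvp > 0 else n_i
    return GrayLevelMatrix(
        family="NGTDM", n_levels=ng, n_voxels=int(nvp),
        s_i=s_i, n_i=n_i, p_i=p_i,
    )


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------


def first_order_features(
    grid: VoxelGrid, mask: VoiMask, disc: DiscretizedVoi
) -> Dict[str, float]:
    """The 18 intensity-distribution features.

    Entropy and Uniformity are computed on the discretized gray-level
    histogram; percentiles use linear interpolation between order
    statistics; TotalEnergy scales Energy by the physical voxel volume.
    Skewness and Kurtosis (non-excess) are 0 by convention for a constant
    or single-voxel VOI.
    """
    x = np.asarray(grid.values, dtype=np.float64)[mask.data]
    if x.size == 0:
        raise DegenerateVoiError("empty VOI mask")
    n = x.size
    voxel_volume = float(np.prod(grid.spacing))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mean = float(x.mean())
    var = float(x.var())  # population variance
    energy = float(np.sum(x**2))
    hist = np.bincount(disc.levels[disc.mask], minlength=disc.n_levels + 1)[1:]
    p = hist / n
    pnz = p[p > 0]
    entropy = float(-np.sum(pnz * np.log2(pnz)))
    uniformity = float(np.sum(p**2))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    if var > 0:
        centred = x - mean
        skew = float(np.mean(centred**3) / var**1.5)
        kurt = float(np.mean(centred**4) / var**2)
    else:
        skew, kurt = 0.0, 0.0
        if n == 1:
            logger.debug("single-voxel VOI: skewness/kurtosis set to 0")
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }


# ---------------------------------------------------------------------------
# shape features
# ---------------------------------------------------------------------------


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(pdist(points).max())


def shape_features(mask: VoiMask, spacing: Sequence[float]) -> Dict[str, float]:
    """The 13 geometry features of the VOI.

    Volume is the raw voxel count (the scale on which the group statistics
    report it); SurfaceArea comes from a triangulated isosurface of the
    mask (marching cubes at physical spacing); diameters are maximal
    pairwise distances between voxel centres in physical coordinates
    (a single-voxel VOI therefore has diameter 0); axis lengths derive
    from the principal axes of the voxel-centre point cloud.
    """
    m = mask.data
    if not m.any():
        raise DegenerateVoiError("empty VOI mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    n = int(m.sum())
    voxel_volume = float(np.prod(spacing))
    phys_volume = n * voxel_volume

    padded = np.pad(m, 1).astype(np.uint8)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))

    coords = np.argwhere(m) * spacing
    d3 = _max_pairwise(coords)
    # in-plane diameters: group voxel centres by the index along one axis
    plane_d = []
    for axis in (2, 1, 0):  # slice (axial), column, row
        keep = [a for a in range(3) if a != axis]
        best = 0.0
        for u in np.unique(np.argwhere(m)[:, axis]):
            pts = coords[np.argwhere(m)[:, axis] == u][:, keep]
            best = max(best, _max_pairwise(pts))
        plane_d.append(best)
    d_slice, d_col, d_row = plane_d

    if n > 1:
        cov = np.cov(coords.T)
        eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    if eig[0] > 0:
        elongation = float(np.sqrt(eig[1] / eig[0]))
        flatness = float(np.sqrt(eig[2] / eig[0]))
        if eig[2] == 0:
            logger.debug("planar/degenerate VOI: flatness 0")
    else:
        elongation, flatness = 0.0, 0.0
        logger.debug("degenerate VOI: axis lengths undefined, set to 0")

    sphericity = (36.0 * np.pi * phys_volume**2) ** (1.0 / 3.0) / area
    return {
        "Volume": float(n),
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / phys_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": d3,
        "Maximum2DDiameterSlice": d_slice,
        "Maximum2DDiameterColumn": d_col,
        "Maximum2DDiameterRow": d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }


# ---------------------------------------------------------------------------
# texture features per family
# ---------------------------------------------------------------------------


def _xlog2(v: np.ndarray) -> np.ndarray:
    """v * log2(v) with the 0*log0 = 0 convention."""
    out = np.zeros_like(v, dtype=np.float64)
    nz = v > 0
    out[nz] = v[nz] * np.log2(v[nz])
    return out


def glcm_features(mat: GrayLevelMatrix) -> Dict[str, float]:
    """The 23 co-occurrence features from one symmetric normalized GLCM."""
    p = mat.normalized
    ng = mat.n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng)  # |i-j| = 0..Ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())

    hx = float(-np.sum(_xlog2(px)))
    hy = float(-np.sum(_xlog2(py)))
    hxy = float(-np.sum(_xlog2(p)))
    pxpy = np.outer(px, py)
    valid = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[valid] * np.log2(pxpy[valid])))
    hxy2 = float(-np.sum(_xlog2(pxpy)))

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x * sig_y > 0:
        correlation = (float(np.sum(p * ii * jj)) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0  # degenerate single-level convention

    da = float(np.sum(k_diff * p_diff))
    off_diag = ii != jj
    inv_var = float(np.sum(p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2))

    return {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "ClusterProminence": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(_xlog2(p_diff))),
        "DifferenceVariance": float(np.sum(p_diff * (k_diff - da) ** 2)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(_xlog2(p_sum))),
        "SumSquares": float(np.sum(p * (ii - mu_x) ** 2)),
    }


def _run_zone_core(counts: np.ndarray):
    """Shared marginals for run-length-style matrices."""
    ng, nl = counts.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nl + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    nz = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    return i, j, ii, jj, nz, row, col


def glrlm_features(mat: GrayLevelMatrix) -> Dict[str, float]:
    """The 16 run-length features for one direction."""
    P = mat.counts
    i, j, ii, jj, nr, row, col = _run_zone_core(P)
    p = P / nr
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))
    return {
        "GrayLevelNonUniformity": float(np.sum(row**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(row**2) / nr**2),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(P * ii**2) / nr),
        "LongRunEmphasis": float(np.sum(P * jj**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 * jj**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(P * jj**2 / ii**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(P / ii**2) / nr),
        "RunEntropy": float(-np.sum(_xlog2(p))),
        "RunLengthNonUniformity": float(np.sum(col**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(col**2) / nr**2),
        "RunPercentage": float(nr / mat.n_voxels),
        "RunVariance": float(np.sum(p * (jj - mu_j) ** 2)),
        "ShortRunEmphasis": float(np.sum(P / jj**2) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 / jj**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * jj**2)) / nr),
    }


def glszm_features(mat: GrayLevelMatrix) -> Dict[str, float]:
    """The 16 size-zone features."""
    P = mat.counts
    i, j, ii, jj, ns, row, col = _run_zone_core(P)
    p = P / ns
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))
    return {
        "GrayLevelNonUniformity": float(np.sum(row**2) / ns),
        "GrayLevelNonUniformityNormalized": float(np.sum(row**2) / ns**2),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(P * ii**2) / ns),
        "LargeAreaEmphasis": float(np.sum(P * jj**2) / ns),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 * jj**2) / ns),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(P * jj**2 / ii**2) / ns),
        "LowGrayLevelZoneEmphasis": float(np.sum(P / ii**2) / ns),
        "SizeZoneNonUniformity": float(np.sum(col**2) / ns),
        "SizeZoneNonUniformityNormalized": float(np.sum(col**2) / ns**2),
        "SmallAreaEmphasis": float(np.sum(P / jj**2) / ns),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 / jj**2) / ns),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * jj**2)) / ns),
        "ZoneEntropy": float(-np.sum(_xlog2(p))),
        "ZonePercentage": float(ns / mat.n_voxels),
        "ZoneVariance": float(np.sum(p * (jj - mu_j) ** 2)),
    }


def gldm_features(mat: GrayLevelMatrix) -> Dict[str, float]:
    """The 14 dependence features (dependence size = column index, 1-based)."""
    P = mat.counts
    i, j, ii, jj, nz, row, col = _run_zone_core(P)
    p = P / nz
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))
    return {
        "DependenceEntropy": float(-np.sum(_xlog2(p))),
        "DependenceNonUniformity": float(np.sum(col**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(col**2) / nz**2),
        "DependenceVariance": float(np.sum(p * (jj - mu_j) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(row**2) / nz),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(P * ii**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(P * jj**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 * jj**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * jj**2 / ii**2) / nz),
        "LowGrayLevelEmphasis": float(np.sum(P / ii**2) / nz),
        "SmallDependenceEmphasis": float(np.sum(P / jj**2) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 / jj**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * jj**2)) / nz),
    }


def ngtdm_features(mat: GrayLevelMatrix) -> Dict[str, float]:
    """The 5 neighbouring gray-tone difference features."""
    s, n, p = mat.s_i, mat.n_i, mat.p_i
    ng = mat.n_levels
    nvp = float(n.sum())
    i = np.arange(1, ng + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    ivec = i[present]
    pvec = p[present]
    svec = s[present]

    denom_coarse = float(np.sum(pvec * svec))
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1 and nvp > 0:
        di = ivec[:, None] - ivec[None, :]
        pp = pvec[:, None] * pvec[None, :]
        contrast = (
            float(np.sum(pp * di**2)) / (ngp * (ngp - 1)) * float(np.sum(svec)) / nvp
        )
    else:
        contrast = 0.0

    ipi = ivec * pvec
    busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
    busyness = denom_coarse / busy_den if busy_den > 0 else 0.0

    if nvp > 0 and ngp > 0:
        psum = pvec[:, None] + pvec[None, :]
        num = (
            np.abs(ivec[:, None] - ivec[None, :])
            * (pvec[:, None] * svec[:, None] + pvec[None, :] * svec[None, :])
            / psum
        )
        complexity = float(np.sum(num)) / nvp
        strength_num = float(
            np.sum(psum * (ivec[:, None] - ivec[None, :]) ** 2)
        )
        s_total = float(np.sum(svec))
        strength = strength_num / s_total if s_total > 0 else 0.0
    else:
        complexity, strength = 0.0, 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def _average_directional(
    per_direction: List[Dict[str, float]], names: List[str]
) -> Dict[str, float]:
    """Average per-direction feature dicts, skipping empty directions."""
    if not per_direction:
        raise DegenerateVoiError("no direction produced a valid matrix")
    return {
        k: float(np.mean([d[k] for d in per_direction])) for k in names
    }


def texture_features(
    disc: DiscretizedVoi, mask_n_voxels: Optional[int] = None
) -> Dict[str, float]:
    """All 74 texture features from a discretized VOI.

    GLCM and GLRLM are evaluated along each of the 13 unique lattice
    directions and the per-direction feature values averaged; directions
    without a single valid pair are excluded from the GLCM average. GLSZM,
    GLDM and NGTDM are direction-free (26-connectivity).
    """
    dirs = direction_set()
    glcm_dicts = []
    glrlm_dicts = []
    for off in dirs:
        cm = glcm(disc, off)
        if cm.n_observations > 0:
            glcm_dicts.append(glcm_features(cm))
        else:
            logger.debug("direction %s dropped from GLCM average", off)
        rm = glrlm(disc, off)
        glrlm_dicts.append(glrlm_features(rm))

    out: Dict[str, float] = {}
    for name, val in _average_directional(glcm_dicts, GLCM_NAMES).items():
        out[f"glcm_{name}"] = val
    for name, val in gldm_features(gldm(disc)).items():
        out[f"gldm_{name}"] = val
    for name, val in _average_directional(glrlm_dicts, GLRLM_NAMES).items():
        out[f"glrlm_{name}"] = val
    for name, val in glszm_features(glszm(disc)).items():
        out[f"glszm_{name}"] = val
    for name, val in ngtdm_features(ngtdm(disc)).items():
        out[f"ngtdm_{name}"] = val
    return out


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


def extract_all(
    grid: VoxelGrid, mask: VoiMask, config: Optional[StudyConfig] = None
) -> Dict[str, float]:
    """Extract the full ordered 105-feature vector for one subject."""
    config = config or StudyConfig()
    disc = discretize(grid, mask, bin_count=config.bin_count, bin_width=config.bin_width)
    vec: Dict[str, float] = {}
    for name, val in first_order_features(grid, mask, disc).items():
        vec[f"firstorder_{name}"] = val
    for name, val in shape_features(mask, grid.spacing).items():
        vec[f"shape_{name}"] = val
    vec.update(texture_features(disc))
    ordered = {name: vec[name] for name in FEATURE_NAMES}
    assert len(ordered) == 105
    return ordered
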