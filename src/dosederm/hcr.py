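"""Handcrafted radiomic features: 14 shape + 18 first-order + 73 texture.

Implements the standard IBSI-style feature families directly:

* shape (14): mesh / voxel volume, surface area, sphericity, diameters and
  principal-axis statistics;
* first-order (18): intensity statistics on the raw HU values (histogram
  features use the fixed-bin-width discretization);
* GLCM (22), GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5): gray-level
  texture matrices built in 3-D.  GLCM and GLRLM are computed per direction
  over the 13 unique distance-1 offsets and feature values averaged over
  directions; GLSZM/GLDM/NGTDM are direction-free with 26-connected
  neighborhoods.

Discretization is fixed bin width (default 25 HU) relative to the ROI
minimum, so adding a constant to the image leaves all texture features
unchanged.  Degenerate denominators (constant ROI, single gray level)
return 0 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from dosederm.core import ImageGrid, StructureMask

EPS = np.finfo(float).eps

# 13 unique direction offsets at Chebyshev distance 1 (half of the 26)
OFFSETS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]
OFFSETS_26 = [o for o in OFFSETS_13] + [tuple(-c for c in o) for o in OFFSETS_13]


@dataclass
class HcrParams:
    """Extraction settings: fixed bin width, distance-1 averaged texture."""

    bin_width: float = 25.0
    min_roi_voxels: int = 8

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def discretize(image: np.ndarray, mask: np.ndarray,
               bin_width: float) -> tuple[np.ndarray, int]:
    """Fixed-bin-width quantization: level = floor((I - min) / width) + 1.

    Returns an integer level map (0 outside the mask) and the level count.
    """
    if not mask.any():
        raise ValueError("empty ROI")
    vals = image[mask]
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[mask] = np.floor((image[mask] - vals.min()) / bin_width).astype(np.int64) + 1
    return levels, int(levels.max())


# ---------------------------------------------------------------------------
# first order

def firstorder_features(image: np.ndarray, mask: np.ndarray,
                        spacing, bin_width: float) -> dict[str, float]:
    x = image[mask].astype(float)
    n = x.size
    voxvol = float(np.prod(spacing))
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    hist, _ = np.histogram(x, bins=max(1, int(np.floor((x.max() - x.min())
                                                       / bin_width)) + 1))
    p = hist / n
    p = p[p > 0]
    sd = np.sqrt(var)
    skew = float(np.mean((x - mean) ** 3) / sd ** 3) if sd > 0 else 0.0
    kurt = float(np.mean((x - mean) ** 4) / var ** 2) if var > 0 else 0.0
    return {
        "Energy": float(np.sum(x ** 2)),
        "TotalEnergy": float(voxvol * np.sum(x ** 2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0),
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float(np.sum(p ** 2)),
    }


# ---------------------------------------------------------------------------
# shape

def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def _planar_diameter(coords: np.ndarray, drop_axis: int) -> float:
    """Largest in-plane voxel-center distance over planes along one axis."""
    keep = [a for a in range(3) if a != drop_axis]
    best = 0.0
    for u in np.unique(coords[:, drop_axis]):
        pts = coords[coords[:, drop_axis] == u][:, keep]
        if len(pts) > 2:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:
                pass
        if len(pts) >= 2:
            best = max(best, float(pdist(pts).max()))
    return best


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    spacing = np.asarray(spacing, dtype=float)
    n = int(mask.sum())
    voxel_volume = float(np.prod(spacing))
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                               spacing=tuple(spacing))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->", tri[:, 0],
                                      np.cross(tri[:, 1], tri[:, 2])) / 6.0))
    idx = np.argwhere(mask).astype(float) * spacing  # physical voxel centers
    centered = idx - idx.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    sphericity = ((36 * np.pi * mesh_volume ** 2) ** (1 / 3)) / surface_area
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": float(n * voxel_volume),
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": float(sphericity) if surface_area > 0 else 0.0,
        "Maximum3DDiameter": _max_pairwise(idx),
        "Maximum2DDiameterSlice": _planar_diameter(idx, 0),
        "Maximum2DDiameterColumn": _planar_diameter(idx, 1),
        "Maximum2DDiameterRow": _planar_diameter(idx, 2),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one offset."""
    dz, dy, dx = offset
    nz, ny, nx = levels.shape
    src = (slice(max(0, -dz), min(nz, nz - dz)),
           slice(max(0, -dy), min(ny, ny - dy)),
           slice(max(0, -dx), min(nx, nx - dx)))
    dst = (slice(max(0, dz), min(nz, nz + dz)),
           slice(max(0, dy), min(ny, ny + dy)),
           slice(max(0, dx), min(nx, nx + dx)))
    a = levels[src]
    b = levels[dst]
    valid = mask[src] & mask[dst]
    mat = np.zeros((n_levels, n_levels), dtype=float)
    if valid.any():
        np.add.at(mat, (a[valid] - 1, b[valid] - 1), 1.0)
    mat = mat + mat.T  # symmetric
    total = mat.sum()
    return mat / total if total > 0 else mat


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())  # symmetric: mu_x = mu_y
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # diagonal/cross-diagonal distributions
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(k_sum.size)
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(k_diff.size)
    for s in range(ng):
        for t in range(ng):
            p_sum[s + t] += P[s, t]
            p_diff[abs(s - t)] += P[s, t]

    nz = P > 0
    hxy = float(-(P[nz] * np.log2(P[nz])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    pxpy = np.outer(px, px)
    both = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[both] * np.log2(pxpy[both])).sum())
    pp = pxpy > 0
    hxy2 = float(-(pxpy[pp] * np.log2(pxpy[pp])).sum())

    diff_avg = float((k_diff * p_diff).sum())
    ps_nz = p_sum > 0
    pd_nz = p_diff > 0

    corr = 0.0
    if sigma2 > 0:
        corr = float(((ii * jj * P).sum() - mu * mu) / sigma2)
    imc1 = 0.0
    if max(hx, hx) > 0:
        imc1 = (hxy - hxy1) / max(hx, hx)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off_diag = ii != jj
    inv_var = float((P[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2).sum())

    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(p_diff[pd_nz] * np.log2(p_diff[pd_nz])).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + (ii - jj) ** 2 / ng ** 2)).sum()),
        "Idn": float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((P ** 2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "SumEntropy": float(-(p_sum[ps_nz] * np.log2(p_sum[ps_nz])).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(levels, mask, n_levels) -> dict[str, float]:
    """22 co-occurrence features averaged over the 13 distance-1 offsets."""
    per_offset = [
        _glcm_features_single(glcm_matrix(levels, mask, n_levels, off))
        for off in OFFSETS_13
    ]
    return {k: float(np.mean([f[k] for f in per_offset])) for k in per_offset[0]}


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                 offset: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix P[level, run_length] along one direction."""
    shape = levels.shape
    max_run = int(np.ceil(np.linalg.norm(shape))) + 1
    mat = np.zeros((n_levels, max_run), dtype=float)
    d = np.asarray(offset)
    coords = np.argwhere(mask)
    coord_set = {tuple(c) for c in coords}

    def in_mask(c):
        return tuple(c) in coord_set

    for c in coords:
        prev = tuple(c - d)
        if prev in coord_set and levels[prev] == levels[tuple(c)]:
            continue  # not a run start
        lvl = levels[tuple(c)]
        length = 1
        nxt = c + d
        while tuple(nxt) in coord_set and levels[tuple(nxt)] == lvl:
            length += 1
            nxt = nxt + d
        mat[lvl - 1, length - 1] += 1.0
    return mat[:, : mat.shape[1]]


def _rl_features(P: np.ndarray, n_voxels: int) -> dict:
    """Shared run-length / size-zone / dependence feature formulas.

    Generic keys (SE, LE, GLN, ...) are renamed to the family-specific
    feature names by each caller.
    """
    nr = P.sum()
    if nr == 0:
        keys = ["SE", "LE", "GLN", "GLNN", "RLN", "RLNN", "RP", "GLV", "RV",
                "RE", "LGLE", "HGLE", "SLGLE", "SHGLE", "LLGLE", "LHGLE"]
        return {k: 0.0 for k in keys}
    p = P / nr
    ng, nl = P.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nl + 1)[None, :]
    pg = p.sum(axis=1)  # gray-level marginal
    pl = p.sum(axis=0)  # length marginal
    mu_i = float((np.arange(1, ng + 1) * pg).sum())
    mu_j = float((np.arange(1, nl + 1) * pl).sum())
    nz = p > 0
    return {
        "SE": float((p / j ** 2).sum()),
        "LE": float((p * j ** 2).sum()),
        "GLN": float((P.sum(axis=1) ** 2).sum() / nr),
        "GLNN": float((pg ** 2).sum()),
        "RLN": float((P.sum(axis=0) ** 2).sum() / nr),
        "RLNN": float((pl ** 2).sum()),
        "RP": float(nr / n_voxels),
        "GLV": float((((i - mu_i) ** 2) * p).sum()),
        "RV": float((((j - mu_j) ** 2) * p).sum()),
        "RE": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LGLE": float((p / i ** 2).sum()),
        "HGLE": float((p * i ** 2).sum()),
        "SLGLE": float((p / (i ** 2 * j ** 2)).sum()),
        "SHGLE": float((p * i ** 2 / j ** 2).sum()),
        "LLGLE": float((p * j ** 2 / i ** 2).sum()),
        "LHGLE": float((p * i ** 2 * j ** 2).sum()),
    }


_GLRLM_NAMES = {
    "SE": "ShortRunEmphasis", "LE": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "RLN": "RunLengthNonUniformity", "RLNN": "RunLengthNonUniformityNormalized",
    "RP": "RunPercentage", "GLV": "GrayLevelVariance", "RV": "RunVariance",
    "RE": "RunEntropy", "LGLE": "LowGrayLevelRunEmphasis",
    "HGLE": "HighGrayLevelRunEmphasis",
    "SLGLE": "ShortRunLowGrayLevelEmphasis",
    "SHGLE": "ShortRunHighGrayLevelEmphasis",
    "LLGLE": "LongRunLowGrayLevelEmphasis",
    "LHGLE": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "SE": "SmallAreaEmphasis", "LE": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "RLN": "SizeZoneNonUniformity", "RLNN": "SizeZoneNonUniformityNormalized",
    "RP": "ZonePercentage", "GLV": "GrayLevelVariance", "RV": "ZoneVariance",
    "RE": "ZoneEntropy", "LGLE": "LowGrayLevelZoneEmphasis",
    "HGLE": "HighGrayLevelZoneEmphasis",
    "SLGLE": "SmallAreaLowGrayLevelEmphasis",
    "SHGLE": "SmallAreaHighGrayLevelEmphasis",
    "LLGLE": "LargeAreaLowGrayLevelEmphasis",
    "LHGLE": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(levels, mask, n_levels) -> dict[str, float]:
    """16 run-length features averaged over the 13 directions."""
    n_vox = int(mask.sum())
    per_dir = []
    for off in OFFSETS_13:
        raw = _rl_features(glrlm_matrix(levels, mask, n_levels, off), n_vox)
        per_dir.append(raw)
    return {_GLRLM_NAMES[k]: float(np.mean([f[k] for f in per_dir]))
            for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix: 26-connected zones of equal gray level."""
    max_size = int(mask.sum())
    mat = np.zeros((n_levels, max_size), dtype=float)
    structure = np.ones((3, 3, 3), dtype=bool)
    for lvl in range(1, n_levels + 1):
        sel = (levels == lvl) & mask
        if not sel.any():
            continue
        lab, n = ndimage.label(sel, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            mat[lvl - 1, s - 1] += 1.0
    return mat


def glszm_features(levels, mask, n_levels) -> dict[str, float]:
    raw = _rl_features(glszm_matrix(levels, mask, n_levels), int(mask.sum()))
    return {_GLSZM_NAMES[k]: v for k, v in raw.items()}


# ---------------------------------------------------------------------------
# GLDM

def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                alpha: float = 0.0) -> np.ndarray:
    """Dependence matrix P[level, j]: j = 1 + count of dependent neighbors."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    nzd = levels.shape
    for off in OFFSETS_26:
        dz, dy, dx = off
        nz_, ny_, nx_ = nzd
        src = (slice(max(0, -dz), min(nz_, nz_ - dz)),
               slice(max(0, -dy), min(ny_, ny_ - dy)),
               slice(max(0, -dx), min(nx_, nx_ - dx)))
        dst = (slice(max(0, dz), min(nz_, nz_ + dz)),
               slice(max(0, dy), min(ny_, ny_ + dy)),
               slice(max(0, dx), min(nx_, nx_ + dx)))
        ok = mask[src] & mask[dst] & (np.abs(levels[src] - levels[dst]) <= alpha)
        contrib = np.zeros(nzd, dtype=np.int64)
        contrib[src] = ok.astype(np.int64)
        dep += contrib
    max_dep = 27
    mat = np.zeros((n_levels, max_dep), dtype=float)
    sel = mask
    np.add.at(mat, (levels[sel] - 1, dep[sel]), 1.0)
    return mat


_GLDM_NAMES = {
    "SE": "SmallDependenceEmphasis", "LE": "LargeDependenceEmphasis",
    "GLN": "GrayLevelNonUniformity", "RLN": "DependenceNonUniformity",
    "RLNN": "DependenceNonUniformityNormalized", "GLV": "GrayLevelVariance",
    "RV": "DependenceVariance", "RE": "DependenceEntropy",
    "LGLE": "LowGrayLevelEmphasis", "HGLE": "HighGrayLevelEmphasis",
    "SLGLE": "SmallDependenceLowGrayLevelEmphasis",
    "SHGLE": "SmallDependenceHighGrayLevelEmphasis",
    "LLGLE": "LargeDependenceLowGrayLevelEmphasis",
    "LHGLE": "LargeDependenceHighGrayLevelEmphasis",
}


def gldm_features(levels, mask, n_levels) -> dict[str, float]:
    """14 dependence features (the shared set minus GLNN)."""
    raw = _rl_features(gldm_matrix(levels, mask, n_levels), int(mask.sum()))
    return {v: raw[k] for k, v in _GLDM_NAMES.items()}


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level (n_i, p_i, s_i): counts, fractions, tone-difference sums."""
    nbr_sum = np.zeros(levels.shape, dtype=float)
    nbr_cnt = np.zeros(levels.shape, dtype=float)
    shape = levels.shape
    for off in OFFSETS_26:
        dz, dy, dx = off
        nz_, ny_, nx_ = shape
        src = (slice(max(0, -dz), min(nz_, nz_ - dz)),
               slice(max(0, -dy), min(ny_, ny_ - dy)),
               slice(max(0, -dx), min(nx_, nx_ - dx)))
        dst = (slice(max(0, dz), min(nz_, nz_ + dz)),
               slice(max(0, dy), min(ny_, ny_ + dy)),
               slice(max(0, dx), min(nx_, nx_ + dx)))
        ok = mask[dst]
        add_sum = np.zeros(shape)
        add_cnt = np.zeros(shape)
        add_sum[src] = np.where(ok, levels[dst], 0)
        add_cnt[src] = ok.astype(float)
        nbr_sum += add_sum
        nbr_cnt += add_cnt
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    sel = mask & (nbr_cnt > 0)
    avg = np.zeros(levels.shape)
    avg[sel] = nbr_sum[sel] / nbr_cnt[sel]
    for lvl in range(1, n_levels + 1):
        voxels = sel & (levels == lvl)
        n_i[lvl - 1] = voxels.sum()
        s_i[lvl - 1] = np.abs(lvl - avg[voxels]).sum()
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(levels, mask, n_levels) -> dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(levels, mask, n_levels)
    nv = n_i.sum()
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=float)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    contrast = 0.0
    if ngp > 1 and nv > 0:
        pi_p, i_p = p_i[present], i[present]
        pair = np.add.outer(np.zeros(ngp), np.zeros(ngp))
        diff2 = (i_p[:, None] - i_p[None, :]) ** 2
        contrast = (float((pi_p[:, None] * pi_p[None, :] * diff2).sum())
                    / (ngp * (ngp - 1))) * (s_i.sum() / nv)

    busyness = 0.0
    if ngp > 1:
        pi_p, i_p = p_i[present], i[present]
        den = float(np.abs(i_p[:, None] * pi_p[:, None]
                           - i_p[None, :] * pi_p[None, :]).sum())
        busyness = coarse_den / den if den > 0 else 0.0

    complexity = 0.0
    strength = 0.0
    if nv > 0 and ngp > 0:
        pi_p, i_p, s_p = p_i[present], i[present], s_i[present]
        psum = pi_p[:, None] + pi_p[None, :]
        absdiff = np.abs(i_p[:, None] - i_p[None, :])
        num_c = absdiff * (pi_p[:, None] * s_p[:, None]
                           + pi_p[None, :] * s_p[None, :]) / psum
        complexity = float(num_c.sum()) / nv
        s_sum = float(s_i.sum())
        if s_sum > 0:
            strength = float((psum * absdiff ** 2).sum()) / s_sum

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# assembly

_FAMILIES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
_FAMILY_SIZES = {"shape": 14, "firstorder": 18, "glcm": 22, "glrlm": 16,
                 "glszm": 16, "gldm": 14, "ngtdm": 5}


def extract_hcr(image: ImageGrid, mask: StructureMask,
                params: HcrParams | None = None) -> dict[str, float]:
    """All 105 handcrafted features for one (image, ROI) pair.

    Keys are ``hcr_<family>_<name>``.  Raises ``roi too small`` when the
    mask has fewer than ``params.min_roi_voxels`` voxels (mirrors the
    exclusion of patients with insufficient skin ROI volume).
    """
    params = params or HcrParams()
    m = mask.mask
    if m.shape != image.shape:
        raise ValueError("mask shape does not match image grid")
    if m.sum() < params.min_roi_voxels:
        raise ValueError("roi too small")
    levels, ng = discretize(image.values, m, params.bin_width)
    out: dict[str, float] = {}
    for name, val in shape_features(m, image.spacing).items():
        out[f"hcr_shape_{name}"] = val
    for name, val in firstorder_features(image.values, m, image.spacing,
                                         params.bin_width).items():
        out[f"hcr_firstorder_{name}"] = val
    for fam, fn in (("glcm", glcm_features), ("glrlm", glrlm_features),
                    ("glszm", glszm_features), ("gldm", gldm_features),
                    ("ngtdm", ngtdm_features)):
        for name, val in fn(levels, m, ng).items():
            out[f"hcr_{fam}_{name}"] = val
    assert len(out) == 105, f"expected 105 features, got {len(out)}"
    return out


def feature_manifest() -> list[str]:
    """The frozen 105-name manifest (order of extraction)."""
    tiny = ImageGrid(np.zeros((3, 3, 3)), spacing=(1, 1, 1))
    grid = np.zeros((3, 3, 3))
    grid[1] = [[0, 25, 50]] * 3
    img = ImageGrid(grid, spacing=(1, 1, 1))
    full = StructureMask("all", np.ones((3, 3, 3), dtype=bool))
    return list(extract_hcr(img, full).keys())
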