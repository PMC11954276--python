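"""Radiomics feature extraction from a 3-D map within a region of interest.

One derivative map yields exactly 819 named features:

* 18 first-order statistics and 73 texture features (22 GLCM + 16 GLRLM +
  16 GLSZM + 5 NGTDM + 14 GLDM) on the original image, and
* the same 91 features on each of the 8 sub-bands of a one-level undecimated
  3-D wavelet decomposition (``wavelet-LLL`` ... ``wavelet-HHH``), giving
  8 x 91 = 728 wavelet features.

Naming follows the ``[wavelet-<S>_]<family>_<Feature>`` convention, e.g.
``wavelet-HHL_glcm_Idmn``.  Sub-band letters are ordered (x, y, z): the i-th
letter says whether the low-pass (L) or high-pass (H) filter was applied
along the i-th axis of the stored grid.

Texture matrices are computed on an equal-width discretization of the
in-ROI intensity range (fixed bin *count*, default 32 — derivative maps are
z-scored, so a fixed bin width would be meaningless).  GLCM and GLRLM
accumulate over the 13 unique 3-D directions at distance 1 and are summed
across directions before feature computation; GLSZM zones and GLDM/NGTDM
neighbourhoods use 26-connectivity.

Degenerate-input conventions (documented and tested): GLCM Correlation on a
constant ROI is 1 (maximal homogeneity); NGTDM Coarseness on a uniform ROI
returns the sentinel 1e6; a single-voxel ROI yields all-zero GLCM features
with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "RoiImage",
    "DiscretizedRoi",
    "discretize",
    "wavelet_subbands",
    "firstorder_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "texture_features",
    "extract_all",
    "FIRSTORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "WAVELET_LABELS",
    "FAMILY_SIZES",
]

_EPS = np.spacing(1.0)
_COARSENESS_SENTINEL = 1.0e6

WAVELET_LABELS = tuple(
    "".join(p) for p in itertools.product("LH", repeat=3)
)  # LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH

# The 13 unique direction offsets of the 26-neighbourhood (first non-zero
# component positive); their negatives complete the 26 directions.
OFFSETS_13 = [
    off
    for off in itertools.product((0, 1, -1), repeat=3)
    if off != (0, 0, 0)
    and next(c for c in off if c != 0) > 0
]

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointAverage", "JointEnergy",
    "JointEntropy", "MaximumProbability", "SumEntropy", "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

FAMILY_SIZES = {
    "firstorder": len(FIRSTORDER_NAMES),
    "glcm": len(GLCM_NAMES),
    "glrlm": len(GLRLM_NAMES),
    "glszm": len(GLSZM_NAMES),
    "ngtdm": len(NGTDM_NAMES),
    "gldm": len(GLDM_NAMES),
}
assert sum(FAMILY_SIZES.values()) == 91  # 18 + 73


@dataclass
class RoiImage:
    """A 3-D scalar map with the region-of-interest mask it is read within."""

    values: np.ndarray
    roi_mask: np.ndarray
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.values.shape != self.roi_mask.shape:
            raise ValueError("values and roi_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.roi_mask])):
            raise ValueError("non-finite values inside ROI")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_mm))


@dataclass
class DiscretizedRoi:
    """Integer gray levels 1..n_levels inside the ROI, 0 outside."""

    levels: np.ndarray
    n_levels: int


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------

def discretize(roi: RoiImage, n_bins: int = 32) -> DiscretizedRoi:
    """Equal-width binning of in-ROI values over their [min, max] range.

    The maximum value is assigned to bin ``n_bins``; a constant ROI maps
    everything to level 1 (with a warning when more bins were requested).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mask = roi.roi_mask
    vals = roi.values[mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(roi.values.shape, dtype=np.int64)
    if hi == lo:
        if n_bins > 1:
            warnings.warn("discretize: constant ROI, all voxels -> level 1")
        levels[mask] = 1
        return DiscretizedRoi(levels, n_bins)
    width = (hi - lo) / n_bins
    lev = np.floor((vals - lo) / width).astype(np.int64) + 1
    np.clip(lev, 1, n_bins, out=lev)
    levels[mask] = lev
    return DiscretizedRoi(levels, n_bins)


# --------------------------------------------------------------------------
# wavelet sub-bands
# --------------------------------------------------------------------------

def wavelet_subbands(
    values: np.ndarray, wavelet: str = "coif1"
) -> dict[str, np.ndarray]:
    """One-level undecimated 3-D wavelet decomposition into 8 sub-bands.

    The stationary (decimation-free) transform keeps every sub-band on the
    original grid, so the ROI mask applies unchanged.  Filters are applied
    separably per axis (letter i -> axis i) with mirror (symmetric) signal
    extension.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("expected a 3-D grid")
    wav = pywt.Wavelet(wavelet)
    filters = {"L": np.asarray(wav.dec_lo), "H": np.asarray(wav.dec_hi)}
    flen = len(filters["L"])
    if min(values.shape) < flen:
        raise ValueError(
            f"grid {values.shape} smaller than the {wavelet} filter ({flen})"
        )
    out: dict[str, np.ndarray] = {}
    for label in WAVELET_LABELS:
        band = values
        for axis, letter in enumerate(label):
            band = ndimage.correlate1d(
                band, filters[letter], axis=axis, mode="mirror"
            )
        out[label] = band
    return out


# --------------------------------------------------------------------------
# first-order statistics
# --------------------------------------------------------------------------

def firstorder_features(
    values: np.ndarray, voxel_volume: float = 1.0, n_bins: int = 32
) -> dict[str, float]:
    """The 18 first-order features of the in-ROI intensity multiset.

    Entropy and Uniformity are computed on the equal-width ``n_bins``
    histogram; percentiles use linear interpolation between order
    statistics; Skewness and Kurtosis (Pearson, normal = 3) of a
    zero-variance ROI are returned as 0 with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = x.mean()
    var = x.var()  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    energy = float(np.sum(x ** 2))

    lo, hi = x.min(), x.max()
    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    else:
        counts = np.array([x.size])
    p = counts[counts > 0] / x.size
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p ** 2))

    if var > 0:
        m2 = var
        skew = float(np.mean((x - mean) ** 3) / m2 ** 1.5)
        kurt = float(np.mean((x - mean) ** 4) / m2 ** 2)
    else:
        warnings.warn("firstorder: zero variance, Skewness/Kurtosis set to 0")
        skew = kurt = 0.0

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": entropy,
        "Minimum": float(lo),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(hi),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(hi - lo),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": uniformity,
    }


# --------------------------------------------------------------------------
# shared helpers for texture matrices
# --------------------------------------------------------------------------

def _shift_slices(shape, off):
    """Slice pairs (src, dst) such that arr[dst] is arr shifted by -off,
    i.e. a[src] and b[dst] pair voxel v with voxel v + off."""
    src, dst = [], []
    for dim, o in zip(shape, off):
        if o == 0:
            src.append(slice(None)); dst.append(slice(None))
        elif o > 0:
            src.append(slice(0, dim - o)); dst.append(slice(o, dim))
        else:
            src.append(slice(-o, dim)); dst.append(slice(0, dim + o))
    return tuple(src), tuple(dst)


def _matrix_stats(P: np.ndarray):
    """Normalized matrix, marginals and index grids for (level, j) matrices."""
    n = P.sum()
    p = P / n if n > 0 else P
    ng, nj = P.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nj + 1, dtype=float)[None, :]
    return p, n, i, j


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def glcm_matrix(d: DiscretizedRoi) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix over the 13 directions."""
    lev = d.levels
    ng = d.n_levels
    P = np.zeros((ng, ng))
    for off in OFFSETS_13:
        src, dst = _shift_slices(lev.shape, off)
        a, b = lev[src], lev[dst]
        valid = (a > 0) & (b > 0)
        if valid.any():
            idx = (a[valid] - 1) * ng + (b[valid] - 1)
            P += np.bincount(idx, minlength=ng * ng).reshape(ng, ng)
    P = P + P.T
    total = P.sum()
    return P / total if total > 0 else P


def glcm_features(d: DiscretizedRoi) -> dict[str, float]:
    """The 22-feature GLCM roster on the direction-summed symmetric matrix."""
    p = glcm_matrix(d)
    ng = d.n_levels
    if p.sum() == 0:
        warnings.warn("glcm: no voxel pairs in ROI, all features 0")
        return {name: 0.0 for name in GLCM_NAMES}
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, ng + 1, dtype=float)[None, :]
    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(px * np.arange(1, ng + 1)))
    sigma2 = float(np.sum(px * (np.arange(1, ng + 1) - mu) ** 2))
    sigma = np.sqrt(sigma2)

    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    ks = (i + j).astype(int)
    pxy_sum = np.bincount(ks.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    kd = np.abs(i - j).astype(int)
    pxy_diff = np.bincount(kd.ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    k_diff = np.arange(0, ng, dtype=float)
    da = float(np.sum(k_diff * pxy_diff))

    autocorr = float(np.sum(i * j * p))
    correlation = (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 1.0

    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hxy = float(-np.sum(p * np.log2(p + _EPS)))
    pxpy = px[:, None] * px[None, :]
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off_diag = kd > 0
    inv_var = float(np.sum(p[off_diag] / (i - j)[off_diag] ** 2))

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(np.sum((i + j - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((i + j - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((i + j - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((i - j) ** 2 * p)),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -np.sum(pxy_diff * np.log2(pxy_diff + _EPS))
        ),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * pxy_diff)),
        "Id": float(np.sum(p / (1.0 + kd))),
        "Idm": float(np.sum(p / (1.0 + (i - j) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((i - j) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + kd / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": float(np.sum(p ** 2)),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-np.sum(pxy_sum * np.log2(pxy_sum + _EPS))),
        "SumSquares": sigma2,
    }


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def glrlm_matrix(d: DiscretizedRoi) -> np.ndarray:
    """Run-length counts P(level, length) summed over the 13 directions.

    A run is a maximal straight sequence of equal-level in-ROI voxels.
    """
    lev = d.levels
    ng = d.n_levels
    shape = lev.shape
    max_len = int(np.ceil(np.sqrt(sum(s ** 2 for s in shape)))) + 1
    P = np.zeros((ng, max_len))
    roi = lev > 0
    for off in OFFSETS_13:
        src, dst = _shift_slices(shape, off)
        cont = np.zeros(shape, dtype=bool)  # run continues one step forward
        cont[src] = roi[src] & (lev[src] == lev[dst])
        # starts: in-ROI voxels whose backward neighbour breaks the run
        is_start = roi.copy()
        is_start[dst] &= ~cont[src]
        # length = 1 + number of consecutive forward continuations:
        # chain_k[v] <=> the run through v extends at least k steps forward.
        length = np.ones(shape, dtype=np.int64)
        chain = cont.copy()
        m = 1
        while chain.any():
            length += chain
            shifted = np.zeros(shape, dtype=bool)
            ksrc, kdst = _shift_slices(shape, tuple(m * o for o in off))
            shifted[ksrc] = cont[kdst]
            chain &= shifted
            m += 1
        ls = lev[is_start] - 1
        lns = length[is_start] - 1
        np.add.at(P, (ls, lns), 1)
    used = max(1, int(np.max(np.nonzero(P.sum(axis=0))[0])) + 1) if P.sum() else 1
    return P[:, :used]


def _rlm_features(P: np.ndarray, n_runs_norm: float, names) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas on a (level, j) matrix."""
    p, n, i, j = _matrix_stats(P)
    if n == 0:
        warnings.warn("run/zone matrix empty, all features 0")
        return {name: 0.0 for name in names}
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    iv = i.ravel()
    jv = j.ravel()
    mu_i = float(np.sum(pi * iv))
    mu_j = float(np.sum(pj * jv))
    pos = p > 0
    vals = {
        "small": float(np.sum(p / j ** 2)),
        "large": float(np.sum(p * j ** 2)),
        "gln": float(np.sum(P.sum(axis=1) ** 2) / n),
        "glnn": float(np.sum(pi ** 2)),
        "jn": float(np.sum(P.sum(axis=0) ** 2) / n),
        "jnn": float(np.sum(pj ** 2)),
        "pct": float(n / n_runs_norm),
        "glv": float(np.sum(p * (i - mu_i) ** 2)),
        "jv": float(np.sum(p * (j - mu_j) ** 2)),
        "ent": float(-np.sum(p[pos] * np.log2(p[pos] + _EPS))),
        "lgl": float(np.sum(p / i ** 2)),
        "hgl": float(np.sum(p * i ** 2)),
        "sl": float(np.sum(p / (i ** 2 * j ** 2))),
        "sh": float(np.sum(p * i ** 2 / j ** 2)),
        "ll": float(np.sum(p * j ** 2 / i ** 2)),
        "lh": float(np.sum(p * i ** 2 * j ** 2)),
    }
    order = [
        "small", "large", "gln", "glnn", "jn", "jnn", "pct",
        "glv", "jv", "ent", "lgl", "hgl", "sl", "sh", "ll", "lh",
    ]
    return dict(zip(names, (vals[k] for k in order)))


def glrlm_features(d: DiscretizedRoi) -> dict[str, float]:
    """The standard 16 run-length features (run percentage is normalized by
    ROI size x number of directions so it stays in (0, 1])."""
    P = glrlm_matrix(d)
    n_roi = int((d.levels > 0).sum())
    return _rlm_features(P, n_roi * len(OFFSETS_13), GLRLM_NAMES)


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(d: DiscretizedRoi) -> np.ndarray:
    """Zone counts P(level, size): 26-connected components of equal level."""
    lev = d.levels
    ng = d.n_levels
    n_roi = int((lev > 0).sum())
    P = np.zeros((ng, max(1, n_roi)))
    for g in np.unique(lev[lev > 0]):
        labelled, n_zones = ndimage.label(lev == g, structure=_STRUCT26)
        if n_zones:
            sizes = np.bincount(labelled.ravel())[1:]
            for s in sizes:
                P[g - 1, s - 1] += 1
    used = max(1, int(np.max(np.nonzero(P.sum(axis=0))[0])) + 1) if P.sum() else 1
    return P[:, :used]


def glszm_features(d: DiscretizedRoi) -> dict[str, float]:
    """The standard 16 size-zone features (zone percentage = zones / ROI)."""
    P = glszm_matrix(d)
    n_roi = int((d.levels > 0).sum())
    return _rlm_features(P, n_roi, GLSZM_NAMES)


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

def _neighbour_sums(lev: np.ndarray):
    """26-neighbourhood in-ROI level sums and neighbour counts (self excluded)."""
    roi = (lev > 0).astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(lev.astype(float) * roi, kernel, mode="constant")
    nb_cnt = ndimage.correlate(roi, kernel, mode="constant")
    return nb_sum, nb_cnt


def ngtdm_table(d: DiscretizedRoi):
    """Per-level occurrence counts n_i and coarseness sums s_i."""
    lev = d.levels
    roi = lev > 0
    nb_sum, nb_cnt = _neighbour_sums(lev)
    s = np.zeros(d.n_levels)
    n = np.zeros(d.n_levels)
    idx = lev[roi] - 1
    have_nb = nb_cnt[roi] > 0
    diffs = np.zeros(idx.shape)
    diffs[have_nb] = np.abs(
        lev[roi][have_nb] - nb_sum[roi][have_nb] / nb_cnt[roi][have_nb]
    )
    np.add.at(s, idx, diffs)
    np.add.at(n, idx, 1)
    return n, s


def ngtdm_features(d: DiscretizedRoi) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity and Strength."""
    n, s = ngtdm_table(d)
    N = n.sum()
    if N == 0:
        raise ValueError("empty ROI")
    p = n / N
    present = p > 0
    ngp = int(present.sum())
    iv = np.arange(1, d.n_levels + 1, dtype=float)

    ps = float(np.sum(p * s))
    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_SENTINEL

    pi, pj = p[present], p[present]
    ii, jj = iv[present][:, None], iv[present][None, :]
    pij_i, pij_j = pi[:, None], pj[None, :]

    if ngp > 1:
        contrast = (
            float(np.sum(pij_i * pij_j * (ii - jj) ** 2))
            / (ngp * (ngp - 1))
            * float(s.sum() / N)
        )
    else:
        contrast = 0.0

    busy_den = float(np.sum(np.abs(ii * pij_i - jj * pij_j)))
    busyness = ps / busy_den if busy_den > 0 else 0.0

    s_present = s[present]
    complexity = float(
        np.sum(
            np.abs(ii - jj)
            * (pij_i * s_present[:, None] + pij_j * s_present[None, :])
            / (pij_i + pij_j)
        )
        / N
    )

    s_total = float(s.sum())
    strength = (
        float(np.sum((pij_i + pij_j) * (ii - jj) ** 2)) / s_total
        if s_total > 0
        else 0.0
    )
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

def gldm_matrix(d: DiscretizedRoi, alpha: int = 0) -> np.ndarray:
    """Dependence counts P(level, k+1): k = number of 26-neighbours whose
    level differs from the centre voxel's by at most ``alpha``.

    The matrix column index is the dependence *size* k + 1 (the voxel
    itself), keeping the small-dependence emphasis denominators finite.
    """
    lev = d.levels
    roi = lev > 0
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in OFFSETS_13:
        src, dst = _shift_slices(lev.shape, off)
        a, b = lev[src], lev[dst]
        m = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[src] += m
        dep[dst] += m
    P = np.zeros((d.n_levels, 27))
    np.add.at(P, (lev[roi] - 1, dep[roi]), 1)
    used = max(1, int(np.max(np.nonzero(P.sum(axis=0))[0])) + 1)
    return P[:, :used]


def gldm_features(d: DiscretizedRoi, alpha: int = 0) -> dict[str, float]:
    """The standard 14 gray-level dependence features."""
    P = gldm_matrix(d, alpha)
    p, n, i, j = _matrix_stats(P)
    if n == 0:
        raise ValueError("empty ROI")
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    iv = np.arange(1, P.shape[0] + 1, dtype=float)
    jv = np.arange(1, P.shape[1] + 1, dtype=float)
    mu_i = float(np.sum(pi * iv))
    mu_j = float(np.sum(pj * jv))
    pos = p > 0
    return {
        "SmallDependenceEmphasis": float(np.sum(p / j ** 2)),
        "LargeDependenceEmphasis": float(np.sum(p * j ** 2)),
        "GrayLevelNonUniformity": float(np.sum(P.sum(axis=1) ** 2) / n),
        "DependenceNonUniformity": float(np.sum(P.sum(axis=0) ** 2) / n),
        "DependenceNonUniformityNormalized": float(np.sum(pj ** 2)),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "DependenceEntropy": float(-np.sum(p[pos] * np.log2(p[pos] + _EPS))),
        "LowGrayLevelEmphasis": float(np.sum(p / i ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(p * i ** 2)),
        "SmallDependenceLowGrayLevelEmphasis": float(
            np.sum(p / (i ** 2 * j ** 2))
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            np.sum(p * i ** 2 / j ** 2)
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            np.sum(p * j ** 2 / i ** 2)
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            np.sum(p * i ** 2 * j ** 2)
        ),
    }


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def texture_features(d: DiscretizedRoi) -> dict[str, float]:
    """All 73 texture features of one discretized image, family-prefixed."""
    out: dict[str, float] = {}
    for fam, fn in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("ngtdm", ngtdm_features),
        ("gldm", gldm_features),
    ):
        for name, val in fn(d).items():
            out[f"{fam}_{name}"] = val
    assert len(out) == 73
    return out


def _image_features(roi: RoiImage, n_bins: int) -> dict[str, float]:
    d = discretize(roi, n_bins)
    feats = {
        f"firstorder_{k}": v
        for k, v in firstorder_features(
            roi.values[roi.roi_mask], roi.voxel_volume, n_bins
        ).items()
    }
    feats.update(texture_features(d))
    return feats


def extract_all(
    roi: RoiImage, n_bins: int = 32, wavelet: str = "coif1"
) -> dict[str, float]:
    """The full 819-feature vector of one map: 91 original-image features
    plus 91 per wavelet sub-band, discretization recomputed per image."""
    if int(roi.roi_mask.sum()) < 27:
        raise ValueError("ROI must contain at least 27 voxels")
    feats = _image_features(roi, n_bins)
    for label, band in wavelet_subbands(roi.values, wavelet).items():
        sub = RoiImage(band, roi.roi_mask, roi.voxel_mm)
        for name, val in _image_features(sub, n_bins).items():
            feats[f"wavelet-{label}_{name}"] = val
    n_wavelet = sum(1 for k in feats if k.startswith("wavelet-"))
    assert len(feats) == 819 and n_wavelet == 728, (
        f"feature roster broken: {len(feats)} total, {n_wavelet} wavelet"
    )
    return feats
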