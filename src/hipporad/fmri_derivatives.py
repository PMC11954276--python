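"""Resting-state fMRI derivative maps: ALFF, ReHo, VMHC and degree centrality.

All four maps are computed from a detrended, band-passed (0.01-0.1 Hz) 4-D
BOLD volume:

* **ALFF** — amplitude of low-frequency fluctuations: the mean, over in-band
  frequency bins, of the square root of the voxel's periodogram power
  spectral density.
* **ReHo** — regional homogeneity: Kendall's coefficient of concordance (W)
  between a voxel's time series and those of its 26-connected in-mask
  neighbours.
* **VMHC** — voxel-mirrored homotopic connectivity: Pearson correlation
  between a voxel's series and the series of its mirror voxel across the
  x mid-plane.
* **DC** — weighted degree centrality: the sum of a voxel's Pearson
  correlations with every other in-mask voxel, restricted to r > 0.25.

Processing order follows the conventional resting-state pipeline: detrend,
band-pass, then 6 mm FWHM spatial smoothing of the *input* for ALFF and VMHC
only — ReHo and DC are computed on unsmoothed data and their maps are
smoothed after z-transformation instead, to avoid the smoothing kernel
inflating local rank concordance and short-range correlations.  Spatial
smoothing and temporal filtering act on different axes and commute, so
filtering first is equivalent to the smooth-then-filter order.

Every map is z-transformed (mean 0, population SD 1) within the brain mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

__all__ = [
    "Bold4D",
    "DerivativeMap",
    "METRICS",
    "detrend_bandpass",
    "compute_alff",
    "kendall_w",
    "compute_reho",
    "compute_vmhc",
    "compute_dc",
    "smooth_gaussian",
    "ztransform",
    "drop_initial_volumes",
    "derive",
]

METRICS = ("alff", "reho", "vmhc", "dc")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Bold4D:
    """A 4-D BOLD volume, axis order (x, y, z, t)."""

    data: np.ndarray
    tr_seconds: float
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("Bold4D.data must be 4-dimensional (x, y, z, t)")
        if self.data.shape[-1] < 32:
            raise ValueError("Bold4D requires at least 32 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Bold4D.data contains non-finite values")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask shape must match spatial grid")
        if not self.brain_mask.any():
            raise ValueError("brain_mask is empty")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]


@dataclass
class DerivativeMap:
    """A 3-D derivative map with its z-transformed form."""

    kind: str  # "alff" | "reho" | "vmhc" | "dc"
    raw: np.ndarray
    z: np.ndarray
    params: dict = field(default_factory=dict)


def drop_initial_volumes(bold: Bold4D, n: int = 10) -> Bold4D:
    """Discard the first ``n`` volumes (magnetization-equilibration frames)."""
    if bold.n_timepoints - n < 32:
        raise ValueError("too few time points would remain after dropping")
    return Bold4D(
        bold.data[..., n:], bold.tr_seconds, bold.voxel_mm, bold.brain_mask
    )


# --------------------------------------------------------------------------
# temporal preprocessing
# --------------------------------------------------------------------------

def detrend_bandpass(
    ts: np.ndarray, tr: float, band: tuple[float, float] = (0.01, 0.1)
) -> np.ndarray:
    """Remove the linear trend, then apply an ideal FFT band-pass filter.

    Works along the last axis of any array.  Frequency bins with
    ``band[0] <= f <= band[1]`` are kept; everything else (including DC) is
    zeroed, giving effectively infinite stop-band attenuation.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if n < 32:
        raise ValueError("series length must be >= 32")
    low, high = band
    nyquist = 0.5 / tr
    if not (0.0 < low < high):
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if high >= nyquist:
        raise ValueError(
            f"band upper edge {high} Hz is at/above Nyquist {nyquist} Hz"
        )
    de = signal.detrend(ts, axis=-1, type="linear")
    spec = np.fft.rfft(de, axis=-1)
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


# --------------------------------------------------------------------------
# ALFF
# --------------------------------------------------------------------------

def _alff_series(ts: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """ALFF along the last axis: mean in-band sqrt(periodogram PSD).

    The PSD convention is the one-sided raw periodogram
    ``P_k = 2 * tr / n * |X_k|^2`` (no windowing), so ALFF scales linearly
    with signal amplitude.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    inband = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not inband.any():
        raise ValueError(f"no frequency bins inside band {band}")
    spec = np.fft.rfft(ts, axis=-1)
    psd = (2.0 * tr / n) * np.abs(spec[..., inband]) ** 2
    return np.sqrt(psd).mean(axis=-1)


def compute_alff(
    bold: Bold4D, band: tuple[float, float] = (0.01, 0.1)
) -> DerivativeMap:
    """ALFF map from a preprocessed (detrended, filtered) BOLD volume."""
    raw = _alff_series(bold.data, bold.tr_seconds, band)
    raw[~bold.brain_mask] = 0.0
    z = _safe_z(raw, bold.brain_mask)
    return DerivativeMap("alff", raw, z, {"band": band})


# --------------------------------------------------------------------------
# Kendall's W / ReHo
# --------------------------------------------------------------------------

def _tie_term(x: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of a 1-D series."""
    _, counts = np.unique(x, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t ** 3 - t))


def kendall_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance among ``m`` series of length ``n``.

    ``W = 12 S / (m^2 (n^3 - n) - m * sum_i T_i)`` with midranks for ties and
    the standard tie correction ``T_i``.  A constant series (all ranks tied)
    is flagged with a warning; a non-positive denominator yields 0.
    """
    x = np.asarray(series_set, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("series_set must be an (m >= 2, n >= 2) array")
    m, n = x.shape
    if np.any(np.ptp(x, axis=1) == 0):
        warnings.warn("kendall_w: constant series present (all ranks tied)")
    ranks = stats.rankdata(x, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    ties = sum(_tie_term(row) for row in x)
    denom = m * m * (n ** 3 - n) - m * ties
    if denom <= 0:
        warnings.warn("kendall_w: degenerate denominator, returning 0")
        return 0.0
    return 12.0 * s / denom


_CUBE27 = np.ones((3, 3, 3), dtype=float)


def compute_reho(bold: Bold4D, fwhm_mm: float = 6.0) -> DerivativeMap:
    """ReHo map: per-voxel Kendall W over the 27-voxel in-mask neighbourhood.

    Input must be unsmoothed band-passed data.  Order of operations:
    compute raw W -> z-transform within the mask -> Gaussian smoothing of the
    z map (the map, not the input, is smoothed).
    """
    data, mask = bold.data, bold.brain_mask
    n = bold.n_timepoints
    ranks = np.zeros_like(data)
    ranks[mask] = stats.rankdata(data[mask], axis=-1)

    m_map = ndimage.correlate(
        mask.astype(float), _CUBE27, mode="constant", cval=0.0
    )
    m_map[~mask] = 0.0
    # Neighbourhood rank sums per time point (3x3x3x1 box filter).
    rank_nb = ndimage.correlate(
        ranks, _CUBE27[..., None], mode="constant", cval=0.0
    )
    mean_rank = m_map[..., None] * (n + 1) / 2.0
    s = np.sum((rank_nb - mean_rank) ** 2, axis=-1)

    # Tie correction: per-voxel T summed over the neighbourhood.  Ties are
    # measure-zero for continuous signals, so the correction map is only
    # built when ties actually occur.
    tie_map = np.zeros(mask.shape)
    srt = np.sort(data[mask], axis=-1)
    if np.any(srt[:, 1:] == srt[:, :-1]):
        tvals = np.array([_tie_term(row) for row in data[mask]])
        tie_map[mask] = tvals
    tie_nb = ndimage.correlate(tie_map, _CUBE27, mode="constant", cval=0.0)

    denom = m_map ** 2 * (n ** 3 - n) - m_map * tie_nb
    raw = np.zeros(mask.shape)
    ok = mask & (m_map >= 2) & (denom > 0)
    raw[ok] = 12.0 * s[ok] / denom[ok]
    isolated = mask & (m_map < 2)
    if isolated.any():
        warnings.warn(
            f"compute_reho: {int(isolated.sum())} voxel(s) without in-mask "
            "neighbours set to 0"
        )
    raw = np.clip(raw, 0.0, 1.0)
    z = _safe_z(raw, mask)
    z = smooth_gaussian(z, fwhm_mm, bold.voxel_mm)
    return DerivativeMap("reho", raw, z, {"fwhm_mm": fwhm_mm})


# --------------------------------------------------------------------------
# VMHC
# --------------------------------------------------------------------------

def compute_vmhc(bold: Bold4D, fwhm_mm: float = 6.0) -> DerivativeMap:
    """VMHC: Pearson correlation of each voxel with its x-mirror voxel."""
    data, mask = bold.data, bold.brain_mask
    if data.shape[0] % 2 != 0:
        raise ValueError("grid x-dimension must be even for VMHC")
    asym = int(np.sum(mask != np.flip(mask, axis=0)))
    if asym:
        raise ValueError(
            f"brain mask is not mirror-symmetric: {asym} offending voxel(s)"
        )
    centred = data - data.mean(axis=-1, keepdims=True)
    norm = np.sqrt(np.sum(centred ** 2, axis=-1))
    constant = mask & (norm == 0)
    if constant.any():
        warnings.warn(
            f"compute_vmhc: {int(constant.sum())} constant voxel(s) set to 0"
        )
    norm[norm == 0] = 1.0
    unit = centred / norm[..., None]
    raw = np.sum(unit * np.flip(unit, axis=0), axis=-1)
    raw[~mask] = 0.0
    raw = np.clip(raw, -1.0, 1.0)
    z = _safe_z(raw, mask)
    return DerivativeMap("vmhc", raw, z, {"fwhm_mm": fwhm_mm})


# --------------------------------------------------------------------------
# degree centrality
# --------------------------------------------------------------------------

def compute_dc(
    bold: Bold4D, r_threshold: float = 0.25, fwhm_mm: float = 6.0
) -> DerivativeMap:
    """Weighted degree centrality with a positive correlation threshold.

    ``DC(v) = sum_{u != v} r(v, u) * 1[r(v, u) > r_threshold]`` over in-mask
    voxels ("r > 0.25" read one-sided).  Unsmoothed input; z-transform then
    6 mm smoothing of the map, as for ReHo.
    """
    data, mask = bold.data, bold.brain_mask
    series = data[mask]
    if series.shape[0] < 2:
        raise ValueError("degree centrality needs at least 2 in-mask voxels")
    centred = series - series.mean(axis=-1, keepdims=True)
    norm = np.sqrt(np.sum(centred ** 2, axis=-1))
    constant = norm == 0
    if constant.any():
        warnings.warn(
            f"compute_dc: {int(constant.sum())} constant voxel(s) contribute 0"
        )
    norm[constant] = 1.0
    unit = centred / norm[:, None]
    corr = unit @ unit.T
    np.fill_diagonal(corr, 0.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    dc = np.where(corr > r_threshold, corr, 0.0).sum(axis=1)
    raw = np.zeros(mask.shape)
    raw[mask] = dc
    z = _safe_z(raw, mask)
    z = smooth_gaussian(z, fwhm_mm, bold.voxel_mm)
    return DerivativeMap(
        "dc", raw, z, {"r_threshold": r_threshold, "fwhm_mm": fwhm_mm}
    )


# --------------------------------------------------------------------------
# smoothing / z-transform
# --------------------------------------------------------------------------

def smooth_gaussian(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> np.ndarray:
    """Separable Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    Reflective ("mirror") boundary handling; FWHM 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_mm]
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=float), sigma=sigmas, mode="mirror"
    )


def ztransform(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD (population convention) within the mask; 0 outside."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(volume, dtype=float)[mask]
    sd = vals.std()  # divide-by-N
    if sd == 0:
        raise ValueError("ztransform: zero variance within mask")
    out = np.zeros(volume.shape)
    out[mask] = (vals - vals.mean()) / sd
    return out


def _safe_z(raw: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """z-transform, degrading to an all-zero map (with a warning) when the
    raw map is constant within the mask — e.g. a perfectly uniform toy
    volume — so metric computation itself never fails on degenerate input."""
    try:
        return ztransform(raw, mask)
    except ValueError:
        warnings.warn("constant raw map: z map set to 0")
        return np.zeros(raw.shape)


def _smooth4d(
    data: np.ndarray, fwhm_mm: float, voxel_mm: tuple[float, float, float]
) -> np.ndarray:
    if fwhm_mm == 0:
        return data
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_mm] + [0.0]
    return ndimage.gaussian_filter(data, sigma=sigmas, mode="mirror")


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def derive(
    bold: Bold4D,
    kind: str,
    band: tuple[float, float] = (0.01, 0.1),
    fwhm_mm: float = 6.0,
    r_threshold: float = 0.25,
) -> DerivativeMap:
    """Compute one derivative map from raw BOLD, with full preprocessing.

    detrend -> band-pass -> (6 mm smoothing of the input for ALFF/VMHC only)
    -> metric -> z-transform -> (6 mm smoothing of the z map for ReHo/DC).
    """
    if kind not in METRICS:
        raise ValueError(f"unknown metric {kind!r}; expected one of {METRICS}")
    filtered = detrend_bandpass(bold.data, bold.tr_seconds, band)
    if kind in ("alff", "vmhc"):
        filtered = _smooth4d(filtered, fwhm_mm, bold.voxel_mm)
    pp = Bold4D(filtered, bold.tr_seconds, bold.voxel_mm, bold.brain_mask)
    if kind == "alff":
        m = compute_alff(pp, band)
        m.params["fwhm_mm"] = fwhm_mm
        return m
    if kind == "reho":
        return compute_reho(pp, fwhm_mm)
    if kind == "vmhc":
        return compute_vmhc(pp, fwhm_mm)
    return compute_dc(pp, r_threshold, fwhm_mm)
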