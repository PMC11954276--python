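"""Synthetic two-group BOLD cohort generator.

No public dataset exists for the hippocampal-radiomics study design this
package implements, so every downstream stage is exercised on a synthetic
cohort: 4-D BOLD-like volumes on a common grid, a mirrored bilateral
"hippocampus" label mask, and a clinical table with planted effects.

The signal model per voxel is a sum of band-limited (0.01-0.1 Hz) components
plus white noise:

* a *local synchrony* component shared by the whole bilateral ROI (this is
  what regional homogeneity measures, since ROI neighbours share it),
* a *homotopic* component shared only between a voxel and its left-right
  mirror (what voxel-mirrored homotopic connectivity measures),
* independent band-limited background signal outside the ROI.

Group effects are multiplicative attenuations of the shared components in the
cognitively-impaired (CI) group: ``effect_synchrony`` and ``effect_homotopy``
are fractional reductions in [0, 1], so an effect of 0 makes the two groups
exchangeable and an effect of 0.8 leaves CI subjects with 20 % of the shared
amplitude.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "ClinicalRecord",
    "generate_atlas_mask",
    "generate_bold",
    "generate_clinical",
    "generate_cohort",
    "CLINICAL_COLUMNS",
]

BAND_HZ = (0.01, 0.1)

# Streams for fanning the single cohort seed out into independent child
# generators: (stream, subject_index) spawn keys on one SeedSequence.
_STREAM_BOLD = 0
_STREAM_CLINICAL = 1


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the acquisition the pipeline targets: 230 retained
    time points at TR = 2 s on a 3 mm isotropic grid (240 acquired minus the
    10 equilibration volumes that are conventionally discarded).
    """

    n_ci: int
    n_cp: int
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    effect_synchrony: float = 0.0
    effect_homotopy: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ci + self.n_cp < 4:
            raise ValueError("cohort must contain at least 4 subjects")
        if self.grid_shape[0] % 2 != 0:
            raise ValueError("grid x-dimension must be even (mirror plane)")
        for name in ("effect_synchrony", "effect_homotopy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def groups(self) -> list[str]:
        """Group label per subject: CI subjects first, then CP."""
        return ["CI"] * self.n_ci + ["CP"] * self.n_cp

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub-{i + 1:03d}" for i in range(self.n_ci + self.n_cp)]


@dataclass
class ClinicalRecord:
    subject_id: str
    group: str  # "CI" | "CP"
    age: float
    education: float
    duration: float
    bmi: float
    moca: float
    updrs3: float
    nmss: float
    pdq39: float
    hama: float
    hamd: float


CLINICAL_COLUMNS = [
    "subject_id", "group", "age", "education", "duration", "bmi",
    "moca", "updrs3", "nmss", "pdq39", "hama", "hamd",
]


# --------------------------------------------------------------------------
# atlas mask
# --------------------------------------------------------------------------

def generate_atlas_mask(
    grid_shape: tuple[int, int, int],
    blob_radius: int = 2,
    center_yz: tuple[int, int] | None = None,
) -> np.ndarray:
    """Integer label volume with two mirrored spherical blobs.

    Label 1 is the "left hippocampus" (low-x half), label 2 its exact mirror
    across the x mid-plane.  The blobs are discrete balls of the given radius
    (Euclidean, ``||offset|| <= radius``).
    """
    nx, ny, nz = grid_shape
    if nx % 2 != 0:
        raise ValueError("grid x-dimension must be even")
    r = int(blob_radius)
    if r < 0:
        raise ValueError("blob_radius must be non-negative")
    cy, cz = center_yz if center_yz is not None else (ny // 2, nz // 2)
    cx = nx // 2 - 1 - r  # left-half centre, mirror partner at nx - 1 - cx
    if cx - r < 0 or cy - r < 0 or cz - r < 0 or cy + r >= ny or cz + r >= nz:
        raise ValueError(
            f"blob of radius {r} does not fit inside grid {grid_shape}"
        )
    xs, ys, zs = np.ogrid[:nx, :ny, :nz]
    labels = np.zeros(grid_shape, dtype=np.int16)
    left = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= r * r
    labels[left] = 1
    right = np.flip(left, axis=0)
    labels[right] = 2
    return labels


# --------------------------------------------------------------------------
# BOLD signal synthesis
# --------------------------------------------------------------------------

def _band_limited(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_timepoints: int,
    tr: float,
    n_components: int = 6,
) -> np.ndarray:
    """Unit-variance sums of sinusoids with frequencies in the 0.01-0.1 Hz band.

    Returns an array of shape ``shape + (n_timepoints,)`` where each leading
    index carries an independent signal.
    """
    t = np.arange(n_timepoints) * tr
    freqs = rng.uniform(BAND_HZ[0], BAND_HZ[1], size=shape + (n_components,))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape + (n_components,))
    sig = np.cos(
        2.0 * np.pi * freqs[..., None] * t + phases[..., None]
    ).sum(axis=-2)
    sd = sig.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def _subject_rng(spec: CohortSpec, stream: int, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(stream, index))
    return np.random.default_rng(ss)


def generate_bold(
    spec: CohortSpec,
    atlas_mask: np.ndarray,
    group: str,
    subject_index: int,
):
    """One subject's 4-D BOLD-like volume under the planted-effect model.

    Reproducible: the time series depend only on ``spec.seed`` and
    ``subject_index`` (group enters only through the attenuation factors).
    Returns a :class:`hipporad.fmri_derivatives.Bold4D`.
    """
    from .fmri_derivatives import Bold4D  # local import to avoid a cycle

    if spec.n_timepoints < 32:
        raise ValueError(
            f"n_timepoints must be >= 32, got {spec.n_timepoints}"
        )
    if group not in ("CI", "CP"):
        raise ValueError(f"group must be 'CI' or 'CP', got {group!r}")
    if atlas_mask.shape != tuple(spec.grid_shape):
        raise ValueError("atlas mask shape does not match spec.grid_shape")

    rng = _subject_rng(spec, _STREAM_BOLD, subject_index)
    nx = spec.grid_shape[0]
    nt, tr = spec.n_timepoints, spec.tr_seconds
    roi = atlas_mask > 0
    if not np.array_equal(roi, np.flip(roi, axis=0)):
        raise ValueError("atlas mask must be mirror-symmetric along x")

    a_sync = 1.0 - spec.effect_synchrony if group == "CI" else 1.0
    a_hom = 1.0 - spec.effect_homotopy if group == "CI" else 1.0

    data = rng.normal(0.0, spec.noise_sd, size=spec.grid_shape + (nt,))

    # Shared local-synchrony component: one signal for the whole bilateral
    # ROI (mirror-symmetric by construction).
    shared = _band_limited(rng, (), nt, tr)
    data[roi] += a_sync * shared

    # Homotopic component: one independent signal per mirror pair, assigned
    # to a left-half voxel and its x-mirror.
    left = roi.copy()
    left[nx // 2:] = False
    li = np.argwhere(left)
    pair_sigs = _band_limited(rng, (len(li),), nt, tr)
    mi = li.copy()
    mi[:, 0] = nx - 1 - li[:, 0]
    data[li[:, 0], li[:, 1], li[:, 2]] += a_hom * pair_sigs
    data[mi[:, 0], mi[:, 1], mi[:, 2]] += a_hom * pair_sigs

    # Background: independent in-band signal per non-ROI voxel, so the rest
    # of the volume has realistic low-frequency power without any planted
    # spatial correlation structure.
    bg = ~roi
    n_bg = int(bg.sum())
    if n_bg:
        data[bg] += _band_limited(rng, (n_bg,), nt, tr)

    return Bold4D(
        data=data,
        tr_seconds=tr,
        voxel_mm=tuple(spec.voxel_mm),
        brain_mask=np.ones(spec.grid_shape, dtype=bool),
    )


# --------------------------------------------------------------------------
# clinical table
# --------------------------------------------------------------------------

# Per-scale (mean_ci, sd_ci, mean_cp, sd_cp, low, high).  Scales without an
# established group difference share one mean, so any group separation they
# show comes only through the planted-effect correlation channel.
_SCALE_PARAMS: dict[str, tuple[float, float, float, float, float, float]] = {
    "age":       (61.6, 7.6, 56.7, 10.4, 30.0, 90.0),
    "education": (5.5, 2.5, 9.0, 3.0, 0.0, 22.0),
    "duration":  (3.0, 1.9, 3.0, 1.9, 0.2, 30.0),
    "bmi":       (22.4, 2.5, 22.4, 2.5, 13.0, 45.0),
    "updrs3":    (38.4, 13.4, 38.4, 13.4, 0.0, 108.0),
    "nmss":      (50.9, 32.0, 50.9, 32.0, 0.0, 360.0),
    "pdq39":     (43.6, 21.5, 43.6, 21.5, 0.0, 156.0),
    "hama":      (10.6, 6.0, 10.6, 6.0, 0.0, 56.0),
    "hamd":      (9.0, 5.0, 9.0, 5.0, 0.0, 52.0),
}


def injected_effect(spec: CohortSpec, groups: list[str]) -> np.ndarray:
    """Per-subject magnitude of the planted imaging effect.

    CI subjects carry the mean of the two attenuation fractions; CP subjects
    carry 0.  This is the latent quantity clinical scales may correlate with.
    """
    e = 0.5 * (spec.effect_synchrony + spec.effect_homotopy)
    return np.array([e if g == "CI" else 0.0 for g in groups])


def generate_clinical(
    spec: CohortSpec,
    group_assignments: list[str],
    planted_moca_gap: float = 8.0,
    seed: int | None = None,
    clinical_corr: float = 0.3,
) -> list[ClinicalRecord]:
    """Clinical records with a MoCA split and optional effect correlations.

    MoCA is generated below 26 for CI and at/above 26 for CP by construction
    (26 is the conventional impairment cut-off); ``planted_moca_gap`` sets
    how far below the cut-off CI scores range.  Every other scale is drawn
    as ``mu + sd * (rho * z_effect + sqrt(1 - rho^2) * noise)`` where
    ``z_effect`` is the standardized injected imaging effect and
    ``rho = clinical_corr``; with ``clinical_corr = 0`` the scales are pure
    noise around their group means.
    """
    if planted_moca_gap < 0:
        raise ValueError("planted_moca_gap must be >= 0")
    if not -1.0 <= clinical_corr <= 1.0:
        raise ValueError("clinical_corr must lie in [-1, 1]")
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else _subject_rng(spec, _STREAM_CLINICAL, 0)
    )
    groups = list(group_assignments)
    n = len(groups)
    eff = injected_effect(spec, groups)
    if eff.std() > 0:
        z_eff = (eff - eff.mean()) / eff.std()
    else:
        z_eff = np.zeros(n)

    is_ci = np.array([g == "CI" for g in groups])
    moca = np.empty(n)
    # CI strictly below the 26 cut-off, CP in [26, 30].
    u = rng.uniform(0.0, 1.0, size=n)
    moca[is_ci] = 25.5 - planted_moca_gap * u[is_ci]
    moca[~is_ci] = 26.0 + 4.0 * u[~is_ci]
    moca = np.clip(moca, 0.0, 30.0)

    rho = clinical_corr
    scales: dict[str, np.ndarray] = {}
    for name, (mu_ci, sd_ci, mu_cp, sd_cp, lo, hi) in _SCALE_PARAMS.items():
        mu = np.where(is_ci, mu_ci, mu_cp)
        sd = np.where(is_ci, sd_ci, sd_cp)
        noise = rng.standard_normal(n)
        vals = mu + sd * (rho * z_eff + np.sqrt(1.0 - rho * rho) * noise)
        scales[name] = np.clip(vals, lo, hi)

    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    return [
        ClinicalRecord(
            subject_id=ids[i],
            group=groups[i],
            age=float(scales["age"][i]),
            education=float(scales["education"][i]),
            duration=float(scales["duration"][i]),
            bmi=float(scales["bmi"][i]),
            moca=float(moca[i]),
            updrs3=float(scales["updrs3"][i]),
            nmss=float(scales["nmss"][i]),
            pdq39=float(scales["pdq39"][i]),
            hama=float(scales["hama"][i]),
            hamd=float(scales["hamd"][i]),
        )
        for i in range(n)
    ]


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(r, c) for c in CLINICAL_COLUMNS] for r in records],
        columns=CLINICAL_COLUMNS,
    )


def generate_cohort(
    spec: CohortSpec,
    blob_radius: int = 2,
    planted_moca_gap: float = 8.0,
    clinical_corr: float = 0.3,
):
    """Full cohort: atlas mask, per-subject BOLD iterator, clinical table.

    The BOLD volumes are produced lazily (one subject at a time) so that
    large cohorts never hold all 4-D arrays in memory at once.
    Returns ``(atlas_mask, subject_iter, clinical_df)`` where ``subject_iter``
    yields ``(subject_id, group, Bold4D)``.
    """
    mask = generate_atlas_mask(spec.grid_shape, blob_radius)
    records = generate_clinical(
        spec, spec.groups, planted_moca_gap=planted_moca_gap,
        clinical_corr=clinical_corr,
    )

    def _iter():
        for i, (sid, grp) in enumerate(zip(spec.subject_ids, spec.groups)):
            yield sid, grp, generate_bold(spec, mask, grp, i)

    return mask, _iter(), clinical_frame(records)
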