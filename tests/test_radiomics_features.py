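"""Radiomics extraction: roster identities and texture-matrix oracles."""

import itertools

import numpy as np
import pytest
import pywt

from hipporad.radiomics_features import (
    FIRSTORDER_NAMES,
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    OFFSETS_13,
    WAVELET_LABELS,
    DiscretizedRoi,
    RoiImage,
    discretize,
    extract_all,
    firstorder_features,
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
    texture_features,
    wavelet_subbands,
)

ALL_26 = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off != (0, 0, 0)
]


def _in_bounds(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


# ----------------------------------------------------------------------
# brute-force oracles
# ----------------------------------------------------------------------

def _glcm_oracle(lev, ng):
    """Pair enumeration over all 26 directed offsets (= symmetrized 13)."""
    P = np.zeros((ng, ng))
    for pos in np.argwhere(lev > 0):
        for off in ALL_26:
            q = tuple(pos + off)
            if _in_bounds(q, lev.shape) and lev[q] > 0:
                P[lev[tuple(pos)] - 1, lev[q] - 1] += 1
    return P / P.sum() if P.sum() else P


def _glrlm_oracle(lev, ng):
    """Maximal-run scanner walking every line in every direction."""
    runs = {}
    shape = lev.shape
    for off in OFFSETS_13:
        for pos in np.argwhere(lev > 0):
            pos = tuple(pos)
            prev = tuple(np.array(pos) - off)
            if _in_bounds(prev, shape) and lev[prev] == lev[pos]:
                continue  # not a run start
            length = 1
            nxt = tuple(np.array(pos) + off)
            while _in_bounds(nxt, shape) and lev[nxt] == lev[pos]:
                length += 1
                nxt = tuple(np.array(nxt) + off)
            runs[(lev[pos], length)] = runs.get((lev[pos], length), 0) + 1
    max_len = max((l for (_, l) in runs), default=1)
    P = np.zeros((ng, max_len))
    for (g, l), c in runs.items():
        P[g - 1, l - 1] = c
    return P


def _glszm_oracle(lev, ng):
    """Flood fill with 26-connectivity, one zone list per gray level."""
    visited = np.zeros(lev.shape, dtype=bool)
    zones = []
    for pos in map(tuple, np.argwhere(lev > 0)):
        if visited[pos]:
            continue
        g = lev[pos]
        stack, size = [pos], 0
        visited[pos] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in ALL_26:
                q = tuple(np.array(cur) + off)
                if (
                    _in_bounds(q, lev.shape)
                    and not visited[q]
                    and lev[q] == g
                ):
                    visited[q] = True
                    stack.append(q)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def _gldm_oracle(lev, ng, alpha=0):
    """Neighbour-count enumeration; column index = dependence count."""
    deps = {}
    for pos in map(tuple, np.argwhere(lev > 0)):
        k = 0
        for off in ALL_26:
            q = tuple(np.array(pos) + off)
            if (
                _in_bounds(q, lev.shape)
                and lev[q] > 0
                and abs(int(lev[q]) - int(lev[pos])) <= alpha
            ):
                k += 1
        deps[(lev[pos], k)] = deps.get((lev[pos], k), 0) + 1
    max_k = max(k for _, k in deps)
    P = np.zeros((ng, max_k + 1))
    for (g, k), c in deps.items():
        P[g - 1, k] = c
    return P


def _ngtdm_oracle(lev, ng):
    """Neighbourhood-average enumeration of the s_i coarseness sums."""
    s = np.zeros(ng)
    n = np.zeros(ng)
    for pos in map(tuple, np.argwhere(lev > 0)):
        nb = [
            lev[tuple(np.array(pos) + off)]
            for off in ALL_26
            if _in_bounds(tuple(np.array(pos) + off), lev.shape)
            and lev[tuple(np.array(pos) + off)] > 0
        ]
        g = lev[pos]
        n[g - 1] += 1
        if nb:
            s[g - 1] += abs(g - np.mean(nb))
    return n, s


# ----------------------------------------------------------------------
# discretization
# ----------------------------------------------------------------------

class TestDiscretize:
    def test_four_values_four_bins(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0]).reshape(1, 1, 4)
        roi = RoiImage(vals, np.ones_like(vals, dtype=bool))
        d = discretize(roi, 4)
        assert list(d.levels.ravel()) == [1, 2, 3, 4]

    def test_constant_roi_all_level_one(self):
        vals = np.full((2, 2, 2), 5.0)
        roi = RoiImage(vals, np.ones_like(vals, dtype=bool))
        with pytest.warns(UserWarning):
            d = discretize(roi, 8)
        assert np.all(d.levels == 1)

    def test_uniform_sample_matches_histogram_oracle(self, rng):
        vals = rng.uniform(size=(10, 10, 10))
        roi = RoiImage(vals, np.ones_like(vals, dtype=bool))
        d = discretize(roi, 32)
        lo, hi = vals.min(), vals.max()
        width = (hi - lo) / 32
        oracle = np.zeros(32, dtype=int)
        for v in vals.ravel():
            oracle[min(int((v - lo) / width), 31)] += 1
        counts = np.bincount(d.levels.ravel(), minlength=33)[1:]
        assert np.array_equal(counts, oracle)


# ----------------------------------------------------------------------
# wavelet sub-bands
# ----------------------------------------------------------------------

class TestWaveletSubbands:
    def test_labels_and_shapes(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        bands = wavelet_subbands(vol)
        assert set(bands) == set(WAVELET_LABELS) and len(bands) == 8
        assert all(b.shape == vol.shape for b in bands.values())

    def test_highpass_kills_constant(self):
        vol = np.full((8, 8, 8), 4.0)
        bands = wavelet_subbands(vol)
        for label, band in bands.items():
            if "H" in label:
                assert np.allclose(band, 0.0, atol=1e-10)
        # LLL carries the constant scaled by (sum dec_lo)^3 = 2^(3/2)
        assert np.allclose(bands["LLL"], 4.0 * 2.0 ** 1.5, atol=1e-10)

    def test_matches_separable_convolution_oracle(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        wav = pywt.Wavelet("coif1")
        filt = {"L": np.array(wav.dec_lo), "H": np.array(wav.dec_hi)}

        def conv1d(arr, w, axis):
            c = len(w) // 2
            pad = len(w)
            out = np.empty_like(arr)
            arr_m = np.moveaxis(arr, axis, 0)
            out_m = np.moveaxis(out, axis, 0)
            n = arr_m.shape[0]
            padded = np.pad(
                arr_m, [(pad, pad)] + [(0, 0)] * (arr.ndim - 1),
                mode="reflect",
            )
            for i in range(n):
                acc = np.zeros(arr_m.shape[1:])
                for k in range(len(w)):
                    acc += w[k] * padded[pad + i + k - c]
                out_m[i] = acc
            return out

        bands = wavelet_subbands(vol)
        for label in ("LLL", "HLH", "HHH"):
            expected = vol
            for axis, letter in enumerate(label):
                expected = conv1d(expected, filt[letter], axis)
            assert np.allclose(bands[label], expected, atol=1e-8)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            wavelet_subbands(np.zeros((3, 8, 8)))


# ----------------------------------------------------------------------
# first-order
# ----------------------------------------------------------------------

class TestFirstOrder:
    def test_constant_triplet(self):
        with pytest.warns(UserWarning):
            f = firstorder_features(np.array([2.0, 2.0, 2.0]), 1.0)
        assert f["Variance"] == 0.0
        assert f["Range"] == 0.0
        assert f["Mean"] == 2.0
        assert f["Energy"] == 12.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_order_statistics_match_sorting_oracle(self):
        x = np.arange(1.0, 11.0)

        def pct(q):  # linear interpolation between order statistics
            s = np.sort(x)
            h = (len(s) - 1) * q / 100.0
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        f = firstorder_features(x, 1.0)
        assert f["10Percentile"] == pytest.approx(pct(10))
        assert f["Median"] == pytest.approx(pct(50))
        assert f["InterquartileRange"] == pytest.approx(pct(75) - pct(25))

    def test_total_energy_uses_voxel_volume(self):
        x = np.array([1.0, 2.0])
        f = firstorder_features(x, voxel_volume=27.0)
        assert f["TotalEnergy"] == pytest.approx(27.0 * f["Energy"])

    def test_exactly_18_unique_names(self, rng):
        f = firstorder_features(rng.normal(size=50), 1.0)
        assert len(f) == 18
        assert set(f) == set(FIRSTORDER_NAMES)


# ----------------------------------------------------------------------
# texture families vs oracles
# ----------------------------------------------------------------------

class TestGlcm:
    def test_printed_slice_pair_counts(self):
        lev = np.array([[1, 1, 2], [2, 2, 3], [3, 3, 3]]).reshape(3, 3, 1)
        d = DiscretizedRoi(lev, 3)
        assert np.allclose(glcm_matrix(d), _glcm_oracle(lev, 3), atol=1e-12)

    def test_random_roi_matches_pair_enumeration(self, random_levels):
        got = glcm_matrix(random_levels)
        want = _glcm_oracle(random_levels.levels, random_levels.n_levels)
        assert np.allclose(got, want, atol=1e-12)

    def test_matrix_normalized(self, random_levels):
        assert glcm_matrix(random_levels).sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_roi_conventions(self):
        lev = np.ones((3, 3, 3), dtype=int)
        f = glcm_features(DiscretizedRoi(lev, 4))
        assert f["Correlation"] == 1.0
        assert f["Idmn"] == pytest.approx(1.0)

    def test_single_voxel_roi_warns_and_zeroes(self):
        lev = np.zeros((3, 3, 3), dtype=int)
        lev[1, 1, 1] = 2
        with pytest.warns(UserWarning):
            f = glcm_features(DiscretizedRoi(lev, 3))
        assert all(v == 0.0 for v in f.values())

    def test_exactly_22_unique_names(self, random_levels):
        f = glcm_features(random_levels)
        assert len(f) == 22 and set(f) == set(GLCM_NAMES)


class TestGlrlm:
    def test_line_of_four_single_run(self):
        lev = np.ones((4, 1, 1), dtype=int)
        P = glrlm_matrix(DiscretizedRoi(lev, 1))
        assert P[0, 3] == 1  # one run of length 4 along x
        assert P.sum() == 1 + 12 * 4  # plus 4 unit runs in the 12 other dirs

    def test_alternating_levels_unit_runs(self):
        lev = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
        P = glrlm_matrix(DiscretizedRoi(lev, 2))
        assert P.shape[1] == 1  # no run longer than 1 in any direction

    def test_random_roi_matches_run_scanner_oracle(self, random_levels):
        got = glrlm_matrix(random_levels)
        want = _glrlm_oracle(random_levels.levels, random_levels.n_levels)
        assert got.shape == want.shape
        assert np.array_equal(got, want)

    def test_exactly_16_unique_names(self, random_levels):
        f = glrlm_features(random_levels)
        assert len(f) == 16 and set(f) == set(GLRLM_NAMES)


class TestGlszm:
    def test_uniform_roi_single_zone(self):
        lev = np.ones((3, 3, 3), dtype=int)
        P = glszm_matrix(DiscretizedRoi(lev, 1))
        assert P[0, 26] == 1 and P.sum() == 1

    def test_two_separated_blobs_two_zones(self):
        lev = np.full((7, 3, 3), 2, dtype=int)
        lev[0:2] = 1
        lev[5:7] = 1
        P = glszm_matrix(DiscretizedRoi(lev, 2))
        assert P[0].sum() == 2  # level 1 splits into two zones

    def test_random_roi_matches_flood_fill_oracle(self, random_levels):
        got = glszm_matrix(random_levels)
        want = _glszm_oracle(random_levels.levels, random_levels.n_levels)
        assert got.shape == want.shape
        assert np.array_equal(got, want)

    def test_exactly_16_unique_names(self, random_levels):
        f = glszm_features(random_levels)
        assert len(f) == 16 and set(f) == set(GLSZM_NAMES)


class TestNgtdm:
    def test_uniform_roi_sentinel_coarseness(self):
        lev = np.ones((3, 3, 3), dtype=int)
        f = ngtdm_features(DiscretizedRoi(lev, 2))
        assert f["Coarseness"] == 1.0e6

    def test_hand_grid_matches_neighbourhood_oracle(self, rng):
        lev = np.array([[1, 2, 2], [3, 1, 2], [1, 3, 3]]).reshape(3, 3, 1)
        d = DiscretizedRoi(lev, 3)
        n, s = ngtdm_table(d)
        n_o, s_o = _ngtdm_oracle(lev, 3)
        assert np.array_equal(n, n_o)
        assert np.allclose(s, s_o, atol=1e-12)

    def test_random_roi_matches_oracle(self, random_levels):
        n, s = ngtdm_table(random_levels)
        n_o, s_o = _ngtdm_oracle(random_levels.levels, random_levels.n_levels)
        assert np.array_equal(n, n_o)
        assert np.allclose(s, s_o, atol=1e-10)

    def test_exactly_5_names(self, random_levels):
        f = ngtdm_features(random_levels)
        assert len(f) == 5 and set(f) == set(NGTDM_NAMES)


class TestGldm:
    def test_uniform_cube_center_dependence_26(self):
        lev = np.ones((3, 3, 3), dtype=int)
        P = gldm_matrix(DiscretizedRoi(lev, 1))
        assert P[0, 26] == 1  # the centre voxel has all 26 neighbours equal

    def test_isolated_differing_voxel_dependence_zero(self):
        lev = np.ones((3, 3, 3), dtype=int)
        lev[1, 1, 1] = 2
        P = gldm_matrix(DiscretizedRoi(lev, 2))
        assert P[1, 0] == 1  # the odd voxel depends on nobody

    def test_random_roi_matches_neighbour_count_oracle(self, random_levels):
        got = gldm_matrix(random_levels)
        want = _gldm_oracle(random_levels.levels, random_levels.n_levels)
        assert got.shape == want.shape
        assert np.array_equal(got, want)

    def test_alpha_tolerance_widens_dependence(self, random_levels):
        got = gldm_matrix(random_levels, alpha=1)
        want = _gldm_oracle(
            random_levels.levels, random_levels.n_levels, alpha=1
        )
        assert got.shape == want.shape
        assert np.array_equal(got, want)

    def test_exactly_14_unique_names(self, random_levels):
        f = gldm_features(random_levels)
        assert len(f) == 14 and set(f) == set(GLDM_NAMES)


# ----------------------------------------------------------------------
# assembly / roster identities
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def extracted():
    rng = np.random.default_rng(99)
    vals = rng.normal(size=(12, 12, 10))
    mask = np.zeros((12, 12, 10), dtype=bool)
    mask[3:9, 3:9, 3:8] = True
    roi = RoiImage(vals, mask)
    return extract_all(roi)


class TestExtractAll:
    def test_roster_identities(self, extracted):
        assert len(extracted) == 819
        assert len(set(extracted)) == 819
        fams = {"firstorder": 0, "glcm": 0, "glrlm": 0, "glszm": 0,
                "ngtdm": 0, "gldm": 0}
        n_wavelet = 0
        for name in extracted:
            stripped = name
            if name.startswith("wavelet-"):
                n_wavelet += 1
                stripped = name.split("_", 1)[1]
            fams[stripped.split("_", 1)[0]] += 1
        assert n_wavelet == 728
        assert fams["firstorder"] == 18 * 9
        assert sum(fams[f] for f in ("glcm", "glrlm", "glszm", "ngtdm",
                                     "gldm")) == 73 * 9

    @pytest.mark.parametrize(
        "name",
        [
            "wavelet-LLL_firstorder_10Percentile",
            "wavelet-HHL_glcm_Idmn",
            "wavelet-HHH_glszm_GrayLevelNonUniformity",
            "wavelet-HLH_gldm_SmallDependenceLowGrayLevelEmphasis",
            "wavelet-HHH_glrlm_ShortRunHighGrayLevelEmphasis",
            "wavelet-LLL_ngtdm_Coarseness",
            "wavelet-HLL_firstorder_Skewness",
            "firstorder_Kurtosis",
            "glcm_Correlation",
        ],
    )
    def test_expected_feature_names_present(self, extracted, name):
        assert name in extracted

    def test_values_finite(self, extracted):
        assert all(np.isfinite(v) for v in extracted.values())

    def test_too_small_roi_rejected(self, rng):
        vals = rng.normal(size=(8, 8, 8))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, :5] = True
        with pytest.raises(ValueError, match="27"):
            extract_all(RoiImage(vals, mask))

    def test_shift_invariance_of_texture_features(self, rng):
        """Adding a constant shifts bin edges identically, so all texture
        features of the discretized grid are unchanged."""
        vals = rng.normal(size=(6, 6, 6))
        mask = np.ones((6, 6, 6), dtype=bool)
        f1 = texture_features(discretize(RoiImage(vals, mask), 16))
        f2 = texture_features(discretize(RoiImage(vals + 11.3, mask), 16))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k
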