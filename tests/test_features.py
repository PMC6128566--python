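import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dermdecide import features as F
from dermdecide.errors import InvalidInputError

ORTHONORMAL = ["haar", "db4", "sym4", "shannon"]  # dmey taps are truncated


# ---------------------------------------------------------------------------
# single-level transform

@pytest.mark.parametrize("name,atol", [
    ("haar", 1e-10), ("db4", 1e-10), ("sym4", 1e-10), ("shannon", 1e-10),
    ("dmey", 5e-3),  # truncated Meyer taps are only approximately QMF
])
def test_constant_matrix_has_zero_detail(name, atol):
    filt = F.get_filter(name)
    bands = F.dwt_level(np.full((16, 16), 0.7), filt)
    for key in ("LH", "HL", "HH"):
        assert np.allclose(bands.bands()[key], 0.0, atol=atol)
    assert np.allclose(bands.LL, bands.LL.flat[0], atol=atol)  # LL constant


def test_haar_matches_direct_convolution_oracle(rng):
    """Brute-force oracle: periodic correlation with the taps followed by
    stride-2 downsampling, computed with explicit Python loops."""
    filt = F.get_filter("haar")
    x = rng.standard_normal((4, 4))
    a, b = filt.lowpass, filt.highpass

    def corr_rows(mat, taps):
        h, w = mat.shape
        out = np.zeros((h, w // 2))
        for i in range(h):
            for n in range(w // 2):
                out[i, n] = sum(taps[m] * mat[i, (2 * n + m) % w]
                                for m in range(len(taps)))
        return out

    lo = corr_rows(x, a)
    hi = corr_rows(x, b)
    ll = corr_rows(lo.T, a).T
    hl = corr_rows(lo.T, b).T
    lh = corr_rows(hi.T, a).T
    hh = corr_rows(hi.T, b).T

    bands = F.dwt_level(x, filt)
    assert np.allclose(bands.LL, ll, atol=1e-12)
    assert np.allclose(bands.HL, hl, atol=1e-12)
    assert np.allclose(bands.LH, lh, atol=1e-12)
    assert np.allclose(bands.HH, hh, atol=1e-12)


@pytest.mark.parametrize("name", ORTHONORMAL)
def test_energy_conservation_per_level(name, rng):
    filt = F.get_filter(name)
    x = rng.standard_normal((32, 32))
    bands = F.dwt_level(x, filt)
    e_in = np.sum(x ** 2)
    e_out = sum(np.sum(v ** 2) for v in bands.bands().values())
    assert abs(e_in - e_out) <= 1e-9 * e_in


@pytest.mark.parametrize("name", ORTHONORMAL)
def test_perfect_reconstruction(name, rng):
    filt = F.get_filter(name)
    x = rng.standard_normal((16, 24))
    rec = F.idwt_level(F.dwt_level(x, filt), filt)
    assert np.allclose(rec, x, atol=1e-8)


def test_odd_dimension_rejected():
    with pytest.raises(InvalidInputError):
        F.dwt_level(np.zeros((15, 16)), F.get_filter("haar"))


# ---------------------------------------------------------------------------
# multilevel

def test_multilevel_shapes_halve(rng):
    pyr = F.multilevel_decompose(rng.random((64, 64)), F.get_filter("haar"), 4)
    assert [lev.LL.shape for lev in pyr] == [(32, 32), (16, 16), (8, 8), (4, 4)]


def test_multilevel_too_deep_rejected(rng):
    with pytest.raises(InvalidInputError):
        F.multilevel_decompose(rng.random((16, 16)), F.get_filter("haar"), 5)


@pytest.mark.parametrize("name", ORTHONORMAL)
def test_multilevel_roundtrip(name, rng):
    filt = F.get_filter(name)
    x = rng.standard_normal((32, 32))
    pyr = F.multilevel_decompose(x, filt, 3)
    assert np.allclose(F.multilevel_reconstruct(pyr, filt), x, atol=1e-8)


def test_quarterband_cosine_lands_in_predicted_band():
    """A 2-D cosine at 3/16 cycles/px lies below the half-band at level 1
    (so it survives into LL) and above it after decimation, so its energy
    must concentrate in the level-2 HH band under the ideal Shannon split."""
    n = 64
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    x = np.cos(2 * np.pi * 3 * i / 16) * np.cos(2 * np.pi * 3 * j / 16)
    pyr = F.multilevel_decompose(x, F.get_filter("shannon"), 2)
    total = np.sum(x ** 2)
    assert np.sum(pyr[1].HH ** 2) / total > 0.99


def test_literal_normalisation_scales_but_does_not_reshape():
    """The printed (factor-2, shifted-index) convention scales level-1
    coefficients by 2; shape statistics such as skewness are unchanged."""
    rng = np.random.default_rng(3)
    x = rng.random((32, 32))
    filt = F.get_filter("haar")
    ortho = F.dwt_level(x, filt)
    literal = F.dwt_level(x, filt, literal_normalisation=True)
    for key in ("LL", "LH", "HL", "HH"):
        s_o = F.subband_statistics(ortho.bands()[key])
        s_l = F.subband_statistics(literal.bands()[key])
        assert np.isclose(s_l[0], 2 * s_o[0])    # mean scales by 2
        assert np.isclose(s_l[2], 4 * s_o[2])    # energy scales by 4
        assert np.isclose(s_l[4], s_o[4], atol=1e-9)  # mean row skew invariant
        assert np.isclose(s_l[8], s_o[8], atol=1e-9)  # mean row kurt invariant


# ---------------------------------------------------------------------------
# statistics

def test_constant_band_statistics():
    s = F.subband_statistics(np.full((4, 4), -0.3))
    expected = np.array([-0.3, 0.3, 0.09, 0.0] + [0.0] * 8)
    assert np.allclose(s, expected, atol=1e-15)


def test_alternating_band_statistics_hand_computed():
    """band = [[1,-1],[-1,1]]: every row/column is a symmetric two-point
    set, so skewness is 0 and raw kurtosis is m4/m2^2 = 1."""
    s = F.subband_statistics(np.array([[1.0, -1.0], [-1.0, 1.0]]))
    expected = np.array([0, 1, 1, 1, 0, 0, 0, 0, 1, 0, 1, 0], dtype=float)
    assert np.allclose(s, expected, atol=1e-14)


def test_axis_moments_match_scipy_oracle(rng):
    band = rng.standard_normal((8, 8))
    s = F.subband_statistics(band)
    row_skew = stats.skew(band, axis=1, bias=True)
    row_kurt = stats.kurtosis(band, axis=1, bias=True, fisher=False)
    col_skew = stats.skew(band, axis=0, bias=True)
    col_kurt = stats.kurtosis(band, axis=0, bias=True, fisher=False)
    assert np.isclose(s[4], row_skew.mean())
    assert np.isclose(s[5], row_skew.var())
    assert np.isclose(s[6], col_skew.mean())
    assert np.isclose(s[7], col_skew.var())
    assert np.isclose(s[8], row_kurt.mean())
    assert np.isclose(s[9], row_kurt.var())
    assert np.isclose(s[10], col_kurt.mean())
    assert np.isclose(s[11], col_kurt.var())


def test_empty_or_tiny_band_rejected():
    with pytest.raises(InvalidInputError):
        F.subband_statistics(np.zeros((1, 5)))


@given(shift=st.floats(-2, 2), scale=st.floats(0.1, 5))
def test_statistics_under_affine_maps(shift, scale):
    """mean is affine-equivariant, variance scales quadratically, and the
    axis shape statistics are invariant to positive affine maps."""
    rng = np.random.default_rng(99)
    band = rng.standard_normal((6, 6))
    s0 = F.subband_statistics(band)
    s1 = F.subband_statistics(scale * band + shift)
    assert np.isclose(s1[0], scale * s0[0] + shift, atol=1e-9)
    assert np.isclose(s1[3], scale ** 2 * s0[3], rtol=1e-9)
    assert np.allclose(s1[4:8], s0[4:8], atol=1e-7)   # skewness block
    assert np.allclose(s1[8:12], s0[8:12], atol=1e-7)  # kurtosis block


# ---------------------------------------------------------------------------
# full feature vector

def test_feature_vector_cardinality_and_determinism(rng):
    img = rng.random((128, 128, 3))
    v1 = F.extract_features(img, "shannon")
    v2 = F.extract_features(img, "shannon")
    assert v1.shape == (F.N_FEATURES,) == (1152,)
    assert np.array_equal(v1, v2)  # bit-identical
    assert np.all(np.isfinite(v1))


def test_all_black_image_all_zero_features():
    v = F.extract_features(np.zeros((128, 128, 3)), "haar")
    assert np.allclose(v, 0.0, atol=1e-12)


def test_channel_permutation_permutes_schema(rng):
    img = rng.random((128, 128, 3))
    swapped = img[..., ::-1].copy()  # R <-> B
    v = F.extract_features(img, "haar")
    w = F.extract_features(swapped, "haar")
    names = F.feature_schema()
    idx = {n: i for i, n in enumerate(names)}
    for n in names:
        if "_R_" in n:
            assert np.isclose(w[idx[n]], v[idx[n.replace("_R_", "_B_")]])
        elif "_B_" in n:
            assert np.isclose(w[idx[n]], v[idx[n.replace("_B_", "_R_")]])
    # luminance weights differ for R and B, so luma features must change
    luma = [idx[n] for n in names if "_Luma_" in n]
    assert not np.allclose(v[luma], w[luma])


def test_schema_is_a_bijection():
    names = F.feature_schema()
    assert len(names) == 1152 == len(set(names))


def test_wrong_shape_rejected():
    with pytest.raises(InvalidInputError):
        F.extract_features(np.zeros((128, 128)), "haar")
    with pytest.raises(InvalidInputError):
        F.get_filter("nonexistent")
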