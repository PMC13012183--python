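import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import midline_of
from mesowin import InsufficientFramesError, ParamError
from mesowin import synthetic_data as sd
from mesowin.connectivity import (
    ConnectivityMap,
    MidlineAxis,
    bandpass_movie,
    build_pair_map,
    connectivity_index,
    csd_block_analysis,
    detrend_movie,
    downsample_movie,
    frame_bookkeeping,
    global_signal_regression,
    homotopic_map,
    mirror_pixel,
    preprocess_movie,
)


# ---------------------------------------------------------------------------
# preprocessing stages
# ---------------------------------------------------------------------------

def test_downsample_block_mean_and_mean_conservation(rng):
    movie = rng.random((5, 512, 512)) * 255
    small = downsample_movie(movie, (128, 128))
    assert small.shape == (5, 128, 128)
    np.testing.assert_allclose(small.mean(axis=(1, 2)), movie.mean(axis=(1, 2)),
                               rtol=1e-12)
    checker = np.zeros((1, 4, 4))
    checker[0, ::2, ::2] = 255
    checker[0, 1::2, 1::2] = 255
    np.testing.assert_allclose(downsample_movie(checker, (1, 1)), 127.5)
    const = np.full((3, 8, 8), 42.0)
    np.testing.assert_allclose(downsample_movie(const, (2, 2)), 42.0)
    with pytest.raises(ParamError):
        downsample_movie(movie, (100, 100))


def test_detrend_removes_exact_ramp_and_keeps_sinusoid():
    n = 300
    t = np.arange(n, dtype=float)
    ramp = (3.0 + 0.25 * t)[:, None, None] * np.ones((1, 4, 4))
    np.testing.assert_allclose(detrend_movie(ramp), 0.0, atol=1e-9)

    sine = np.sin(2 * np.pi * 7 * t / n)
    series = sine + 1.5 + 0.01 * t
    movie = series[:, None, None] * np.ones((1, 2, 2))
    resid = detrend_movie(movie)
    slope, intercept = np.polyfit(t, series, 1)    # direct least-squares oracle
    expected = series - (intercept + slope * t)
    assert np.abs(resid[:, 0, 0] - expected).max() < 1e-6
    assert np.abs(detrend_movie(movie).mean(axis=0)).max() < 1e-9
    with pytest.raises(ParamError):
        detrend_movie(np.zeros((2, 2, 2)))


def test_bandpass_keeps_in_band_and_rejects_out_of_band():
    n, fs = 1800, 3.0
    t = np.arange(n) / fs
    inband = np.sin(2 * np.pi * 0.055 * t)[:, None, None]
    out = bandpass_movie(inband, fs)
    assert np.abs(out[400:1400, 0, 0]).max() >= 0.9

    fast = np.sin(2 * np.pi * 0.5 * t)[:, None, None]
    assert np.abs(bandpass_movie(fast, fs)[400:1400, 0, 0]).max() <= 0.1

    dc = np.full((n, 1, 1), 11.0)
    assert np.abs(bandpass_movie(dc, fs)).max() < 1e-3

    with pytest.raises(ParamError):
        bandpass_movie(inband, fs, low=0.5, high=2.0)


def test_gsr_residuals_orthogonal_to_global_signal(rng):
    n = 400
    g = np.cumsum(rng.standard_normal(n))
    movie = np.empty((n, 4, 4))
    movie[:] = g[:, None, None]
    movie += 0.3 * rng.standard_normal((n, 4, 4))
    resid = global_signal_regression(movie)
    gc = movie.mean(axis=(1, 2)) - movie.mean()
    corr = np.abs(resid.reshape(n, -1).T @ (gc - gc.mean()))
    assert corr.max() < 1e-8 * n              # orthogonality up to float error

    pure = np.repeat(g, 9).reshape(n, 3, 3)
    assert np.abs(global_signal_regression(pure)).max() < 1e-9


def test_pipeline_order_is_fixed():
    """The chain applies downsample, detrend, bandpass, GSR in that order;
    flags can only disable stages."""
    rng = np.random.default_rng(0)
    movie = rng.random((300, 8, 8))
    full, _, _ = preprocess_movie(movie, 3.0)
    manual = global_signal_regression(
        bandpass_movie(detrend_movie(movie), 3.0))
    np.testing.assert_allclose(full, manual, atol=1e-12)


# ---------------------------------------------------------------------------
# mirror geometry
# ---------------------------------------------------------------------------

def test_mirror_pixel_examples():
    mid = MidlineAxis(bregma=(0, 64), lambda_pt=(100, 64))
    assert mirror_pixel((10, 60), mid) == (10, 68)
    assert mirror_pixel((37, 64), mid) == (37, 64)   # on the line


@settings(deadline=None, max_examples=50, derandomize=True)
@given(r=st.integers(0, 63), c=st.integers(0, 63),
       br=st.integers(0, 63), bc=st.integers(0, 63),
       lr=st.integers(0, 63), lc=st.integers(0, 63))
def test_mirror_is_involution_up_to_rounding(r, c, br, bc, lr, lc):
    if (br, bc) == (lr, lc):
        return
    mid = MidlineAxis(bregma=(br, bc), lambda_pt=(lr, lc))
    m = mirror_pixel((r, c), mid)
    back = mirror_pixel(m, mid)
    assert abs(back[0] - r) <= 1 and abs(back[1] - c) <= 1


def test_mirror_outside_image_returns_none():
    mid = MidlineAxis(bregma=(0, 2), lambda_pt=(10, 2))
    assert mirror_pixel((5, 9), mid, shape=(11, 8)) is None


def test_pair_map_symmetric_and_excludes_midline(vertical_midline):
    idx, partner = build_pair_map((24, 24), vertical_midline)
    pairs = set(zip(idx.tolist(), partner.tolist()))
    assert all((b, a) in pairs for a, b in pairs)
    from mesowin.connectivity import hemisphere_sides
    side = hemisphere_sides((24, 24), vertical_midline).ravel()
    assert (side[idx] != 0).all()


# ---------------------------------------------------------------------------
# homotopic correlation
# ---------------------------------------------------------------------------

def test_perfect_mirror_movie_gives_clipped_unit_correlation(rng,
                                                             vertical_midline):
    n = 64
    half = rng.random((n, 24, 12))
    movie = np.concatenate([half, half[:, :, ::-1]], axis=2)
    cmap = homotopic_map(movie, vertical_midline)
    assert cmap.paired_mask.all()
    np.testing.assert_allclose(cmap.r_map[cmap.paired_mask], 1.0, atol=1e-9)
    np.testing.assert_allclose(cmap.z_map[cmap.paired_mask],
                               np.arctanh(1 - 1e-7), atol=1e-4)


def test_white_noise_hemispheres_average_near_zero(rng, vertical_midline):
    movie = rng.standard_normal((1800, 24, 24))
    idx = connectivity_index(homotopic_map(movie, vertical_midline))
    assert abs(idx.value) < 3.0 / np.sqrt(1800 - 3)


def test_zero_variance_pixels_dropped(vertical_midline):
    rng = np.random.default_rng(1)
    movie = rng.random((100, 24, 24))
    movie[:, 5, 3] = 7.0                      # constant pixel
    cmap = homotopic_map(movie, vertical_midline)
    assert not cmap.paired_mask[5, 3]
    assert not cmap.paired_mask[5, 20]        # its mirror also unusable


def test_z_map_symmetric_under_hemisphere_swap(rng, vertical_midline):
    movie = rng.random((200, 24, 24))
    cmap = homotopic_map(movie, vertical_midline)
    z = cmap.z_map
    np.testing.assert_allclose(z[:, :12], z[:, ::-1][:, :12], atol=1e-12)


def test_connectivity_index_is_plain_mean():
    z = np.full((4, 4), np.nan)
    z[0, :2] = [0.2, 0.8]
    z[1, :2] = [0.5, 0.5]
    mask = np.isfinite(z)
    cmap = ConnectivityMap(r_map=np.tanh(z), z_map=z, paired_mask=mask)
    assert connectivity_index(cmap).value == pytest.approx(0.5)
    with pytest.raises(ParamError):
        connectivity_index(ConnectivityMap(z * np.nan, z * np.nan,
                                           np.zeros((4, 4), bool)))


def test_recovered_index_matches_atanh_rho():
    p = sd.BilateralSimParams(n_frames=1800, shape=(24, 24), rho=0.6, seed=42)
    movie, truth = sd.gen_bilateral_movie(p)
    cmap = homotopic_map(movie.frames.astype(float), midline_of(truth))
    assert connectivity_index(cmap).value == pytest.approx(np.arctanh(0.6),
                                                           abs=0.1)


def test_gsr_removes_global_component_bias():
    common = dict(n_frames=1800, shape=(16, 16), rho=0.5, seed=77)
    clean, t1 = sd.gen_bilateral_movie(sd.BilateralSimParams(**common))
    dirty, t2 = sd.gen_bilateral_movie(
        sd.BilateralSimParams(global_amp=0.8, **common))
    mid = midline_of(t1)

    def idx(movie):
        pre, _, _ = preprocess_movie(movie.frames.astype(float), 3.0)
        return connectivity_index(homotopic_map(pre, mid)).value

    assert idx(dirty) == pytest.approx(idx(clean), abs=0.1)


# ---------------------------------------------------------------------------
# block analysis and frame bookkeeping
# ---------------------------------------------------------------------------

def test_frame_bookkeeping_of_standard_recording():
    info = frame_bookkeeping(total_minutes=32.7, fps=3.0, discard_frames=500,
                             block_minutes=10.0, n_blocks=3)
    assert info["total_frames"] == 5886
    assert info["discard_minutes"] == 2.8
    assert info["remaining_frames"] == 5386
    assert info["block_len"] == 1800
    assert info["block_frames"] == [1800, 1800, 1786]
    assert info["short_blocks"] == [2]
    assert info["analyzed_minutes"] == 30.0


def test_block_analysis_flags_short_final_block(vertical_midline):
    rng = np.random.default_rng(3)
    from mesowin.io_config import ImageStack
    n = 500 + 3 * 360 - 20                    # 2-min blocks, last one short
    movie = ImageStack(
        frames=rng.integers(0, 255, size=(n, 24, 24)).astype(np.uint8),
        frame_rate_hz=3.0)
    res = csd_block_analysis(movie, vertical_midline, fps=3.0,
                             discard_frames=500, block_minutes=2.0)
    labels = [r.block_label for r in res]
    assert labels == ["block1", "block2", "block3"]
    assert [r.short for r in res] == [False, False, True]
    assert res[2].n_frames == 340

    with pytest.raises(InsufficientFramesError):
        csd_block_analysis(movie, vertical_midline, fps=3.0,
                           discard_frames=500, block_minutes=10.0)


def test_csd_movie_transiently_lowers_index(vertical_midline):
    p = sd.BilateralSimParams(n_frames=2300, shape=(24, 24), rho=0.6,
                              noise_sd=0.2, seed=8)
    csd = sd.CSDParams(origin=(6, 4), onset_frame=50, recovery_frames=1200)
    movie, truth = sd.gen_csd_movie(p, csd)
    baseline, _ = sd.gen_bilateral_movie(
        sd.BilateralSimParams(n_frames=900, shape=(24, 24), rho=0.6,
                              noise_sd=0.2, seed=9))
    res = csd_block_analysis(movie, midline_of(truth), fps=3.0,
                             discard_frames=500, block_minutes=5.0,
                             n_blocks=2, baseline_movie=baseline)
    by = {r.block_label: r.value for r in res}
    assert by["block1"] < by["baseline"] - 0.15
    assert by["block2"] == pytest.approx(by["baseline"], abs=0.2)
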