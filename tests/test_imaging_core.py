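import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluoroquant import (
    BinaryMask,
    ConfigurationError,
    DegenerateImageError,
    EmptyPlantError,
    FvFmMap,
    ImagePair,
    ParameterizationError,
    RawImage,
    compute_fvfm_map,
    render_pseudocolor,
    segment_plant,
    summarize_fvfm,
)


def make_pair(fm, fo, bit_depth=8, **meta):
    return ImagePair(
        fo=RawImage(np.asarray(fo), bit_depth=bit_depth, channel="Fo"),
        fm=RawImage(np.asarray(fm), bit_depth=bit_depth, channel="Fm"),
        **meta,
    )


def full_mask(shape):
    return BinaryMask(np.ones(shape, dtype=bool))


def brute_force_otsu(pixels: np.ndarray, bit_depth: int = 8) -> int:
    """Independent oracle: sweep every threshold, maximize between-class variance."""
    best_t, best_var = 0, -1.0
    flat = pixels.ravel().astype(float)
    for t in range(0, 2 ** bit_depth - 1):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestRawImageValidation:
    def test_intensity_range_enforced(self):
        with pytest.raises(ParameterizationError):
            RawImage(np.array([[0, 300]]), bit_depth=8)

    def test_bad_bit_depth(self):
        with pytest.raises(ParameterizationError):
            RawImage(np.zeros((2, 2), dtype=np.uint8), bit_depth=12)

    def test_shape_mismatch_in_pair(self):
        with pytest.raises(ParameterizationError):
            make_pair(np.zeros((2, 2), dtype=np.uint8), np.zeros((3, 3), dtype=np.uint8))


class TestSegmentPlant:
    def test_fixed_threshold_two_level(self):
        px = np.where(np.arange(100).reshape(10, 10) < 50, 10, 200).astype(np.uint8)
        mask = segment_plant(RawImage(px, bit_depth=8), method="fixed", threshold=100)
        assert np.array_equal(mask.pixels, px == 200)
        assert mask.threshold == 100

    def test_fixed_low_threshold_all_foreground(self):
        px = np.where(np.arange(100).reshape(10, 10) < 50, 10, 200).astype(np.uint8)
        mask = segment_plant(RawImage(px, bit_depth=8), method="fixed", threshold=5)
        assert mask.pixels.all()

    def test_otsu_matches_brute_force_oracle_on_bimodal(self):
        rng = np.random.default_rng(3)
        n = 64 * 64
        lo = rng.normal(20, 5, n // 2)
        hi = rng.normal(180, 5, n - n // 2)
        px = np.clip(np.rint(np.concatenate([lo, hi])), 0, 255).astype(np.uint8)
        rng.shuffle(px)
        px = px.reshape(64, 64)
        img = RawImage(px, bit_depth=8)
        otsu_mask = segment_plant(img, method="otsu")
        oracle_t = brute_force_otsu(px)
        fixed_mask = px > oracle_t
        agreement = np.mean(otsu_mask.pixels == fixed_mask)
        assert agreement >= 0.99
        # and ≥99% agreement with a plain fixed-100 split of the two modes
        assert np.mean(otsu_mask.pixels == (px > 100)) >= 0.99

    def test_blank_image_otsu_raises(self):
        with pytest.raises(DegenerateImageError):
            segment_plant(RawImage(np.full((8, 8), 7, dtype=np.uint8), bit_depth=8))

    def test_fixed_requires_threshold(self):
        img = RawImage(np.zeros((4, 4), dtype=np.uint8), bit_depth=8)
        with pytest.raises(ConfigurationError):
            segment_plant(img, method="fixed")

    def test_unknown_method(self):
        img = RawImage(np.zeros((4, 4), dtype=np.uint8), bit_depth=8)
        with pytest.raises(ConfigurationError):
            segment_plant(img, method="watershed")

    def test_mask_idempotence_on_binary_image(self):
        rng = np.random.default_rng(0)
        binary = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        img = RawImage(binary, bit_depth=8)
        mask = segment_plant(img, method="fixed", threshold=0)
        assert np.array_equal(mask.pixels, binary.astype(bool))


class TestComputeFvFm:
    def test_pointwise_values(self):
        pair = make_pair(fm=[[200, 100, 0]], fo=[[40, 100, 0]])
        fvfm = compute_fvfm_map(pair, full_mask((1, 3)))
        assert fvfm.values[0, 0] == pytest.approx(0.8)
        assert fvfm.values[0, 1] == 0.0
        assert not fvfm.valid[0, 2]  # Fm <= eps -> invalid
        assert fvfm.valid[0, 0] and fvfm.valid[0, 1]

    def test_clipping_negative_fv(self):
        pair = make_pair(fm=[[100]], fo=[[120]])
        fvfm = compute_fvfm_map(pair, full_mask((1, 1)))
        assert fvfm.values[0, 0] == 0.0
        assert fvfm.clipped_fraction == 1.0

    def test_background_invalid(self):
        pair = make_pair(fm=[[200, 200]], fo=[[40, 40]])
        mask = BinaryMask(np.array([[True, False]]))
        fvfm = compute_fvfm_map(pair, mask)
        assert fvfm.valid.tolist() == [[True, False]]
        assert fvfm.values[0, 1] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scalar_loop_oracle_bitwise(self, seed):
        rng = np.random.default_rng(seed)
        fm = rng.integers(0, 256, (12, 13)).astype(np.uint8)
        fo = rng.integers(0, 256, (12, 13)).astype(np.uint8)
        mask = BinaryMask(rng.random((12, 13)) > 0.3)
        fvfm = compute_fvfm_map(make_pair(fm, fo), mask, eps=1.0)
        for i in range(12):
            for j in range(13):
                if mask.pixels[i, j] and float(fm[i, j]) > 1.0:
                    expect = (float(fm[i, j]) - float(fo[i, j])) / float(fm[i, j])
                    expect = min(1.0, max(0.0, expect))
                    assert fvfm.values[i, j] == expect  # bit-for-bit
                    assert fvfm.valid[i, j]
                else:
                    assert not fvfm.valid[i, j]
                    assert fvfm.values[i, j] == 0.0

    @given(fm=st.integers(2, 255), fo=st.integers(0, 255), delta=st.integers(1, 50))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_fo(self, fm, fo, delta):
        fo = min(fo, 255)
        fo_lower = max(0, fo - delta)
        pair_hi = make_pair([[fm]], [[fo]])
        pair_lo = make_pair([[fm]], [[fo_lower]])
        m = full_mask((1, 1))
        v_hi = compute_fvfm_map(pair_hi, m).values[0, 0]
        v_lo = compute_fvfm_map(pair_lo, m).values[0, 0]
        assert v_lo >= v_hi

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        fm = rng.integers(2, 120, (10, 10)).astype(np.uint16)
        fo = (fm * rng.random((10, 10))).astype(np.uint16)
        m = full_mask((10, 10))
        base = compute_fvfm_map(make_pair(fm, fo, bit_depth=16), m, eps=0.5)
        scaled = compute_fvfm_map(make_pair(fm * 4, fo * 4, bit_depth=16), m, eps=0.5)
        assert np.array_equal(base.values, scaled.values)


class TestSummarize:
    def make_map(self, values, valid=None):
        values = np.asarray(values, dtype=float)
        valid = np.ones_like(values, dtype=bool) if valid is None else valid
        return FvFmMap(values=values, valid=valid)

    def test_uniform_map(self):
        s = summarize_fvfm(self.make_map(np.full((5, 5), 0.75)))
        assert s.bin_edges[int(np.argmax(s.counts))] <= 0.75 < s.bin_edges[int(np.argmax(s.counts)) + 1]
        assert s.mean == pytest.approx(0.75)
        assert s.n_valid == 25

    def test_majority_bin_wins(self):
        vals = np.concatenate([np.full(90, 0.80), np.full(10, 0.40)]).reshape(10, 10)
        s = summarize_fvfm(self.make_map(vals))
        assert 0.80 <= s.mode < 0.81

    def test_health_rule_against_group_means(self):
        healthy = summarize_fvfm(self.make_map(np.full((4, 4), 0.802)))
        stressed = summarize_fvfm(self.make_map(np.full((4, 4), 0.749)))
        assert healthy.health == "healthy"
        assert stressed.health == "stressed"
        assert healthy.mode >= 0.79 > stressed.mode

    def test_tie_breaks_to_lower_bin(self):
        vals = np.array([[0.105, 0.905]])
        s = summarize_fvfm(self.make_map(vals))
        assert s.mode == pytest.approx(0.105)
        assert s.mode_tied

    def test_mean_within_min_max(self, rng):
        vals = rng.random((20, 20))
        s = summarize_fvfm(self.make_map(vals))
        assert vals.min() <= s.mean <= vals.max()

    def test_mode_close_to_dense_mode_on_smooth_field(self, rng):
        vals = np.clip(rng.normal(0.63, 0.05, (200, 200)), 0, 1)
        s = summarize_fvfm(self.make_map(vals), bin_width=0.01)
        assert abs(s.mode - 0.63) <= 0.01 + 0.005

    def test_empty_map_raises(self):
        with pytest.raises(EmptyPlantError):
            summarize_fvfm(self.make_map(np.zeros((3, 3)), valid=np.zeros((3, 3), bool)))

    @pytest.mark.parametrize("bw", [0.0, -0.01, 0.2])
    def test_bad_bin_width(self, bw):
        with pytest.raises(ConfigurationError):
            summarize_fvfm(self.make_map(np.full((2, 2), 0.5)), bin_width=bw)


class TestRender:
    def make_map(self):
        vals = np.array([[0.0, 0.5], [1.0, 0.0]])
        valid = np.array([[True, True], [True, False]])
        return FvFmMap(values=vals, valid=valid)

    def test_deterministic(self):
        m = self.make_map()
        assert np.array_equal(render_pseudocolor(m), render_pseudocolor(m))

    def test_range_contract(self):
        from matplotlib import colormaps

        rgb = render_pseudocolor(self.make_map(), colormap_name="jet")
        cmap = colormaps["jet"]
        top = (np.asarray(cmap(1.0)[:3]) * 255).round().astype(np.uint8)
        bottom = (np.asarray(cmap(0.0)[:3]) * 255).round().astype(np.uint8)
        assert np.array_equal(rgb[1, 0], top)
        assert np.array_equal(rgb[0, 0], bottom)

    def test_background_reserved_color(self):
        from matplotlib import colormaps

        rgb = render_pseudocolor(self.make_map(), colormap_name="jet")
        assert np.array_equal(rgb[1, 1], [0, 0, 0])
        # the reserved color is outside the colormap's range
        table = (colormaps["jet"](np.linspace(0, 1, 256))[:, :3] * 255).round()
        assert not (table == np.zeros(3)).all(axis=1).any()

    def test_unknown_colormap(self):
        with pytest.raises(ConfigurationError):
            render_pseudocolor(self.make_map(), colormap_name="not-a-colormap")
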