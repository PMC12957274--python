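"""Dual-stream CNN extractor: shape arithmetic, symmetry, feature modes."""

import math

import numpy as np
import pytest

from kansleep.extractor import (
    ConvBranch,
    ConvBranchSpec,
    DEFAULT_BANDS,
    ExtractorParams,
    alt_features,
    branch_forward,
    extract_features,
    frequency_branch_spec,
    load_features,
    save_features,
    temporal_branch_spec,
)
from kansleep.io import zscore_epoch


def _simulate_lengths(spec: ConvBranchSpec, ts: int) -> int:
    """Independent step-by-step length simulator: same convs, valid pools."""
    n = ts
    order = [("conv", 0), ("pool", 0), ("conv", 1), ("conv", 2), ("conv", 3),
             ("pool", 1)]
    for kind, i in order:
        if kind == "conv":
            n = math.ceil(n / spec.stride_sizes[i])
        else:
            n = (n - spec.pool_kernels[i]) // spec.pool_strides[i] + 1
        if n < 1:
            raise ValueError("empty")
    return n * spec.channel_sizes[-1]


class TestShapeArithmetic:
    def test_temporal_branch_lengths(self):
        spec = temporal_branch_spec()
        # 3000 -> 500 -> 31 -> 31 -> 31 -> 31 -> 3; 64 x 3 = 192
        assert spec.output_length(3000) == 3
        assert spec.output_features(3000) == 192

    def test_frequency_branch_lengths(self):
        spec = frequency_branch_spec()
        # 3000 -> 60 -> 7 -> 7 -> 7 -> 7 -> 1; 64 x 1 = 64
        assert spec.output_length(3000) == 1
        assert spec.output_features(3000) == 64

    def test_forward_shape_matches_closed_form(self, rng):
        ex = ExtractorParams(seed=0)
        out = branch_forward(rng.standard_normal(3000), ex.temporal)
        assert out.shape == (192,)
        out = branch_forward(rng.standard_normal(3000), ex.frequency)
        assert out.shape == (64,)

    def test_random_specs_match_simulator(self, rng):
        checked = 0
        while checked < 50:
            spec = ConvBranchSpec(
                channel_sizes=[int(rng.integers(1, 5)) for _ in range(4)],
                kernel_sizes=[int(rng.integers(2, 12)) for _ in range(4)],
                stride_sizes=[int(rng.integers(1, 5))] + [1, 1, 1],
                pool_kernels=[int(rng.integers(2, 6)) for _ in range(2)],
                pool_strides=[int(rng.integers(2, 6)) for _ in range(2)],
                dropout_rate=0.0,
            )
            ts = int(rng.integers(100, 400))
            try:
                expected = _simulate_lengths(spec, ts)
            except ValueError:
                continue
            branch = ConvBranch(spec, rng)
            out = branch.forward(rng.standard_normal((1, 1, ts)).astype(np.float32))
            assert out.shape == (1, expected)
            assert spec.output_features(ts) == expected
            checked += 1

    def test_empty_layer_rejected(self, rng):
        spec = ConvBranchSpec([2, 2, 2, 2], [3, 3, 3, 3], [4, 1, 1, 1],
                              [8, 8], [8, 8], 0.0)
        branch = ConvBranch(spec, rng)
        with pytest.raises(ValueError):
            branch.forward(rng.standard_normal((1, 1, 64)).astype(np.float32))


class TestExtractFeatures:
    def test_zero_input_zero_features(self):
        ex = ExtractorParams(seed=0)  # biases start at zero
        feats = extract_features(np.zeros((2, 3000)), ex)
        np.testing.assert_array_equal(feats, 0.0)

    def test_per_channel_width(self):
        ex = ExtractorParams(seed=0)
        assert ex.features_per_channel(3000) == 256
        feats = extract_features(np.random.default_rng(0).standard_normal((1, 3000)),
                                 ex)
        assert feats.shape == (256,)

    def test_ten_channel_kan_input_width(self, rng):
        ex = ExtractorParams(seed=0)
        feats = extract_features(rng.standard_normal((10, 3000)), ex)
        assert feats.shape == (2560,)

    def test_channel_permutation_permutes_blocks(self, rng):
        ex = ExtractorParams(seed=0)
        epoch = rng.standard_normal((3, 3000))
        feats = extract_features(epoch, ex)
        swapped = extract_features(epoch[[1, 0, 2]], ex)
        np.testing.assert_array_equal(swapped[:256], feats[256:512])
        np.testing.assert_array_equal(swapped[256:512], feats[:256])
        np.testing.assert_array_equal(swapped[512:], feats[512:])

    def test_inference_determinism(self, rng):
        ex = ExtractorParams(seed=0)
        epoch = rng.standard_normal((2, 3000))
        np.testing.assert_array_equal(extract_features(epoch, ex),
                                      extract_features(epoch, ex))

    def test_dropout_only_when_training(self, rng):
        ex = ExtractorParams(seed=0)
        epoch = rng.standard_normal((1, 3000)).astype(np.float32)
        a = ex.forward_batch(epoch[None], training=True)
        b = ex.forward_batch(epoch[None], training=True)
        assert not np.array_equal(a, b)  # dropout masks differ

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros(3000), ExtractorParams(seed=0))


class TestAltFeatures:
    def test_de_closed_form_full_band(self, rng):
        x = rng.standard_normal(3000)
        x = (x - x.mean()) / x.std()
        de = alt_features(x[None], "DE", band_plan=[(0.0, 50.0)], fs=100.0)
        assert de[0] == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=1e-6)

    def test_statistic_mode_on_zscored(self, rng):
        epoch = zscore_epoch(rng.standard_normal((1, 3000)) * 40 + 3)
        stats = alt_features(epoch, "statistic")
        assert stats.shape == (6,)
        assert stats[0] == pytest.approx(0.0, abs=1e-9)  # mean
        assert stats[1] == pytest.approx(1.0, abs=1e-6)  # variance

    def test_stft_alpha_peak_for_alpha_sine(self):
        t = np.arange(3000) / 100.0
        x = np.sin(2 * np.pi * 10.0 * t)
        lp = alt_features(x[None], "STFT", fs=100.0)
        assert lp.shape == (len(DEFAULT_BANDS),)
        assert np.argmax(lp) == 2  # alpha band 8-13 Hz

    def test_empty_band_plan_rejected(self):
        with pytest.raises(ValueError):
            alt_features(np.zeros((1, 100)), "DE", band_plan=[])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            alt_features(np.zeros((1, 100)), "wavelets")


class TestFeaturePersistence:
    def test_round_trip(self, tmp_path, rng):
        feats = rng.standard_normal((7, 12))
        labels = rng.integers(0, 5, 7)
        path = tmp_path / "feats.tsv"
        save_features(path, feats, labels)
        back_f, back_l = load_features(path)
        np.testing.assert_allclose(back_f, feats, rtol=1e-4, atol=1e-5)
        np.testing.assert_array_equal(back_l, labels)
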