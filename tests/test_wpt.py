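"""Wavelet packet decomposition, frequency ordering and band features."""

import numpy as np
import pytest
import pywt

from vims_eeg.recording import Epoch
from vims_eeg.wpt import (DEFAULT_BANDS, BandSpec, FeatureScaler,
                          WaveletFilterPair, extract_features,
                          frequency_to_natural_order,
                          natural_to_frequency_order, node_centre_hz,
                          reconstruct_band, reconstruct_bands, stream_names,
                          wpt_decompose, wpt_reconstruct)

FS = 500.0


def _tone(freq, n=5000, fs=FS, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestDecomposition:
    def test_matches_reference_wavelet_packet_implementation(self, rng):
        x = rng.normal(size=512)
        tree = wpt_decompose(x, 4, "db4", fs=FS)
        wp = pywt.WaveletPacket(x, "db4", mode="periodization", maxlevel=4)
        paths = [n.path for n in wp.get_level(4, order="natural")]
        for i, path in enumerate(paths):
            assert np.max(np.abs(tree.leaf(i) - wp[path].data)) < 1e-10

    @pytest.mark.parametrize("level", [1, 3, 5, 8])
    def test_parseval_energy_conservation(self, level, rng):
        x = rng.normal(size=512)
        tree = wpt_decompose(x, level, "db4")
        energy = sum(np.sum(tree.leaf(i) ** 2) for i in range(2 ** level))
        assert energy == pytest.approx(np.sum(x ** 2), rel=1e-8)

    def test_zero_signal_gives_zero_tree(self):
        tree = wpt_decompose(np.zeros(256), 5, "db4")
        assert all(np.all(tree.leaf(i) == 0) for i in range(32))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            wpt_decompose(np.zeros(100), 8)

    def test_node_count_and_length(self, rng):
        tree = wpt_decompose(rng.normal(size=512), 3)
        assert tree.n_leaves == 8
        assert all(tree.leaf(i).size == 64 for i in range(8))


class TestReconstruction:
    def test_perfect_reconstruction_identity(self, rng):
        x = rng.normal(size=512)
        assert np.max(np.abs(wpt_reconstruct(wpt_decompose(x, 6)) - x)) < 1e-8

    def test_perfect_reconstruction_with_padding(self, rng):
        x = rng.normal(size=5000)  # not a multiple of 2**8
        assert np.max(np.abs(wpt_reconstruct(wpt_decompose(x, 8)) - x)) < 1e-8

    def test_band_partition_sums_to_original(self, rng):
        """The four rhythm bands plus the complement reconstruct the signal."""
        x = rng.normal(size=2048)
        tree = wpt_decompose(x, 6, "db4", fs=FS)
        recs = reconstruct_bands(tree, DEFAULT_BANDS)
        selected = set()
        for band in DEFAULT_BANDS:
            for r in range(64):
                if band.contains(node_centre_hz(6, r, FS)):
                    selected.add(frequency_to_natural_order(6, r))
        rest = wpt_reconstruct(tree, set(range(64)) - selected)
        total = rest + sum(recs.values())
        assert np.max(np.abs(total - x)) < 1e-8

    def test_all_zero_tree_reconstructs_to_zero(self):
        tree = wpt_decompose(np.zeros(512), 4)
        assert np.all(wpt_reconstruct(tree, {0, 3}) == 0)

    def test_empty_band_selection_raises(self, rng):
        tree = wpt_decompose(rng.normal(size=512), 2, fs=FS)  # nodes 62.5 Hz wide
        with pytest.raises(ValueError, match="selects no node"):
            reconstruct_band(tree, BandSpec("delta", 0.5, 4.0))

    def test_alpha_tone_band_energy_split(self):
        """A 10 Hz tone concentrates in the alpha reconstruction.

        db4's node-level leakage at depth 8 caps the alpha share near
        0.81 (measured); delta stays below 5%.
        """
        tone = _tone(10.0)
        tree = wpt_decompose(tone, 8, "db4", fs=FS)
        recs = reconstruct_bands(tree)
        total = np.sum(tone ** 2)
        shares = {k: np.sum(v ** 2) / total for k, v in recs.items()}
        assert shares["alpha"] > 0.80
        assert shares["alpha"] == max(shares.values())
        assert shares["delta"] < 0.05


class TestFrequencyOrdering:
    def test_level_one_and_two(self):
        assert [natural_to_frequency_order(1, i) for i in range(2)] == [0, 1]
        assert [natural_to_frequency_order(2, i) for i in range(4)] == [0, 1, 3, 2]

    @pytest.mark.parametrize("level", range(1, 7))
    def test_mapping_is_a_permutation(self, level):
        ranks = sorted(natural_to_frequency_order(level, i)
                       for i in range(2 ** level))
        assert ranks == list(range(2 ** level))

    @pytest.mark.parametrize("level", range(1, 7))
    def test_against_tone_sweep_oracle(self, level):
        """Drive a tone at each node's passband centre; the node with the
        largest coefficient energy must be the mapped natural index."""
        n = 4096
        for rank in range(2 ** level):
            tone = _tone(node_centre_hz(level, rank, FS), n=n)
            tree = wpt_decompose(tone, level, "db4", fs=FS)
            energies = [np.sum(tree.leaf(i) ** 2) for i in range(2 ** level)]
            assert int(np.argmax(energies)) == frequency_to_natural_order(level, rank)

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            natural_to_frequency_order(3, 8)
        with pytest.raises(IndexError):
            frequency_to_natural_order(3, -1)


class TestFeatures:
    def _epoch(self, data):
        names = [f"ch{i}" for i in range(data.shape[0])]
        return Epoch(data, FS, names)

    def test_zero_epoch_gives_zero_frames(self):
        frames = extract_features(self._epoch(np.zeros((8, 5000))))
        assert frames.shape == (100, 40)
        assert np.all(frames == 0)

    def test_frame_shape_10s_at_10fps(self, rng):
        frames = extract_features(self._epoch(rng.normal(size=(8, 5000))))
        assert frames.shape == (100, 40)

    def test_alpha_energy_dominates_alpha_streams(self):
        data = np.stack([_tone(10.0, phase=0.3 * i) for i in range(8)])
        frames = extract_features(self._epoch(data))
        names = stream_names([f"ch{i}" for i in range(8)])
        var = frames.var(axis=0) + frames.mean(axis=0) ** 2  # mean power
        for ch in range(8):
            by_band = {names[ch * 5 + j].split("_")[1]: var[ch * 5 + j]
                       for j in range(1, 5)}
            assert by_band["alpha"] > 5 * by_band["delta"]
            assert by_band["alpha"] > 3 * by_band["theta"]
            assert by_band["alpha"] > 3 * by_band["beta"]

    def test_translation_preserves_stream_energy(self):
        """Shifting a pure tone moves frames but keeps per-stream energy."""
        a = np.tile(_tone(10.0), (8, 1))
        b = np.tile(_tone(10.0, phase=2 * np.pi * 10 * 0.25), (8, 1))
        fa = extract_features(self._epoch(a))
        fb = extract_features(self._epoch(b))
        ea, eb = (fa ** 2).sum(axis=0), (fb ** 2).sum(axis=0)
        active = ea > 1e-9
        assert np.all(np.abs(ea - eb)[active] / ea[active] < 0.02)

    def test_incompatible_frame_rate_rejected(self):
        with pytest.raises(ValueError, match="frames_per_second"):
            extract_features(self._epoch(np.zeros((8, 5000))),
                             frames_per_second=3.0)

    def test_scaler_standardizes_training_set(self, rng):
        feats = [rng.normal(loc=2.0, size=(100, 40)) for _ in range(5)]
        sc = FeatureScaler().fit(feats)
        z = np.concatenate([sc.transform(f) for f in feats])
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1, atol=1e-6)


def test_filter_pair_orthogonality():
    f = WaveletFilterPair.from_name("db4")
    h = f.dec_lo
    for m in range(4):
        expected = 1.0 if m == 0 else 0.0
        assert np.dot(h[2 * m:], h[:len(h) - 2 * m]) == pytest.approx(expected, abs=1e-12)
    # g is the quadrature mirror of h (alternating-sign reversal)
    assert np.allclose(f.dec_hi, [(-1) ** (k + 1) * h[len(h) - 1 - k]
                                  for k in range(len(h))])
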