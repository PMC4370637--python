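import numpy as np
import pandas as pd
import pytest

from emopso.features import (
    FAMILY_SIZES,
    FeatureConfig,
    FeatureTable,
    extract_all,
    extract_stream,
    family_of,
    feature_names,
    frame_signal,
    gtfb24,
    lpcc18,
    mfcc24,
    plp13,
    rwpf60,
    rwpf_frame,
    swt_ttf144,
    timbral_sequence,
    ttf24,
    ttf_stats,
)
from emopso.glottal import estimate_glottal
from emopso.preprocess import preprocess_audio


@pytest.fixture(scope="module")
def voiced(noisy_vowel):
    audio, _ = noisy_vowel
    return preprocess_audio(audio).samples


def _tone(freq, n=4096, rate=8000.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / rate)


class TestFraming:
    def test_frame_count_formula(self):
        fs = frame_signal(np.zeros(512), 256, 128, "rect")
        assert fs.frames.shape == (3, 256)

    def test_rect_taper_is_identity(self):
        x = np.arange(512.0)
        fs = frame_signal(x, 256, 256, "rect")
        np.testing.assert_array_equal(fs.frames[0], x[:256])

    def test_hamming_endpoints(self):
        fs = frame_signal(np.ones(256), 256, 128, "hamming")
        assert fs.frames[0, 0] == pytest.approx(0.08, abs=0.001)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            frame_signal(np.zeros(100), 256, 128)


class TestCepstralFamilies:
    def test_output_sizes(self, voiced):
        assert len(mfcc24(voiced)) == 24
        assert len(lpcc18(voiced)) == 18
        assert len(gtfb24(voiced)) == 24
        assert len(plp13(voiced)) == 13

    def test_determinism(self, voiced):
        for fn in (mfcc24, lpcc18, plp13):
            np.testing.assert_array_equal(fn(voiced), fn(voiced))

    def test_mfcc_scaling_touches_only_c0(self, voiced):
        """Doubling the signal adds a constant in the log-mel domain, which
        the orthonormal DCT routes entirely into coefficient 0."""
        a = mfcc24(voiced)
        b = mfcc24(2.0 * voiced)
        assert abs(b[0] - a[0]) > 1e-3
        np.testing.assert_allclose(a[1:], b[1:], atol=1e-6)

    def test_gtfb_tone_peaks_at_matching_channel(self):
        from emopso.features import erb_space

        fcs = erb_space(50.0, 3999.0, 24)
        ch = 12
        out = gtfb24(_tone(fcs[ch]))
        assert np.argmax(out) == ch

    def test_gtfb_silence_hits_log_floor(self):
        out = gtfb24(np.zeros(2048))
        np.testing.assert_allclose(out, -10.0, atol=1e-9)

    def test_plp_distinguishes_tone_from_noise(self):
        noise = np.random.default_rng(0).standard_normal(4096)
        assert np.linalg.norm(plp13(_tone(1000)) - plp13(noise)) > 0


class TestTimbral:
    def test_centroid_of_pure_tone(self):
        fs = frame_signal(_tone(1000.0), 256, 128, "rect")
        series = timbral_sequence(fs)
        bin_width = 8000 / 256
        assert np.all(np.abs(series["centroid"] - 1000.0) <= bin_width)

    def test_zcr_constant_for_stationary_tone(self):
        fs = frame_signal(_tone(500.0), 256, 128, "rect")
        zcr = timbral_sequence(fs)["zcr"]
        assert zcr.std() < 0.01

    def test_silence_has_zero_energy_series(self):
        fs = frame_signal(np.zeros(1024), 256, 128, "rect")
        np.testing.assert_array_equal(timbral_sequence(fs)["energy"], 0.0)

    def test_single_frame_rejected(self):
        fs = frame_signal(np.zeros(256), 256, 128, "rect")
        with pytest.raises(ValueError):
            timbral_sequence(fs)

    def test_stats_hand_example(self):
        np.testing.assert_allclose(ttf_stats(np.array([1.0, 2.0, 3.0])), [1, 3, 1.5, 0.25])

    def test_stats_constant_series(self):
        out = ttf_stats(np.full(5, 4.0))
        np.testing.assert_allclose(out, [0.0, 0.0, 1.0, 0.0])

    def test_ttf_block_size(self, voiced):
        assert len(ttf24(voiced)) == 24


class TestWaveletFamilies:
    def test_swt_ttf_size_and_determinism(self, voiced):
        a = swt_ttf144(voiced)
        assert len(a) == 144
        np.testing.assert_array_equal(a, swt_ttf144(voiced))

    def test_rwpf_size(self, voiced):
        assert len(rwpf60(voiced)) == 60

    def test_rwpf_relative_values_sum_to_one_per_frame(self, voiced):
        frames = frame_signal(voiced, 256, 128, "rect").frames
        checked = 0
        for frame in frames[:10]:
            res = rwpf_frame(frame)
            if res is None:
                continue
            rel_e, rel_p = res
            assert rel_e.sum() == pytest.approx(1.0, abs=1e-9)
            assert rel_p.sum() == pytest.approx(1.0, abs=1e-9)
            checked += 1
        assert checked > 0

    def test_rwpf_energy_reading_switch(self, voiced):
        printed = rwpf60(voiced, FeatureConfig(rwpf_energy="as-printed"))
        alt = rwpf60(voiced, FeatureConfig(rwpf_energy="energy"))
        assert np.linalg.norm(printed[:30] - alt[:30]) > 0


class TestAssembly:
    def test_full_vector_bookkeeping(self, noisy_vowel):
        audio, _ = noisy_vowel
        voiced = preprocess_audio(audio)
        flow = estimate_glottal(voiced)
        fv = extract_all(voiced, flow)
        assert len(fv.values) == 614
        assert np.all(np.isfinite(fv.values))
        names = feature_names()
        assert fv.names == tuple(names)
        assert len(set(names)) == 614
        speech = [n for n in names if n.startswith("speech.")]
        assert len(speech) == 307
        for fam, size in FAMILY_SIZES.items():
            assert sum(family_of(n) == fam for n in speech) == size

    def test_not_order_invariant(self, voiced):
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(voiced)
        a = extract_stream(voiced)
        b = extract_stream(shuffled)
        assert np.linalg.norm(a - b) > 0


class TestFeatureTable:
    def test_csv_round_trip(self, tmp_path, small_table):
        path = tmp_path / "t.csv"
        small_table.to_csv(path)
        back = FeatureTable.from_csv(path)
        np.testing.assert_allclose(back.X, small_table.X, rtol=1e-11)
        assert list(back.labels) == list(small_table.labels)
        assert list(back.speakers) == list(small_table.speakers)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError):
            FeatureTable(df, pd.Series(["x", "y"]), pd.Series(["s", "s"]))
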