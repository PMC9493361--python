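"""EEG features: band filters, wICA correction, AM extraction."""

import numpy as np
import pytest

from neurocpm import CohortSpec, Recording
from neurocpm.core import DecompositionError, ParameterError
from neurocpm.eeg import (BANDS, ModulationPair, WicaParams,
                          amplitude_modulation, bandpass_broadband,
                          valid_modulation_pairs, wica_clean)
from neurocpm.synth import inject_artifacts, synthesize_eeg

FS = 500.0


def tone(freq, fs=FS, dur=30.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t), t


class TestModulationPairs:
    def test_enumeration(self):
        pairs = valid_modulation_pairs()
        names = [p.name for p in pairs]
        assert len(pairs) == 14
        assert "beta_m_alpha" in names and "gamma_m_alpha" in names
        assert "alpha_m_alpha" not in names
        # beta-m-beta and gamma-m-gamma are admitted despite the exclusion of
        # alpha-m-alpha: the set is an enumeration, not a bandwidth formula
        assert "beta_m_beta" in names and "gamma_m_gamma" in names

    def test_stable_order(self):
        assert [p.name for p in valid_modulation_pairs()] == \
            [p.name for p in valid_modulation_pairs()]
        assert valid_modulation_pairs()[0].name == "delta_m_delta"


class TestBroadbandFilter:
    def test_passband_preserves_50hz(self):
        x, _ = tone(50.0)
        rec = Recording(x[np.newaxis], FS)
        out = bandpass_broadband(rec).data[0]
        core = slice(int(5 * FS), int(25 * FS))
        ratio = np.std(out[core]) / np.std(x[core])
        assert abs(ratio - 1.0) < 0.05

    def test_slow_drift_attenuated(self):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 0.01 * t)
        out = bandpass_broadband(Recording(x[np.newaxis], FS)).data[0]
        core = slice(int(50 * FS), int(250 * FS))
        assert np.std(out[core]) < 0.1 * np.std(x[core])

    def test_zero_in_zero_out(self):
        out = bandpass_broadband(Recording(np.zeros((2, 5000)), FS))
        assert np.allclose(out.data, 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ParameterError, match="200"):
            bandpass_broadband(Recording(np.zeros((1, 1000)), 150.0))


class TestAmplitudeModulation:
    def test_recovers_known_alpha_modulator(self):
        """Carrier 20 Hz with amplitude 1 + 0.5 cos(2 pi 10 t): beta-m-alpha
        recovers the 10 Hz modulator waveform away from the edges."""
        _, t = tone(20.0)
        mod = 0.5 * np.cos(2 * np.pi * 10.0 * t)
        x = (1 + mod) * np.cos(2 * np.pi * 20.0 * t)
        am = amplitude_modulation(Recording(x[np.newaxis], FS), "beta_m_alpha",
                                  edge_trim_s=2.0)
        core = am.trimmed[0]
        ref = mod[int(2 * FS):len(mod) - int(2 * FS)]
        assert np.corrcoef(core, ref)[0, 1] > 0.95

    def test_band_selectivity_of_carrier(self):
        """A 40 Hz carrier with 10 Hz AM appears in gamma-m-alpha but not in
        beta-m-alpha."""
        _, t = tone(40.0)
        mod = 0.5 * np.cos(2 * np.pi * 10.0 * t)
        x = (1 + mod) * np.cos(2 * np.pi * 40.0 * t)
        rec = Recording(x[np.newaxis], FS)
        am_g = amplitude_modulation(rec, "gamma_m_alpha", edge_trim_s=2.0)
        am_b = amplitude_modulation(rec, "beta_m_alpha", edge_trim_s=2.0)
        ref = mod[int(2 * FS):len(mod) - int(2 * FS)]
        assert np.corrcoef(am_g.trimmed[0], ref)[0, 1] > 0.95
        assert np.std(am_b.trimmed[0]) < 0.05 * np.std(am_g.trimmed[0])

    def test_unmodulated_carrier_gives_empty_modulation_band(self):
        x, t = tone(20.0)
        am = amplitude_modulation(Recording(x[np.newaxis], FS), "beta_m_alpha",
                                  edge_trim_s=2.0)
        mod = 0.5 * np.cos(2 * np.pi * 10.0 * t)
        am_ref = amplitude_modulation(
            Recording(((1 + mod) * x)[np.newaxis], FS), "beta_m_alpha",
            edge_trim_s=2.0)
        assert np.std(am.trimmed) < 0.02 * np.std(am_ref.trimmed)

    def test_invalid_pair_rejected(self):
        x, _ = tone(10.0, dur=5.0)
        bad = ModulationPair(BANDS["alpha"], BANDS["alpha"])
        with pytest.raises(ParameterError, match="valid_modulation_pairs"):
            amplitude_modulation(Recording(x[np.newaxis], FS), bad)

    def test_channel_permutation_equivariance(self, rng):
        x = rng.standard_normal((4, 8000))
        rec = Recording(x, FS)
        perm = [2, 0, 3, 1]
        out = amplitude_modulation(rec, "beta_m_alpha").values
        out_p = amplitude_modulation(Recording(x[perm], FS),
                                     "beta_m_alpha").values
        assert np.allclose(out[perm], out_p)

    def test_amplitude_scale_covariance(self, rng):
        x = rng.standard_normal((2, 8000))
        a = amplitude_modulation(Recording(x, FS), "gamma_m_alpha").values
        b = amplitude_modulation(Recording(2.5 * x, FS), "gamma_m_alpha").values
        assert np.allclose(2.5 * a, b, rtol=1e-8, atol=1e-10)
        assert np.all(np.isfinite(b))


class TestWica:
    @pytest.fixture(scope="class")
    def clean_eeg(self):
        # full 5-minute record: the wavelet universal threshold (and hence
        # how conservatively wICA treats clean data) scales with record length
        spec = CohortSpec(n_subjects=3, duration_s=300.0, seed=21)
        latent = {m: np.eye(8) for m in ("beta_m_alpha", "gamma_m_alpha")}
        rec = synthesize_eeg(latent, spec, np.random.default_rng(8))
        return bandpass_broadband(rec)

    def test_artifact_free_signal_preserved(self, clean_eeg):
        out = wica_clean(clean_eeg)
        assert out.data.shape == clean_eeg.data.shape
        for i in range(clean_eeg.n_channels):
            r = np.corrcoef(clean_eeg.data[i], out.data[i])[0, 1]
            assert r >= 0.95, f"channel {i}: r={r:.3f}"

    def test_transients_reduced(self, clean_eeg):
        dirty = inject_artifacts(clean_eeg, np.random.default_rng(9))
        cleaned = wica_clean(dirty)
        rmse_dirty = np.sqrt(np.mean((dirty.data - clean_eeg.data) ** 2))
        rmse_clean = np.sqrt(np.mean((cleaned.data - clean_eeg.data) ** 2))
        assert rmse_clean < rmse_dirty

    def test_infinite_thresholds_round_trip(self, clean_eeg):
        params = WicaParams(cleaning_tolerance=np.inf,
                            ic_artifact_threshold=np.inf)
        out = wica_clean(clean_eeg, params)
        scale = np.max(np.abs(clean_eeg.data))
        assert np.max(np.abs(out.data - clean_eeg.data)) / scale < 1e-6

    def test_rank_deficient_input_rejected(self, rng):
        x = rng.standard_normal((3, 2000))
        x[2] = x[0]  # duplicated channel
        with pytest.raises(DecompositionError, match="rank"):
            wica_clean(Recording(x, FS))

    def test_preconditions(self, rng):
        with pytest.raises(ParameterError, match="channels"):
            wica_clean(Recording(rng.standard_normal((1, 100)), FS))
        with pytest.raises(ParameterError, match="samples"):
            wica_clean(Recording(rng.standard_normal((5, 4)), FS))
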