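"""Generator ground truth: determinism, planted effects, signal structure."""

import numpy as np
import pytest

from neurocpm import CohortSpec, MODALITIES, generate_cohort, sample_cohort_table
from neurocpm.core import ParameterError
from neurocpm.eeg import amplitude_modulation, bandpass_broadband
from neurocpm.nirs import fnirs_bandpass, mbll, split_wavelengths
from neurocpm.synth import _latent_cohort, inject_artifacts, synthesize_eeg


def test_seeded_determinism(tiny_cohort):
    spec, subjects, gt = tiny_cohort
    again, gt2 = generate_cohort(CohortSpec(**{
        f: getattr(spec, f) for f in ("n_subjects", "duration_s", "seed")}))
    for a, b in zip(subjects, again):
        assert np.array_equal(a.eeg.data, b.eeg.data)
        assert np.array_equal(a.fnirs.data, b.fnirs.data)
        assert a.performance == b.performance
    assert np.array_equal(gt.performance, gt2.performance)


@pytest.mark.parametrize("kw, field", [
    ({"n_subjects": 2}, "n_subjects"),
    ({"duration_s": 0}, "duration_s"),
    ({"effect_r": 1.5}, "effect_r"),
    ({"noise_sd": -1}, "noise_sd"),
    ({"predictive_edges": (("hbo", 0, 99),)}, "predictive_edges"),
    ({"predictive_edges": (("bogus", 0, 1),)}, "predictive_edges"),
    ({"eeg_fs": 60.0}, "eeg_fs"),
])
def test_invalid_spec_names_offending_field(kw, field):
    with pytest.raises(ParameterError, match=field):
        CohortSpec(**kw)


def test_recording_shapes_and_bounds(tiny_cohort):
    spec, subjects, gt = tiny_cohort
    for sub in subjects:
        assert sub.eeg.data.shape == (8, round(spec.duration_s * spec.eeg_fs))
        assert sub.fnirs.data.shape == (
            50, round(spec.duration_s * spec.fnirs_fs))
        assert 0.0 <= sub.performance <= 100.0
    for mod in MODALITIES:
        mats = gt.latent_connectivity[mod]
        assert np.allclose(mats, np.transpose(mats, (0, 2, 1)))
        assert np.allclose(mats[:, range(mats.shape[1]), range(mats.shape[1])],
                           1.0)
    for w in gt.planted_edge_targets.values():
        assert np.all((w > 0) & (w < 1))


def test_planted_effect_converges_to_effect_r():
    """At n = 200, the latent weight / performance correlation of every
    planted edge sits within +/-0.05 of the requested effect_r."""
    spec = CohortSpec(n_subjects=200, effect_r=0.8, seed=31)
    rng = np.random.default_rng(np.random.SeedSequence(31).spawn(1)[0])
    perf, gt = _latent_cohort(spec, rng)
    for w in gt.planted_edge_targets.values():
        r = np.corrcoef(w, perf)[0, 1]
        assert abs(r - 0.8) < 0.05


def test_null_planted_effect_matches_monte_carlo_oracle():
    """With effect_r = 0 the edge-weight / performance correlation follows
    the null sampling distribution of r at the cohort size (oracle: direct
    simulation of independent normal pairs)."""
    n, reps = 40, 200
    obs = []
    for s in range(reps):
        spec = CohortSpec(n_subjects=n, effect_r=0.0, seed=9000 + s)
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
        perf, gt = _latent_cohort(spec, rng)
        for w in gt.planted_edge_targets.values():
            obs.append(abs(np.corrcoef(w, perf)[0, 1]))
    oracle_rng = np.random.default_rng(123)
    null = [abs(np.corrcoef(oracle_rng.standard_normal(n),
                            oracle_rng.standard_normal(n))[0, 1])
            for _ in range(2000)]
    assert abs(np.mean(obs) - np.mean(null)) < 0.03


def test_recovery_averaged_over_replicates():
    """effect_r = 0.8, n = 60: each planted edge's empirical weight-vs-
    performance r, averaged over 50 replicate cohorts, lands within
    +/-0.15 of 0.8."""
    per_edge: dict = {}
    for s in range(50):
        spec = CohortSpec(n_subjects=60, effect_r=0.8, seed=4000 + s)
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
        perf, gt = _latent_cohort(spec, rng)
        for key, w in gt.planted_edge_targets.items():
            per_edge.setdefault(key, []).append(np.corrcoef(w, perf)[0, 1])
    for key, vals in per_edge.items():
        assert abs(np.mean(vals) - 0.8) < 0.15, key


def _latent_with_edge(w, mods=("beta_m_alpha", "gamma_m_alpha"), edge=(0, 1)):
    latent = {m: np.eye(8) for m in mods}
    for m in latent:
        latent[m][edge[0], edge[1]] = latent[m][edge[1], edge[0]] = w
    return latent


def test_shared_modulator_gives_high_am_correlation():
    """Planted weight 1.0, no noise: the beta-m-alpha AM series of the two
    channels are nearly identical (shared modulator)."""
    spec = CohortSpec(n_subjects=3, noise_sd=0.0, seed=7)
    rec = bandpass_broadband(
        synthesize_eeg(_latent_with_edge(1.0), spec, np.random.default_rng(1)))
    for pair in ("beta_m_alpha", "gamma_m_alpha"):
        am = amplitude_modulation(rec, pair)
        r = np.corrcoef(am.trimmed[0], am.trimmed[1])[0, 1]
        assert r > 0.99, pair
        # unplanted pair: independent modulators stay near zero over 300 s
        r0 = np.corrcoef(am.trimmed[2], am.trimmed[3])[0, 1]
        assert abs(r0) < 0.2, pair


def test_fnirs_planted_pair_and_anticorrelation():
    spec = CohortSpec(n_subjects=3, noise_sd=0.0, seed=7, hbo_hbr_rho=0.8,
                      fnirs_channels=6,
                      predictive_edges=(("hbo", 0, 1),))
    latent = {m: np.eye(spec.n_channels(m)) for m in MODALITIES}
    latent["hbo"][0, 1] = latent["hbo"][1, 0] = 1.0
    from neurocpm.synth import synthesize_fnirs
    rec = synthesize_fnirs(latent, spec, np.random.default_rng(3))
    filtered = fnirs_bandpass(rec)
    r760, r850 = split_wavelengths(filtered)
    hb = mbll(r760, r850)
    assert np.corrcoef(hb.hbo[0], hb.hbo[1])[0, 1] > 0.99
    cc = [np.corrcoef(hb.hbo[i], hb.hbr[i])[0, 1] for i in range(6)]
    assert abs(np.mean(cc) - (-0.8)) < 0.1


def test_forward_od_round_trips_through_mbll():
    """Generator OD output, inverted by mbll, matches a direct hemoglobin
    synthesis of the same seed to near machine precision (no noise)."""
    spec_od = CohortSpec(n_subjects=3, noise_sd=0.0, seed=13, fnirs_output="od")
    spec_hb = CohortSpec(n_subjects=3, noise_sd=0.0, seed=13, fnirs_output="hb")
    subs_od, _ = generate_cohort(spec_od)
    subs_hb, _ = generate_cohort(spec_hb)
    r760, r850 = split_wavelengths(subs_od[0].fnirs)
    hb = mbll(r760, r850)
    n = 25
    truth_hbo = subs_hb[0].fnirs.data[:n]
    truth_hbr = subs_hb[0].fnirs.data[n:]
    scale = np.max(np.abs(truth_hbo))
    assert np.max(np.abs(hb.hbo - truth_hbo)) / scale < 1e-6
    assert np.max(np.abs(hb.hbr - truth_hbr)) / scale < 1e-6


def test_artifact_injection_is_optional_and_reversible(tiny_cohort):
    spec, subjects, _ = tiny_cohort
    rec = subjects[0].eeg
    dirty = inject_artifacts(rec, np.random.default_rng(2),
                             ocular_per_min=30.0, spike_per_min=15.0)
    assert dirty.data.shape == rec.data.shape
    assert not np.array_equal(dirty.data, rec.data)
    assert np.array_equal(dirty.meta["clean"], rec.data)


def test_sample_cohort_table_matches_latent_targets():
    spec = CohortSpec(n_subjects=12, seed=3, effect_r=0.5)
    table, gt = sample_cohort_table(spec, t_eff=400)
    assert table.n_subjects == 12
    for mod in MODALITIES:
        n = spec.n_channels(mod)
        assert table.matrices[mod].shape == (12, n, n)
        err = np.abs(table.matrices[mod] - gt.latent_connectivity[mod])
        assert err.mean() < 0.1  # finite-sample correlation noise only
    t2, _ = sample_cohort_table(spec, t_eff=400)
    assert np.array_equal(table.matrices["hbo"], t2.matrices["hbo"])
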