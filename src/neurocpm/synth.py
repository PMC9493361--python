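"""Synthetic EEG + fNIRS resting-state cohort generator with known ground truth.

The generator emulates the structure of a joint EEG-fNIRS resting-state
study: per subject, 5 min of 8-channel EEG at 500 Hz and 25-channel fNIRS
at 5.2083 Hz (two wavelengths, 760/850 nm), plus one behavioral performance
score in [0, 100] %.

Ground truth is planted at the level of *connectivity edges*:

* Each subject has a latent connectivity target matrix per feature modality
  (``hbo``, ``hbr``, ``beta_m_alpha``, ``gamma_m_alpha``): identity plus the
  planted pairwise weights.
* For a planted edge, the per-subject weight is a linear function of a
  standardized performance variate, so that the population correlation
  between edge weight and performance equals ``effect_r``.
* EEG amplitude-modulation connectivity is realized by *modulator sharing*:
  channels carry band-limited tone carriers (beta ~ 12-30 Hz, gamma ~
  30-50 Hz) whose instantaneous amplitude contains an alpha-band (8-12 Hz)
  modulator; planted channel pairs mix a common modulator so the envelope
  correlation approximates the latent weight.
* fNIRS connectivity is realized by mixing slow (0.01-0.2 Hz) latent
  oscillations; oxy- and deoxyhemoglobin are generated with a configurable
  negative mutual correlation, and can be forward-projected through the
  modified Beer-Lambert law to two-wavelength optical densities.

A scaled sampler (:func:`sample_cohort_table`) draws measured connectivity
matrices directly from the same latent ground truth with finite-sample
correlation noise, for replicate-heavy calibration studies where full
signal synthesis would be wasteful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._filters import bandpass
from .core import MODALITIES, ParameterError, Recording

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SubjectData",
    "generate_cohort",
    "synthesize_eeg",
    "synthesize_fnirs",
    "sample_cohort_table",
    "inject_artifacts",
]

_EEG_MODALITIES = ("beta_m_alpha", "gamma_m_alpha")
_FNIRS_MODALITIES = ("hbo", "hbr")

#: Default planted predictive edges: 3 per fNIRS modality, 1 per EEG modality.
DEFAULT_PREDICTIVE_EDGES = (
    ("hbo", 0, 1), ("hbo", 2, 3), ("hbo", 4, 5),
    ("hbr", 6, 7), ("hbr", 8, 9), ("hbr", 10, 11),
    ("beta_m_alpha", 0, 1),
    ("gamma_m_alpha", 2, 3),
)


@dataclass
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the emulated acquisition: 5 min eyes-open rest,
    8 EEG channels at 500 Hz, 25 fNIRS channels at 5.2083 Hz.

    ``effect_r`` is the target population correlation between each planted
    edge's latent weight and the performance score. ``cross_modal_r`` plants
    a shared subject-level latent between the hbo and gamma_m_alpha edge
    weights (negative by default, the empirically observed direction of
    oxyhemoglobin/EEG-gamma-AM coupling), which propagates to the
    cross-modality connectome-summary-score correlation.
    """

    n_subjects: int = 31
    duration_s: float = 300.0
    eeg_channels: int = 8
    fnirs_channels: int = 25
    eeg_fs: float = 500.0
    fnirs_fs: float = 5.2083
    predictive_edges: tuple = DEFAULT_PREDICTIVE_EDGES
    effect_r: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    # generator mechanics
    cross_modal_r: float = -0.5
    hbo_hbr_rho: float = 0.6        # HbO-HbR mutual correlation is -rho
    modulation_depth: float = 0.5   # AM depth of the alpha-band modulator
    fnirs_output: str = "od"        # "od" (two-wavelength) or "hb"
    artifacts: bool = False         # inject ocular-like transients + spikes

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ParameterError("n_subjects must be >= 3")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.eeg_channels < 2:
            raise ParameterError("eeg_channels must be >= 2")
        if self.fnirs_channels < 2:
            raise ParameterError("fnirs_channels must be >= 2")
        if self.eeg_fs < 2 * 50.0:
            raise ParameterError("eeg_fs must satisfy Nyquist for the 50 Hz "
                                 "gamma edge (>= 100 Hz)")
        if self.fnirs_fs <= 0.4:
            raise ParameterError("fnirs_fs must be > 0.4 Hz")
        if not -1.0 <= self.effect_r <= 1.0:
            raise ParameterError("effect_r must be in [-1, 1]")
        if not -1.0 <= self.cross_modal_r <= 1.0:
            raise ParameterError("cross_modal_r must be in [-1, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.hbo_hbr_rho < 1.0:
            raise ParameterError("hbo_hbr_rho must be in [0, 1)")
        if self.fnirs_output not in ("od", "hb"):
            raise ParameterError("fnirs_output must be 'od' or 'hb'")
        for mod, i, j in self.predictive_edges:
            if mod not in MODALITIES:
                raise ParameterError(f"predictive_edges: unknown modality {mod!r}")
            n = self.eeg_channels if mod in _EEG_MODALITIES else self.fnirs_channels
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ParameterError(
                    f"predictive_edges: edge ({mod}, {i}, {j}) out of range "
                    f"for {n} channels")

    def n_channels(self, modality: str) -> int:
        return self.eeg_channels if modality in _EEG_MODALITIES else self.fnirs_channels


@dataclass
class GroundTruth:
    """What was planted: the targets that parameter-recovery tests compare to.

    ``latent_connectivity[mod]`` has shape (n_subjects, n, n); symmetric with
    unit diagonal. For ``hbr`` it stores the *achieved* targets after the
    positive-definite projection required by the HbO/HbR mixing (see
    :func:`synthesize_fnirs`).
    """

    performance: np.ndarray
    planted_edge_targets: dict
    latent_connectivity: dict


@dataclass
class SubjectData:
    """One subject's recording bundle."""

    subject_id: str
    eeg: Recording
    fnirs: Recording
    performance: float


# ---------------------------------------------------------------------------
# latent cohort machinery

def _clipped_normal_moments(lo: float, hi: float) -> tuple[float, float]:
    """Mean and sd of clip(Z, lo, hi) for Z ~ N(0,1), in closed form."""
    Phi, phi = stats.norm.cdf, stats.norm.pdf
    m = lo * Phi(lo) + hi * (1 - Phi(hi)) + phi(lo) - phi(hi)
    m2 = (lo ** 2 * Phi(lo) + hi ** 2 * (1 - Phi(hi))
          + (Phi(hi) - Phi(lo)) + lo * phi(lo) - hi * phi(hi))
    return m, float(np.sqrt(m2 - m ** 2))


_PERF_CENTER, _PERF_SCALE = 70.0, 24.0
_PERF_LO = (0.0 - _PERF_CENTER) / _PERF_SCALE
_PERF_HI = (100.0 - _PERF_CENTER) / _PERF_SCALE
_PERF_M, _PERF_SD = _clipped_normal_moments(_PERF_LO, _PERF_HI)

# Planted weights live on w = center + scale * v, v ~ unit variance (a linear
# map preserves the edge-performance Pearson correlation). HbR uses a
# compressed range: with per-channel HbO-HbR anticorrelation -rho, the
# achievable HbR pair correlation is capped at (1 - rho^2) + rho^2 * R_hbo,
# so HbR targets must stay below ~1 - rho^2 (0.64 at the default rho = 0.6)
# for the joint (HbO, HbR) process to remain positive definite.
_W_MAP = {"hbr": (0.3, 0.1)}
_W_DEFAULT = (0.5, 0.15)


def _draw_performance(rng: np.random.Generator, n: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Performance in [0,100] as a clipped-linear transform of N(0,1), plus
    the exactly standardized variate (population moments, not sample)."""
    z = rng.standard_normal(n)
    c = np.clip(z, _PERF_LO, _PERF_HI)
    perf = _PERF_CENTER + _PERF_SCALE * c
    perf_std = (c - _PERF_M) / _PERF_SD
    return perf, perf_std


def _nearest_correlation(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest PD correlation matrix by
    eigenvalue clipping followed by diagonal rescaling."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _latent_cohort(spec: CohortSpec, rng: np.random.Generator
                   ) -> tuple[np.ndarray, GroundTruth]:
    """Draw performance scores, planted edge weights, and per-subject latent
    connectivity target matrices for every modality."""
    n = spec.n_subjects
    perf, perf_std = _draw_performance(rng, n)
    coupling_latent = rng.standard_normal(n)

    er = spec.effect_r
    k = np.sqrt(abs(spec.cross_modal_r))
    cm_sign = float(np.sign(spec.cross_modal_r)) if spec.cross_modal_r else 0.0

    planted: dict = {}
    for mod, i, j in spec.predictive_edges:
        if mod == "hbo":
            load = k
        elif mod == "gamma_m_alpha":
            load = cm_sign * k
        else:
            load = 0.0
        eps = rng.standard_normal(n)
        resid = load * coupling_latent + np.sqrt(max(0.0, 1 - load ** 2)) * eps
        v = er * perf_std + np.sqrt(max(0.0, 1 - er ** 2)) * resid
        center, scale = _W_MAP.get(mod, _W_DEFAULT)
        planted[(mod, i, j)] = np.clip(center + scale * v, 0.02, 0.98)

    latent: dict = {}
    for mod in MODALITIES:
        nch = spec.n_channels(mod)
        mats = np.broadcast_to(np.eye(nch), (n, nch, nch)).copy()
        for (m, i, j), w in planted.items():
            if m == mod:
                mats[:, i, j] = w
                mats[:, j, i] = w
        latent[mod] = mats
    gt = GroundTruth(performance=perf, planted_edge_targets=planted,
                     latent_connectivity=latent)
    return perf, gt


def _correlated_band_noise(rng: np.random.Generator, corr: np.ndarray,
                           n_samples: int, f_low: float, f_high: float,
                           fs: float, transition_hz: float,
                           max_taps: int | None = None) -> np.ndarray:
    """Rows of band-limited unit-variance noise with the given correlation.

    White noise is mixed through the Cholesky factor *before* filtering; a
    common linear filter preserves cross-correlations exactly.
    """
    L = np.linalg.cholesky(_nearest_correlation(corr))
    white = rng.standard_normal((corr.shape[0], n_samples))
    mixed = L @ white
    out = bandpass(mixed, f_low, f_high, fs, transition_hz, max_taps)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


# ---------------------------------------------------------------------------
# signal synthesis

def synthesize_eeg(latent: dict, spec: CohortSpec,
                   rng: np.random.Generator) -> Recording:
    """Synthesize one subject's multichannel EEG from latent AM connectivity.

    ``latent`` maps the two EEG modalities to (n, n) target matrices for the
    alpha-band modulator correlations. Each channel is a sum of a beta tone
    and a gamma tone, each amplitude-modulated by an alpha-band (8-12 Hz)
    modulator shared across planted pairs, plus independent alpha-band
    background and broadband noise at ``noise_sd``.
    """
    nch = spec.eeg_channels
    T = round(spec.duration_s * spec.eeg_fs)
    fs = spec.eeg_fs
    t = np.arange(T) / fs
    d = spec.modulation_depth
    max_taps = 2 * (T // 2) - 1 if T < 900 else None

    # One carrier tone per band, shared across channels (random phase per
    # channel). A shared frequency keeps the band-edge shaping of the AM
    # sidebands identical in every channel, so the recovered modulators of a
    # planted pair stay correlated at the planted weight; the tone sits where
    # both sidebands (f_c +/- 8..12 Hz) survive the carrier band-pass best.
    x = np.zeros((nch, T))
    for mod, f_c in (("beta_m_alpha", 21.0), ("gamma_m_alpha", 45.0)):
        m = _correlated_band_noise(rng, latent[mod], T, 8.0, 12.0, fs, 2.0,
                                   max_taps)
        m = 2.2 * np.tanh(m / 2.2)  # keep 1 + d*m positive
        phases = rng.uniform(0, 2 * np.pi, size=nch)
        carrier = np.cos(2 * np.pi * f_c * t + phases[:, None])
        x += (1.0 + d * m) * carrier
    # Independent alpha-band background plus broadband noise, both scaled by
    # noise_sd: the alpha background is a nuisance source for the AM pipeline
    # (its band-edge leakage beats against the beta carrier inside the
    # modulation band), so it belongs to the noise budget.
    if spec.noise_sd > 0:
        alpha_bg = bandpass(rng.standard_normal((nch, T)), 8.0, 12.0, fs, 2.0,
                            max_taps)
        sd = alpha_bg.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x += 0.3 * spec.noise_sd * alpha_bg / sd
        x += spec.noise_sd * rng.standard_normal((nch, T))
    x *= 10.0  # microvolt-ish scale
    rec = Recording(data=x, fs=fs,
                    ch_names=[f"EEG{i + 1}" for i in range(nch)],
                    kind="eeg", meta={"units": "uV"})
    if spec.artifacts:
        rec = inject_artifacts(rec, rng)
    return rec


def synthesize_fnirs(latent: dict, spec: CohortSpec,
                     rng: np.random.Generator) -> Recording:
    """Synthesize one subject's fNIRS record from latent slow connectivity.

    Slow (0.01-0.2 Hz) unit-variance latents realize the ``hbo`` target
    correlations; HbR is built as ``-rho * z_hbo + sqrt(1-rho^2) * z_u`` so
    each channel's HbO-HbR correlation is ``-rho``. The auxiliary latents
    ``z_u`` are mixed to hit the requested HbR pair correlations; because the
    achievable HbR correlation is ``rho^2*R_hbo + (1-rho^2)*R_u``, the solved
    ``R_u`` is PD-projected and the achieved targets are stored by the
    caller's ground truth.

    Output is either hemoglobin concentrations directly (``fnirs_output ==
    "hb"``; channels HbO then HbR) or two-wavelength optical densities via
    the forward modified Beer-Lambert law (``"od"``; channels at 760 nm then
    850 nm), with additive measurement noise scaled by ``noise_sd``.
    """
    from .nirs import MbllParams, forward_mbll  # local: avoid import cycle

    nch = spec.fnirs_channels
    T = round(spec.duration_s * spec.fnirs_fs)
    fs = spec.fnirs_fs
    rho = spec.hbo_hbr_rho
    max_taps = 2 * (T // 2) - 1

    R_hbo = latent["hbo"]
    R_u = (latent["hbr"] - rho ** 2 * R_hbo) / (1 - rho ** 2)
    R_u = _nearest_correlation(R_u)
    # record achieved HbR target back into the latent dict (caller-visible)
    latent["hbr"] = rho ** 2 * R_hbo + (1 - rho ** 2) * R_u
    np.fill_diagonal(latent["hbr"], 1.0)

    z_hbo = _correlated_band_noise(rng, R_hbo, T, 0.01, 0.2, fs, 0.02, max_taps)
    z_u = _correlated_band_noise(rng, R_u, T, 0.01, 0.2, fs, 0.02, max_taps)
    hbo = 1.0 * z_hbo                                   # ~1 uM fluctuation
    hbr = 0.33 * (-rho * z_hbo + np.sqrt(1 - rho ** 2) * z_u)

    labels = [f"S{i // 5 + 1}_D{i % 5 + 1}" for i in range(nch)]
    if spec.fnirs_output == "hb":
        data = np.vstack([hbo, hbr])
        if spec.noise_sd > 0:
            data = data + 0.02 * spec.noise_sd * rng.standard_normal(data.shape)
        names = [f"{c} hbo" for c in labels] + [f"{c} hbr" for c in labels]
        return Recording(data=data, fs=fs, ch_names=names, kind="hb",
                         meta={"units": "uM", "n_sd_channels": nch})
    params = MbllParams()
    od = forward_mbll(hbo, hbr, params)                 # (2, nch, T)
    data = np.vstack([od[0], od[1]])
    if spec.noise_sd > 0:
        data = data + 0.003 * spec.noise_sd * rng.standard_normal(data.shape)
    names = ([f"{c} 760" for c in labels] + [f"{c} 850" for c in labels])
    return Recording(data=data, fs=fs, ch_names=names, kind="od",
                     meta={"wavelengths": [760.0, 850.0],
                           "n_sd_channels": nch,
                           "mbll_params": params})


def inject_artifacts(rec: Recording, rng: np.random.Generator,
                     ocular_per_min: float = 4.0,
                     spike_per_min: float = 2.0) -> Recording:
    """Add ocular-like slow transients and high-amplitude spikes (for
    artifact-correction testing). Returns a new Recording; the clean data
    stays available in ``meta['clean']``."""
    x = rec.data.copy()
    nch, T = x.shape
    fs = rec.fs
    sd = x.std()
    n_ocular = rng.poisson(ocular_per_min * rec.duration_s / 60.0)
    weights = np.exp(-np.arange(nch) / 2.0)  # frontal-dominant projection
    for _ in range(n_ocular):
        start = rng.integers(0, max(1, T - int(0.4 * fs)))
        length = int(rng.uniform(0.2, 0.4) * fs)
        pulse = np.sin(np.pi * np.arange(length) / length) ** 2
        amp = rng.uniform(6, 10) * sd
        x[:, start:start + length] += amp * weights[:, None] * pulse[None, :]
    n_spk = rng.poisson(spike_per_min * rec.duration_s / 60.0)
    for _ in range(n_spk):
        ch = rng.integers(0, nch)
        start = rng.integers(0, max(1, T - int(0.02 * fs) - 1))
        length = max(3, int(0.02 * fs))
        x[ch, start:start + length] += rng.choice([-1, 1]) * rng.uniform(
            12, 18) * sd * np.hanning(length)
    return rec.copy_with(x, clean=rec.data)


# ---------------------------------------------------------------------------
# cohort-level entry points

def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectData], GroundTruth]:
    """Generate a full signal-level cohort. Deterministic in (spec, seed)."""
    ss = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    perf, gt = _latent_cohort(spec, cohort_rng)
    subjects: list[SubjectData] = []
    for s in range(spec.n_subjects):
        sub_rng = np.random.default_rng(np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(1, s)))
        latent_s = {mod: gt.latent_connectivity[mod][s] for mod in MODALITIES}
        eeg = synthesize_eeg(latent_s, spec, sub_rng)
        fnirs = synthesize_fnirs(latent_s, spec, sub_rng)
        gt.latent_connectivity["hbr"][s] = latent_s["hbr"]  # achieved target
        subjects.append(SubjectData(subject_id=f"sub-{s + 1:02d}",
                                    eeg=eeg, fnirs=fnirs,
                                    performance=float(perf[s])))
    return subjects, gt


def sample_cohort_table(spec: CohortSpec, t_eff: int = 150):
    """Draw measured connectivity matrices directly from the latent targets.

    For each subject and modality, ``t_eff`` i.i.d. multivariate-normal
    samples with the subject's latent correlation are drawn and their sample
    correlation matrix is the "measured" connectivity — i.e. the latent
    ground truth observed through finite-sample estimation noise, skipping
    waveform synthesis. Used for replicate-heavy calibration studies.

    Returns (CohortTable, GroundTruth).
    """
    from .cpm import CohortTable  # local: avoid import cycle

    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    perf, gt = _latent_cohort(spec, rng)
    rho = spec.hbo_hbr_rho
    matrices = {}
    for mod in MODALITIES:
        nch = spec.n_channels(mod)
        out = np.empty((spec.n_subjects, nch, nch))
        for s in range(spec.n_subjects):
            target = gt.latent_connectivity[mod][s]
            if mod == "hbr":
                R_u = _nearest_correlation(
                    (target - rho ** 2 * gt.latent_connectivity["hbo"][s])
                    / (1 - rho ** 2))
                target = rho ** 2 * gt.latent_connectivity["hbo"][s] \
                    + (1 - rho ** 2) * R_u
                np.fill_diagonal(target, 1.0)
                gt.latent_connectivity["hbr"][s] = target
            L = np.linalg.cholesky(_nearest_correlation(target))
            draws = L @ rng.standard_normal((nch, t_eff))
            out[s] = np.corrcoef(draws)
        matrices[mod] = out
    table = CohortTable(
        subject_ids=[f"sub-{s + 1:02d}" for s in range(spec.n_subjects)],
        matrices=matrices, performance=perf)
    return table, gt
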