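"""EEG feature extraction: broadband filtering, wICA artifact correction,
and spectro-temporal amplitude-modulation (AM) series.

The AM representation characterizes the frequency content of a band-limited
EEG signal's instantaneous amplitude: a carrier band (e.g. beta, 12-30 Hz)
is isolated with a linear-phase FIR filter, its Hilbert envelope extracted,
and the envelope band-passed to a modulation band (e.g. m-alpha, 8-12 Hz).
By Bedrosian's theorem the envelope of a band-limited signal cannot carry
modulation frequencies beyond the carrier band's extent, so only 14
(carrier, modulator) pairs are meaningful; the two wired into the default
pipeline are beta-m-alpha and gamma-m-alpha, the bands whose modulations
track regional blood flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal
from sklearn.decomposition import FastICA

from ._filters import fir_bandpass_taps, zero_phase_filter
from .core import DecompositionError, ParameterError, Recording

__all__ = [
    "BandSpec",
    "ModulationPair",
    "AMSeries",
    "WicaParams",
    "BANDS",
    "bandpass_broadband",
    "wica_clean",
    "valid_modulation_pairs",
    "amplitude_modulation",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not 0 <= self.f_low < self.f_high:
            raise ParameterError(f"band {self.name}: need 0 <= f_low < f_high")


#: Canonical band table: delta, theta, alpha, beta, gamma.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.1, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 50.0),
}


@dataclass(frozen=True)
class ModulationPair:
    """A (carrier band, modulation band) combination, e.g. beta-m-alpha."""

    carrier: BandSpec
    modulator: BandSpec

    @property
    def name(self) -> str:
        return f"{self.carrier.name}_m_{self.modulator.name}"


# Bedrosian-admissible pairs, hard-coded in canonical order. Note the set is
# an enumeration, not a formula: alpha-m-alpha is excluded while beta-m-beta
# and gamma-m-gamma are included.
_VALID_PAIR_NAMES = (
    ("delta", "delta"),
    ("theta", "delta"), ("theta", "theta"),
    ("alpha", "delta"), ("alpha", "theta"),
    ("beta", "delta"), ("beta", "theta"), ("beta", "alpha"), ("beta", "beta"),
    ("gamma", "delta"), ("gamma", "theta"), ("gamma", "alpha"),
    ("gamma", "beta"), ("gamma", "gamma"),
)


def valid_modulation_pairs() -> list[ModulationPair]:
    """The 14 admissible (carrier, modulator) pairs, in stable order."""
    return [ModulationPair(BANDS[c], BANDS[m]) for c, m in _VALID_PAIR_NAMES]


def get_pair(name: str) -> ModulationPair:
    """Look up a pair by name like ``"beta_m_alpha"``."""
    for p in valid_modulation_pairs():
        if p.name == name:
            return p
    raise ParameterError(f"unknown modulation pair {name!r}; valid: "
                         + ", ".join(p.name for p in valid_modulation_pairs()))


@dataclass
class AMSeries:
    """Per-channel amplitude-modulation time series for one pair.

    ``edge_trim_s`` flags how much of each end is filter/Hilbert transient
    and should be excluded from downstream correlation.
    """

    values: np.ndarray
    fs: float
    pair: ModulationPair
    ch_names: list[str] = field(default_factory=list)
    edge_trim_s: float = 1.0

    @property
    def trimmed(self) -> np.ndarray:
        k = int(round(self.edge_trim_s * self.fs))
        if 2 * k >= self.values.shape[1]:
            return self.values
        return self.values[:, k:self.values.shape[1] - k]


@dataclass
class WicaParams:
    """wICA knobs. The two dimensionless thresholds are expressed in units of
    the per-component universal wavelet threshold sigma*sqrt(2 ln N)."""

    cleaning_tolerance: float = 1.4
    ic_artifact_threshold: float = 1.6
    wavelet_family: str = "sym8"
    decomposition_level: int | None = None  # default: floor(log2(fs/4))
    seed: int = 0
    max_iter: int = 1000

    def __post_init__(self):
        if self.cleaning_tolerance <= 0 or self.ic_artifact_threshold <= 0:
            raise ParameterError("wICA thresholds must be > 0")


def bandpass_broadband(recording: Recording) -> Recording:
    """Zero-phase second-order Butterworth band-pass, 0.1-100 Hz."""
    if recording.fs <= 200:
        raise ParameterError("fs must exceed 200 Hz for the 100 Hz band edge")
    sos = signal.butter(2, [0.1, 100.0], btype="bandpass", output="sos",
                        fs=recording.fs)
    out = signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy_with(out, broadband_filtered=True)


def _level_thresholds(coeffs: list[np.ndarray], n: int) -> list[float]:
    """Per-level universal thresholds sigma_l * sqrt(2 ln N), with sigma_l
    from the MAD of that level's coefficients (robust to sparse artifact
    outliers within the level)."""
    factor = np.sqrt(2.0 * np.log(max(n, 2)))
    out = []
    for c in coeffs:
        sigma = np.median(np.abs(c)) / 0.6745 if c.size else 0.0
        out.append(float(sigma * factor))
    return out


def wica_clean(recording: Recording, params: WicaParams | None = None
               ) -> Recording:
    """Wavelet-enhanced ICA artifact correction.

    Channels are unmixed into independent components (FastICA, seeded).
    Each IC is wavelet-decomposed; an IC is flagged artifactual when any
    coefficient exceeds ``ic_artifact_threshold`` times its universal
    threshold. In flagged ICs, coefficients beyond ``cleaning_tolerance``
    times the universal threshold are clipped back to that level, so
    high-amplitude transients are removed while sub-threshold (neural)
    structure — including neural content leaked into artifactual ICs — is
    retained. All ICs are kept; the record is rebuilt from the corrected
    sources, so output shape equals input shape.
    """
    params = params or WicaParams()
    x = recording.data
    nch, n = x.shape
    if nch < 2:
        raise ParameterError("wICA needs >= 2 channels")
    if n <= nch:
        raise ParameterError("wICA needs more samples than channels")
    centered = x - x.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise DecompositionError(
            "rank-deficient input (constant or duplicated channels); "
            "ICA unmixing is undefined")

    ica = FastICA(n_components=nch, whiten="unit-variance",
                  random_state=params.seed, max_iter=params.max_iter)
    import warnings as _warnings
    with _warnings.catch_warnings():
        # near-Gaussian sources can stop FastICA at max_iter without harm:
        # the reconstruction below uses whatever rotation was reached
        _warnings.simplefilter("ignore", category=UserWarning)
        sources = ica.fit_transform(x.T)  # (n_samples, n_components)

    level = params.decomposition_level
    if level is None:
        level = max(1, int(np.floor(np.log2(recording.fs / 4.0))))
    level = min(level, pywt.dwt_max_level(n, params.wavelet_family))

    cleaned = np.empty_like(sources)
    for k in range(sources.shape[1]):
        s = sources[:, k]
        coeffs = pywt.wavedec(s, params.wavelet_family, level=level)
        thresholds = _level_thresholds(coeffs, n)
        flagged = any(
            u > 0 and np.max(np.abs(c)) > params.ic_artifact_threshold * u
            for c, u in zip(coeffs, thresholds))
        if not flagged:
            cleaned[:, k] = s          # no artifactual coefficients
            continue
        new_coeffs = [
            np.clip(c, -params.cleaning_tolerance * u,
                    params.cleaning_tolerance * u) if u > 0 else c
            for c, u in zip(coeffs, thresholds)]
        rec = pywt.waverec(new_coeffs, params.wavelet_family)
        cleaned[:, k] = rec[:n]
    out = ica.inverse_transform(cleaned).T
    return recording.copy_with(out, wica=True)


def amplitude_modulation(recording: Recording, pair: ModulationPair | str,
                         transition_hz: float = 2.0,
                         edge_trim_s: float = 1.0) -> AMSeries:
    """Extract the per-channel AM time series for one (carrier, modulator)
    pair: zero-phase FIR band-pass to the carrier band, Hilbert-envelope
    magnitude, then zero-phase FIR band-pass of the envelope to the
    modulation band. Output sampling rate equals the input rate and no group
    delay is introduced between channels.
    """
    if isinstance(pair, str):
        pair = get_pair(pair)
    if (pair.carrier.name, pair.modulator.name) not in _VALID_PAIR_NAMES:
        raise ParameterError(
            f"pair {pair.carrier.name}-m-{pair.modulator.name} is not in the "
            "admissible set; see valid_modulation_pairs()")
    fs = recording.fs
    x = recording.data
    max_taps = 2 * (x.shape[1] // 2) - 1
    car_taps = fir_bandpass_taps(pair.carrier.f_low, pair.carrier.f_high, fs,
                                 transition_hz, max_taps)
    band = zero_phase_filter(x, car_taps)
    envelope = np.abs(signal.hilbert(band, axis=1))
    mod_taps = fir_bandpass_taps(pair.modulator.f_low, pair.modulator.f_high,
                                 fs, transition_hz, max_taps)
    am = zero_phase_filter(envelope, mod_taps)
    return AMSeries(values=am, fs=fs, pair=pair,
                    ch_names=list(recording.ch_names),
                    edge_trim_s=edge_trim_s)
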