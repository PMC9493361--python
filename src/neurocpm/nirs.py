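"""fNIRS feature extraction: band-limited, detrended hemoglobin
concentration changes via the modified Beer-Lambert law (MBLL).

The pipeline order is fixed: band-pass (0.01-0.2 Hz linear-phase FIR) →
linear detrend over the whole record → MBLL inversion of the two-wavelength
optical-density changes into oxy-/deoxyhemoglobin concentration changes →
segmentation of the resting block.

MBLL model, per channel and time point::

    dOD(lambda) = [eps_HbO(lambda)*dHbO + eps_HbR(lambda)*dHbR] * d * DPF(lambda)

with extinction coefficients ``eps`` in 1/(mM*cm), source-detector distance
``d`` converted to cm, and a per-wavelength differential pathlength factor
(DPF). The 2x2 system is solved exactly for (dHbO, dHbR), reported in uM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ._filters import fir_bandpass_taps, zero_phase_filter
from .core import ParameterError, Recording

__all__ = [
    "MbllParams",
    "HbSeries",
    "fnirs_bandpass",
    "detrend_series",
    "mbll",
    "forward_mbll",
    "split_wavelengths",
]

# Hemoglobin molar extinction coefficients (base-10), 1/(mM*cm), from the
# standard compiled spectra; rows = wavelengths (760, 850 nm),
# columns = chromophores (HbO, HbR).
DEFAULT_EXTINCTION = np.array([
    [0.586, 1.54852],   # 760 nm
    [1.058, 0.69132],   # 850 nm
])


@dataclass
class MbllParams:
    """MBLL constants. DPFs are bound per wavelength: 7.25 at 760 nm and
    6.38 at 850 nm (the acquisition-software convention for this pair);
    source-detector distance in mm."""

    dpf_760: float = 7.25
    dpf_850: float = 6.38
    source_detector_distance_mm: float = 30.0
    extinction: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXTINCTION.copy())

    def __post_init__(self):
        if self.dpf_760 <= 0 or self.dpf_850 <= 0:
            raise ParameterError("DPFs must be > 0")
        if self.source_detector_distance_mm <= 0:
            raise ParameterError("source_detector_distance_mm must be > 0")
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ParameterError("extinction must be 2x2 (wavelength x chromophore)")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ParameterError("extinction matrix is singular")

    @property
    def pathlengths_cm(self) -> np.ndarray:
        d_cm = self.source_detector_distance_mm / 10.0
        return d_cm * np.array([self.dpf_760, self.dpf_850])


@dataclass
class HbSeries:
    """Oxy/deoxyhemoglobin concentration-change series, in uM."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ParameterError("hbo and hbr must share shape")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.hbo.shape[0])]


def fnirs_bandpass(recording: Recording, f_low: float = 0.01,
                   f_high: float = 0.2, transition_hz: float = 0.02
                   ) -> Recording:
    """Zero-phase linear-phase FIR band-pass (default 0.01-0.2 Hz).

    Group delay is compensated exactly (centered symmetric kernel). Records
    shorter than ~3 periods of the low edge get a capped kernel and a
    warning; the filter is still applied.
    """
    if recording.fs <= 2 * f_high:
        raise ParameterError(f"fs must exceed {2 * f_high} Hz")
    n = recording.n_samples
    if recording.duration_s < 2.85 / f_low:   # ~3 periods of the low edge
        warnings.warn(
            f"record ({recording.duration_s:.0f} s) is shorter than ~3 "
            f"periods of the {f_low} Hz band edge; low-frequency response "
            "is poorly defined", stacklevel=2)
    max_taps = 2 * (n // 2) - 1
    taps = fir_bandpass_taps(f_low, f_high, recording.fs, transition_hz,
                             max_taps)
    return recording.copy_with(zero_phase_filter(recording.data, taps),
                               fnirs_filtered=True)


def detrend_series(recording: Recording) -> Recording:
    """Remove the least-squares linear trend over the whole record, per
    channel, before any segmentation."""
    out = signal.detrend(recording.data, axis=1, type="linear")
    return recording.copy_with(out, detrended=True)


def forward_mbll(hbo_um: np.ndarray, hbr_um: np.ndarray,
                 params: MbllParams | None = None) -> np.ndarray:
    """Project hemoglobin concentration changes (uM) to optical-density
    changes at 760/850 nm. Returns array of shape (2, n_channels, n_samples)
    ordered (760, 850). Inverse of :func:`mbll` (round-trip exact up to
    float error)."""
    params = params or MbllParams()
    hbo = np.atleast_2d(np.asarray(hbo_um, dtype=float)) * 1e-3  # uM -> mM
    hbr = np.atleast_2d(np.asarray(hbr_um, dtype=float)) * 1e-3
    L = params.pathlengths_cm
    E = params.extinction
    od = np.empty((2,) + hbo.shape)
    for w in range(2):
        od[w] = (E[w, 0] * hbo + E[w, 1] * hbr) * L[w]
    return od


def mbll(od_760: Recording | np.ndarray, od_850: Recording | np.ndarray,
         params: MbllParams | None = None, fs: float | None = None,
         ch_names: list[str] | None = None) -> HbSeries:
    """Invert the modified Beer-Lambert law.

    Solves the per-sample 2x2 linear system for (dHbO, dHbR) from
    optical-density changes at both wavelengths. Inputs must share shape and
    sampling rate; output concentrations are in uM.
    """
    params = params or MbllParams()
    if isinstance(od_760, Recording):
        if isinstance(od_850, Recording) and od_850.fs != od_760.fs:
            raise ParameterError("wavelength records must share fs")
        fs = od_760.fs
        ch_names = ch_names or list(od_760.ch_names)
        od_760 = od_760.data
    if isinstance(od_850, Recording):
        od_850 = od_850.data
    a = np.atleast_2d(np.asarray(od_760, dtype=float))
    b = np.atleast_2d(np.asarray(od_850, dtype=float))
    if a.shape != b.shape:
        raise ParameterError("optical-density arrays must share shape")
    L = params.pathlengths_cm
    Einv = np.linalg.inv(params.extinction)
    y0 = a / L[0]
    y1 = b / L[1]
    hbo_mm = Einv[0, 0] * y0 + Einv[0, 1] * y1
    hbr_mm = Einv[1, 0] * y0 + Einv[1, 1] * y1
    return HbSeries(hbo=hbo_mm * 1e3, hbr=hbr_mm * 1e3, fs=fs or 0.0,
                    ch_names=ch_names or [])


def split_wavelengths(recording: Recording) -> tuple[Recording, Recording]:
    """Split a stacked two-wavelength optical-density Recording (760-nm
    channels first, then 850-nm) into per-wavelength Recordings."""
    n = recording.meta.get("n_sd_channels")
    if n is None:
        if recording.n_channels % 2:
            raise ParameterError("cannot infer wavelength split: odd channel "
                                 "count and no 'n_sd_channels' in meta")
        n = recording.n_channels // 2
    labels = [c.rsplit(" ", 1)[0] for c in recording.ch_names[:n]]
    r760 = Recording(recording.data[:n], recording.fs, labels, "od",
                     dict(recording.meta, wavelength=760.0))
    r850 = Recording(recording.data[n:2 * n], recording.fs, list(labels),
                     "od", dict(recording.meta, wavelength=850.0))
    return r760, r850


def process_fnirs(recording: Recording, params: MbllParams | None = None
                  ) -> HbSeries:
    """Full fNIRS feature path in the fixed order: band-pass → detrend →
    MBLL. Accepts a stacked two-wavelength OD Recording (``kind="od"``) or a
    stacked hemoglobin Recording (``kind="hb"``, band-pass + detrend only)."""
    filtered = detrend_series(fnirs_bandpass(recording))
    n = recording.meta.get("n_sd_channels", recording.n_channels // 2)
    if recording.kind == "hb":
        labels = [c.rsplit(" ", 1)[0] for c in recording.ch_names[:n]]
        return HbSeries(hbo=filtered.data[:n], hbr=filtered.data[n:2 * n],
                        fs=recording.fs, ch_names=labels)
    r760, r850 = split_wavelengths(filtered)
    return mbll(r760, r850, params)
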