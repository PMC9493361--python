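"""Internal zero-phase FIR filtering helpers.

All band filters in the pipeline are linear-phase FIRs applied as a centered
convolution with an odd-length symmetric kernel: the group delay of such a
kernel is exactly (numtaps-1)/2 samples, so centering the convolution yields
an exactly zero-phase single-pass filter with the designed magnitude
response. Kernels use a Hamming window (~53 dB stopband).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal

logger = logging.getLogger("neurocpm")

# Hamming-window design: transition width ~ 3.3 / numtaps (normalized freq).
_HAMMING_TW = 3.3


def fir_bandpass_taps(f_low: float, f_high: float, fs: float,
                      transition_hz: float, max_taps: int | None = None
                      ) -> np.ndarray:
    """Design odd-length linear-phase band-pass taps.

    ``transition_hz`` sets the transition-band width; the order follows the
    Hamming-window rule. ``max_taps`` caps the kernel (e.g. for records
    shorter than the nominal impulse response); a cap is logged as a warning
    because it widens the transition band.
    """
    nyq = fs / 2.0
    if not (0 <= f_low < f_high):
        raise ValueError(f"invalid band ({f_low}, {f_high})")
    if f_high >= nyq:
        raise ValueError(f"band edge {f_high} Hz >= Nyquist {nyq} Hz")
    numtaps = int(np.ceil(_HAMMING_TW * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd
    if max_taps is not None and numtaps > max_taps:
        capped = max(3, max_taps - (1 - max_taps % 2))
        warnings.warn(
            f"FIR kernel capped at {capped} taps (designed {numtaps}); "
            "transition bands widen on this short record", stacklevel=2)
        logger.warning("FIR kernel capped: %d -> %d taps", numtaps, capped)
        numtaps = capped
    if f_low <= 0:
        return signal.firwin(numtaps, f_high, pass_zero="lowpass", fs=fs)
    return signal.firwin(numtaps, [f_low, f_high], pass_zero=False, fs=fs)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply odd-length symmetric FIR taps with zero phase via centered FFT
    convolution. Works on the last axis of 1-D or 2-D input."""
    taps = np.asarray(taps, dtype=float)
    if taps.size % 2 != 1:
        raise ValueError("taps length must be odd for exact zero phase")
    squeeze = np.ndim(x) == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    half = taps.size // 2
    padded = np.pad(x, [(0, 0), (half, half)], mode="reflect")
    out = signal.fftconvolve(padded, taps[np.newaxis, :], mode="valid", axes=1)
    return out[0] if squeeze else out


def bandpass(x: np.ndarray, f_low: float, f_high: float, fs: float,
             transition_hz: float, max_taps: int | None = None) -> np.ndarray:
    """One-call zero-phase FIR band-pass on the last axis."""
    taps = fir_bandpass_taps(f_low, f_high, fs, transition_hz, max_taps)
    squeeze = np.ndim(x) == 1
    out = zero_phase_filter(np.atleast_2d(x), taps)
    return out[0] if squeeze else out
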