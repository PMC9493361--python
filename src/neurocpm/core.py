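"""Core containers and errors shared across the pipeline.

The package operates on multichannel resting-state recordings from two
modalities: EEG (8 frontal channels, 500 Hz) and fNIRS (25 source-detector
channels, 5.2083 Hz, wavelengths 760/850 nm). Everything downstream —
amplitude-modulation features, hemoglobin concentrations, connectivity,
prediction — consumes or produces :class:`Recording` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "ParameterError",
    "DecompositionError",
    "FormatError",
    "FoldError",
    "MODALITIES",
]

#: Canonical connectivity feature modalities, in fixed report order.
MODALITIES = ("hbo", "hbr", "beta_m_alpha", "gamma_m_alpha")


class ParameterError(ValueError):
    """An invalid parameter or specification field; names the offending field."""


class DecompositionError(RuntimeError):
    """Signal decomposition (ICA/wavelet) failed, e.g. rank-deficient input."""


class FormatError(IOError):
    """A file could not be parsed as the requested format."""


class FoldError(RuntimeError):
    """A leave-one-subject-out fold could not be fit; carries the fold id."""

    def __init__(self, fold_id, message: str):
        self.fold_id = fold_id
        super().__init__(f"fold {fold_id!r}: {message}")


@dataclass
class Recording:
    """One subject's one-modality multichannel time series.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    ch_names
        Channel labels, length ``n_channels``.
    kind
        Free-form content tag: ``"eeg"``, ``"od"`` (optical density, channels
        interleaved per wavelength via ``meta["wavelengths"]``), ``"hbo"``,
        ``"hbr"``, ...
    meta
        Arbitrary metadata (units, wavelengths, subject id).
    """

    data: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)
    kind: str = "eeg"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise ParameterError("ch_names length must match n_channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, **meta) -> "Recording":
        """Return a new Recording with replaced data, inheriting metadata."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Recording(
            data=np.asarray(data, dtype=float),
            fs=self.fs,
            ch_names=list(self.ch_names),
            kind=self.kind,
            meta=new_meta,
        )


def as_2d(x: Sequence | np.ndarray) -> np.ndarray:
    """Coerce a 1-D or 2-D array-like to (n_channels, n_samples) float."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ParameterError("expected 1-D or 2-D array")
    return arr
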