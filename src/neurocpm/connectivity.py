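"""Per-subject Pearson functional-connectivity matrices and edge bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ParameterError

__all__ = ["ConnectivityMatrix", "pearson_connectivity", "edge_list",
           "edge_vector", "matrix_from_edges", "n_edges"]


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel Pearson matrix for one subject/modality."""

    values: np.ndarray
    ch_names: list[str] = field(default_factory=list)
    modality: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ParameterError("connectivity matrix must be square")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pearson_connectivity(series: np.ndarray, ch_names=None, modality: str = "",
                         subject_id: str = "", trim_s: float = 0.0,
                         fs: float | None = None) -> ConnectivityMatrix:
    """Pearson correlation between all channel pairs over a block.

    ``trim_s`` (with ``fs``) drops that many seconds from each end before
    correlating — used for AM series whose ends are filter transients.
    Constant channels make the correlation undefined and raise, naming the
    channel.
    """
    x = np.atleast_2d(np.asarray(getattr(series, "values", series), dtype=float))
    if fs is None:
        fs = getattr(series, "fs", None)
    if ch_names is None:
        ch_names = getattr(series, "ch_names", None)
    if trim_s:
        if not fs:
            raise ParameterError("trim_s requires a sampling rate")
        k = int(round(trim_s * fs))
        if 2 * k < x.shape[1]:
            x = x[:, k:x.shape[1] - k]
    sd = x.std(axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1))
    # exact constants have ptp == 0; offset constants leave sd at float noise
    bad = np.flatnonzero((np.ptp(x, axis=1) == 0) | (sd <= 1e-12 * rms))
    if bad.size:
        names = ch_names or [f"ch{i}" for i in range(x.shape[0])]
        raise ParameterError(
            f"channel(s) {[names[i] for i in bad]} constant within block; "
            "Pearson correlation undefined")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, ch_names=list(ch_names or []),
                              modality=modality, subject_id=subject_id)


def n_edges(n: int) -> int:
    return n * (n - 1) // 2


def edge_list(matrix: ConnectivityMatrix | np.ndarray
              ) -> list[tuple[int, int, float]]:
    """Strict-upper-triangle edges in row-major order: (i, j, value), i < j."""
    vals = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    n = vals.shape[0]
    return [(i, j, float(vals[i, j])) for i in range(n) for j in range(i + 1, n)]


def edge_vector(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangle values as a flat vector in edge_list order."""
    vals = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    iu = np.triu_indices(vals.shape[0], k=1)
    return vals[iu]


def matrix_from_edges(edges: np.ndarray, n: int, diag: float = 1.0
                      ) -> np.ndarray:
    """Rebuild the symmetric matrix from an edge vector (edge_list order)."""
    edges = np.asarray(edges, dtype=float)
    if edges.size != n_edges(n):
        raise ParameterError(f"expected {n_edges(n)} edges for n={n}")
    out = np.full((n, n), 0.0)
    iu = np.triu_indices(n, k=1)
    out[iu] = edges
    out = out + out.T
    np.fill_diagonal(out, diag)
    return out
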