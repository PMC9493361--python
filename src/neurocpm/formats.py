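"""Readers and writers for the standard interchange formats.

* EDF for EEG: reading through :mod:`mne`; writing through a minimal
  self-contained EDF encoder (16-bit, per-channel physical scaling).
* SNIRF (HDF5) for fNIRS: a minimal SNIRF 1.0 subset read and written
  directly with :mod:`h5py` — continuous-wave amplitude/OD time series, the
  measurement list, and the probe wavelength table.
* Delimited tables for matrices, per-subject scores, and generic recordings.
* JSON for reports and ground-truth sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import FormatError, ParameterError, Recording

__all__ = [
    "read_recording",
    "write_edf",
    "write_snirf",
    "read_snirf",
    "write_delimited",
    "read_delimited",
    "write_matrix_csv",
    "read_matrix_csv",
    "save_cohort",
]


# ---------------------------------------------------------------------------
# EDF

def write_edf(recording: Recording, path) -> Path:
    """Write a Recording as EDF (16-bit). Requires an integer number of
    samples per second; whole seconds only (a trailing partial second is
    dropped)."""
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError(
            f"EDF needs an integer sampling rate (got {fs}); use SNIRF or "
            "a delimited table for fractional rates")
    fs = int(round(fs))
    x = recording.data
    nch = recording.n_channels
    n_rec = x.shape[1] // fs
    if n_rec < 1:
        raise FormatError("record shorter than one second")
    x = x[:, :n_rec * fs]

    phys_min = x.min(axis=1)
    phys_max = x.max(axis=1)
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((x - phys_min[:, None]) / scale[:, None]
                       + dig_min).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + nch)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(nch), 4),
    ])
    units = recording.meta.get("units", "uV")
    sig = b"".join(pad(c, 16) for c in recording.ch_names)
    sig += b"".join(pad("", 80) for _ in range(nch))
    sig += b"".join(pad(units, 8) for _ in range(nch))
    sig += b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_min)
    sig += b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_max)
    sig += b"".join(pad(str(dig_min), 8) for _ in range(nch))
    sig += b"".join(pad(str(dig_max), 8) for _ in range(nch))
    sig += b"".join(pad("", 80) for _ in range(nch))
    sig += b"".join(pad(str(fs), 8) for _ in range(nch))
    sig += b"".join(pad("", 32) for _ in range(nch))

    path = Path(path)
    with open(path, "wb") as f:
        f.write(header + sig)
        for rec_i in range(n_rec):
            block = digital[:, rec_i * fs:(rec_i + 1) * fs]
            f.write(block.tobytes())
    return path


def _read_edf(path) -> Recording:
    import mne
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"could not parse EDF {path}: {exc}") from exc
    data = raw.get_data(units={"eeg": "uV"}) if any(
        t == "eeg" for t in raw.get_channel_types()) else raw.get_data()
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     ch_names=list(raw.ch_names), kind="eeg",
                     meta={"units": "uV", "source": str(path)})


# ---------------------------------------------------------------------------
# SNIRF

def write_snirf(recording: Recording, path) -> Path:
    """Write a stacked two-wavelength OD/amplitude Recording (760-nm
    channels first) as a minimal SNIRF 1.0 file."""
    wavelengths = recording.meta.get("wavelengths", [760.0, 850.0])
    n = recording.meta.get("n_sd_channels", recording.n_channels // 2)
    if recording.n_channels != 2 * n:
        raise FormatError("expected stacked channels for two wavelengths")
    T = recording.n_samples
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=recording.data.T)
        data1.create_dataset("time",
                             data=np.arange(T, dtype=float) / recording.fs)
        for col in range(2 * n):
            ml = data1.create_group(f"measurementList{col + 1}")
            ml.create_dataset("sourceIndex", data=col % n + 1)
            ml.create_dataset("detectorIndex", data=col % n + 1)
            ml.create_dataset("wavelengthIndex", data=col // n + 1)
            ml.create_dataset("dataType", data=1)        # CW amplitude/OD
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths,
                                                            dtype=float))
        pos = np.zeros((n, 2))
        probe.create_dataset("sourcePos2D", data=pos)
        probe.create_dataset("detectorPos2D", data=pos)
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
    return path


def read_snirf(path) -> Recording:
    """Read the minimal SNIRF subset back into a stacked OD Recording."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            nirs = f["nirs"]
            probe = nirs["probe"]
            if "wavelengths" not in probe:
                raise FormatError(f"{path}: missing /nirs/probe/wavelengths")
            wavelengths = np.asarray(probe["wavelengths"][()], dtype=float)
            data1 = nirs["data1"]
            ts = np.asarray(data1["dataTimeSeries"][()], dtype=float)
            time = np.asarray(data1["time"][()], dtype=float)
            fs = 1.0 / (time[1] - time[0]) if time.size > 2 else 1.0 / time[1]
            cols = sorted(
                (int(k[len("measurementList"):]) for k in data1
                 if k.startswith("measurementList")))
            widx = np.array([
                int(np.asarray(data1[f"measurementList{c}"]
                               ["wavelengthIndex"][()]).item())
                for c in cols])
            srcs = np.array([
                int(np.asarray(data1[f"measurementList{c}"]
                               ["sourceIndex"][()]).item())
                for c in cols])
            dets = np.array([
                int(np.asarray(data1[f"measurementList{c}"]
                               ["detectorIndex"][()]).item())
                for c in cols])
    except FormatError:
        raise
    except (OSError, KeyError, IndexError) as exc:
        raise FormatError(f"could not parse SNIRF {path}: {exc}") from exc
    order = np.lexsort((np.arange(len(cols)), widx))  # wavelength-major
    data = ts.T[order]
    n = int(np.sum(widx == widx.min()))
    names = [f"S{srcs[c]}_D{dets[c]} {wavelengths[widx[c] - 1]:.0f}"
             for c in order]
    return Recording(data=data, fs=float(fs), ch_names=names, kind="od",
                     meta={"wavelengths": list(wavelengths),
                           "n_sd_channels": n, "source": str(path)})


# ---------------------------------------------------------------------------
# delimited tables

def write_delimited(recording: Recording, path) -> Path:
    """CSV with '#'-prefixed metadata lines (fs, kind) and one column per
    channel."""
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# fs={recording.fs!r}\n# kind={recording.kind}\n")
        if "n_sd_channels" in recording.meta:
            f.write(f"# n_sd_channels={recording.meta['n_sd_channels']}\n")
        pd.DataFrame(recording.data.T, columns=recording.ch_names).to_csv(
            f, index=False)
    return path


def read_delimited(path) -> Recording:
    path = Path(path)
    meta: dict = {}
    try:
        with open(path) as f:
            pos = f.tell()
            while True:
                line = f.readline()
                if not line.startswith("#"):
                    f.seek(pos)
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = f.tell()
            df = pd.read_csv(f)
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"could not parse table {path}: {exc}") from exc
    if "fs" not in meta:
        raise FormatError(f"{path}: missing '# fs=' metadata line")
    extra = {}
    if "n_sd_channels" in meta:
        extra["n_sd_channels"] = int(meta["n_sd_channels"])
    return Recording(data=df.to_numpy().T, fs=float(meta["fs"]),
                     ch_names=list(df.columns),
                     kind=meta.get("kind", "eeg"),
                     meta=dict(extra, source=str(path)))


def write_matrix_csv(values: np.ndarray, ch_names, path) -> Path:
    path = Path(path)
    pd.DataFrame(np.asarray(values), index=ch_names,
                 columns=ch_names).to_csv(path)
    return path


def read_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


# ---------------------------------------------------------------------------
# dispatch + cohort export

def read_recording(path, format: str | None = None) -> Recording:
    """Read a Recording from EDF, SNIRF, or a delimited table. Format is
    inferred from the suffix when not given."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or {".edf": "edf", ".snirf": "snirf"}.get(
        path.suffix.lower(), "delimited")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "snirf":
        return read_snirf(path)
    if fmt == "delimited":
        return read_delimited(path)
    raise ParameterError(f"unknown format {format!r}")


def save_cohort(subjects, ground_truth, out_dir) -> Path:
    """Write a synthetic cohort to disk: EDF per subject (EEG), SNIRF per
    subject (fNIRS, OD output) or delimited table (hb output), a
    subject/performance CSV, and a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in subjects:
        write_edf(sub.eeg, out / f"{sub.subject_id}_eeg.edf")
        if sub.fnirs.kind == "od":
            write_snirf(sub.fnirs, out / f"{sub.subject_id}_fnirs.snirf")
        else:
            write_delimited(sub.fnirs, out / f"{sub.subject_id}_fnirs.csv")
        rows.append({"subject_id": sub.subject_id,
                     "performance": sub.performance})
    pd.DataFrame(rows).to_csv(out / "performance.csv", index=False)
    gt = {
        "performance": ground_truth.performance.tolist(),
        "planted_edge_targets": {
            f"{mod}:{i}-{j}": w.tolist()
            for (mod, i, j), w in ground_truth.planted_edge_targets.items()},
        "latent_connectivity": {
            mod: m.tolist()
            for mod, m in ground_truth.latent_connectivity.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(gt))
    return out
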