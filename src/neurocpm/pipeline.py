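"""End-to-end pipeline driver: simulate → EEG features → fNIRS features →
connectivity → LOSO prediction → coupling statistics.

All randomness (cohort generation, ICA initialization, permutations) flows
from named seeds in the configuration; a run writes its resolved config and
a manifest next to its outputs, and can resume from persisted connectivity
matrices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import pearson_connectivity
from .core import MODALITIES, ParameterError, Recording
from .coupling import CouplingReport, coupling_analysis
from .cpm import CohortTable, PredictionReport, SvrSpec, loso_predict
from .eeg import WicaParams, amplitude_modulation, bandpass_broadband, wica_clean
from .formats import read_matrix_csv, write_matrix_csv
from .nirs import MbllParams, process_fnirs
from .synth import CohortSpec, generate_cohort

logger = logging.getLogger("neurocpm")

__all__ = ["PipelineConfig", "run_pipeline", "extract_features",
           "build_cohort_table"]

_EEG_PAIRS = ("beta_m_alpha", "gamma_m_alpha")


@dataclass
class PipelineConfig:
    """Resolved configuration for one end-to-end run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    wica: WicaParams = field(default_factory=WicaParams)
    mbll: MbllParams = field(default_factory=MbllParams)
    apply_wica: bool = True
    modulation_pairs: tuple = _EEG_PAIRS
    edge_trim_s: float = 1.0
    channel_include: list | None = None     # fNIRS channel subset (indices)
    alpha: float = 0.05
    svr: SvrSpec = field(default_factory=SvrSpec)
    n_perm: int = 10_000
    perm_seed: int = 0
    out_dir: str | None = None
    resume: bool = False

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ParameterError("alpha must be in (0, 1]")
        if set(self.modulation_pairs) != set(_EEG_PAIRS):
            # the default pipeline wires exactly the two alpha-modulation pairs
            raise ParameterError(
                "modulation_pairs must be beta_m_alpha and gamma_m_alpha")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return enc(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text_or_path) -> "PipelineConfig":
        s = str(text_or_path)
        raw = s
        if "\n" not in s and len(s) < 1024:
            p = Path(s)
            if p.exists():
                raw = p.read_text()
        d = yaml.safe_load(raw) or {}
        kw = dict(d)
        if "cohort" in kw:
            c = dict(kw["cohort"])
            if "predictive_edges" in c:
                c["predictive_edges"] = tuple(
                    (m, int(i), int(j)) for m, i, j in c["predictive_edges"])
            kw["cohort"] = CohortSpec(**c)
        if "wica" in kw:
            kw["wica"] = WicaParams(**kw["wica"])
        if "mbll" in kw:
            m = dict(kw["mbll"])
            if "extinction" in m:
                m["extinction"] = np.asarray(m["extinction"], dtype=float)
            kw["mbll"] = MbllParams(**m)
        if "svr" in kw:
            kw["svr"] = SvrSpec(**kw["svr"])
        if "modulation_pairs" in kw:
            kw["modulation_pairs"] = tuple(kw["modulation_pairs"])
        return cls(**kw)


def extract_features(eeg: Recording, fnirs: Recording,
                     config: PipelineConfig) -> dict:
    """One subject's four connectivity matrices from raw-like recordings."""
    rec = bandpass_broadband(eeg)
    if config.apply_wica:
        rec = wica_clean(rec, config.wica)
    out = {}
    for pair in config.modulation_pairs:
        am = amplitude_modulation(rec, pair, edge_trim_s=config.edge_trim_s)
        out[pair] = pearson_connectivity(
            am.values, ch_names=am.ch_names, modality=pair,
            trim_s=am.edge_trim_s, fs=am.fs)
    hb = process_fnirs(fnirs, config.mbll)
    hbo, hbr, names = hb.hbo, hb.hbr, hb.ch_names
    if config.channel_include is not None:
        idx = list(config.channel_include)
        hbo, hbr = hbo[idx], hbr[idx]
        names = [names[i] for i in idx]
    out["hbo"] = pearson_connectivity(hbo, ch_names=names, modality="hbo")
    out["hbr"] = pearson_connectivity(hbr, ch_names=names, modality="hbr")
    return out


def build_cohort_table(config: PipelineConfig, subjects=None,
                       ground_truth=None) -> tuple[CohortTable, object]:
    """Simulate (unless given) and extract features for every subject."""
    if subjects is None:
        subjects, ground_truth = generate_cohort(config.cohort)
    bundles, perf = [], []
    for sub in subjects:
        t0 = time.perf_counter()
        feats = extract_features(sub.eeg, sub.fnirs, config)
        for mod in MODALITIES:
            feats[mod].subject_id = sub.subject_id
        logger.info("features %s: %.1f s", sub.subject_id,
                    time.perf_counter() - t0)
        bundles.append(feats)
        perf.append(sub.performance)
    return CohortTable.from_matrices(bundles, perf), ground_truth


def _save_table(table: CohortTable, out: Path) -> None:
    conn = out / "connectivity"
    conn.mkdir(parents=True, exist_ok=True)
    for mod in MODALITIES:
        for s, sid in enumerate(table.subject_ids):
            names = [f"ch{i}" for i in range(table.matrices[mod].shape[1])]
            write_matrix_csv(table.matrices[mod][s], names,
                             conn / f"{sid}_{mod}.csv")
    pd_rows = [{"subject_id": sid, "performance": float(p)}
               for sid, p in zip(table.subject_ids, table.performance)]
    (out / "performance.json").write_text(json.dumps(pd_rows))


def _load_table(out: Path, n_subjects: int) -> CohortTable | None:
    perf_path = out / "performance.json"
    conn = out / "connectivity"
    if not perf_path.exists() or not conn.is_dir():
        return None
    rows = json.loads(perf_path.read_text())
    if len(rows) != n_subjects:
        return None
    ids = [r["subject_id"] for r in rows]
    matrices = {}
    for mod in MODALITIES:
        mats = []
        for sid in ids:
            p = conn / f"{sid}_{mod}.csv"
            if not p.exists():
                return None
            mats.append(read_matrix_csv(p)[0])
        matrices[mod] = np.stack(mats)
    return CohortTable(subject_ids=ids, matrices=matrices,
                       performance=np.array([r["performance"] for r in rows]))


def run_pipeline(config: PipelineConfig
                 ) -> tuple[PredictionReport, CouplingReport]:
    """Execute the full pipeline per the resolved config.

    Persists stage outputs (connectivity matrices, reports, resolved config,
    manifest) under ``config.out_dir`` when set; with ``resume=True`` a
    previously persisted connectivity stage is reloaded instead of being
    recomputed.
    """
    out = Path(config.out_dir) if config.out_dir else None
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    table = None
    if out is not None and config.resume:
        table = _load_table(out, config.cohort.n_subjects)
        if table is not None:
            logger.info("resumed connectivity stage from %s", out)
    if table is None:
        table, _ = build_cohort_table(config)
        if out is not None:
            _save_table(table, out)
    timings["features_connectivity"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    prediction = loso_predict(table, alpha=config.alpha, svr_spec=config.svr)
    timings["cpm_predict"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    coupling = coupling_analysis(table, prediction.fold_masks,
                                 n_perm=config.n_perm, seed=config.perm_seed)
    timings["coupling_stats"] = time.perf_counter() - t0

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        resolved = config.to_yaml()
        (out / "config.yaml").write_text(resolved)
        (out / "prediction.json").write_text(
            json.dumps(prediction.to_dict(), indent=1))
        (out / "coupling.json").write_text(
            json.dumps(coupling.to_dict(), indent=1))
        manifest = {
            "tool": "neurocpm",
            "version": __version__,
            "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
            "numpy": np.__version__,
            "stage_seconds": timings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return prediction, coupling
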