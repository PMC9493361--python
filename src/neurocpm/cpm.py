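"""Connectome-based predictive modeling (CPM) with leave-one-subject-out
cross-validation.

For each left-out subject, every connectivity edge of every modality is
correlated with performance across the *training* subjects; edges with
p <= alpha (inclusive) form a mask; each training subject's masked edge
values are summed into one connectivity summary score (CSS) per modality;
the four CSS features train a linear support vector regressor (C = 1,
epsilon = sd(train performance)/10), which then predicts the left-out
subject's performance from CSS values computed with the training fold's
masks. The left-out subject never contributes to edge selection or fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVR

from .connectivity import ConnectivityMatrix, edge_vector
from .core import MODALITIES, FoldError, ParameterError

__all__ = [
    "CohortTable",
    "EdgeMask",
    "SvrSpec",
    "PredictionReport",
    "edge_performance_correlation",
    "build_mask",
    "css",
    "loso_predict",
    "mae",
]


@dataclass
class CohortTable:
    """Per-subject bundle: one connectivity matrix per modality plus the
    performance score (%). ``matrices[mod]`` has shape (n_subjects, n, n)."""

    subject_ids: list[str]
    matrices: dict
    performance: np.ndarray

    def __post_init__(self):
        self.performance = np.asarray(self.performance, dtype=float)
        n = len(self.subject_ids)
        if self.performance.shape != (n,):
            raise ParameterError("performance length must match subject count")
        for mod in MODALITIES:
            if mod not in self.matrices:
                raise ParameterError(f"missing modality {mod!r}")
            m = np.asarray(self.matrices[mod], dtype=float)
            if m.ndim != 3 or m.shape[0] != n or m.shape[1] != m.shape[2]:
                raise ParameterError(
                    f"matrices[{mod!r}] must be (n_subjects, n, n)")
            self.matrices[mod] = m

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def edge_values(self, modality: str) -> np.ndarray:
        """(n_subjects, n_edges) upper-triangle edge values."""
        mats = self.matrices[modality]
        iu = np.triu_indices(mats.shape[1], k=1)
        return mats[:, iu[0], iu[1]]

    @classmethod
    def from_matrices(cls, per_subject: list[dict], performance) -> "CohortTable":
        """Build from a list of per-subject {modality: ConnectivityMatrix}."""
        ids = []
        stacks = {mod: [] for mod in MODALITIES}
        for k, bundle in enumerate(per_subject):
            first = next(iter(bundle.values()))
            ids.append(getattr(first, "subject_id", "") or f"sub-{k + 1:02d}")
            for mod in MODALITIES:
                m = bundle[mod]
                stacks[mod].append(np.asarray(
                    getattr(m, "values", m), dtype=float))
        return cls(subject_ids=ids,
                   matrices={mod: np.stack(v) for mod, v in stacks.items()},
                   performance=np.asarray(performance, dtype=float))


@dataclass
class EdgeMask:
    """Edge-selection result for one fold and modality: per-edge r and p of
    the edge-vs-performance correlation, and the boolean mask p <= alpha."""

    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    alpha: float = 0.05
    fold_id: str | int | None = None
    modality: str = ""

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class SvrSpec:
    """Linear SVR hyperparameters: C fixed at 1, epsilon estimated per fold
    as a tenth of the training performances' standard deviation."""

    C: float = 1.0
    epsilon_sd_fraction: float = 0.1
    zscore_features: bool = True
    clip_predictions: bool = False

    def __post_init__(self):
        if self.C <= 0:
            raise ParameterError("C must be > 0")
        if self.epsilon_sd_fraction < 0:
            raise ParameterError("epsilon_sd_fraction must be >= 0")


@dataclass
class PredictionReport:
    """LOSO predictions: one out-of-fold prediction per subject, absolute
    errors, and their mean +/- sd (the MAE). ``fold_masks[mod][k]`` is fold
    k's EdgeMask for that modality, kept for the union-mask coupling stage."""

    subject_ids: list[str]
    predicted: np.ndarray
    observed: np.ndarray
    abs_error: np.ndarray
    mae: float
    mae_sd: float
    alpha: float
    fold_masks: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "mae": self.mae,
            "mae_sd": self.mae_sd,
            "subjects": [
                {"subject_id": s, "predicted": float(p), "observed": float(o),
                 "abs_error": float(e)}
                for s, p, o, e in zip(self.subject_ids, self.predicted,
                                      self.observed, self.abs_error)],
        }


def edge_performance_correlation(edge_values: np.ndarray,
                                 performance: np.ndarray
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge Pearson r and two-tailed p of edge value vs performance.

    ``edge_values``: (n_subjects, n_edges); also accepts a list of
    ConnectivityMatrix (converted to edge vectors). p-values use the exact
    beta null distribution of r under bivariate normality (as
    ``scipy.stats.pearsonr``).
    """
    if isinstance(edge_values, (list, tuple)) and edge_values and isinstance(
            edge_values[0], ConnectivityMatrix):
        edge_values = np.stack([edge_vector(m) for m in edge_values])
    x = np.asarray(edge_values, dtype=float)
    y = np.asarray(performance, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ParameterError("need >= 3 training subjects")
    if y.shape != (n,):
        raise ParameterError("performance length must match subject count")
    if np.std(y) == 0:
        raise ParameterError("performance vector constant; correlation undefined")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    r = np.where(denom == 0, 0.0, r)          # constant edge -> r = 0, p = 1
    r = np.clip(r, -1.0, 1.0)
    ab = n / 2.0 - 1.0
    p = 2.0 * stats.beta.sf(np.abs(r), ab, ab, loc=-1, scale=2)
    p = np.where(denom == 0, 1.0, np.clip(p, 0.0, 1.0))
    return r, p


def build_mask(p: np.ndarray, alpha: float = 0.05, r: np.ndarray | None = None,
               fold_id=None, modality: str = "") -> EdgeMask:
    """Select edges with p <= alpha (inclusive threshold)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    mask = p <= alpha
    return EdgeMask(r=(np.zeros_like(p) if r is None else np.asarray(r)),
                    p=p, mask=mask, alpha=alpha, fold_id=fold_id,
                    modality=modality)


def css(edges: np.ndarray | ConnectivityMatrix, mask: EdgeMask | np.ndarray
        ) -> float:
    """Connectivity summary score: signed sum of the masked edge values.
    Empty mask -> 0."""
    if isinstance(edges, ConnectivityMatrix):
        edges = edge_vector(edges)
    edges = np.asarray(edges, dtype=float)
    m = mask.mask if isinstance(mask, EdgeMask) else np.asarray(mask, dtype=bool)
    if edges.shape != m.shape:
        raise ParameterError(
            f"edge vector shape {edges.shape} != mask shape {m.shape}")
    return float(edges[m].sum())


def mae(predicted, observed, ddof: int = 1) -> tuple[float, float]:
    """Mean and standard deviation of absolute errors, on the % scale."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 1:
        raise ParameterError("predicted and observed must be equal-length 1-D")
    err = np.abs(p - o)
    sd = float(np.std(err, ddof=ddof)) if err.size > ddof else 0.0
    return float(err.mean()), sd


def _fold_features(table: CohortTable, train_idx: np.ndarray,
                   test_idx: int | None, alpha: float, fold_id
                   ) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Masks + CSS features for one fold, computed on training subjects only."""
    y_train = table.performance[train_idx]
    feats = np.empty((train_idx.size, len(MODALITIES)))
    test_feats = np.empty(len(MODALITIES)) if test_idx is not None else None
    masks = {}
    for c, mod in enumerate(MODALITIES):
        edges = table.edge_values(mod)
        r, p = edge_performance_correlation(edges[train_idx], y_train)
        em = build_mask(p, alpha, r=r, fold_id=fold_id, modality=mod)
        masks[mod] = em
        feats[:, c] = edges[train_idx][:, em.mask].sum(axis=1)
        if test_idx is not None:
            test_feats[c] = edges[test_idx][em.mask].sum()
    return feats, test_feats, masks


def loso_predict(table: CohortTable, alpha: float = 0.05,
                 svr_spec: SvrSpec | None = None) -> PredictionReport:
    """Leave-one-subject-out CPM prediction.

    Per fold: edge selection and CSS computation on the n-1 training
    subjects (independently per modality), linear SVR fit on the four CSS
    features, prediction for the held-out subject with the training fold's
    masks. Returns per-subject predictions, absolute errors, MAE (mean and
    sd of absolute errors), and the per-fold masks.
    """
    svr_spec = svr_spec or SvrSpec()
    n = table.n_subjects
    if n < 4:
        raise ParameterError("LOSO prediction needs >= 4 subjects")
    predicted = np.empty(n)
    fold_masks: dict = {mod: [] for mod in MODALITIES}
    for k in range(n):
        fold_id = table.subject_ids[k]
        train_idx = np.array([i for i in range(n) if i != k])
        y_train = table.performance[train_idx]
        if np.std(y_train) == 0:
            raise FoldError(fold_id, "training performances constant")
        feats, test_feats, masks = _fold_features(table, train_idx, k, alpha,
                                                  fold_id)
        for mod in MODALITIES:
            fold_masks[mod].append(masks[mod])
        if svr_spec.zscore_features:
            mu = feats.mean(axis=0)
            sd = feats.std(axis=0)
            sd[sd == 0] = 1.0
            feats = (feats - mu) / sd
            test_feats = (test_feats - mu) / sd
        eps = svr_spec.epsilon_sd_fraction * float(np.std(y_train))
        model = SVR(kernel="linear", C=svr_spec.C, epsilon=eps)
        model.fit(feats, y_train)
        pred = float(model.predict(test_feats[np.newaxis, :])[0])
        if svr_spec.clip_predictions:
            pred = float(np.clip(pred, 0.0, 100.0))
        predicted[k] = pred
    err_mean, err_sd = mae(predicted, table.performance)
    return PredictionReport(
        subject_ids=list(table.subject_ids), predicted=predicted,
        observed=table.performance.copy(), abs_error=np.abs(
            predicted - table.performance),
        mae=err_mean, mae_sd=err_sd, alpha=alpha, fold_masks=fold_masks)
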