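"""Cross-modality coupling statistics on connectome summary scores.

After LOSO prediction, each modality's edges selected in *at least one* fold
form a union mask; CSS vectors computed with the union masks (all subjects,
no fold exclusion) are compared pairwise across the six modality
combinations with Pearson correlation, permutation p-values, and
Benjamini-Hochberg FDR correction over the six tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import MODALITIES, ParameterError
from .cpm import CohortTable, EdgeMask, css

__all__ = [
    "UnionMask",
    "CouplingResult",
    "CouplingReport",
    "union_mask",
    "css_vectors",
    "permutation_corr_test",
    "fdr_correct",
    "coupling_analysis",
    "COUPLING_PAIRS",
]

#: The six CSS comparisons: two intra-modality, four inter-modality.
COUPLING_PAIRS = (
    ("hbo", "hbr"),
    ("beta_m_alpha", "gamma_m_alpha"),
    ("hbo", "beta_m_alpha"),
    ("hbo", "gamma_m_alpha"),
    ("hbr", "beta_m_alpha"),
    ("hbr", "gamma_m_alpha"),
)


@dataclass
class UnionMask:
    """Edges selected in >= 1 LOSO fold, with per-edge fold provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)
    modality: str = ""

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class CouplingResult:
    pair: tuple[str, str]
    r: float
    p: float
    q: float = float("nan")


@dataclass
class CouplingReport:
    results: list[CouplingResult]
    n_permutations: int
    css: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "comparisons": [
                {"pair": list(res.pair), "r": res.r, "p": res.p, "q": res.q}
                for res in self.results],
        }


def union_mask(fold_masks: list[EdgeMask | np.ndarray], modality: str = ""
               ) -> UnionMask:
    """Element-wise OR of per-fold masks, recording which folds selected
    each edge."""
    if not fold_masks:
        raise ParameterError("no fold masks given")
    arrays, fold_ids = [], []
    for k, m in enumerate(fold_masks):
        if isinstance(m, EdgeMask):
            arrays.append(np.asarray(m.mask, dtype=bool))
            fold_ids.append(m.fold_id if m.fold_id is not None else k)
        else:
            arrays.append(np.asarray(m, dtype=bool))
            fold_ids.append(k)
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ParameterError("fold masks must share shape")
    out = np.zeros(shape, dtype=bool)
    provenance: dict = {}
    for fid, a in zip(fold_ids, arrays):
        out |= a
        for e in np.flatnonzero(a):
            provenance.setdefault(int(e), set()).add(fid)
    return UnionMask(mask=out, provenance=provenance, modality=modality)


def css_vectors(table: CohortTable, union_masks: dict) -> dict:
    """Per-modality per-subject CSS computed with the union masks; every
    subject included (no fold exclusion at this stage)."""
    out = {}
    for mod in MODALITIES:
        if mod not in union_masks:
            raise ParameterError(f"missing union mask for modality {mod!r}")
        um = union_masks[mod]
        m = um.mask if isinstance(um, UnionMask) else np.asarray(um, dtype=bool)
        edges = table.edge_values(mod)
        out[mod] = np.array([css(edges[s], m) for s in range(table.n_subjects)])
    return out


def permutation_corr_test(x: np.ndarray, y: np.ndarray, n_perm: int = 10_000,
                          seed: int | np.random.Generator = 0,
                          chunk: int = 20_000) -> tuple[float, float]:
    """Two-tailed permutation test of Pearson correlation.

    The null is built by permuting ``y`` across subjects ``n_perm`` times;
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), which is positively
    biased (never zero) and exact for exchangeable nulls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ParameterError("need length >= 3")
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("constant vector; correlation undefined")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    xs = (x - x.mean()) / (x.std() * np.sqrt(n))
    ys = (y - y.mean()) / (y.std() * np.sqrt(n))
    r_obs = float(np.clip(xs @ ys, -1.0, 1.0))
    count = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(ys, (b, n)).copy(), axis=1)
        r_perm = perms @ xs
        count += int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        done += b
    p = (1 + count) / (1 + n_perm)
    return r_obs, float(p)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def coupling_analysis(table: CohortTable, fold_masks: dict,
                      n_perm: int = 1_000_000, seed: int = 0
                      ) -> CouplingReport:
    """Full coupling pipeline: union masks from the LOSO fold masks, CSS
    vectors over all subjects, the six pairwise permutation correlation
    tests, and BH-FDR over the six p-values."""
    unions = {mod: union_mask(fold_masks[mod], modality=mod)
              for mod in MODALITIES}
    vectors = css_vectors(table, unions)
    rng = np.random.default_rng(seed)
    results = []
    for a, b in COUPLING_PAIRS:
        va, vb = vectors[a], vectors[b]
        if np.std(va) == 0 or np.std(vb) == 0:
            # empty/degenerate union mask: no coupling estimate possible
            results.append(CouplingResult(pair=(a, b), r=float("nan"), p=1.0))
            continue
        r, p = permutation_corr_test(va, vb, n_perm=n_perm, seed=rng)
        results.append(CouplingResult(pair=(a, b), r=r, p=p))
    q = fdr_correct([res.p for res in results])
    for res, qv in zip(results, q):
        res.q = float(qv)
    return CouplingReport(results=results, n_permutations=n_perm, css=vectors)
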