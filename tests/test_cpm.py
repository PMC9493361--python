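"""Connectome-based prediction: edge selection, CSS, LOSO SVR, MAE."""

import numpy as np
import pytest
from scipy import stats
from sklearn.svm import SVR

from neurocpm import MODALITIES
from neurocpm.core import FoldError, ParameterError
from neurocpm.cpm import (CohortTable, SvrSpec, build_mask, css,
                          edge_performance_correlation, loso_predict, mae)

from conftest import random_cohort_table


class TestEdgePerformanceCorrelation:
    def test_perfect_edge(self, rng):
        y = rng.uniform(0, 100, 8)
        edges = rng.standard_normal((8, 5))
        edges[:, 2] = y
        r, p = edge_performance_correlation(edges, y)
        assert r[2] == pytest.approx(1.0, abs=1e-12)
        assert p[2] < 1e-10

    def test_matches_pearsonr_oracle(self, rng):
        edges = rng.standard_normal((5, 12))
        y = rng.uniform(0, 100, 5)
        r, p = edge_performance_correlation(edges, y)
        for e in range(12):
            ref = stats.pearsonr(edges[:, e], y)
            assert abs(r[e] - ref.statistic) < 1e-12
            assert abs(p[e] - ref.pvalue) < 1e-12

    def test_null_calibration(self, rng):
        """Independent performance: the p <= 0.05 selection rate is 5%."""
        hits = total = 0
        for _ in range(1000):
            edges = rng.standard_normal((30, 50))
            y = rng.standard_normal(30)
            _, p = edge_performance_correlation(edges, y)
            hits += np.sum(p <= 0.05)
            total += p.size
        assert abs(hits / total - 0.05) < 0.02

    def test_errors(self, rng):
        with pytest.raises(ParameterError, match="constant"):
            edge_performance_correlation(rng.standard_normal((5, 3)),
                                         np.full(5, 7.0))
        with pytest.raises(ParameterError, match="3"):
            edge_performance_correlation(rng.standard_normal((2, 3)),
                                         np.array([1.0, 2.0]))


class TestMaskAndCss:
    def test_mask_threshold_inclusive(self):
        p = np.array([1.0, 0.05, 0.051, 0.0])
        m = build_mask(p, alpha=0.05)
        assert list(m.mask) == [False, True, False, True]
        assert build_mask(np.ones(6)).n_selected == 0

    def test_mask_matches_enumeration(self, rng):
        p = rng.uniform(0, 1, 300)
        m = build_mask(p, 0.05)
        assert m.n_selected == sum(1 for v in p if v <= 0.05)
        assert np.array_equal(m.mask, np.array([v <= 0.05 for v in p]))

    def test_css_cases(self, rng):
        edges = rng.standard_normal(28)
        assert css(edges, np.zeros(28, dtype=bool)) == 0.0
        single = np.zeros(28, dtype=bool)
        single[7] = True
        edges[7] = 0.42
        assert css(edges, single) == pytest.approx(0.42, abs=1e-15)
        mask = np.zeros(28, dtype=bool)
        mask[rng.choice(28, 10, replace=False)] = True
        loop = sum(edges[i] for i in range(28) if mask[i])
        assert abs(css(edges, mask) - loop) < 1e-12
        with pytest.raises(ParameterError, match="shape"):
            css(edges, np.zeros(27, dtype=bool))


class TestMae:
    def test_forced_arithmetic(self):
        assert mae([50.0, 60.0], [40.0, 80.0])[0] == pytest.approx(15.0)
        assert mae([3.0, 4.0], [3.0, 4.0]) == (0.0, 0.0)

    def test_loop_oracle(self, rng):
        p = rng.uniform(0, 100, 31)
        o = rng.uniform(0, 100, 31)
        m, sd = mae(p, o)
        errs = [abs(a - b) for a, b in zip(p, o)]
        assert abs(m - sum(errs) / 31) < 1e-12
        mean = sum(errs) / 31
        var = sum((e - mean) ** 2 for e in errs) / 30
        assert abs(sd - np.sqrt(var)) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            mae([1.0], [1.0, 2.0])


class TestLoso:
    def test_each_subject_predicted_once(self, rng):
        table = random_cohort_table(rng, n_subjects=8)
        rep = loso_predict(table)
        assert len(rep.predicted) == 8
        assert rep.subject_ids == table.subject_ids
        for mod in MODALITIES:
            assert len(rep.fold_masks[mod]) == 8
        assert rep.mae == pytest.approx(np.mean(rep.abs_error), abs=1e-12)

    def test_constant_features_ignore_test_subject(self, rng):
        """With constant CSS features, the fitted SVR has a zero weight
        vector: predictions do not depend on the held-out subject's data."""
        n = 8
        base = random_cohort_table(rng, n_subjects=1)
        matrices = {mod: np.repeat(base.matrices[mod], n, axis=0)
                    for mod in MODALITIES}
        table = CohortTable(subject_ids=[f"s{i}" for i in range(n)],
                            matrices=matrices,
                            performance=rng.uniform(20, 80, n))
        rep = loso_predict(table)
        other = random_cohort_table(rng, n_subjects=n)
        k = 3
        for mod in MODALITIES:
            matrices[mod][k] = other.matrices[mod][k]
        rep2 = loso_predict(CohortTable(
            subject_ids=table.subject_ids, matrices=matrices,
            performance=table.performance))
        assert rep2.predicted[k] == rep.predicted[k]

    def test_alpha_one_saturates_to_full_edge_sum(self, rng):
        table = random_cohort_table(rng, n_subjects=6)
        rep = loso_predict(table, alpha=1.0)
        for mod in MODALITIES:
            for m in rep.fold_masks[mod]:
                assert m.mask.all()
            full = table.edge_values(mod).sum(axis=1)
            assert np.allclose(
                [css(table.edge_values(mod)[s], rep.fold_masks[mod][0])
                 for s in range(6)], full, atol=1e-12)

    def test_too_few_or_degenerate(self, rng):
        with pytest.raises(ParameterError, match="4"):
            loso_predict(random_cohort_table(rng, n_subjects=3))
        table = random_cohort_table(rng, n_subjects=5)
        table.performance[:] = 50.0
        with pytest.raises(FoldError, match="s0"):
            loso_predict(table)

    def test_leakage_audit(self, rng):
        """Each fold's mask and prediction are reproduced bit-identically
        from a process in which the left-out subject's data never exists."""
        table = random_cohort_table(rng, n_subjects=9)
        rep = loso_predict(table)
        spec = SvrSpec()
        for k in (0, 4, 8):
            train = np.array([i for i in range(9) if i != k])
            y = table.performance[train]
            feats = np.empty((8, 4))
            test_feats = np.empty(4)
            for c, mod in enumerate(MODALITIES):
                edges = table.edge_values(mod)
                r, p = edge_performance_correlation(edges[train], y)
                stored = rep.fold_masks[mod][k]
                assert np.array_equal(r, stored.r)
                assert np.array_equal(p, stored.p)
                assert np.array_equal(p <= 0.05, stored.mask)
                feats[:, c] = edges[train][:, stored.mask].sum(axis=1)
                test_feats[c] = edges[k][stored.mask].sum()
            mu, sd = feats.mean(axis=0), feats.std(axis=0)
            sd[sd == 0] = 1.0
            model = SVR(kernel="linear", C=spec.C,
                        epsilon=0.1 * float(np.std(y)))
            model.fit((feats - mu) / sd, y)
            pred = float(model.predict(((test_feats - mu) / sd)[None])[0])
            assert pred == rep.predicted[k]

    def test_invalid_cohort_table(self, rng):
        table = random_cohort_table(rng, n_subjects=5)
        bad = dict(table.matrices)
        bad.pop("hbo")
        with pytest.raises(ParameterError, match="hbo"):
            CohortTable(subject_ids=table.subject_ids, matrices=bad,
                        performance=table.performance)
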