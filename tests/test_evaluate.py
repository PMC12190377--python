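"""Metrics identities, fold hygiene, cross-validation plumbing, t-SNE."""

import numpy as np
import pytest

import brainwin as bw
from brainwin.core import SubjectRecord
from brainwin.evaluate import METRIC_NAMES


def _records(n, balanced=True, sites=("A",)):
    recs = []
    for i in range(n):
        recs.append(
            SubjectRecord(
                subject_id=f"s{i:03d}",
                site=sites[i % len(sites)],
                label=(i % 2) if balanced else (1 if i < n // 3 else 0),
            )
        )
    return recs


class TestContingencyMetrics:
    def test_worked_case(self):
        m = bw.contingency_metrics(tp=3, tn=4, fp=1, fn=2)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 / 3, abs=1e-4)
        assert m.specificity == pytest.approx(0.8)
        assert not m.undefined

    def test_perfect_classifier(self):
        m = bw.contingency_metrics(tp=2, tn=2, fp=0, fn=0)
        for name in METRIC_NAMES:
            assert getattr(m, name) == 1.0

    def test_degenerate_denominators_flagged(self):
        m = bw.contingency_metrics(tp=0, fp=0, tn=5, fn=5)
        assert "precision" in m.undefined and np.isnan(m.precision)
        assert m.recall == 0.0
        assert m.specificity == 1.0
        assert "f1" in m.undefined

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bw.contingency_metrics(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bw.contingency_metrics(-1, 1, 1, 1)

    def test_matches_sklearn_on_grid(self):
        """Independent oracle: rebuild label vectors, score with sklearn."""
        from sklearn import metrics as skm

        for tp in range(0, 5):
            for tn in range(0, 5):
                for fp in range(0, 5):
                    for fn in range(0, 5):
                        if tp + tn + fp + fn == 0:
                            continue
                        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
                        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
                        m = bw.contingency_metrics(tp, tn, fp, fn)
                        assert m.accuracy == pytest.approx(
                            skm.accuracy_score(y_true, y_pred)
                        )
                        if "precision" not in m.undefined:
                            assert m.precision == pytest.approx(
                                skm.precision_score(y_true, y_pred, zero_division=np.nan)
                            )
                        if "recall" not in m.undefined:
                            assert m.recall == pytest.approx(
                                skm.recall_score(y_true, y_pred, zero_division=np.nan)
                            )
                        if "f1" not in m.undefined and m.f1 > 0:
                            assert m.f1 == pytest.approx(
                                skm.f1_score(y_true, y_pred)
                            )

    def test_f1_between_harmonic_bounds(self):
        for tp in range(1, 8):
            for fp in range(0, 8):
                for fn in range(0, 8):
                    m = bw.contingency_metrics(tp, 1, fp, fn)
                    if "f1" in m.undefined:
                        continue
                    assert m.f1 <= (m.precision + m.recall) / 2 + 1e-12
                    assert m.f1 >= min(m.precision, m.recall) - 1e-12
                    if m.precision == m.recall:
                        assert m.f1 == pytest.approx(m.precision)


class TestKFoldSplit:
    def test_equal_fold_sizes(self):
        folds = bw.kfold_split(_records(10), K=5, seed=0)
        sizes = [len(folds.test_indices(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_stratified_class_balance(self):
        recs = _records(40)
        folds = bw.kfold_split(recs, K=5, stratified=True, seed=1)
        for f in range(5):
            labels = [recs[i].label for i in folds.test_indices(f)]
            assert labels.count(0) == labels.count(1) == 4

    def test_seed_determinism(self):
        recs = _records(17)
        a = bw.kfold_split(recs, K=5, seed=3)
        b = bw.kfold_split(recs, K=5, seed=3)
        assert a.fold_of == b.fold_of

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            bw.kfold_split(_records(4), K=5)

    def test_partition_properties_over_seeds(self):
        recs = _records(23)
        for seed in range(100):
            folds = bw.kfold_split(recs, K=5, seed=seed)
            all_idx = np.concatenate([folds.test_indices(f) for f in range(5)])
            assert sorted(all_idx) == list(range(23))  # disjoint and covering
            sizes = [len(folds.test_indices(f)) for f in range(5)]
            assert max(sizes) - min(sizes) <= 1


class _StubPredictor:
    def __init__(self, fn):
        self.fn = fn

    def predict(self, rec, vol):
        return self.fn(rec)


class TestCrossValidate:
    def test_oracle_stub_scores_perfectly(self):
        recs = _records(20, sites=("A", "B"))
        cfg = bw.toy_pipeline_config()
        rep = bw.cross_validate(
            recs, cfg, K=5, seed=0,
            pipeline_factory=lambda tr, vols, s: _StubPredictor(lambda r: r.label),
        )
        for m in rep.per_fold:
            for name in METRIC_NAMES:
                assert getattr(m, name) == 1.0
        assert set(rep.per_site) == {"A", "B"}

    def test_always_negative_stub_on_balanced_cohort(self):
        recs = _records(20)
        cfg = bw.toy_pipeline_config()
        rep = bw.cross_validate(
            recs, cfg, K=5, seed=0,
            pipeline_factory=lambda tr, vols, s: _StubPredictor(lambda r: 0),
        )
        assert rep.mean["accuracy"] == pytest.approx(0.5)
        assert rep.mean["recall"] == 0.0
        assert rep.mean["specificity"] == 1.0

    def test_report_mean_is_arithmetic_mean(self):
        recs = _records(30)
        cfg = bw.toy_pipeline_config()
        rng = np.random.default_rng(5)
        rep = bw.cross_validate(
            recs, cfg, K=5, seed=2,
            pipeline_factory=lambda tr, vols, s: _StubPredictor(
                lambda r: int(rng.random() < 0.5)
            ),
        )
        accs = [m.accuracy for m in rep.per_fold]
        assert rep.mean["accuracy"] == pytest.approx(np.mean(accs), abs=1e-9)

    def test_subject_level_hygiene(self):
        """No subject appears in both train and test of any fold."""
        recs = _records(24)
        seen = {}

        def factory(train_recs, vols, seed):
            fold_train_ids = {r.subject_id for r in train_recs}
            seen[len(seen)] = fold_train_ids
            return _StubPredictor(lambda r: r.label)

        rep = bw.cross_validate(recs, bw.toy_pipeline_config(), K=4, seed=0,
                                pipeline_factory=factory)
        fold_of = rep.metadata["fold_of"]
        ids = rep.metadata["subject_ids"]
        for fold, train_ids in seen.items():
            test_ids = {ids[i] for i in range(len(ids)) if fold_of[i] == fold}
            assert not (train_ids & test_ids)
            assert train_ids | test_ids == set(ids)

    def test_report_json_roundtrip(self, tmp_path):
        import json

        recs = _records(10)
        rep = bw.cross_validate(
            recs, bw.toy_pipeline_config(), K=2, seed=0,
            pipeline_factory=lambda tr, vols, s: _StubPredictor(lambda r: r.label),
        )
        path = bw.write_report(rep, tmp_path / "report.json")
        loaded = json.loads(path.read_text())
        assert loaded["mean"]["accuracy"] == 1.0
        assert "config_hash" in loaded["metadata"]


class TestTSNE:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 8))
        labels = rng.integers(0, 2, 30)
        a = bw.tsne_embed(x, labels, seed=4)
        b = bw.tsne_embed(x, labels, seed=4)
        assert a.shape == (30, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_stay_separated(self, tmp_path):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(1)
        x = np.vstack([
            rng.normal(0.0, 1.0, (25, 10)),
            rng.normal(10.0, 1.0, (25, 10)),
        ])
        labels = np.r_[np.zeros(25, int), np.ones(25, int)]
        emb = bw.tsne_embed(x, labels, seed=0, out_path=tmp_path / "tsne.png")
        assert silhouette_score(emb, labels) > 0.5
        assert (tmp_path / "tsne.png").exists()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            bw.tsne_embed(np.zeros((4, 3)), [0, 1, 0, 1], seed=0)

    def test_too_few_dims_rejected(self):
        with pytest.raises(ValueError, match="d >= 2"):
            bw.tsne_embed(np.zeros((10, 1)), np.zeros(10), seed=0)
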