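"""Label remapping, LOSO folds, metrics, and training-loop contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score, recall_score

from dual_atme.evalproto import (MappingError, ProtocolError, TrainConfig,
                                 UndefinedMetricsError,
                                 build_composite_manifest, compute_metrics,
                                 confusion_matrix, evaluate_loso, loso_splits,
                                 remap_label, train)
from dual_atme.objective import LossConfig
from dual_atme.model import BranchConfig
from dual_atme.synthdata import CLASSES

# published per-corpus raw emotion counts
RAW_COUNTS = {
    "SMIC": {"Negative": 70, "Positive": 51, "Surprise": 43},
    "CASMEII": {"Disgust": 63, "Fear": 2, "Happiness": 32, "Repression": 27,
                "Sadness": 7, "Surprise": 25, "Others": 99},
    "SAMM": {"Anger": 57, "Contempt": 12, "Disgust": 9, "Fear": 8,
             "Happiness": 26, "Sadness": 6, "Surprise": 15, "Others": 26},
}


def records_from_counts(counts):
    rows = []
    for source, table in counts.items():
        i = 0
        for raw, n in table.items():
            for _ in range(n):
                rows.append({"sample_id": f"{source}_{i:04d}",
                             "subject_id": f"{source}_s{i % 7}",
                             "source": source, "raw_label": raw})
                i += 1
    return pd.DataFrame(rows)


class TestRemap:
    @pytest.mark.parametrize("source, raw, expected", [
        ("SAMM", "Contempt", "Negative"),
        ("SAMM", "Fear", "Negative"),
        ("CASMEII", "Happiness", "Positive"),
        ("CASMEII", "Repression", "Negative"),
        ("SMIC", "Surprise", "Surprise"),
        ("CASMEII", "Others", None),
        ("SAMM", "Others", None),
        ("CASMEII", "Fear", None),
    ])
    def test_mapping_table(self, source, raw, expected):
        assert remap_label(source, raw) == expected

    def test_unknown_raw_label_lists_valid(self):
        with pytest.raises(MappingError, match="Disgust"):
            remap_label("CASMEII", "Joy")

    def test_unknown_source(self):
        with pytest.raises(MappingError):
            remap_label("MMEW", "Happiness")


class TestCompositeManifest:
    def test_published_raw_counts(self):
        with pytest.warns(UserWarning, match="CASMEII"):
            manifest, counts = build_composite_manifest(records_from_counts(RAW_COUNTS))
        by_source = counts.set_index("source")
        assert by_source.loc["SAMM", "Negative"] == 92
        assert by_source.loc["SAMM", list(CLASSES)].sum() == 133
        assert by_source.loc["SMIC", list(CLASSES)].sum() == 164
        # raw Disgust 63 + Repression 27 = 90, two more than the published 88
        assert by_source.loc["CASMEII", "Negative"] == 90
        assert len(manifest) == counts.set_index("source").loc["total", list(CLASSES)].sum()

    def test_dropped_labels_not_retained(self):
        manifest, _ = build_composite_manifest(pd.DataFrame([
            {"sample_id": "a", "subject_id": "s1", "source": "CASMEII", "raw_label": "Others"},
            {"sample_id": "b", "subject_id": "s1", "source": "CASMEII", "raw_label": "Disgust"},
        ]))
        assert list(manifest["sample_id"]) == ["b"]
        assert list(manifest["composite_label"]) == ["Negative"]

    def test_empty_input(self):
        manifest, counts = build_composite_manifest(pd.DataFrame(
            columns=["sample_id", "subject_id", "source", "raw_label"]))
        assert len(manifest) == 0 and len(counts) == 0


class TestLosoSplits:
    def _manifest(self, sizes):
        rows = []
        for si, n in enumerate(sizes):
            for k in range(n):
                rows.append({"sample_id": f"s{si}_{k}", "subject_id": f"subj{si}",
                             "source": "SYNTH", "composite_label": "Negative"})
        return pd.DataFrame(rows)

    def test_fold_sizes(self):
        folds = loso_splits(self._manifest([2, 3, 4]))
        assert sorted(len(test) for _, _, test in folds) == [2, 3, 4]

    def test_single_subject_raises(self):
        with pytest.raises(ProtocolError):
            loso_splits(self._manifest([5]))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=2, max_size=8),
           st.randoms(use_true_random=False))
    def test_folds_disjoint_exhaustive_subject_pure(self, sizes, rnd):
        manifest = self._manifest(sizes).sample(frac=1.0, random_state=rnd.randint(0, 10**6))
        manifest = manifest.reset_index(drop=True)
        folds = loso_splits(manifest)
        assert len(folds) == len(sizes)
        all_test = np.concatenate([test for _, _, test in folds])
        assert sorted(all_test) == list(range(len(manifest)))
        for subject, train_idx, test_idx in folds:
            assert set(train_idx).isdisjoint(test_idx)
            assert set(manifest.iloc[test_idx]["subject_id"]) == {subject}
            assert subject not in set(manifest.iloc[train_idx]["subject_id"])


class TestMetrics:
    def test_perfect_predictor(self):
        m = compute_metrics(np.diag([5, 3, 2]))
        assert (m.acc, m.uar, m.uf1) == (1.0, 1.0, 1.0)

    def test_constant_predictor_on_composite_counts(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[:, 0] = [250, 109, 83]          # always predict Negative
        m = compute_metrics(cm)
        assert m.acc == pytest.approx(250 / 442)
        assert m.uar == pytest.approx(1 / 3)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 30), min_size=9, max_size=9))
    def test_matches_sklearn_macro_metrics(self, entries):
        cm = np.array(entries).reshape(3, 3)
        if cm.sum() == 0 or (cm.sum(axis=1) == 0).any():
            return                         # oracle undefined for absent classes
        y_true = np.repeat(np.arange(3), cm.sum(axis=1))
        y_pred = np.concatenate([np.repeat(np.arange(3), row) for row in cm])
        m = compute_metrics(cm)
        assert m.uar == pytest.approx(recall_score(y_true, y_pred, average="macro",
                                                   zero_division=0), abs=1e-12)
        assert m.uf1 == pytest.approx(f1_score(y_true, y_pred, average="macro",
                                               zero_division=0), abs=1e-12)
        assert m.acc == pytest.approx((y_true == y_pred).mean(), abs=1e-12)

    def test_absent_class_excluded_from_macro(self):
        cm = np.array([[4, 1, 0], [2, 3, 0], [0, 0, 0]])
        m = compute_metrics(cm)
        assert m.uar == pytest.approx((4 / 5 + 3 / 5) / 2)

    def test_all_zero_matrix_raises(self):
        with pytest.raises(UndefinedMetricsError):
            compute_metrics(np.zeros((3, 3), dtype=int))


class TestTrain:
    def test_smoke_and_determinism(self, tiny_manifest, tiny_features):
        cfg = TrainConfig(epochs=1, batch_size=8, seed=5)
        r1 = train(cfg, tiny_manifest, tiny_features)
        r2 = train(cfg, tiny_manifest, tiny_features)
        assert np.isfinite(r1.history[["cls", "con", "total"]].to_numpy()).all()
        assert r1.history.iloc[0]["total"] == r2.history.iloc[0]["total"]

    def test_shared_branch_input_drives_contrast_down(self, tiny_manifest, tiny_features):
        """Feeding the puzzled branch the full-face feature, the contrastive
        term is optimised toward 0 over training."""
        shared = {k: (e, e) for k, (e, _) in tiny_features.items()}
        cfg = TrainConfig(epochs=8, batch_size=18, seed=0,
                          loss=LossConfig(lam=0.1), augment=False)
        result = train(cfg, tiny_manifest, shared)
        con = result.history["con"].to_numpy()
        assert con[-1] < con[0]
        assert con[-1] < 0.35

    def test_missing_features_raise(self, tiny_manifest):
        with pytest.raises(KeyError):
            train(TrainConfig(epochs=1), tiny_manifest, {})


class TestEvaluateLoso:
    def _stub(self, fn):
        def factory(train_mf, features, fold_seed):
            return fn
        return factory

    def test_perfect_oracle_stub(self, tiny_manifest, tiny_features):
        oracle = self._stub(lambda mf: [CLASSES.index(c) for c in mf["composite_label"]])
        report = evaluate_loso(TrainConfig(), tiny_manifest, tiny_features,
                               predictor_factory=oracle)
        assert report.pooled.acc == report.pooled.uar == report.pooled.uf1 == 1.0

    def test_constant_stub_matches_counting(self, tiny_manifest, tiny_features):
        constant = self._stub(lambda mf: np.zeros(len(mf), dtype=int))
        report = evaluate_loso(TrainConfig(), tiny_manifest, tiny_features,
                               predictor_factory=constant)
        n_neg = (tiny_manifest["composite_label"] == "Negative").sum()
        assert report.pooled.acc == pytest.approx(n_neg / len(tiny_manifest))
        assert report.pooled.uar == pytest.approx(1 / 3)

    def test_pooled_matrix_is_fold_sum(self, tiny_manifest, tiny_features):
        constant = self._stub(lambda mf: np.ones(len(mf), dtype=int))
        report = evaluate_loso(TrainConfig(), tiny_manifest, tiny_features,
                               predictor_factory=constant)
        np.testing.assert_array_equal(report.pooled_confusion,
                                      np.sum(report.fold_confusions, axis=0))
        assert report.pooled_confusion.sum() == len(tiny_manifest)

    def test_trained_fold_end_to_end_smoke(self, tiny_manifest, tiny_features):
        """One real (tiny) LOSO pass trains and predicts without error."""
        cfg = TrainConfig(epochs=2, batch_size=12, seed=0)
        small = BranchConfig(hidden_units=32)
        report = evaluate_loso(cfg, tiny_manifest, tiny_features, model_config=small)
        assert report.pooled_confusion.sum() == len(tiny_manifest)
        assert report.seeds == [0, 1, 2]


def test_confusion_matrix_convention():
    cm = confusion_matrix([0, 0, 1, 2], [0, 1, 1, 0], 3)
    np.testing.assert_array_equal(cm, [[1, 1, 0], [0, 1, 0], [1, 0, 0]])
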