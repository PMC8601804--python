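import math

import numpy as np
import pandas as pd
import pytest

from cryclass.features import FeatureMatrix
from cryclass.gsvn import (
    GsvnModel,
    MemberModel,
    SchemaError,
    StratificationError,
    boosting_vote_weight,
    grid_search,
    predict,
    predict_clip,
    train_gsvn,
)


class TestVoteWeight:
    def test_closed_form_eps_03_k3(self):
        assert boosting_vote_weight(0.3, 3) == pytest.approx(
            math.log(0.7 / 0.3) + math.log(2), abs=1e-10
        )
        assert boosting_vote_weight(0.3, 3) == pytest.approx(1.5404, abs=5e-4)

    def test_chance_member_gets_zero(self):
        assert boosting_vote_weight(2 / 3, 3) == 0.0
        assert boosting_vote_weight(0.8, 3) == 0.0

    def test_perfect_member_capped(self):
        assert boosting_vote_weight(0.0, 3) == math.log(1e6)


class TestGridSearch:
    def test_separated_blobs_tie_breaks_to_smallest(self, blobs):
        fm = blobs(n_per_class=20, separation=10.0, seed=0, classes=("a", "b"))
        C, gamma = grid_search(fm, C_grid=(1, 3, 33), gamma_grid=(0.1, 0.5, 1.0), seed=0)
        assert (C, gamma) == (1, 0.1)

    def test_xor_needs_nonlinear_kernel(self):
        rng = np.random.default_rng(0)
        n = 50
        pts = np.vstack(
            [rng.normal([s1, s2], 0.3, size=(n, 2))
             for s1 in (-1, 1) for s2 in (-1, 1)]
        )
        labels = ["a"] * n + ["b"] * n + ["b"] * n + ["a"] * n
        fm = FeatureMatrix(pd.DataFrame(pts, columns=["mfcc_1", "mfcc_2"]), pd.Series(labels))
        C, gamma = grid_search(fm, C_grid=(1, 3, 33), gamma_grid=(0.1, 0.5, 1.0, 2.0), seed=0)
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X = StandardScaler().fit_transform(pts)
        acc = SVC(kernel="rbf", C=C, gamma=gamma).fit(X, labels).score(X, labels)
        assert acc > 0.9

    def test_single_class_rejected(self):
        fm = FeatureMatrix(
            pd.DataFrame({"mfcc_1": np.arange(20.0)}), pd.Series(["a"] * 20)
        )
        with pytest.raises(StratificationError):
            grid_search(fm, seed=0)

    def test_tiny_class_rejected(self):
        fm = FeatureMatrix(
            pd.DataFrame({"mfcc_1": np.arange(12.0)}),
            pd.Series(["a"] * 10 + ["b"] * 2),
        )
        with pytest.raises(StratificationError):
            grid_search(fm, folds=3, seed=0)


class TestTrainGsvn:
    def test_separable_blobs_members_accurate(self, blobs):
        fm = blobs(n_per_class=100, separation=8.0, seed=1)
        model = train_gsvn(fm, n_members=10, C=1.0, gamma=0.5, seed=1)
        assert all(m.val_accuracy > 0.95 for m in model.members)
        labels, _ = predict(model, fm)
        assert np.mean(labels == fm.labels.to_numpy()) == 1.0

    def test_committee_of_one_equals_base_svm(self, blobs):
        fm = blobs(n_per_class=30, separation=3.0, seed=2)
        model = train_gsvn(fm, n_members=1, C=1.0, gamma=0.5, seed=3)
        member = model.members[0]
        labels, _ = predict(model, fm)
        np.testing.assert_array_equal(labels, member.predict(fm.X.to_numpy()))

    def test_deterministic(self, blobs):
        fm = blobs(n_per_class=30, separation=2.0, seed=4)
        m1 = train_gsvn(fm, n_members=5, C=1.0, gamma=0.5, seed=7)
        m2 = train_gsvn(fm, n_members=5, C=1.0, gamma=0.5, seed=7)
        l1, s1 = predict(m1, fm)
        l2, s2 = predict(m2, fm)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(s1, s2)
        assert [m.vote_weight for m in m1.members] == [m.vote_weight for m in m2.members]

    def test_too_few_rows_rejected(self):
        fm = FeatureMatrix(
            pd.DataFrame({"mfcc_1": np.arange(6.0)}),
            pd.Series(["a", "a", "a", "b", "b", "b"]),
        )
        with pytest.raises(StratificationError):
            train_gsvn(fm, n_members=2, seed=0)

    def test_accuracy_improves_with_separation(self, blobs):
        """Ensemble test accuracy is non-decreasing as blob separation grows."""
        accs = []
        for sep in (1.0, 2.0, 4.0):
            tr = blobs(n_per_class=60, separation=sep, seed=10)
            te = blobs(n_per_class=40, separation=sep, seed=11)
            model = train_gsvn(tr, n_members=10, C=1.0, gamma=0.5, seed=0)
            labels, _ = predict(model, te)
            accs.append(float(np.mean(labels == te.labels.to_numpy())))
        assert accs[1] >= accs[0] - 0.02
        assert accs[2] >= accs[1] - 0.02

    def test_bagging_mode_vote_weights_are_accuracies(self, blobs):
        fm = blobs(n_per_class=30, separation=4.0, seed=5)
        model = train_gsvn(fm, n_members=4, C=1.0, gamma=0.5, seed=0, mode="bag")
        for m in model.members:
            assert m.vote_weight == m.val_accuracy


class TestPredict:
    @staticmethod
    def _fixed_model(member_specs, classes, schema=("mfcc_1",)):
        """Members with canned predictions via tiny fitted SVMs are awkward;
        build them by monkeypatching predict on real MemberModel objects."""
        members = []
        for pred_label, weight in member_specs:
            m = MemberModel.__new__(MemberModel)
            m.scaler = None
            m.svm = None
            m.C = 1.0
            m.gamma = 0.1
            m.vote_weight = weight
            m.val_accuracy = 1.0
            m.predict = (lambda lbl: lambda X: np.array([lbl] * len(X)))(pred_label)
            members.append(m)
        return GsvnModel(members, list(classes), list(schema), {"C": 1, "gamma": 0.1}, "clip", 0)

    def test_weighted_vote_arithmetic(self):
        model = self._fixed_model([("A", 0.9), ("B", 0.4), ("B", 0.4)], ["A", "B"])
        rows = pd.DataFrame({"mfcc_1": [0.0]})
        labels, scores = predict(model, rows)
        assert labels[0] == "A"  # 0.9 > 0.8
        np.testing.assert_allclose(scores[0], [0.9 / 1.7, 0.8 / 1.7])

    def test_unanimous_vote_normalized_score_one(self):
        model = self._fixed_model([("C", 0.5), ("C", 0.2)], ["A", "B", "C"])
        labels, scores = predict(model, pd.DataFrame({"mfcc_1": [1.0, 2.0]}))
        assert list(labels) == ["C", "C"]
        np.testing.assert_allclose(scores[:, 2], 1.0)

    def test_exact_tie_goes_to_class_order(self):
        model = self._fixed_model([("A", 0.5), ("B", 0.5)], ["A", "B"])
        labels, _ = predict(model, pd.DataFrame({"mfcc_1": [0.0]}))
        assert labels[0] == "A"

    def test_scores_sum_to_one(self, blobs):
        fm = blobs(n_per_class=20, separation=2.0, seed=6)
        model = train_gsvn(fm, n_members=5, C=1.0, gamma=0.5, seed=0)
        _, scores = predict(model, fm)
        assert np.all(scores >= 0)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0)

    def test_schema_mismatch_reports_columns(self, blobs):
        fm = blobs(n_per_class=20, separation=2.0, seed=6)
        model = train_gsvn(fm, n_members=2, C=1.0, gamma=0.5, seed=0)
        bad = fm.X.rename(columns={"mfcc_1": "bogus"})
        with pytest.raises(SchemaError, match="mfcc_1"):
            predict(model, bad)


class TestPredictClip:
    def test_unanimous_frames(self, blobs):
        fm = blobs(n_per_class=30, separation=6.0, seed=7)
        model = train_gsvn(fm, n_members=3, C=1.0, gamma=0.5, seed=0, unit="frame")
        frames = FeatureMatrix(
            fm.X.iloc[:5], fm.labels.iloc[:5],
            pd.DataFrame({"clip_id": ["clip0"] * 5}),
        )
        out = predict_clip(model, frames)
        labels, _ = predict(model, frames)
        assert out["clip0"] == labels[0]

    def test_majority_wins(self):
        model = TestPredict._fixed_model([("A", 1.0)], ["A", "B"])
        # single always-A member: every frame predicts A regardless of clip
        frames = FeatureMatrix(
            pd.DataFrame({"mfcc_1": [0.0, 1.0, 2.0]}),
            meta=pd.DataFrame({"clip_id": ["c1", "c1", "c1"]}),
        )
        assert predict_clip(model, frames)["c1"] == "A"
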