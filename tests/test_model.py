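"""Probability forest: AUC oracle, OOB identity, LOOCV, elimination, maps."""

import numpy as np
import pandas as pd
import pytest

from recurmap.core import GridSpec, read_volume
from recurmap.features import FEATURE_NAMES
from recurmap.model import (
    FoldResult,
    ForestConfig,
    auc_voxelwise,
    backward_eliminate,
    loocv,
    predict_probabilities,
    probability_volume,
    reliability_correlation,
    train_forest,
    write_probability_map,
)


def toy_table(n, rng, patient_id="P00", informative=True, n_noise=3):
    """Synthetic voxel table: one informative feature + pure-noise features."""
    labels = (rng.random(n) < 0.3).astype(int)
    cols = {"patient_id": patient_id, "i": np.arange(n) % 8, "j": (np.arange(n) // 8) % 8,
            "k": np.arange(n) // 64}
    if informative:
        cols["signal"] = labels + rng.normal(0, 0.3, n)
    for q in range(n_noise):
        cols[f"noise{q}"] = rng.normal(size=n)
    cols["label"] = labels
    return pd.DataFrame(cols)


def feature_names(df):
    return tuple(c for c in df.columns if c not in ("patient_id", "i", "j", "k", "label"))


class TestAUC:
    def test_all_pairs_example(self):
        assert auc_voxelwise([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_ordering(self):
        assert auc_voxelwise([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auc_voxelwise([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pair_enumeration(self, rng):
        p = rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        pos, neg = p[y == 1], p[y == 0]
        wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        assert auc_voxelwise(p, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_voxelwise([0.1, 0.2], [1, 1])


class TestTrainForest:
    def test_separable_table(self, rng):
        df = toy_table(400, rng)
        model = train_forest(df, ForestConfig(n_trees=300, seed=0), feature_names(df))
        probs = predict_probabilities(model, df)
        assert auc_voxelwise(probs, df.label.to_numpy()) > 0.99
        assert model.oob_error <= 0.05

    def test_oob_identity_holds(self, rng):
        """Reported OOB error is exactly 1 - AUC of the OOB vote probabilities."""
        df = toy_table(300, rng)
        model = train_forest(df, ForestConfig(n_trees=100, seed=3), feature_names(df))
        from recurmap.model import _design, _oob_vote_probabilities

        x = _design(df, model.feature_names)
        probs, covered = _oob_vote_probabilities(model.forest, x, "hard")
        auc = auc_voxelwise(probs[covered], df.label.to_numpy()[covered])
        assert model.oob_error == 1.0 - auc

    def test_label_permutation_null(self, rng):
        aucs = []
        for seed in range(5):
            df = toy_table(400, rng)
            df["label"] = rng.permutation(df["label"].to_numpy())
            if df.label.nunique() < 2:
                continue
            model = train_forest(df, ForestConfig(n_trees=200, seed=seed), feature_names(df))
            aucs.append(1.0 - model.oob_error)
        assert 0.4 < np.mean(aucs) < 0.6

    def test_planted_feature_ranks_first(self, rng):
        df = toy_table(600, rng, n_noise=21)
        names = feature_names(df)
        model = train_forest(df, ForestConfig(n_trees=300, seed=1), names)
        assert names[int(np.argmax(model.importance))] == "signal"

    def test_single_class_rejected(self, rng):
        df = toy_table(50, rng)
        df["label"] = 1
        with pytest.raises(ValueError):
            train_forest(df, ForestConfig(n_trees=10), feature_names(df))

    def test_deterministic_given_seed(self, rng):
        df = toy_table(200, rng)
        m1 = train_forest(df, ForestConfig(n_trees=50, seed=9), feature_names(df))
        m2 = train_forest(df, ForestConfig(n_trees=50, seed=9), feature_names(df))
        np.testing.assert_array_equal(
            predict_probabilities(m1, df), predict_probabilities(m2, df)
        )
        assert m1.oob_error == m2.oob_error


class TestLOOCV:
    def test_two_identical_separable_patients(self, rng):
        a = toy_table(300, rng, "A")
        b = a.copy()
        b["patient_id"] = "B"
        folds = loocv([a, b], ForestConfig(n_trees=100, seed=2), feature_names(a))
        assert all(f.auc > 0.99 for f in folds)

    def test_single_class_fold_flagged(self, rng):
        a = toy_table(200, rng, "A")
        b = toy_table(200, rng, "B")
        b["label"] = 0
        b["signal"] = rng.normal(size=200)
        c = toy_table(200, rng, "C")
        folds = loocv([a, b, c], ForestConfig(n_trees=50, seed=2), feature_names(a))
        by_pid = {f.held_out_patient: f for f in folds}
        assert not by_pid["B"].auc_defined
        assert by_pid["A"].auc_defined and by_pid["C"].auc_defined

    def test_min_patients(self, rng):
        with pytest.raises(ValueError):
            loocv([toy_table(50, rng)], ForestConfig(n_trees=10))


class TestBackwardElimination:
    def test_planted_feature_survives(self, rng):
        df = toy_table(500, rng, n_noise=3)
        names = feature_names(df)
        trace = backward_eliminate([df], ForestConfig(n_trees=200, seed=4), names)
        assert "signal" in trace.selected_set
        errs = [s["oob_error"] for s in trace.steps]
        full_err = errs[0]
        sel_err = min(errs)
        assert sel_err <= full_err
        # bookkeeping: one feature removed per step
        sizes = [len(s["remaining"]) for s in trace.steps]
        assert sizes == list(range(len(names), 0, -1))

    def test_redundant_copies_complete(self, rng):
        labels = (rng.random(300) < 0.3).astype(int)
        base = labels + rng.normal(0, 0.5, 300)
        df = pd.DataFrame({"patient_id": "A", "i": 0, "j": 0, "k": 0,
                           "f1": base, "f2": base, "f3": base, "label": labels})
        trace = backward_eliminate([df], ForestConfig(n_trees=100, seed=5), ("f1", "f2", "f3"))
        assert len(trace.steps) == 3
        assert len(trace.selected_set) >= 1


class TestReliability:
    @staticmethod
    def _fold(auc, maxp):
        return FoldResult("P", np.array([maxp]), np.array([1]), np.zeros((1, 3), int),
                          auc, maxp, 0.1)

    def test_linear_relation(self):
        folds = [self._fold(a, 0.5 * a + 0.1) for a in (0.2, 0.5, 0.8, 0.9)]
        assert reliability_correlation(folds) == pytest.approx(1.0)

    def test_anti_linear(self):
        folds = [self._fold(a, 1.0 - a) for a in (0.2, 0.5, 0.8)]
        assert reliability_correlation(folds) == pytest.approx(-1.0)

    def test_longhand_pearson(self):
        xs = [0.3, 0.5, 0.6, 0.8, 0.9]
        ys = [0.41, 0.52, 0.50, 0.77, 0.80]
        folds = [self._fold(a, m) for a, m in zip(ys, xs)]
        mx, my = np.mean(xs), np.mean(ys)
        r = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / np.sqrt(
            sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys)
        )
        assert reliability_correlation(folds) == pytest.approx(r, abs=1e-12)

    def test_min_folds(self):
        with pytest.raises(ValueError):
            reliability_correlation([self._fold(0.5, 0.5)] * 2)


class TestProbabilityMap:
    def test_round_trip_and_fill(self, tmp_path, rng):
        grid = GridSpec((8, 8, 8), (2.0, 2.0, 2.0))
        idx = np.argwhere(rng.random((8, 8, 8)) < 0.2)
        probs = rng.random(len(idx))
        fold = FoldResult("P", probs, (probs > 0.5).astype(int), idx,
                          0.7, float(probs.max()), 0.2)
        path = write_probability_map(fold, grid, tmp_path / "p.nii.gz")
        back = read_volume(path, "CT_HU")
        vol = probability_volume(fold, grid)
        np.testing.assert_allclose(back.values, vol.values, atol=1e-6)
        outside = np.ones((8, 8, 8), bool)
        outside[idx[:, 0], idx[:, 1], idx[:, 2]] = False
        assert np.all(back.values[outside] == -1.0)

    def test_separable_map_orders_regions(self, rng):
        labels = (rng.random(300) < 0.3).astype(int)
        df = pd.DataFrame(
            {
                "patient_id": "A",
                "i": 0,
                "j": 0,
                "k": 0,
                "signal": labels + rng.uniform(0, 0.2, 300),  # fully separable
                "noise0": rng.normal(size=300),
                "label": labels,
            }
        )
        model = train_forest(df, ForestConfig(n_trees=200, seed=6), ("signal", "noise0"))
        probs = predict_probabilities(model, df)
        assert probs[labels == 1].min() >= probs[labels == 0].max()
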