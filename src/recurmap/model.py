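"""Voxel-wise prediction of recurrence membership with a probability random forest.

Each GTV voxel is a training sample; the forest's output for a voxel is the
fraction of trees voting that it belongs to the failure region, read as a
probability.  Evaluation is leave-one-patient-out: the model never sees the
held-out patient's voxels, and per-patient performance is the area under the
ROC curve of the probability map against the true failure labels.

Out-of-bag (OOB) error is defined as 1 - AUC of the OOB vote probabilities on
the training voxels — an identity this module enforces by construction — with
the Brier score of the OOB probabilities logged alongside for transparency.
Feature importance is the mean decrease in Gini impurity (MDGI); backward
elimination repeatedly drops the least important feature, retrains, and keeps
the feature set minimizing the OOB error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._util import derive_seed
from .core import GridSpec, ImageVolume, write_volume
from .features import FEATURE_NAMES

__all__ = [
    "ForestConfig",
    "TrainedForest",
    "FoldResult",
    "EliminationTrace",
    "auc_voxelwise",
    "train_forest",
    "predict_probabilities",
    "loocv",
    "backward_eliminate",
    "reliability_correlation",
    "probability_volume",
    "write_probability_map",
    "summarize_folds",
]

PROBABILITY_FILL = -1.0  # value outside the GTV in serialized probability maps


@dataclass
class ForestConfig:
    """Probability-forest settings: 10,000 trees for production runs, 500 for
    desk-scale experiments; mtry = floor(sqrt(p)); minimum node size 10."""

    n_trees: int = 500
    mtry: int | None = None  # None: floor(sqrt(n_features))
    min_node_size: int = 10
    seed: int = 0
    vote_mode: str = "hard"  # "hard": fraction of trees; "soft": mean leaf probability
    voxel_cap: int | None = None  # per-patient training-voxel subsample, None = all

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class TrainedForest:
    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    importance: np.ndarray  # mean decrease in Gini impurity per feature
    oob_error: float  # 1 - AUC of OOB vote probabilities
    oob_brier: float
    config: ForestConfig


@dataclass
class FoldResult:
    held_out_patient: str
    probabilities: np.ndarray  # per held-out GTV voxel
    labels: np.ndarray
    voxel_index: np.ndarray  # (n, 3) indices on the feature grid
    auc: float
    max_probability: float
    oob_error_train: float
    auc_defined: bool = True


@dataclass
class EliminationTrace:
    steps: list[dict] = field(default_factory=list)  # removed, remaining, oob_error
    selected_set: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_features": len(s["remaining"]),
                    "oob_error": s["oob_error"],
                    "removed_next": s["removed"],
                    "remaining": "|".join(s["remaining"]),
                }
                for s in self.steps
            ]
        )


def auc_voxelwise(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    from scipy.stats import rankdata

    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _design(table: pd.DataFrame, features: tuple[str, ...]) -> np.ndarray:
    return table.loc[:, list(features)].to_numpy(dtype=np.float64)


def _cap_voxels(table: pd.DataFrame, cap: int | None, seed: int) -> pd.DataFrame:
    if cap is None:
        return table
    parts = []
    for pid, grp in table.groupby("patient_id", sort=True):
        if len(grp) > cap:
            rng = np.random.default_rng(derive_seed(seed, "cap", pid))
            grp = grp.iloc[np.sort(rng.choice(len(grp), cap, replace=False))]
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def _vote_probabilities(forest: RandomForestClassifier, x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "soft":
        return forest.predict_proba(x)[:, list(forest.classes_).index(1)]
    votes = np.zeros(len(x))
    for tree in forest.estimators_:
        votes += tree.predict(x) == 1
    return votes / len(forest.estimators_)


def _oob_vote_probabilities(
    forest: RandomForestClassifier, x: np.ndarray, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample OOB vote fraction and the mask of samples with >= 1 OOB tree."""
    n = len(x)
    votes = np.zeros(n)
    counts = np.zeros(n)
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, bool)
        oob[sampled] = False
        if not oob.any():
            continue
        pred = tree.predict(x[oob]) if mode == "hard" else tree.predict_proba(x[oob])[:, 1]
        if mode == "hard":
            votes[oob] += pred == 1
        else:
            votes[oob] += pred
        counts[oob] += 1
    covered = counts > 0
    probs = np.zeros(n)
    probs[covered] = votes[covered] / counts[covered]
    return probs, covered


def train_forest(
    table: pd.DataFrame,
    cfg: ForestConfig | None = None,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> TrainedForest:
    """Fit the probability forest on a labeled voxel table.

    The table needs a binary ``label`` column with both classes present.
    Returns the fitted forest, the MDGI importance vector, and the OOB error
    (1 - AUC of OOB vote probabilities on the training voxels).
    """
    cfg = cfg or ForestConfig()
    if "label" not in table.columns:
        raise ValueError("table has no label column")
    y = table["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training table contains a single class")
    x = _design(table, features)
    mtry = cfg.mtry or max(1, int(np.sqrt(len(features))))
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=min(mtry, len(features)),
        min_samples_split=cfg.min_node_size,
        criterion="gini",
        bootstrap=True,
        oob_score=False,
        random_state=cfg.seed % (2**31),
        n_jobs=1,
    )
    forest.fit(x, y)
    oob_probs, covered = _oob_vote_probabilities(forest, x, cfg.vote_mode)
    oob_auc = auc_voxelwise(oob_probs[covered], y[covered])
    brier = float(np.mean((oob_probs[covered] - y[covered]) ** 2))
    return TrainedForest(
        forest=forest,
        feature_names=tuple(features),
        importance=np.asarray(forest.feature_importances_),
        oob_error=1.0 - oob_auc,
        oob_brier=brier,
        config=cfg,
    )


def predict_probabilities(model: TrainedForest, table: pd.DataFrame) -> np.ndarray:
    """Per-voxel probability of belonging to the failure region (tree-vote fraction)."""
    x = _design(table, model.feature_names)
    return _vote_probabilities(model.forest, x, model.config.vote_mode)


def loocv(
    cohort_tables: list[pd.DataFrame],
    cfg: ForestConfig | None = None,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> list[FoldResult]:
    """Leave-one-patient-out cross-validation.

    For each fold the forest is trained on every other patient's voxels
    (optionally capped per patient for runtime) and evaluated on all of the
    held-out patient's GTV voxels.
    """
    cfg = cfg or ForestConfig()
    if len(cohort_tables) < 2:
        raise ValueError("leave-one-out needs at least 2 patients")
    results: list[FoldResult] = []
    for held in range(len(cohort_tables)):
        test = cohort_tables[held]
        pid = str(test["patient_id"].iloc[0])
        train = pd.concat(
            [t for i, t in enumerate(cohort_tables) if i != held], ignore_index=True
        )
        train = _cap_voxels(train, cfg.voxel_cap, cfg.seed)
        fold_cfg = ForestConfig(
            n_trees=cfg.n_trees,
            mtry=cfg.mtry,
            min_node_size=cfg.min_node_size,
            seed=derive_seed(cfg.seed, "fold", pid),
            vote_mode=cfg.vote_mode,
            voxel_cap=cfg.voxel_cap,
        )
        model = train_forest(train, fold_cfg, features)
        probs = predict_probabilities(model, test)
        labels = test["label"].to_numpy(dtype=int)
        try:
            auc = auc_voxelwise(probs, labels)
            defined = True
        except ValueError:
            auc = float("nan")
            defined = False
        results.append(
            FoldResult(
                held_out_patient=pid,
                probabilities=probs,
                labels=labels,
                voxel_index=test[["i", "j", "k"]].to_numpy(),
                auc=auc,
                max_probability=float(probs.max()),
                oob_error_train=model.oob_error,
                auc_defined=defined,
            )
        )
    return results


def summarize_folds(folds: list[FoldResult]) -> dict:
    aucs = np.array([f.auc for f in folds if f.auc_defined])
    return {
        "n_folds": len(folds),
        "n_auc_defined": int(len(aucs)),
        "mean_auc": float(aucs.mean()),
        "median_auc": float(np.median(aucs)),
        "min_auc": float(aucs.min()),
        "max_auc": float(aucs.max()),
        "mean_oob_error": float(np.mean([f.oob_error_train for f in folds])),
    }


def backward_eliminate(
    cohort_tables: list[pd.DataFrame],
    cfg: ForestConfig | None = None,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> EliminationTrace:
    """Recursive backward elimination on the lowest-MDGI feature.

    Trains on the pooled cohort voxels, drops the single least important
    feature, retrains (importance recomputed each step, not reused), down to
    one feature; the selected set is the remaining set at the global minimum
    of the OOB error (first such step on ties).
    """
    cfg = cfg or ForestConfig()
    pooled = pd.concat(cohort_tables, ignore_index=True)
    pooled = _cap_voxels(pooled, cfg.voxel_cap, cfg.seed)
    remaining = list(features)
    trace = EliminationTrace()
    while remaining:
        step_cfg = ForestConfig(
            n_trees=cfg.n_trees,
            mtry=cfg.mtry,
            min_node_size=cfg.min_node_size,
            seed=derive_seed(cfg.seed, "elim", len(remaining)),
            vote_mode=cfg.vote_mode,
            voxel_cap=cfg.voxel_cap,
        )
        model = train_forest(pooled, step_cfg, tuple(remaining))
        removed = None
        if len(remaining) > 1:
            removed = remaining[int(np.argmin(model.importance))]
        trace.steps.append(
            {"remaining": tuple(remaining), "oob_error": model.oob_error, "removed": removed}
        )
        if removed is None:
            break
        remaining.remove(removed)
    errs = [s["oob_error"] for s in trace.steps]
    best = int(np.argmin(errs))  # first occurrence on ties
    trace.selected_set = trace.steps[best]["remaining"]
    return trace


def reliability_correlation(folds: list[FoldResult]) -> float:
    """Pearson correlation between per-fold max probability and per-fold AUC."""
    ok = [f for f in folds if f.auc_defined]
    if len(ok) < 3:
        raise ValueError("need at least 3 folds with defined AUC")
    x = np.array([f.max_probability for f in ok])
    y = np.array([f.auc for f in ok])
    return float(np.corrcoef(x, y)[0, 1])


def probability_volume(fold: FoldResult, reference: GridSpec) -> ImageVolume:
    """Probability map on the reference grid: vote fraction inside the GTV,
    a fill value of -1 outside."""
    vals = np.full(reference.shape, PROBABILITY_FILL)
    idx = fold.voxel_index
    vals[idx[:, 0], idx[:, 1], idx[:, 2]] = fold.probabilities
    return ImageVolume(grid=reference, values=vals, modality="CT_HU")


def write_probability_map(fold: FoldResult, reference: GridSpec, path: str | Path) -> Path:
    return write_volume(probability_volume(fold, reference), path)
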