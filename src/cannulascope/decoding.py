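"""Population decoding of odor identity from trial-aligned dF/F.

Each head-fixation trial delivers 0.5 s of blank air followed by 1 s of
odorized air; the decoding feature for a trial is each cell's mean dF/F
over that 1 s odor window.  Decoding uses a K-fold cross-validated
linear classifier (multinomial logistic regression, L2, features
z-scored on the training fold only); the chance level is estimated by
re-running the decoder on label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "DecodeResult",
    "trial_features",
    "kfold_linear_decode",
    "permutation_chance",
]

ODOR_WINDOW_S = (0.5, 1.5)  # relative to fixation start: blank 0.5 s, odor 1 s


@dataclass
class DecodeResult:
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    n_classes: int
    k_folds: int
    chance_distribution: np.ndarray | None = None
    chance_level: float | None = None
    fold_indices: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"K-fold linear decoding ({self.k_folds} folds, {self.n_classes} classes)",
            f"  mean accuracy : {self.mean_accuracy:.3f}",
            "  per fold      : " + ", ".join(f"{a:.3f}" for a in self.per_fold_accuracy),
        ]
        if self.chance_level is not None:
            lines.append(f"  chance level  : {self.chance_level:.3f} "
                         f"(n_perm={len(self.chance_distribution)})")
        return "\n".join(lines)


def trial_features(
    dff_traces: np.ndarray,
    trial_table: pd.DataFrame,
    frame_rate_hz: float,
    window_s: tuple[float, float] = ODOR_WINDOW_S,
) -> np.ndarray:
    """Mean dF/F per cell over each trial's odor window -> (trials, cells)."""
    dff_traces = np.atleast_2d(np.asarray(dff_traces, dtype=float))
    n_frames = dff_traces.shape[1]
    feats = []
    for _, row in trial_table.iterrows():
        f0 = int(round((row["t_start_s"] + window_s[0]) * frame_rate_hz))
        f1 = int(round((row["t_start_s"] + window_s[1]) * frame_rate_hz))
        if f0 < 0 or f1 > n_frames or f1 <= f0:
            raise ValueError(
                f"trial {row['trial_id']}: window frames [{f0}, {f1}) outside traces"
            )
        feats.append(dff_traces[:, f0:f1].mean(axis=1))
    return np.asarray(feats)


def _make_classifier() -> object:
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=1.0, max_iter=2000),
    )


def kfold_linear_decode(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> DecodeResult:
    """Stratified K-fold cross-validated linear decoding accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError("each class needs at least k members for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    folds = []
    for train, test in skf.split(X, y):
        clf = _make_classifier()
        clf.fit(X[train], y[train])
        accs.append(float(clf.score(X[test], y[test])))
        folds.append((train, test))
    accs = np.asarray(accs)
    return DecodeResult(
        per_fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        n_classes=len(classes),
        k_folds=k,
        fold_indices=folds,
    )


def permutation_chance(
    X: np.ndarray, y: np.ndarray, k: int = 5, n_perm: int = 200, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Decoding-accuracy null distribution under label permutation.

    Returns the permutation accuracies and their mean (the chance level,
    drawn as the dashed line on decoding figures).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    dist = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        dist[i] = kfold_linear_decode(X, yp, k=k, seed=int(rng.integers(2**31))).mean_accuracy
    return dist, float(dist.mean())


def decode_session(
    dff_traces: np.ndarray,
    trial_table: pd.DataFrame,
    frame_rate_hz: float,
    activity_threshold: float = 0.03,
    k: int = 5,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[DecodeResult, np.ndarray]:
    """Full session decoding: activity-filter cells, build odor-window
    features, decode, optionally estimate the permutation chance level.

    Returns ``(result, kept_cell_indices)``; feature columns are exactly
    the kept cells.
    """
    from .traces import active_cell_filter

    kept = active_cell_filter(dff_traces, activity_threshold)
    if kept.size == 0:
        raise ValueError("no cells pass the activity threshold")
    X = trial_features(dff_traces[kept], trial_table, frame_rate_hz)
    y = trial_table["odor_label"].to_numpy()
    res = kfold_linear_decode(X, y, k=k, seed=seed)
    if n_perm:
        dist, level = permutation_chance(X, y, k=k, n_perm=n_perm, seed=seed)
        res.chance_distribution = dist
        res.chance_level = level
    return res, kept
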