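"""Condition classification from fitted transition matrices.

Transition matrices are packed into fixed 4-channel 4x4 tensors (one
block per channel, padded to size) and classified with a small CNN under
leakage-free session-level splits.  Metrics follow the usual confusion
conventions; AUC is the rank statistic over class scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from ._cnn import CNNModel, CNNSpec, train_cnn
from .dynamics import SessionFit
from .types import (
    InvalidConfigError,
    InvalidInputError,
    SessionChain,
    TransitionMatrix,
)

LABEL_POSITIVE = "NFT"  # positive class for TPR/TNR bookkeeping


# ---------------------------------------------------------------------------
# session-level splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Session-level train/validation/test split specification."""

    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise InvalidConfigError("split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise InvalidConfigError("split ratios must sum to 1")


def split_sessions(
    session_ids: list[str], spec: SplitSpec | None = None
) -> dict[str, list[str]]:
    """Deterministic disjoint partition: test/val by floor, train the rest."""
    spec = spec or SplitSpec()
    ids = list(session_ids)
    if len(set(ids)) != len(ids):
        raise InvalidInputError("session ids must be unique")
    n = len(ids)
    if n < 3:
        raise InvalidInputError("need at least 3 sessions to split")
    n_test = math.floor(n * spec.ratios[2])
    n_val = math.floor(n * spec.ratios[1])
    n_train = n - n_test - n_val
    if min(n_train, n_val, n_test) < 1:
        needed = math.ceil(1.0 / min(spec.ratios))
        raise InvalidInputError(
            f"partition would be empty for n={n}; need at least {needed} sessions"
        )
    rng = np.random.default_rng(spec.seed)
    order = [ids[i] for i in rng.permutation(n)]
    return {
        "test": sorted(order[:n_test]),
        "val": sorted(order[n_test : n_test + n_val]),
        "train": sorted(order[n_test + n_val :]),
    }


def assert_leakage_free(partition: dict[str, list[str]]) -> None:
    seen: set[str] = set()
    for part, ids in partition.items():
        overlap = seen & set(ids)
        if overlap:
            raise InvalidInputError(f"session leakage into '{part}': {sorted(overlap)}")
        seen |= set(ids)


# ---------------------------------------------------------------------------
# tensor packing
# ---------------------------------------------------------------------------


def transition_to_tensor(A: TransitionMatrix) -> np.ndarray:
    """Pack one transition matrix into a 4-channel 4x4 tensor.

    Channel order: motor (identity-padded), occipital (native 4x4),
    cross (zero-padded), mesoscale (zero-padded).  The packing is
    lossless: 43 weights land at fixed positions.
    """
    out = np.zeros((4, 4, 4))
    out[0, :3, :3] = A.mc
    out[0, 3, 3] = 1.0  # identity padding for the motor block
    out[1] = A.loc
    out[2, :3, :3] = A.mc_loc
    out[3, :3, :3] = A.mnet
    return out


def tensor_to_transition(t: np.ndarray) -> TransitionMatrix:
    t = np.asarray(t, dtype=np.float64)
    if t.shape != (4, 4, 4):
        raise InvalidInputError(f"expected tensor of shape (4, 4, 4), got {t.shape}")
    return TransitionMatrix(
        mc=t[0, :3, :3], loc=t[1], mc_loc=t[2, :3, :3], mnet=t[3, :3, :3]
    )


@dataclass
class TensorSet:
    """Labelled tensor samples with their session provenance."""

    x: np.ndarray                 # (n, 4, 4, 4)
    y: np.ndarray                 # (n,) int, 1 == positive condition
    session_ids: list[str]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, session_ids: list[str]) -> "TensorSet":
        wanted = set(session_ids)
        mask = np.array([s in wanted for s in self.session_ids])
        return TensorSet(
            x=self.x[mask],
            y=self.y[mask],
            session_ids=[s for s, m in zip(self.session_ids, mask) if m],
        )


def tensorize_transitions(sources: list[SessionFit | SessionChain]) -> TensorSet:
    """One labelled sample per transition, labelled by its chain's condition."""
    xs, ys, sids = [], [], []
    for src in sources:
        if isinstance(src, SessionFit):
            transitions = src.final_transitions
            condition, sid = src.condition, src.session_id
        else:
            if src.transitions is None:
                raise InvalidInputError(
                    f"chain '{src.session_id}' carries no transitions"
                )
            transitions = src.transitions
            condition, sid = src.condition, src.session_id
        for A in transitions:
            xs.append(transition_to_tensor(A))
            ys.append(1 if condition == LABEL_POSITIVE else 0)
            sids.append(sid)
    if not xs:
        raise InvalidInputError("no transitions to tensorize")
    return TensorSet(x=np.stack(xs), y=np.array(ys, dtype=np.int64), session_ids=sids)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def train_classifier(
    train: TensorSet,
    val: TensorSet,
    spec: CNNSpec | None = None,
    seed: int = 0,
) -> CNNModel:
    if len(np.unique(train.y)) < 2:
        raise InvalidInputError("training set must contain both classes")
    return train_cnn(train.x, train.y, val.x, val.y, spec=spec, seed=seed)


@dataclass
class EvalReport:
    accuracy: float
    f1_score: float
    tpr: float
    tnr: float
    auc: float | None
    confusion: dict[str, int]
    session_majority_accuracy: float | None = None
    per_session: dict[str, dict] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1_score": self.f1_score,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "auc": self.auc,
            "confusion": self.confusion,
            "session_majority_accuracy": self.session_majority_accuracy,
            "per_session": self.per_session,
        }


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else float("nan")
    tpr = tp / (tp + fn) if tp + fn else float("nan")
    tnr = tn / (tn + fp) if tn + fp else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    if precision + tpr > 0 and np.isfinite(precision) and np.isfinite(tpr):
        f1 = 2 * precision * tpr / (precision + tpr)
    else:
        f1 = 0.0
    return {"accuracy": accuracy, "tpr": tpr, "tnr": tnr, "f1_score": f1}


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised rank-sum of positive-class scores."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("AUC needs both classes")
    ranks = sp_stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(model: CNNModel, test: TensorSet) -> EvalReport:
    if len(test) == 0:
        raise InvalidInputError("empty test set")
    probs = model.predict_proba(test.x)[:, 1]
    pred = (probs >= 0.5).astype(np.int64)
    y = test.y
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    metrics = metrics_from_confusion(tp, fp, tn, fn)

    if len(np.unique(y)) < 2:
        warnings.warn("single-class test set; AUC not defined")
        auc = None
    else:
        auc = rank_auc(probs, y)

    # session-level majority vote over (session, condition) groups
    per_session: dict[str, dict] = {}
    votes_correct, votes_total = 0, 0
    keys = [f"{sid}|{label}" for sid, label in zip(test.session_ids, y)]
    for key in sorted(set(keys)):
        mask = np.array([k == key for k in keys])
        majority = int(np.round(pred[mask].mean()))
        true_label = int(y[mask][0])
        per_session[key] = {
            "n": int(mask.sum()),
            "majority_prediction": majority,
            "true_label": true_label,
        }
        votes_correct += int(majority == true_label)
        votes_total += 1

    return EvalReport(
        accuracy=metrics["accuracy"],
        f1_score=metrics["f1_score"],
        tpr=metrics["tpr"],
        tnr=metrics["tnr"],
        auc=auc,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        session_majority_accuracy=votes_correct / votes_total if votes_total else None,
        per_session=per_session,
    )


def knn_baseline_accuracy(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    n_neighbors: int = 5,
) -> float:
    """Reference KNN accuracy on flattened raw features (comparison only)."""
    from sklearn.neighbors import KNeighborsClassifier

    knn = KNeighborsClassifier(n_neighbors=n_neighbors)
    knn.fit(train_x.reshape(len(train_x), -1), train_y)
    return float(knn.score(test_x.reshape(len(test_x), -1), test_y))
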