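"""Leave-one-subject-out evaluation: folds, metrics, averaged ROC, summaries.

Every fold holds out all epochs (both sessions) of one subject; feature
selection and standardization are, by default, recomputed inside each
training fold so no information from the held-out subject leaks into the
model.  Metrics take "after" (post-rehabilitation) as the positive class.
Per-subject accuracies are summarized as mean / median / sample SD in
percent, over subjects rather than epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .classifier import MLPParams, Standardizer, TrainConfig, init_mlp, predict, train_sgdm
from .connectivity import FeatureTable
from .feature_selection import FeatureMask, apply_mask, paired_ttest, select_top_fraction

logger = logging.getLogger(__name__)


@dataclass
class FoldResult:
    held_out_subject: str
    y_true: np.ndarray  # epoch labels "before"/"after"
    y_pred: np.ndarray
    p_after: np.ndarray  # predicted probability of the positive class
    measure: str = ""
    band: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        if not (len(self.y_true) == len(self.y_pred) == len(self.p_after)):
            raise ValueError("label/prediction vectors differ in length")
        if np.any((self.p_after < 0) | (self.p_after > 1)):
            raise ValueError("probabilities outside [0, 1]")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f_measure: float
    undefined: list[str] = field(default_factory=list)
    roc: list[tuple[float, float]] = field(default_factory=list)


def loso_folds(subject_sessions: dict[str, set[str]]) -> list[tuple[list[str], str]]:
    """Fold plan: (training subjects, held-out subject), one fold per subject.

    ``subject_sessions`` maps subject id -> set of session labels present.
    Subjects missing one of the two sessions are excluded with a warning.
    """
    complete = sorted(s for s, sess in subject_sessions.items()
                      if {"before", "after"} <= set(sess))
    dropped = sorted(set(subject_sessions) - set(complete))
    for s in dropped:
        logger.warning("subject %s missing a session; excluded from LOSO", s)
    if len(complete) < 3:
        raise ValueError(f"LOSO needs at least 3 complete subjects, got {len(complete)}")
    return [([t for t in complete if t != s], s) for s in complete]


def run_loso(
    ft: FeatureTable,
    selection_fraction: float = 0.10,
    selection_scope: str = "fold",
    pairing_unit: str = "subject_mean",
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> list[FoldResult]:
    """Train and evaluate one model per held-out subject.

    ``selection_scope="fold"`` recomputes the t-test mask on the training
    subjects of each fold (leakage-free default); ``"global"`` computes one
    mask on all subjects first, matching a selection-before-validation
    protocol.  Per-fold seeds are offset deterministically from ``seed``.
    """
    if train_cfg is None:
        train_cfg = TrainConfig()
    sessions: dict[str, set[str]] = {}
    for s, lbl in zip(ft.subject_ids, ft.labels):
        sessions.setdefault(str(s), set()).add(str(lbl))
    folds = loso_folds(sessions)

    global_mask: FeatureMask | None = None
    if selection_scope == "global":
        global_mask = select_top_fraction(paired_ttest(ft, pairing_unit), selection_fraction)
    elif selection_scope != "fold":
        raise ValueError("selection_scope must be 'fold' or 'global'")

    results = []
    for k, (train_subjects, test_subject) in enumerate(folds):
        train_rows = np.isin(ft.subject_ids, train_subjects)
        test_rows = ft.subject_ids == test_subject
        train_ft = _subset_rows(ft, train_rows)
        if global_mask is not None:
            mask = global_mask
        else:
            mask = select_top_fraction(paired_ttest(train_ft, pairing_unit),
                                       selection_fraction)
        x_train = apply_mask(train_ft, mask).matrix
        x_test = apply_mask(_subset_rows(ft, test_rows), mask).matrix
        y_train = (train_ft.labels == "after").astype(int)
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {k}: a training class is absent")
        std = Standardizer.fit(x_train)
        fold_seed = (seed * 1000 + k) % (2**31 - 1)
        params = init_mlp(x_train.shape[1], seed=fold_seed)
        cfg = TrainConfig(
            learning_rate=train_cfg.learning_rate,
            momentum=train_cfg.momentum,
            max_epochs=train_cfg.max_epochs,
            batch_size=train_cfg.batch_size,
            shuffle_each_epoch=train_cfg.shuffle_each_epoch,
            seed=fold_seed,
        )
        params = train_sgdm(params, std.transform(x_train), y_train, cfg)
        y_pred, p_after = predict(params, std.transform(x_test))
        results.append(FoldResult(
            held_out_subject=test_subject,
            y_true=ft.labels[test_rows].astype(str),
            y_pred=y_pred,
            p_after=p_after,
            measure=ft.measure,
            band=ft.band,
            task=ft.task,
        ))
    return results


def _subset_rows(ft: FeatureTable, rows: np.ndarray) -> FeatureTable:
    return FeatureTable(
        matrix=ft.matrix[rows],
        pair_index=list(ft.pair_index),
        labels=ft.labels[rows],
        subject_ids=ft.subject_ids[rows],
        measure=ft.measure,
        band=ft.band,
        task=ft.task,
        convention=ft.convention,
    )


def compute_metrics(frs: FoldResult | list[FoldResult]) -> MetricsReport:
    """Confusion-matrix metrics pooled over folds; positive class = "after"."""
    if isinstance(frs, FoldResult):
        frs = [frs]
    y_true = np.concatenate([f.y_true for f in frs])
    y_pred = np.concatenate([f.y_pred for f in frs])
    pos_t, pos_p = y_true == "after", y_pred == "after"
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    accuracy = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        undefined.append("f_measure")
        f = float("nan")
    else:
        f = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, precision=precision,
                         sensitivity=sensitivity, specificity=specificity,
                         accuracy=accuracy, f_measure=f, undefined=undefined)


def roc_average(frs: list[FoldResult], grid_size: int = 101) -> np.ndarray:
    """Vertically averaged ROC: mean TPR on a fixed FPR grid across folds.

    Folds with a single true class carry no ROC information and are excluded
    with a warning.  Returns (grid_size, 2) array of (fpr, tpr) points with
    the (0,0) and (1,1) endpoints enforced.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for f in frs:
        if len(set(f.y_true.tolist())) < 2:
            logger.warning("fold %s has a single class; excluded from ROC", f.held_out_subject)
            continue
        fpr, tpr, _ = roc_curve(f.y_true == "after", f.p_after)
        tprs.append(np.interp(grid, fpr, tpr))
    if not tprs:
        raise ValueError("no fold with both classes; ROC undefined")
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return np.column_stack([grid, mean_tpr])


def per_subject_accuracies(frs: list[FoldResult]) -> dict[str, float]:
    """Fraction of each held-out subject's epochs classified correctly."""
    return {f.held_out_subject: f.accuracy for f in frs}


def aggregate_accuracies(groups: dict[tuple[str, str, str], list[FoldResult]]) -> pd.DataFrame:
    """Summary table: mean/median/SD (%) of per-subject accuracies per group.

    ``groups`` maps (measure, band, task) -> fold results.  SD is the sample
    standard deviation over subjects; a single-subject group reports SD 0
    and is flagged.
    """
    rows = []
    for (measure, band, task), frs in groups.items():
        acc = 100.0 * np.array([f.accuracy for f in frs])
        flagged = len(acc) < 2
        rows.append({
            "measure": measure, "band": band, "task": task,
            "n_subjects": len(acc),
            "mean": float(np.mean(acc)),
            "median": float(np.median(acc)),
            "std": 0.0 if flagged else float(np.std(acc, ddof=1)),
            "std_undefined": flagged,
        })
    return pd.DataFrame(rows)
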