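"""t-test-based feature selection: keep the top fraction of lowest p-values.

The default pairing unit averages each feature over a subject's epochs
within a session and runs a paired (repeated-measures) t-test across
subjects, so the test respects the within-subject design; a Welch
epoch-level two-sample variant is available for exploratory use.  Selection
is a ranking, not an inference, so no multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import FeatureTable

CLASSES = ("before", "after")


@dataclass
class PValueVector:
    p: np.ndarray
    t_stat: np.ndarray
    df: int
    pairing_unit: str
    zero_variance: np.ndarray  # flags features where the test is degenerate

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values outside [0, 1]")


@dataclass
class FeatureMask:
    selected: np.ndarray  # sorted feature indices
    fraction: float
    source_pvalues: PValueVector | None = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("duplicate indices in mask")


def _session_means(ft: FeatureTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    subjects = sorted(set(ft.subject_ids.tolist()))
    pre, post = [], []
    for s in subjects:
        for label, out in (("before", pre), ("after", post)):
            rows = (ft.subject_ids == s) & (ft.labels == label)
            if not rows.any():
                raise ValueError(f"subject {s} has no '{label}' epochs")
            out.append(ft.matrix[rows].mean(axis=0))
    return np.asarray(pre), np.asarray(post), subjects


def paired_ttest(ft: FeatureTable, pairing_unit: str = "subject_mean") -> PValueVector:
    """Per-feature two-sided t-test between the before and after classes.

    ``subject_mean``: paired t-test across subjects on per-subject session
    means (df = n_subjects - 1).  ``epoch_unpaired``: Welch two-sample test
    across epochs.  Zero-variance features get p = 1 and a flag.
    """
    if pairing_unit == "subject_mean":
        pre, post, subjects = _session_means(ft)
        if len(subjects) < 3:
            raise ValueError("paired t-test needs at least 3 subjects")
        diff = post - pre
        sd = diff.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_rel(post, pre, axis=0)
        df = len(subjects) - 1
    elif pairing_unit == "epoch_unpaired":
        a = ft.matrix[ft.labels == "after"]
        b = ft.matrix[ft.labels == "before"]
        if len(a) < 3 or len(b) < 3:
            raise ValueError("Welch test needs at least 3 epochs per class")
        sd = np.minimum(a.std(axis=0), b.std(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        df = len(a) + len(b) - 2
    else:
        raise ValueError(f"unknown pairing unit {pairing_unit!r}")
    p = np.asarray(res.pvalue, dtype=float)
    t = np.asarray(res.statistic, dtype=float)
    degenerate = ~np.isfinite(p) | (sd == 0)
    p[degenerate] = 1.0
    t[~np.isfinite(t)] = 0.0
    return PValueVector(p=p, t_stat=t, df=df, pairing_unit=pairing_unit,
                        zero_variance=degenerate)


def select_top_fraction(pv: PValueVector, fraction: float = 0.10) -> FeatureMask:
    """Keep the floor(fraction * n) features with smallest p-values.

    Ties are broken by larger |t|, then by lower feature index, so the mask
    is deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(pv.p)
    k = int(np.floor(fraction * n))
    if k == 0:
        raise ValueError(f"fraction {fraction} of {n} features selects nothing")
    order = np.lexsort((np.arange(n), -np.abs(pv.t_stat), pv.p))
    return FeatureMask(selected=np.sort(order[:k]), fraction=fraction, source_pvalues=pv)


def apply_mask(ft: FeatureTable, mask: FeatureMask) -> FeatureTable:
    """Column subset of a feature table, with pair provenance carried along."""
    idx = mask.selected
    if idx.size and (idx.min() < 0 or idx.max() >= ft.n_features):
        raise IndexError("mask index out of range for this table")
    return FeatureTable(
        matrix=ft.matrix[:, idx],
        pair_index=[ft.pair_index[i] for i in idx],
        labels=ft.labels,
        subject_ids=ft.subject_ids,
        measure=ft.measure,
        band=ft.band,
        task=ft.task,
        convention=ft.convention,
    )
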