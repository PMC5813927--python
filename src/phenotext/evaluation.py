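"""Evaluation: patient-grouped splits, exact confusion-matrix metrics,
rank-based AUC, Cohen's kappa, chi-squared model comparison, and the
benchmark driver that compares all model families on a corpus.

Splits are grouped by patient so no patient contributes notes to more than
one of train/validation/test — leakage through patient identity would
otherwise inflate every score. AUC is computed as the Mann–Whitney
probability with midrank tie handling (exactly the pair-enumeration value),
and precision/recall/F1, kappa and the 2×2 chi-squared statistic are exact
rational computations on the integer counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# Patient-grouped splitting

@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # note_id -> "train" | "val" | "test"
    seed: int
    fractions: tuple[float, float, float]

    def ids(self, split: str) -> list[str]:
        return [nid for nid, s in self.assignment.items() if s == split]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "fractions": self.fractions,
                       "assignment": self.assignment}, fh, sort_keys=True)


def grouped_split(note_patient: Mapping[str, str],
                  fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                  seed: int = 0) -> SplitAssignment:
    """Assign notes to train/val/test keeping each patient's notes together.

    Patients are shuffled by the seed, then assigned greedily in order to
    fill the train note-count target, then validation, then test; realized
    fractions deviate from the targets by at most one patient's worth of
    notes per boundary.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients: dict[str, list[str]] = {}
    for nid, pid in note_patient.items():
        patients.setdefault(pid, []).append(nid)
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to form three splits")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(patients))
    n_total = len(note_patient)
    targets = [fractions[0] * n_total, (fractions[0] + fractions[1]) * n_total]
    assignment: dict[str, str] = {}
    filled = 0
    for pid in order:
        notes = patients[pid]
        if filled < targets[0]:
            split = "train"
        elif filled < targets[1]:
            split = "val"
        else:
            split = "test"
        for nid in notes:
            assignment[nid] = split
        filled += len(notes)
    return SplitAssignment(assignment=assignment, seed=seed,
                           fractions=tuple(fractions))


# ---------------------------------------------------------------------------
# Confusion-matrix metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted: np.ndarray, actual: np.ndarray) -> ConfusionMatrix:
    p = np.asarray(predicted).astype(int)
    a = np.asarray(actual).astype(int)
    if p.shape != a.shape:
        raise ValueError("prediction and label vectors differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((p == 1) & (a == 1))),
        fp=int(np.sum((p == 1) & (a == 0))),
        tn=int(np.sum((p == 0) & (a == 0))),
        fn=int(np.sum((p == 0) & (a == 1))))


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Precision, recall, F1 as exact rationals cast to float.

    Degenerate conventions: P = 0 when TP+FP = 0, R = 0 when TP+FN = 0,
    F1 = 0 when P + R = 0.
    """
    p = Fraction(cm.tp, cm.tp + cm.fp) if cm.tp + cm.fp else Fraction(0)
    r = Fraction(cm.tp, cm.tp + cm.fn) if cm.tp + cm.fn else Fraction(0)
    f1 = 2 * p * r / (p + r) if p + r else Fraction(0)
    return float(p), float(r), float(f1)


def choose_threshold(scores: np.ndarray, labels: np.ndarray
                     ) -> tuple[float, float]:
    """Decision threshold maximizing F1 on the given (validation) data.

    Every labeling achievable by a cut of the score axis is evaluated; the
    returned threshold sits at the midpoint of the score gap realizing the
    best cut (ties favor the higher cut), which transfers to held-out data
    better than an extreme tied score. Returns (threshold, F1 at threshold).
    Degenerate single-class labels return (0.5, 0.0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        return 0.5, 0.0
    uniq = np.unique(scores)
    best_thr, best_f1 = 0.5, -1.0
    for i, cut in enumerate(uniq):
        thr = cut if i == 0 else (uniq[i - 1] + cut) / 2.0
        _, _, f1 = metrics(confusion((scores >= cut).astype(int), labels))
        if f1 >= best_f1:
            best_f1, best_thr = f1, float(thr)
    return best_thr, best_f1


# ---------------------------------------------------------------------------
# Rank statistics

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann–Whitney probability with midrank tie handling:
    (concordant + 0.5·tied) / (n_pos · n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined for single-class labels")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cohens_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected agreement with marginal-product expected agreement.

    Returns 1.0 for identical vectors even when the expected agreement is 1
    (both raters constant and equal)."""
    a = np.asarray(labels_a).astype(int)
    b = np.asarray(labels_b).astype(int)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = len(a)
    if n == 0:
        raise ValueError("empty label vectors")
    po = Fraction(int(np.sum(a == b)), n)
    pe = Fraction(0)
    for c in (0, 1):
        pe += Fraction(int(np.sum(a == c)), n) * Fraction(int(np.sum(b == c)), n)
    if pe == 1:
        return 1.0 if po == 1 else 0.0
    return float((po - pe) / (1 - pe))


def chi2_compare(preds_a: np.ndarray, preds_b: np.ndarray,
                 labels: np.ndarray) -> tuple[float, float, bool]:
    """Compare two models' per-note correctness on the same test set.

    Builds the 2×2 table (model × correct/incorrect) and evaluates the
    1-df chi-squared statistic by the closed form
    N(ad - bc)² / ((a+b)(c+d)(a+c)(b+d)), with p from the chi-squared
    survival function. Returns (statistic, p, exact_fallback_flag); the flag
    is set when an expected cell count falls below 1, in which case the
    p-value reported is from Fisher's exact test instead.

    Note: the table treats the two models' correctness vectors as independent
    samples, which is one of several reasonable constructions for paired
    model comparison; report metadata records this choice.
    """
    la = np.asarray(labels).astype(int)
    ca = int(np.sum(np.asarray(preds_a).astype(int) == la))
    cb = int(np.sum(np.asarray(preds_b).astype(int) == la))
    n = len(la)
    a, b = ca, n - ca
    c, d = cb, n - cb
    total = a + b + c + d
    det = a * d - b * c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0, True
    stat = float(Fraction(total * det * det, denom))
    expected_min = min((a + b) * (a + c), (a + b) * (b + d),
                       (c + d) * (a + c), (c + d) * (b + d)) / total
    fallback = expected_min < 1
    if fallback:
        _, p = stats.fisher_exact([[a, b], [c, d]])
    else:
        p = float(stats.chi2.sf(stat, df=1))
    return stat, float(p), fallback


# ---------------------------------------------------------------------------
# Benchmark driver

@dataclass
class EvalReport:
    """Per-phenotype, per-model scores plus comparison metadata."""

    scores: dict[str, dict[str, dict[str, float]]]  # phenotype -> model -> metric
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)
    comparisons: dict[str, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ph, models in self.scores.items():
            for model, ms in models.items():
                rows.append({"phenotype": ph, "model": model, **ms})
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"scores": self.scores, "thresholds": self.thresholds,
                       "comparisons": self.comparisons,
                       "metadata": self.metadata}, fh, indent=2, sort_keys=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def evaluate_scores(probs: np.ndarray, y_val_probs: np.ndarray,
                    y_val: np.ndarray, y_test: np.ndarray
                    ) -> tuple[dict[str, float], float]:
    """Tune the threshold on validation, report P/R/F1/AUC on test."""
    thr, _ = choose_threshold(y_val_probs, y_val)
    labels = (probs >= thr).astype(int)
    p, r, f1 = metrics(confusion(labels, y_test))
    out = {"precision": p, "recall": r, "f1": f1}
    try:
        out["auc"] = roc_auc(probs, y_test)
    except ValueError:
        out["auc"] = float("nan")
    return out, thr
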