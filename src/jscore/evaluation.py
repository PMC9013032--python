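"""Model validation: train/test split, ROC/PR analysis, cutoffs, reports.

The validation protocol mirrors standard severity-score development:
encounters are randomly split 3:1 into training and testing sets, each
model variant is fitted on the training set, the classification cutoff is
chosen on the *training* ROC curve as the threshold minimizing the
Euclidean distance to the ideal (0, 1) corner, and prediction accuracy,
false-positive and false-negative rates are then measured on the held-out
test set at that cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from jscore.codes import ReferenceMaps
from jscore.contrasts import Variant
from jscore.features import Encounter, Phase
from jscore.model import SeverityModel, SeverityResults

__all__ = [
    "SplitSpec",
    "split_train_test",
    "roc_curve",
    "pr_curve",
    "optimal_cutoff",
    "classification_metrics",
    "descriptive_comparison",
    "EvalReport",
    "evaluate_variant",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition specification (3:1 by default)."""

    train_fraction: float = 0.75
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_test(
    encounters: Sequence, spec: SplitSpec = SplitSpec()
) -> tuple[list, list]:
    """Randomly partition encounters into (train, test).

    Exhaustive and disjoint; reproducible under ``spec.seed``.  With
    ``stratified=True`` the split is performed within each discharge-SOI
    high/low stratum.
    """
    items = list(encounters)
    if not items:
        raise ValueError("cannot split an empty encounter list")
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        from jscore.features import binarize_outcome

        train: list = []
        test: list = []
        strata: dict[int, list[int]] = {}
        for i, e in enumerate(items):
            strata.setdefault(binarize_outcome(e.discharge_soi), []).append(i)
        for idx in strata.values():
            perm = rng.permutation(len(idx))
            n_train = round(spec.train_fraction * len(idx))
            chosen = set(idx[j] for j in perm[:n_train])
            train.extend(items[i] for i in idx if i in chosen)
            test.extend(items[i] for i in idx if i not in chosen)
        return train, test
    perm = rng.permutation(len(items))
    n_train = round(spec.train_fraction * len(items))
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return [items[i] for i in train_idx], [items[i] for i in test_idx]


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    return scores, labels


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC sweep over distinct score thresholds.

    Returns ``(fpr, tpr, thresholds, auc)``; the curve starts at (0, 0)
    (threshold above every score) and ends at (1, 1), with tied scores
    grouped at a single threshold.  AUC is the trapezoidal area, equal to
    the Mann–Whitney pairwise concordance probability.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("ROC analysis needs both outcome classes present")
    fpr, tpr, thresholds = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return fpr, tpr, thresholds, auc


def pr_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Precision/recall at each distinct threshold.

    Returns ``(precision, recall, thresholds, pr_auc)`` where ``pr_auc``
    is the average-precision step sum (not a trapezoidal interpolation,
    which is biased for PR curves).
    """
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() == 0:
        raise ValueError("PR analysis needs at least one positive label")
    precision, recall, thresholds = _skm.precision_recall_curve(labels, scores)
    pr_auc = float(_skm.average_precision_score(labels, scores))
    return precision, recall, thresholds, pr_auc


def optimal_cutoff(scores, labels) -> float:
    """Score threshold whose ROC point is closest to the ideal corner.

    Minimizes the Euclidean distance sqrt(FPR^2 + (1 - TPR)^2) between the
    ROC point of "predict high iff score >= t" and the upper-left corner
    (0, 1), scanning every distinct score as a candidate threshold t.
    Ties break toward the larger threshold (the more conservative
    high-severity call).
    """
    scores, labels = _check_scores_labels(scores, labels)
    fpr, tpr, thresholds, _ = roc_curve(scores, labels)
    finite = np.isfinite(thresholds)
    fpr, tpr, thresholds = fpr[finite], tpr[finite], thresholds[finite]
    dist = np.hypot(fpr, 1.0 - tpr)
    best = dist.min()
    candidates = thresholds[dist <= best + 1e-15]
    return float(candidates.max())


def classification_metrics(
    scores, labels, cutoff: float
) -> dict[str, float]:
    """Accuracy, FPR and FNR of the rule "high iff score >= cutoff".

    FPR = FP / (FP + TN); FNR = FN / (FN + TP); a rate with an empty
    denominator is reported as NaN.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = scores >= cutoff
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    n = labels.size
    return {
        "accuracy": (tp + tn) / n,
        "fpr": fp / (fp + tn) if (fp + tn) else float("nan"),
        "fnr": fn / (fn + tp) if (fn + tp) else float("nan"),
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


def descriptive_comparison(
    train: Sequence[Encounter], test: Sequence[Encounter]
) -> dict[str, dict]:
    """Table-1 style comparison of the train and test cohorts.

    Age is summarized by mean/SD and compared with a Welch two-sample
    t-test; sex, race and the admission/discharge SOI distributions by
    counts and proportions with a Pearson chi-square test (no continuity
    correction).  Variables missing from either cohort are skipped with a
    warning.
    """
    if not train or not test:
        raise ValueError("both cohorts must be non-empty")
    report: dict[str, dict] = {
        "n": {"train": len(train), "test": len(test)},
    }
    ages_train = np.array([e.age for e in train], dtype=float)
    ages_test = np.array([e.age for e in test], dtype=float)
    tstat, pval = stats.ttest_ind(ages_train, ages_test, equal_var=False)
    report["age"] = {
        "train_mean": float(ages_train.mean()),
        "train_sd": float(ages_train.std(ddof=1)),
        "test_mean": float(ages_test.mean()),
        "test_sd": float(ages_test.std(ddof=1)),
        "p_value": float(pval),
        "test": "welch_t",
    }
    for name, getter in (
        ("sex", lambda e: e.sex),
        ("race", lambda e: e.race),
        ("admit_soi", lambda e: e.admit_soi),
        ("discharge_soi", lambda e: e.discharge_soi),
    ):
        try:
            values_train = [getter(e) for e in train]
            values_test = [getter(e) for e in test]
        except AttributeError:
            warnings.warn(f"variable {name!r} missing; skipped", stacklevel=2)
            continue
        levels = sorted(set(values_train) | set(values_test), key=str)
        counts = np.array(
            [
                [values_train.count(level) for level in levels],
                [values_test.count(level) for level in levels],
            ],
            dtype=float,
        )
        occupied = counts.sum(axis=0) > 0
        if occupied.sum() < 2 or (counts.sum(axis=1) == 0).any():
            pval = 1.0
        else:
            chi2, pval, _, _ = stats.chi2_contingency(
                counts[:, occupied], correction=False
            )
        report[name] = {
            "levels": [str(level) for level in levels],
            "train_counts": counts[0].astype(int).tolist(),
            "train_proportions": (counts[0] / len(train)).tolist(),
            "test_counts": counts[1].astype(int).tolist(),
            "test_proportions": (counts[1] / len(test)).tolist(),
            "p_value": float(pval),
            "test": "chi_square",
        }
    return report


@dataclass
class EvalReport:
    """Validation report for one (variant, phase) model.

    Curves and AUCs come from the training set; the cutoff is chosen on
    the training ROC; accuracy/FPR/FNR are measured on the test set at
    that cutoff.
    """

    variant: Variant
    phase: Phase
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    roc_auc: float
    pr_auc: float
    optimal_cutoff: float
    accuracy: float
    fpr: float
    fnr: float
    n_train: int
    n_test: int
    train_accuracy: float = float("nan")
    n_predictors: int = 0
    maps_version: str | None = None

    def __post_init__(self) -> None:
        first, last = self.roc_points[0], self.roc_points[-1]
        if first != (0.0, 0.0) or last != (1.0, 1.0):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        xs = np.array(self.roc_points)
        if (np.diff(xs, axis=0) < -1e-12).any():
            raise ValueError("ROC FPR/TPR must be non-decreasing along the curve")

    def to_dict(self) -> dict:
        return {
            "format": "jscore-eval-v1",
            "variant": self.variant,
            "phase": self.phase,
            "n_predictors": self.n_predictors,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "optimal_cutoff": self.optimal_cutoff,
            "accuracy": self.accuracy,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "train_accuracy": self.train_accuracy,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "maps_version": self.maps_version,
            "roc_points": [list(p) for p in self.roc_points],
            "pr_points": [list(p) for p in self.pr_points],
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    def save_curves(self, path: str | Path) -> Path:
        """Export ROC and PR point lists as delimited text for plotting."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("curve\tx\ty\n")
            for x, y in self.roc_points:
                fh.write(f"roc\t{x:.6g}\t{y:.6g}\n")
            for x, y in self.pr_points:
                fh.write(f"pr\t{x:.6g}\t{y:.6g}\n")
        return path


def evaluate_variant(
    train: Sequence[Encounter],
    test: Sequence[Encounter],
    maps: ReferenceMaps,
    variant: Variant,
    phase: Phase,
    *,
    ridge: float = 0.0,
) -> tuple[EvalReport, SeverityResults]:
    """Fit one variant on the training set and validate on the test set.

    Returns the report together with the fitted results so the model can
    be reused for scoring.
    """
    model = SeverityModel.from_encounters(train, maps, variant=variant, phase=phase)
    results = model.fit(ridge=ridge)
    train_scores = results.predict(model.exog)
    train_labels = model.endog.astype(int)
    fpr_arr, tpr_arr, _, roc_auc = roc_curve(train_scores, train_labels)
    precision, recall, _, pr_auc = pr_curve(train_scores, train_labels)
    cutoff = optimal_cutoff(train_scores, train_labels)
    train_metrics = classification_metrics(train_scores, train_labels, cutoff)

    test_model = SeverityModel.from_encounters(test, maps, variant=variant, phase=phase)
    test_scores = results.predict(test_model.exog)
    test_labels = test_model.endog.astype(int)
    test_metrics = classification_metrics(test_scores, test_labels, cutoff)

    report = EvalReport(
        variant=variant,
        phase=phase,
        roc_points=[(float(x), float(y)) for x, y in zip(fpr_arr, tpr_arr)],
        pr_points=[(float(r), float(p)) for p, r in zip(precision, recall)],
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        optimal_cutoff=cutoff,
        accuracy=test_metrics["accuracy"],
        fpr=test_metrics["fpr"],
        fnr=test_metrics["fnr"],
        n_train=len(train),
        n_test=len(test),
        train_accuracy=train_metrics["accuracy"],
        n_predictors=model.design.n_predictors,
        maps_version=maps.version_label,
    )
    return report, results
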