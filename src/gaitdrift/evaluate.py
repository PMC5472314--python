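"""Leave-one-out classification designs, grid search and interval grouping.

Two designs quantify how distinguishable a subject's sessions are:

* **six-session**: one-versus-all multiclass over all 90 trials (chance level
  1/6 = 16.7%);
* **one-on-one**: binary classification for each of the 15 session pairs,
  tagged with the elapsed time between the two sessions and grouped into the
  intervals T1 (10 min), T2 (30-50), T3 (90-110) and T4 (130-150 min).

Rates are 100 * correct / total under leave-one-out cross-validation: each
trial is predicted by a model fitted on all remaining trials of the design.
Hyperparameters are selected by (non-nested, by default) grid search over the
same LOOCV rate; nested selection — an inner LOOCV on every training fold —
is available behind a flag for honest generalisation estimates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .classify import (
    KBDR_ALPHA_GRID,
    KBDR_BETA_GRID,
    KBDR_EXP_GRID,
    SVM_C_GRID,
    KBDRClassifier,
    KernelParams,
    LinearSVMClassifier,
)
from .preprocess import FeatureMatrix, apply_column_transform, fit_column_transform
from .schedule import SessionSchedule, default_schedule

__all__ = [
    "DegenerateDesignError",
    "PairRate",
    "EvaluationReport",
    "GridSearchResult",
    "INTERVALS",
    "DEFAULT_KBDR_GRID",
    "DEFAULT_SVM_GRID",
    "make_classifier",
    "loocv_predictions",
    "loocv_rate",
    "grid_search",
    "run_full_design",
    "group_into_intervals",
]

#: Time-interval grouping of pairwise session gaps, minutes (inclusive bounds).
INTERVALS: tuple[tuple[str, float, float], ...] = (
    ("T1", 10.0, 10.0),
    ("T2", 30.0, 50.0),
    ("T3", 90.0, 110.0),
    ("T4", 130.0, 150.0),
)

DEFAULT_KBDR_GRID: dict = {
    "exp": KBDR_EXP_GRID,
    "alpha": KBDR_ALPHA_GRID,
    "beta": KBDR_BETA_GRID,
}
DEFAULT_SVM_GRID: dict = {"cost": SVM_C_GRID}


class DegenerateDesignError(ValueError):
    """A class has too few trials for leave-one-out evaluation."""


def make_classifier(kind: str, setting):
    """Instantiate a classifier from a grid point / chosen setting."""
    if kind == "kbdr":
        params = setting if isinstance(setting, KernelParams) else KernelParams(**setting)
        return KBDRClassifier(params)
    if kind == "svm":
        cost = setting["cost"] if isinstance(setting, dict) else float(setting)
        return LinearSVMClassifier(cost)
    raise ValueError(f"unknown classifier kind {kind!r}")


def _check_design(labels: np.ndarray) -> None:
    counts = Counter(labels.tolist())
    if len(counts) < 2:
        raise DegenerateDesignError("need at least 2 classes")
    bad = [c for c, n in counts.items() if n < 2]
    if bad:
        raise DegenerateDesignError(
            f"classes {bad} have fewer than 2 trials; LOOCV design invalid"
        )


def loocv_predictions(
    values: np.ndarray,
    labels: np.ndarray,
    kind: str,
    setting,
    fold_safe: bool = False,
    modality: str | None = None,
) -> np.ndarray:
    """Predict every trial from a model fitted on all remaining trials.

    With ``fold_safe=True`` the across-trials preprocessing stages (global
    z-transform for GRF, [-1, 1] column scaling) are re-fitted on each fold's
    training rows only; ``values`` must then be the unscaled matrix and
    ``modality`` given.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    _check_design(labels)
    if fold_safe and modality is None:
        raise ValueError("fold_safe LOOCV needs the modality")
    n = len(labels)
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = values[mask], labels[mask]
        Xte = values[i : i + 1]
        if fold_safe:
            tf = fit_column_transform(Xtr, modality)
            Xtr = apply_column_transform(Xtr, tf)
            Xte = apply_column_transform(Xte, tf)
        clf = make_classifier(kind, setting).fit(Xtr, ytr)
        preds.append(clf.predict(Xte)[0])
    return np.asarray(preds)


def loocv_rate(
    values: np.ndarray,
    labels: np.ndarray,
    kind: str,
    setting,
    fold_safe: bool = False,
    modality: str | None = None,
) -> tuple[float, np.ndarray]:
    """LOOCV classification rate in percent, plus per-trial predictions."""
    preds = loocv_predictions(values, labels, kind, setting, fold_safe, modality)
    rate = 100.0 * float(np.mean(preds == np.asarray(labels)))
    return rate, preds


def _grid_points(kind: str, grid: dict) -> list:
    """Documented grid order: exp, then alpha, then beta; SVM by ascending C."""
    if kind == "kbdr":
        return [
            KernelParams(exp=e, alpha=a, beta=b)
            for e, a, b in product(grid["exp"], grid["alpha"], grid["beta"])
        ]
    return [{"cost": c} for c in grid["cost"]]


@dataclass
class GridSearchResult:
    best: object
    rate: float
    rates: list[float] = field(default_factory=list)
    per_fold: list | None = None  # nested mode: setting chosen in each fold


def _kbdr_grid_rates(
    values: np.ndarray, labels: np.ndarray, points: list[KernelParams]
) -> np.ndarray:
    """Correct counts for every KBDR grid point, caching per-fold linear grams.

    Uses the classifier itself on each fold (with the cached X_tr @ X_tr.T
    passed in), so predictions are bitwise identical to plain refits.
    """
    n = len(labels)
    correct = np.zeros(len(points), dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = values[mask], labels[mask]
        lin = Xtr @ Xtr.T
        Xte = values[i : i + 1]
        for j, params in enumerate(points):
            clf = KBDRClassifier(params)
            clf.fit(Xtr, ytr, _lin_gram=lin)
            if clf.predict(Xte)[0] == labels[i]:
                correct[j] += 1
    return correct


def grid_search(
    values: np.ndarray,
    labels: np.ndarray,
    kind: str,
    grid: dict | None = None,
    nested: bool = False,
) -> GridSearchResult:
    """Select hyperparameters by LOOCV rate.

    Non-nested (default): the setting maximising the LOOCV rate on the full
    design matrix; ties break to the first point in documented grid order.
    Nested: an inner LOOCV grid search on each training fold selects that
    fold's setting; the reported rate is the honest outer rate and ``best``
    is the most frequently selected setting.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    _check_design(labels)
    if grid is None:
        grid = DEFAULT_KBDR_GRID if kind == "kbdr" else DEFAULT_SVM_GRID
    points = _grid_points(kind, grid)
    if not points:
        raise ValueError("empty grid")

    if nested:
        n = len(labels)
        preds, chosen = [], []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            inner = grid_search(values[mask], labels[mask], kind, grid, nested=False)
            clf = make_classifier(kind, inner.best).fit(values[mask], labels[mask])
            preds.append(clf.predict(values[i : i + 1])[0])
            chosen.append(inner.best)
        rate = 100.0 * float(np.mean(np.asarray(preds) == labels))
        best = Counter(
            [repr(c) for c in chosen]
        ).most_common(1)[0][0]
        best_setting = next(c for c in chosen if repr(c) == best)
        return GridSearchResult(best=best_setting, rate=rate, per_fold=chosen)

    if kind == "kbdr":
        correct = _kbdr_grid_rates(values, labels, points)
        rates = 100.0 * correct / len(labels)
    else:
        rates = np.array(
            [loocv_rate(values, labels, kind, p)[0] for p in points]
        )
    j = int(np.argmax(rates))  # first maximum: documented tie-break
    return GridSearchResult(best=points[j], rate=float(rates[j]), rates=rates.tolist())


@dataclass
class PairRate:
    pair: tuple[str, str]
    duration: float
    rate: float


@dataclass
class EvaluationReport:
    """Per-subject, per-modality, per-classifier evaluation results."""

    subject_id: str
    modality: str
    classifier: str
    six_session_rate: float
    correct_count: int
    confusion_matrix: np.ndarray  # rows: true session, cols: predicted
    session_order: tuple[str, ...]
    pairwise_rates: list[PairRate]
    interval_means: dict[str, float]
    chosen_setting: object
    n_trials: int

    def to_dict(self) -> dict:
        chosen = self.chosen_setting
        if isinstance(chosen, KernelParams):
            chosen = {"exp": chosen.exp, "alpha": chosen.alpha, "beta": chosen.beta}
        return {
            "subject": self.subject_id,
            "modality": self.modality,
            "classifier": self.classifier,
            "six_session_rate": self.six_session_rate,
            "correct_count": self.correct_count,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "session_order": list(self.session_order),
            "pairwise": [
                {"pair": list(p.pair), "duration": p.duration, "rate": p.rate}
                for p in self.pairwise_rates
            ],
            "interval_means": self.interval_means,
            "chosen_setting": chosen,
            "n_trials": self.n_trials,
        }


def group_into_intervals(
    pairwise_rates: list[PairRate],
) -> dict[str, float]:
    """Mean rate per time interval; every pair must fall in exactly one."""
    buckets: dict[str, list[float]] = {name: [] for name, _, _ in INTERVALS}
    for pr in pairwise_rates:
        for name, lo, hi in INTERVALS:
            if lo <= pr.duration <= hi:
                buckets[name].append(pr.rate)
                break
        else:
            raise ValueError(
                f"pair {pr.pair} duration {pr.duration} min lies outside all "
                "intervals; schedule mismatch"
            )
    return {
        name: float(np.mean(vals)) for name, vals in buckets.items() if vals
    }


def run_full_design(
    fm: FeatureMatrix,
    classifier: str,
    schedule: SessionSchedule | None = None,
    grid: dict | None = None,
    setting=None,
    nested: bool = False,
    permute_rng: np.random.Generator | None = None,
    fold_safe: bool = False,
) -> EvaluationReport:
    """Six-session and all pairwise designs for one subject.

    Either a fixed ``setting`` (KernelParams / cost) is used throughout, or a
    grid search on the six-session design selects one setting that is reused
    for all 15 pairwise designs.  ``permute_rng`` permutes the session labels
    once before evaluation (chance-level control).
    """
    if schedule is None:
        schedule = default_schedule()
    sessions = schedule.session_ids
    labels = np.asarray(fm.session_labels).copy()
    missing = set(sessions) - set(labels.tolist())
    if missing:
        raise DegenerateDesignError(f"missing sessions: {sorted(missing)}")
    if permute_rng is not None:
        labels = permute_rng.permutation(labels)

    modality = fm.modality
    if setting is None:
        gs = grid_search(fm.values, labels, classifier, grid, nested=nested)
        setting = gs.best
    six_rate, preds = loocv_rate(
        fm.values, labels, classifier, setting, fold_safe, modality
    )
    correct = int(np.sum(preds == labels))
    k = len(sessions)
    confusion = np.zeros((k, k), dtype=int)
    index = {s: i for i, s in enumerate(sessions)}
    for true, pred in zip(labels, preds):
        confusion[index[true], index[pred]] += 1

    pairwise: list[PairRate] = []
    for a, b in combinations(sessions, 2):
        sel = np.isin(labels, [a, b])
        rate, _ = loocv_rate(
            fm.values[sel], labels[sel], classifier, setting, fold_safe, modality
        )
        pairwise.append(PairRate(pair=(a, b), duration=schedule.duration(a, b), rate=rate))

    return EvaluationReport(
        subject_id=fm.subject_id,
        modality=modality,
        classifier=classifier,
        six_session_rate=six_rate,
        correct_count=correct,
        confusion_matrix=confusion,
        session_order=sessions,
        pairwise_rates=pairwise,
        interval_means=group_into_intervals(pairwise),
        chosen_setting=setting,
        n_trials=len(labels),
    )
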